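"""Synthetic paired primary-relapse cohort generator.

Emulates the statistical structure of a matched medulloblastoma
primary/relapse bulk RNA-seq cohort so the whole analysis chain can be
exercised and calibrated without patient data:

* three molecular groups (default 24 SHH, 5 Group 3, 14 Group 4 pairs,
  each patient contributing one primary and one relapse sample),
* every sample is a negative-binomial count profile around a
  library-size-scaled mixture of six cell-type signature profiles
  (A1/A2 cell-cycle, B1/B2 undifferentiated progenitors, C1/C2
  differentiated neuronal-like), with per-sample mixing fractions drawn
  from group- and timepoint-specific Dirichlet distributions,
* programmed relapse shifts: Group 4 relapses raise the A1 (cell-cycle)
  mean fraction 1.5-fold and lower C1; SHH relapses raise B1 and lower
  C1 — the composition effects the deconvolution step must recover,
* designated differentially expressed genes shifted by ``de_log2fc`` in
  relapses; novel-CNV pairs get a multiplicative block effect over one
  contiguous gene run on a synthetic chromosome (relapse only),
* proportional-hazards survival from re-operation whose linear
  predictor is the z-scored unfavorable-metagene mean expression, with
  independent uniform censoring calibrated to the target censor rate,
* shared per-patient SNP genotypes (with VAF read noise) for the
  fingerprint check, and a labeled single-cell reference drawn from the
  same signature profiles.

All randomness flows from one integer seed; a rerun with the same
config is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .matrix_io import ANNOTATION_COLUMNS, CohortAnnotation, ExpressionMatrix, MatrixIOError

CELL_TYPE_LABELS = ("A1", "A2", "B1", "B2", "C1", "C2")
GROUPS = ("SHH", "G3", "G4")
N_SYNTHETIC_CHROMS = 22


def shift_alpha(alpha: np.ndarray, index: int, factor: float) -> np.ndarray:
    """Rescale one Dirichlet component so its *mean* changes exactly by ``factor``.

    The component's concentration is multiplied by ``factor`` and the
    remaining components are shrunk so the total concentration is
    unchanged; since the Dirichlet mean is alpha_i / sum(alpha), the
    target component's mean is then exactly ``factor`` times its old
    mean (requires factor * alpha_i < sum(alpha)).
    """
    return shift_alpha_means(alpha, {index: factor})


def shift_alpha_means(alpha: np.ndarray, factors: Mapping[int, float]) -> np.ndarray:
    """Rescale several Dirichlet components so each target *mean* changes by
    exactly its factor, total concentration preserved.

    Untouched components share the leftover mass proportionally.  A naive
    composition of single-component rescales would perturb earlier
    targets; solving all targets jointly keeps every stated fold change
    exact.
    """
    alpha = np.asarray(alpha, dtype=float)
    total = alpha.sum()
    means = alpha / total
    target = dict(factors)
    shifted_mass = sum(f * means[i] for i, f in target.items())
    rest_mass = sum(m for i, m in enumerate(means) if i not in target)
    if shifted_mass >= 1.0 or rest_mass <= 0:
        raise MatrixIOError(f"factors {target} exceed total probability mass")
    rest_scale = (1.0 - shifted_mass) / rest_mass
    new_means = np.array(
        [target[i] * m if i in target else rest_scale * m for i, m in enumerate(means)]
    )
    return new_means * total


def _default_alphas() -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    # total concentration 56: per-sample fraction SD ~0.04-0.06 per type,
    # the between-tumor composition variability the paired tests assume
    prim = {
        "SHH": np.array([4.0, 4.0, 10.0, 10.0, 14.0, 14.0]),
        "G3": np.array([8.0, 8.0, 8.0, 8.0, 12.0, 12.0]),
        "G4": np.array([8.0, 8.0, 8.0, 8.0, 12.0, 12.0]),
    }
    rel = {
        # progenitors (B1) up, differentiated (C1) down in SHH relapses
        "SHH": shift_alpha_means(prim["SHH"], {2: 1.4, 4: 0.7}),
        # cell-cycle (A1) up exactly 1.5x, differentiated (C1) down in G3/G4
        "G3": shift_alpha_means(prim["G3"], {0: 1.5, 4: 0.7}),
        "G4": shift_alpha_means(prim["G4"], {0: 1.5, 4: 0.7}),
    }
    return prim, rel


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Counts and rates mirror the cohort being emulated: 43 pairs split
    24/5/14 across SHH / Group 3 / Group 4; ~45% of pairs acquiring
    novel CNVs at relapse; a small Group 4 -> Group 3 label-switch rate
    so molecular groups are conserved in ~95% of pairs.
    """

    n_patients_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"SHH": 24, "G3": 5, "G4": 14}
    )
    n_genes: int = 2000
    n_cell_types: int = 6
    cell_type_labels: tuple[str, ...] = CELL_TYPE_LABELS
    dirichlet_alpha_primary: dict[str, np.ndarray] = field(
        default_factory=lambda: _default_alphas()[0]
    )
    dirichlet_alpha_relapse: dict[str, np.ndarray] = field(
        default_factory=lambda: _default_alphas()[1]
    )
    n_de_genes: int = 50
    de_log2fc: float = 1.0
    nb_dispersion: float = 10.0  # NB size; variance = mu + mu^2/size
    libsize_range: tuple[float, float] = (5e5, 2e6)
    cnv_block_effect: float = 1.5
    cnv_pair_fraction: float = 0.45
    group_switch_rate: float = 2.0 / 43.0  # G4 relapses reclassified as G3
    survival_baseline_scale: float = 36.0  # months (exponential baseline mean)
    survival_metagene_loghr: float = 0.8
    censor_rate: float = 0.3
    n_snp_sites: int = 200
    vaf_noise_sd: float = 0.05
    vaf_missing_rate: float = 0.05
    n_cells_per_type: int = 120
    sc_libsize: float = 5000.0
    marker_genes_per_type: int = 60
    marker_fold: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cell_types <= 0 or self.n_snp_sites <= 0:
            raise MatrixIOError("counts must be positive")
        if any(n <= 0 for n in self.n_patients_per_group.values()):
            raise MatrixIOError("patient counts must be positive")
        if not 0 <= self.censor_rate <= 1:
            raise MatrixIOError("censor_rate must lie in [0, 1]")
        if self.n_de_genes > self.n_genes:
            raise MatrixIOError(f"n_de_genes={self.n_de_genes} exceeds n_genes={self.n_genes}")
        block = max(1, int(round(0.05 * self.n_genes)))
        if block > self.n_genes:
            raise MatrixIOError("CNV block larger than gene panel")
        for tag, alphas in (
            ("primary", self.dirichlet_alpha_primary),
            ("relapse", self.dirichlet_alpha_relapse),
        ):
            for g in self.n_patients_per_group:
                a = np.asarray(alphas[g], dtype=float)
                if len(a) != self.n_cell_types or (a <= 0).any():
                    raise MatrixIOError(
                        f"{tag} Dirichlet vector for {g} must be strictly positive, "
                        f"length {self.n_cell_types}"
                    )
        if len(self.cell_type_labels) != self.n_cell_types:
            raise MatrixIOError("cell_type_labels length must equal n_cell_types")


def null_config(**overrides) -> SimulationConfig:
    """A cohort with every programmed signal switched off.

    Relapse Dirichlet parameters equal the primary ones, no DE genes,
    no CNV blocks, no survival effect — the calibration reference for
    type-I error checks.
    """
    base = SimulationConfig(**overrides)
    return replace(
        base,
        dirichlet_alpha_relapse={g: np.asarray(a, float).copy() for g, a in base.dirichlet_alpha_primary.items()},
        n_de_genes=0,
        cnv_pair_fraction=0.0,
        group_switch_rate=0.0,
        survival_metagene_loghr=0.0,
    )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    true_fractions: pd.DataFrame  # samples x cell types
    true_de_genes: dict[str, float]  # gene -> signed log2fc
    true_metagene_genes: list[str]
    true_metagene_beta: float
    pair_assignments: dict[str, tuple[str, str]]
    cnv_pairs: set[str]
    cnv_block_genes: list[str]
    snp_genotypes: pd.DataFrame  # patients x sites, codes {0,1,2}
    signature_profiles: pd.DataFrame  # genes x cell types (relative expression)


def _signature_profiles(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    base = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)
    prof = np.tile(base[:, None], (1, config.n_cell_types)).astype(float)
    # disjoint marker blocks, positions scattered across the panel
    marker_pool = rng.permutation(config.n_genes)
    k = config.marker_genes_per_type
    for t in range(config.n_cell_types):
        idx = marker_pool[t * k : (t + 1) * k]
        prof[idx, t] *= config.marker_fold
    return pd.DataFrame(prof, index=genes, columns=list(config.cell_type_labels))


def _gene_info(config: SimulationConfig, rng: np.random.Generator, genes: list[str]) -> pd.DataFrame:
    lengths = np.exp(
        rng.uniform(math.log(300.0), math.log(30000.0), size=config.n_genes)
    ).astype(int)
    block = math.ceil(config.n_genes / N_SYNTHETIC_CHROMS)
    chroms = [f"chr{(i // block) + 1}" for i in range(config.n_genes)]
    return pd.DataFrame(
        {"gene_id": genes, "length_bp": lengths, "chrom": chroms}
    ).set_index("gene_id")


def _censor_horizon(mean_time: float, censor_rate: float) -> float:
    """Uniform-censoring horizon c with P(T > C) = censor_rate for exp(T)."""
    if censor_rate <= 0:
        return math.inf
    if censor_rate >= 1:
        return 1e-9

    def prob_censored(c: float) -> float:
        return mean_time / c * (1.0 - math.exp(-c / mean_time)) - censor_rate

    return float(optimize.brentq(prob_censored, 1e-6 * mean_time, 1e4 * mean_time))


def _draw_age(group: str, rng: np.random.Generator) -> float:
    if group == "SHH":
        # bimodal: infant and child/adult modes
        if rng.random() < 0.4:
            return float(max(0.3, rng.normal(2.5, 1.0)))
        return float(max(4.0, rng.normal(22.0, 8.0)))
    return float(max(1.0, rng.normal(8.0, 3.0)))


_RELAPSE_PATTERN_P = {
    "SHH": {"local": 0.5, "distant": 1.0 / 6.0, "combined": 1.0 / 3.0},
    "G3": {"local": 0.0, "distant": 0.7, "combined": 0.3},
    "G4": {"local": 0.0, "distant": 0.5, "combined": 0.5},
}


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortAnnotation, SyntheticTruth]:
    """Generate one paired cohort.

    Returns (counts, gene_info, annotation, truth).  Counts are
    non-negative integers: per sample the expected expression is a
    library-size-scaled mixture of the cell-type signature profiles at
    the sample's Dirichlet-drawn fractions, with negative-binomial
    noise; programmed effects are layered on top of the relapse
    expectation before noise.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    signature = _signature_profiles(config, rng)
    genes = list(signature.index)
    gene_info = _gene_info(config, rng, genes)

    # ---- patients, groups, clinical covariates -------------------------
    patients, groups = [], []
    for g in GROUPS:
        n = config.n_patients_per_group.get(g, 0)
        for i in range(n):
            patients.append(f"{g}_p{i:02d}")
            groups.append(g)
    n_patients = len(patients)
    ages = np.array([_draw_age(g, rng) for g in groups])
    sexes = np.where(rng.random(n_patients) < 0.65, "M", "F")
    patterns = [
        rng.choice(
            list(_RELAPSE_PATTERN_P[g]), p=list(_RELAPSE_PATTERN_P[g].values())
        )
        for g in groups
    ]
    m_stages = [
        rng.choice(["M0", "M1", "M2", "M3"], p=[0.6, 0.1, 0.15, 0.15]) for _ in groups
    ]

    # novel-CNV pairs: overall fraction fixed; within SHH weighted toward
    # the young (acquired CNVs drive the age-variance association)
    n_cnv = int(round(config.cnv_pair_fraction * n_patients))
    weights = np.ones(n_patients)
    for i, g in enumerate(groups):
        if g == "SHH":
            weights[i] = 1.0 / (1.0 + ages[i] / 5.0)
    weights /= weights.sum()
    cnv_idx = (
        rng.choice(n_patients, size=n_cnv, replace=False, p=weights)
        if n_cnv
        else np.array([], dtype=int)
    )
    cnv_pairs = {patients[i] for i in cnv_idx}

    # CNV block: contiguous run of 5% of genes on one synthetic chromosome
    block_size = max(1, int(round(0.05 * config.n_genes)))
    chrom_of = gene_info["chrom"].to_numpy()
    start = int(rng.integers(0, config.n_genes - block_size + 1))
    block_chrom = chrom_of[start]
    same = np.where(chrom_of == block_chrom)[0]
    block_idx = same[: block_size] if len(same) >= block_size else same
    cnv_block_genes = [genes[i] for i in block_idx]

    # DE genes: outside the CNV block, half up / half down at relapse
    candidates = np.setdiff1d(np.arange(config.n_genes), block_idx)
    de_idx = rng.choice(candidates, size=config.n_de_genes, replace=False)
    signs = np.ones(config.n_de_genes)
    signs[config.n_de_genes // 2 :] = -1.0
    true_de = {genes[i]: float(s * config.de_log2fc) for i, s in zip(de_idx, signs)}
    up_de = [g for g, s in true_de.items() if s > 0]
    metagene_genes = sorted(up_de)[: max(1, len(up_de) // 2)] if up_de else []

    # ---- expression ----------------------------------------------------
    sample_ids, frac_rows, count_cols = [], {}, {}
    ann_rows = []
    sig_values = signature.to_numpy()
    group_at_relapse = list(groups)
    switch_mask = (np.asarray(groups) == "G4") & (
        rng.random(n_patients) < config.group_switch_rate
    )
    for i in np.where(switch_mask)[0]:
        group_at_relapse[i] = "G3"

    for i, patient in enumerate(patients):
        g = groups[i]
        for timepoint in ("primary", "relapse"):
            sid = f"{patient}_{'P' if timepoint == 'primary' else 'R'}"
            alpha = (
                config.dirichlet_alpha_primary[g]
                if timepoint == "primary"
                else config.dirichlet_alpha_relapse[g]
            )
            frac = rng.dirichlet(np.asarray(alpha, float))
            frac_rows[sid] = frac
            expected = sig_values @ frac
            if timepoint == "relapse":
                for gi, s in zip(de_idx, signs):
                    expected[gi] *= 2.0 ** (s * config.de_log2fc)
                if patient in cnv_pairs:
                    expected[block_idx] *= config.cnv_block_effect
            expected = expected / expected.sum()
            libsize = rng.uniform(*config.libsize_range)
            mu = expected * libsize
            k = config.nb_dispersion
            counts = rng.negative_binomial(k, k / (k + mu))
            count_cols[sid] = counts
            sample_ids.append(sid)
            ann_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": patient,
                    "timepoint": timepoint,
                    "group": g if timepoint == "primary" else group_at_relapse[i],
                    "subgroup": f"{g}_sub{1 + i % 2}",
                    "age_years": round(float(ages[i]), 1),
                    "sex": sexes[i],
                    "relapse_pattern": patterns[i],
                    "m_stage": m_stages[i],
                    "novel_cnv": int(patient in cnv_pairs),
                }
            )

    counts_df = pd.DataFrame(count_cols, index=pd.Index(genes, name="gene_id"))
    counts = ExpressionMatrix(counts_df, scale="counts")
    fractions = pd.DataFrame.from_dict(frac_rows, orient="index", columns=list(config.cell_type_labels))

    # ---- survival (clock starts at re-operation) -----------------------
    libsizes = counts_df.sum(axis=0)
    log_cpm = np.log2(counts_df.mul(1e6).div(libsizes, axis=1) + 1.0)
    relapse_samples = [f"{p}_R" for p in patients]
    if metagene_genes and config.survival_metagene_loghr != 0:
        score = log_cpm.loc[metagene_genes, relapse_samples].mean(axis=0)
        z = (score - score.mean()) / (score.std(ddof=1) or 1.0)
        lp = config.survival_metagene_loghr * z.to_numpy()
    else:
        lp = np.zeros(n_patients)
    os_scale = config.survival_baseline_scale * np.exp(-lp)
    os_time = rng.exponential(os_scale)
    horizon = _censor_horizon(config.survival_baseline_scale, config.censor_rate)
    censor_at = (
        rng.uniform(0.0, horizon, size=n_patients)
        if math.isfinite(horizon)
        else np.full(n_patients, math.inf)
    )
    os_event = (os_time <= censor_at).astype(int)
    os_months = np.minimum(os_time, censor_at)
    pfs_months = rng.exponential(30.0, size=n_patients)
    pfs_event = np.ones(n_patients, dtype=int)  # every patient relapsed

    for row in ann_rows:
        i = patients.index(row["patient_id"])
        row.update(
            {
                "pfs_months": round(float(pfs_months[i]), 2),
                "os_months": round(float(os_months[i]), 2),
                "os_event": int(os_event[i]),
                "pfs_event": int(pfs_event[i]),
            }
        )
    ann = CohortAnnotation(pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS))

    # ---- SNP fingerprints ----------------------------------------------
    maf = rng.uniform(0.1, 0.5, size=config.n_snp_sites)
    genotypes = rng.binomial(2, maf[None, :].repeat(n_patients, axis=0))
    snp = pd.DataFrame(
        genotypes,
        index=pd.Index(patients, name="patient_id"),
        columns=[f"site{j:04d}" for j in range(config.n_snp_sites)],
    )

    truth = SyntheticTruth(
        true_fractions=fractions,
        true_de_genes=true_de,
        true_metagene_genes=metagene_genes,
        true_metagene_beta=config.survival_metagene_loghr,
        pair_assignments={p: (f"{p}_P", f"{p}_R") for p in patients},
        cnv_pairs=cnv_pairs,
        cnv_block_genes=cnv_block_genes,
        snp_genotypes=snp,
        signature_profiles=signature,
    )
    return counts, gene_info, ann, truth


def simulate_vaf_table(
    truth: SyntheticTruth, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Site x sample VAF table: genotype/2 plus read noise, shared per patient."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = {}
    for patient, (prim, rel) in sorted(truth.pair_assignments.items()):
        geno = truth.snp_genotypes.loc[patient].to_numpy(dtype=float)
        for sid in (prim, rel):
            vaf = geno / 2.0 + rng.normal(0.0, config.vaf_noise_sd, size=len(geno))
            vaf = np.clip(vaf, 0.0, 1.0)
            miss = rng.random(len(geno)) < config.vaf_missing_rate
            vaf[miss] = np.nan
            rows[sid] = vaf
    return pd.DataFrame(rows, index=truth.snp_genotypes.columns)


def simulate_sc_reference(
    config: SimulationConfig | None = None,
    signature: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Labeled single-cell reference drawn from the cohort's signature profiles.

    Per cell, counts are negative-binomial around the cell's type profile
    scaled to the single-cell library size.  At least 100 cells per type
    by default.  Passing the cohort's ``truth.signature_profiles`` makes
    bulk and reference share a generative platform.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 7919)
    if signature is None:
        # same signature profiles the cohort generator would draw for this seed
        signature = _signature_profiles(config, np.random.default_rng(config.seed))
    cols, labels = {}, {}
    k = config.nb_dispersion
    for t, ct in enumerate(signature.columns):
        profile = signature[ct].to_numpy(dtype=float)
        profile = profile / profile.sum()
        mu = profile * config.sc_libsize
        for c in range(config.n_cells_per_type):
            cid = f"{ct}_c{c:04d}"
            cols[cid] = rng.negative_binomial(k, k / (k + mu))
            labels[cid] = ct
    counts = ExpressionMatrix(
        pd.DataFrame(cols, index=pd.Index(signature.index, name="gene_id")),
        scale="counts",
    )
    return counts, pd.Series(labels, name="cell_type")
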