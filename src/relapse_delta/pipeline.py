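"""End-to-end orchestration of the paired-cohort workflow.

Stages (simulate -> normalize -> variance -> dge -> deconvolution ->
survival -> fingerprint) run in dependency order from a single config;
each produced file is SHA-256 hashed into a manifest so a rerun with
the same seed can be verified bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import composition, fingerprint, matrix_io, normalization, pair_variance, paired_dge, survival
from .matrix_io import MatrixIOError
from .pair_variance import AnalysisConfig
from .synthetic_cohort import SimulationConfig, simulate_cohort, simulate_sc_reference, simulate_vaf_table

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "normalize", "variance", "dge", "deconvolution", "survival", "fingerprint")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    dge_groups: tuple[str, ...] = ("G3", "G4")
    alpha: float = 0.05
    top_k: int = 20
    markers_per_type: int = 50
    n_perm: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        analysis = raw.pop("analysis", None)
        cfg = cls(
            out_dir=Path(raw.pop("out_dir", "pipeline_out")),
            seed=int(raw.pop("seed", 0)),
            stages=tuple(raw.pop("stages", ALL_STAGES)),
            **raw,
        )
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        if analysis:
            cfg.analysis = AnalysisConfig(**analysis)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the enabled stages; return {relative path: sha256} manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise MatrixIOError(f"unknown stages: {sorted(unknown)}")
    produced: list[Path] = []

    sim = config.simulation or SimulationConfig(seed=config.seed)
    counts = gene_info = ann = truth = None
    log_mat = cpm_mat = None

    def _track(path: Path) -> None:
        produced.append(path)

    if "simulate" in config.stages:
        logger.info("stage simulate")
        counts, gene_info, ann, truth = simulate_cohort(sim)
        matrix_io.write_expression(counts, out / "counts.tsv")
        matrix_io.write_gene_info(gene_info, out / "gene_info.tsv")
        matrix_io.write_annotation(ann, out / "annotation.tsv")
        vaf = simulate_vaf_table(truth, sim)
        vaf.rename_axis("site_id").to_csv(out / "vaf.tsv", sep="\t")
        sc_counts, labels = simulate_sc_reference(sim, truth.signature_profiles)
        matrix_io.write_expression(sc_counts, out / "sc_counts.tsv")
        labels.rename_axis("cell_id").to_frame().to_csv(out / "sc_labels.tsv", sep="\t")
        for name in ("counts.tsv", "gene_info.tsv", "annotation.tsv", "vaf.tsv", "sc_counts.tsv", "sc_labels.tsv"):
            _track(out / name)

    def _need(obj, stage: str, what: str):
        if obj is None:
            raise MatrixIOError(f"stage {stage!r} needs {what}; enable the simulate stage or provide inputs")
        return obj

    if "normalize" in config.stages:
        logger.info("stage normalize")
        counts = _need(counts, "normalize", "counts")
        log_mat = normalization.log2_rpkm(counts, gene_info)
        cpm_mat = normalization.cpm(counts)
        matrix_io.write_expression(log_mat, out / "log2rpkm.tsv")
        matrix_io.write_expression(cpm_mat, out / "cpm.tsv")
        _track(out / "log2rpkm.tsv")
        _track(out / "cpm.tsv")

    if "variance" in config.stages:
        logger.info("stage variance")
        log_mat = _need(log_mat, "variance", "log2 RPKM matrix")
        rows = []
        for tag, sub_ann in (
            ("all", ann),
            ("SHH", ann.subset_groups(["SHH"])),
            ("G3G4", ann.subset_groups(["G3", "G4"])),
        ):
            res = pair_variance.analyze_cohort(log_mat, sub_ann, config.analysis, tag)
            res.scores.rename_axis("sample_id").to_csv(out / f"pca_scores_{tag}.tsv", sep="\t")
            res.distances.rename_axis("patient_id").to_csv(out / f"distances_{tag}.tsv", sep="\t")
            _track(out / f"pca_scores_{tag}.tsv")
            _track(out / f"distances_{tag}.tsv")
            if tag == "all":
                grouping = ann.table.drop_duplicates("patient_id").set_index("patient_id")["group"]
                comp = pair_variance.compare_groups(res.distances, grouping)
                comp.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
                _track(out / "group_comparisons.tsv")

    dge_tables = {}
    if "dge" in config.stages:
        logger.info("stage dge")
        log_mat = _need(log_mat, "dge", "log2 RPKM matrix")
        sub_ann = ann.subset_groups(config.dge_groups)
        pairs = matrix_io.pair_index(sub_ann)
        _, table = paired_dge.run_paired_dge(
            log_mat.subset_samples([s for p in pairs for s in p[1:]]), pairs
        )
        table.to_csv(out / "dge.tsv", sep="\t")
        _track(out / "dge.tsv")
        dge_tables["main"] = table

    fracs = None
    if "deconvolution" in config.stages:
        logger.info("stage deconvolution")
        cpm_mat = _need(cpm_mat, "deconvolution", "CPM matrix")
        sc_counts, labels = simulate_sc_reference(sim, truth.signature_profiles if truth else None)
        sig = composition.build_signature(sc_counts, labels, config.markers_per_type)
        fracs = composition.deconvolve_nnls(cpm_mat, sig, n_perm=config.n_perm, seed=config.seed)
        fracs.to_csv(out / "fractions.tsv", sep="\t")
        comp = composition.compare_fractions(fracs, ann)
        comp.to_csv(out / "fraction_comparisons.tsv", sep="\t", index=False)
        _track(out / "fractions.tsv")
        _track(out / "fraction_comparisons.tsv")

    if "survival" in config.stages and dge_tables:
        logger.info("stage survival")
        table = dge_tables["main"]
        degs = paired_dge.select_degs(table, config.alpha, config.top_k)
        sub_ann = ann.subset_groups(config.dge_groups)
        rel = sub_ann.table[sub_ann.table["timepoint"] == "relapse"]
        records = pd.DataFrame(
            {"time": rel["os_months"].to_numpy(), "event": rel["os_event"].to_numpy()},
            index=rel["sample_id"],
        )
        unfav, fav, scan_table = survival.build_metagene(
            log_mat, records, degs["top_up"], degs["top_down"], config.alpha
        )
        scan_table.to_csv(out / "kaplan_scans.tsv", sep="\t", index=False)
        _track(out / "kaplan_scans.tsv")
        meta_rows = []
        for mset in (unfav, fav):
            if mset.genes:
                score = mset.score(log_mat.subset_samples(list(records.index)))
                cox_in = records.copy()
                cox_in[mset.name] = score
                fit = survival.cox_fit(cox_in, [mset.name])
                meta_rows.append(
                    {
                        "metagene": mset.name,
                        "n_genes": len(mset.genes),
                        "genes": ",".join(mset.genes),
                        "cox_beta": fit.loc[mset.name, "beta"],
                        "cox_p": fit.loc[mset.name, "p"],
                    }
                )
        pd.DataFrame(meta_rows).to_csv(out / "metagenes.tsv", sep="\t", index=False)
        _track(out / "metagenes.tsv")

    if "fingerprint" in config.stages:
        logger.info("stage fingerprint")
        truth_ = _need(truth, "fingerprint", "simulated truth")
        vaf = simulate_vaf_table(truth_, sim)
        report = fingerprint.verify_cohort(vaf, ann)
        report.to_csv(out / "fingerprint.tsv", sep="\t", index=False)
        _track(out / "fingerprint.tsv")

    manifest = {str(p.relative_to(out)): _sha256(p) for p in produced}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
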