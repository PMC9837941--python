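"""Per-patient transcriptome variance in principal-component space.

The headline statistic: restrict log2 RPKM expression to the top highly
variable genes, project samples onto the leading principal components,
and measure each patient's primary-to-relapse shift as the Euclidean
distance between the two sample scores in that joint PC space.  Group
comparisons use Welch t-tests; covariate association uses Pearson
correlation (Spearman available).

Subset analyses (e.g. one molecular group) re-select HVGs and refit the
PCA within the subset, so results never depend on excluded samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import CohortAnnotation, ExpressionMatrix, MatrixIOError, pair_index


@dataclass
class AnalysisConfig:
    """Knobs for the variance analysis.

    n_hvg
        Number of highly variable genes retained (by cross-sample
        variance of log2 RPKM).
    n_pcs
        Number of leading principal components forming the joint space
        in which pair distances are measured.
    center / scale_genes
        Gene-wise centering (always sensible) and optional unit scaling.
        Scaling is off by default: HVG selection deliberately keeps
        high-variance genes, and scaling would undo that emphasis.
    weight_by_variance
        If True, PC scores are divided through by their singular values
        before distances are taken (variance-weighted space).  Raw
        scores are the default.
    """

    n_hvg: int = 500
    n_pcs: int = 3
    center: bool = True
    scale_genes: bool = False
    weight_by_variance: bool = False


@dataclass
class PairVarianceResult:
    scores: pd.DataFrame  # samples x n_pcs
    variance_pct: np.ndarray
    distances: pd.Series  # patient -> distance
    cohort_tag: str = ""
    hvg: list[str] = field(default_factory=list)


def select_hvg(mat: ExpressionMatrix, n_hvg: int = 500) -> list[str]:
    """Top ``n_hvg`` genes by sample variance, ties broken by gene id.

    Deterministic: sorted by (-variance, gene id).
    """
    if n_hvg > mat.n_genes:
        raise MatrixIOError(f"n_hvg={n_hvg} exceeds {mat.n_genes} genes")
    var = mat.values.var(axis=1, ddof=1)
    order = sorted(zip(-var.to_numpy(), var.index.astype(str)))
    return [g for _, g in order[:n_hvg]]


def pca_scores(
    mat: ExpressionMatrix, config: AnalysisConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the top principal components.

    Genes are centered (and unit-scaled iff ``scale_genes``); the SVD of
    the samples x genes matrix gives scores U*S.  ``variance_pct[k]`` is
    100 * sigma_k^2 / sum(sigma^2) over the full spectrum.  Signs are
    fixed by forcing the largest-|loading| entry of each component
    positive, so output is reproducible across SVD implementations.
    """
    X = mat.values.to_numpy(dtype=float).T  # samples x genes
    n_samples = X.shape[0]
    if config.n_pcs > n_samples - 1:
        raise MatrixIOError(f"n_pcs={config.n_pcs} exceeds n_samples-1={n_samples - 1}")
    if config.center:
        X = X - X.mean(axis=0)
    if config.scale_genes:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if config.n_pcs > rank:
        raise MatrixIOError(f"n_pcs={config.n_pcs} exceeds matrix rank {rank}")
    # deterministic sign: largest-magnitude loading of each PC positive
    for k in range(config.n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, : config.n_pcs] * S[: config.n_pcs]
    if config.weight_by_variance:
        scores = scores / S[: config.n_pcs]
    total = float(np.sum(S**2))
    variance_pct = 100.0 * S[: config.n_pcs] ** 2 / total
    frame = pd.DataFrame(
        scores,
        index=mat.sample_ids,
        columns=[f"PC{k + 1}" for k in range(config.n_pcs)],
    )
    return frame, variance_pct


def pair_distances(
    scores: pd.DataFrame, pairs: list[tuple[str, str, str]]
) -> pd.Series:
    """Euclidean distance between each patient's two sample scores."""
    dists = {}
    for patient, prim, rel in pairs:
        for s in (prim, rel):
            if s not in scores.index:
                raise MatrixIOError(f"sample {s!r} of patient {patient!r} missing from scores")
        delta = scores.loc[prim].to_numpy() - scores.loc[rel].to_numpy()
        dists[patient] = float(np.linalg.norm(delta))
    return pd.Series(dists, name="distance").sort_index()


def analyze_cohort(
    mat: ExpressionMatrix,
    ann: CohortAnnotation,
    config: AnalysisConfig | None = None,
    cohort_tag: str = "all",
) -> PairVarianceResult:
    """HVG selection -> PCA -> pair distances for one sample subset."""
    config = config or AnalysisConfig()
    sub = mat.subset_samples([s for s in ann.sample_ids if s in mat.values.columns])
    hvg = select_hvg(sub, min(config.n_hvg, sub.n_genes))
    scores, variance_pct = pca_scores(sub.subset_genes(hvg), config)
    pairs = pair_index(ann)
    distances = pair_distances(scores, pairs)
    return PairVarianceResult(scores, variance_pct, distances, cohort_tag, hvg)


def compare_groups(
    distances: pd.Series, grouping: pd.Series | dict[str, str]
) -> pd.DataFrame:
    """Welch two-sample t-tests of pair distances between groups.

    ``grouping`` maps patient id to a group label.  For more than two
    groups every pairwise comparison is reported.  Groups with fewer
    than two patients are excluded with a warning column in the output.
    """
    grouping = pd.Series(grouping)
    common = distances.index.intersection(grouping.index)
    by_group: dict[str, np.ndarray] = {}
    for g, members in grouping.loc[common].groupby(grouping.loc[common]):
        by_group[str(g)] = distances.loc[members.index].to_numpy()
    usable = {g: v for g, v in by_group.items() if len(v) >= 2}
    skipped = sorted(set(by_group) - set(usable))
    rows = []
    for g1, g2 in combinations(sorted(usable), 2):
        x, y = usable[g1], usable[g2]
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean1": float(np.mean(x)),
                "mean2": float(np.mean(y)),
                "n1": len(x),
                "n2": len(y),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(
        rows, columns=["group1", "group2", "mean1", "mean2", "n1", "n2", "t", "p"]
    )
    out.attrs["skipped_groups"] = skipped
    return out


def correlate_covariate(
    distances: pd.Series,
    covariate: pd.Series | dict[str, float],
    method: str = "pearson",
) -> dict[str, float]:
    """Correlation between pair distances and a per-patient covariate.

    Pearson (default) with the two-sided t-based p-value; ``method=
    'spearman'`` for the rank version.  Patients missing either value
    are dropped.
    """
    covariate = pd.Series(covariate, dtype=float)
    common = distances.index.intersection(covariate.dropna().index)
    if len(common) < 3:
        raise MatrixIOError(f"need >=3 complete observations, have {len(common)}")
    x = distances.loc[common].to_numpy(dtype=float)
    y = covariate.loc[common].to_numpy(dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        raise MatrixIOError("zero-variance input to correlation")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise MatrixIOError(f"unknown correlation method {method!r}")
    return {"r": float(r), "p": float(p), "n": int(len(common))}
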