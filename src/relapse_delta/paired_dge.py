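"""Pair-blocked moderated differential expression.

Matched primary/relapse samples are collapsed to within-pair differences
(relapse minus primary, log2 RPKM), which turns the paired two-level
design into a one-sample problem: for balanced pairs the within-pair
difference model and a two-level linear model with a patient blocking
factor give the identical estimand.  Gene-wise variances are then shrunk
toward a global prior by empirical Bayes: each residual variance s_g^2
(d_g = n_pairs - 1 df) is assumed scaled-inverse-chi-square around a
prior (d_0, s_0^2) whose hyperparameters are estimated by moment
matching on log s_g^2 using digamma/trigamma identities, and the
moderated t uses the posterior variance

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

with d_0 + d_g degrees of freedom (standard normal when d_0 is
infinite).  This is the classic moderation payoff: stable inference at
a handful of pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix_io import ExpressionMatrix, GeneSetCollection, MatrixIOError


@dataclass
class EBayesFit:
    """Empirical-Bayes variance prior and per-gene residual variances."""

    d0: float  # prior df, may be math.inf
    s0_sq: float  # prior variance
    s_g_sq: np.ndarray
    d_g: float  # residual df (n_pairs - 1)

    @property
    def posterior_var(self) -> np.ndarray:
        if math.isinf(self.d0):
            return np.full_like(self.s_g_sq, self.s0_sq)
        return (self.d0 * self.s0_sq + self.d_g * self.s_g_sq) / (self.d0 + self.d_g)


def paired_differences(
    mat: ExpressionMatrix, pairs: list[tuple[str, str, str]]
) -> pd.DataFrame:
    """Patients x genes matrix of relapse-minus-primary differences."""
    if not pairs:
        raise MatrixIOError("no complete pairs")
    rows = {}
    for patient, prim, rel in pairs:
        for s in (prim, rel):
            if s not in mat.values.columns:
                raise MatrixIOError(f"sample {s!r} of patient {patient!r} missing from matrix")
        rows[patient] = mat.values[rel].to_numpy() - mat.values[prim].to_numpy()
    return pd.DataFrame.from_dict(rows, orient="index", columns=mat.gene_ids)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a 1/x-scaled step)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_variance_prior(s_g_sq: np.ndarray, d_g: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-inverse-chi-square variance prior.

    Works on z_g = log s_g^2, whose mean and variance under the model are
    analytic in digamma/trigamma terms; inverting the trigamma relation
    yields the prior df d_0, then the prior variance s_0^2 follows from
    the mean.  A non-positive excess variance means the observed spread
    is no wider than sampling noise alone: d_0 = +inf and s_0^2 is the
    common variance.
    """
    s = np.asarray(s_g_sq, dtype=float)
    positive = s[s > 0]
    if positive.size < 2:
        raise MatrixIOError("all gene variances zero; cannot fit variance prior")
    z = np.log(positive)
    e = z - float(special.digamma(d_g / 2.0)) + math.log(d_g / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d_g / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def ebayes_moderated_t(
    diffs: pd.DataFrame,
    d0_override: float | None = None,
    s0_sq_override: float | None = None,
) -> tuple[EBayesFit, pd.DataFrame]:
    """Moderated one-sample t-test on within-pair differences.

    Returns the prior fit and a per-gene table with log2fc (mean paired
    difference), t_mod, df_total and two-sided p_raw.  Overrides for the
    prior exist for the degenerate limits (d0=0 reproduces the ordinary
    paired t; d0=inf pools all genes to the prior variance).
    """
    n = diffs.shape[0]
    if n < 3:
        raise MatrixIOError(f"need >=3 pairs, have {n}")
    X = diffs.to_numpy(dtype=float)
    m_g = X.mean(axis=0)
    s_g_sq = X.var(axis=0, ddof=1)
    d_g = float(n - 1)
    if d0_override is not None:
        d0 = float(d0_override)
        if s0_sq_override is not None:
            s0_sq = float(s0_sq_override)
        elif math.isinf(d0) or d0 == 0:
            s0_sq = float(np.mean(s_g_sq[s_g_sq > 0])) if (s_g_sq > 0).any() else 1.0
        else:
            _, s0_sq = fit_variance_prior(s_g_sq, d_g)
    else:
        if diffs.shape[1] < 10:
            raise MatrixIOError("need >=10 genes to estimate the variance prior")
        d0, s0_sq = fit_variance_prior(s_g_sq, d_g)
    fit = EBayesFit(d0=d0, s0_sq=s0_sq, s_g_sq=s_g_sq, d_g=d_g)
    if d0 == 0:
        post_var = s_g_sq.copy()
        df_total = d_g
    else:
        post_var = fit.posterior_var
        df_total = d0 + d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = m_g / np.sqrt(post_var / n)
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    table = pd.DataFrame(
        {
            "log2fc": m_g,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "direction": np.where(m_g >= 0, "up_in_relapse", "down_in_relapse"),
        },
        index=pd.Index(diffs.columns, name="gene_id"),
    )
    return fit, table


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise MatrixIOError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_paired_dge(
    mat: ExpressionMatrix, pairs: list[tuple[str, str, str]]
) -> tuple[EBayesFit, pd.DataFrame]:
    """Full DGE table: paired differences -> moderated t -> BH adjust."""
    diffs = paired_differences(mat, pairs)
    fit, table = ebayes_moderated_t(diffs)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    return fit, _sort_dge(table)


def _sort_dge(table: pd.DataFrame) -> pd.DataFrame:
    tmp = table.copy()
    tmp["_abs_fc"] = -tmp["log2fc"].abs()
    tmp = tmp.sort_values(["p_adj", "_abs_fc", "gene_id"], kind="mergesort")
    return tmp.drop(columns="_abs_fc")


def select_degs(
    table: pd.DataFrame, alpha: float = 0.05, top_k: int = 20
) -> dict[str, list[str]]:
    """Split significant genes by direction; extract top-k of each side.

    Ordering: ascending adjusted p, then |log2fc| descending, then gene
    id — fully deterministic.
    """
    if "p_adj" not in table.columns:
        raise MatrixIOError("table lacks adjusted p-values")
    ordered = _sort_dge(table)
    sig = ordered[ordered["p_adj"] < alpha]
    up = sig.index[sig["direction"] == "up_in_relapse"].tolist()
    down = sig.index[sig["direction"] == "down_in_relapse"].tolist()
    return {
        "up": up,
        "down": down,
        "top_up": up[:top_k],
        "top_down": down[:top_k],
    }


def ora_hypergeometric(
    hits: set[str] | list[str],
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
) -> dict[str, float]:
    """Upper-tail hypergeometric over-representation of ``hits`` in ``gene_set``.

    p = P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|set|, n=|hits|).
    """
    universe = set(universe)
    if not universe:
        raise MatrixIOError("empty universe")
    hits = set(hits) & universe
    members = set(gene_set) & universe
    overlap = len(hits & members)
    N, K, n = len(universe), len(members), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    expected = K * n / N if N else 0.0
    fold = overlap / expected if expected > 0 else math.nan
    return {"overlap": overlap, "set_size": K, "n_hits": n, "p": min(p, 1.0), "fold_enrichment": fold}


def ora_collection(
    hits: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Over-representation across a GMT collection with BH adjustment."""
    rows = {}
    for name, members in collection:
        rows[name] = ora_hypergeometric(hits, members, universe)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values(["p_adj", "p"]).rename_axis("set_name")
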