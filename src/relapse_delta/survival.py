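"""Survival analysis: Kaplan-Meier, log-rank, cutoff scans, metagenes, Cox.

Estimation and testing are delegated to lifelines (product-limit
estimator, log-rank statistic, Cox partial likelihood with Efron tie
handling); this module adds the study-specific machinery on top:

* ``kaplan_scan`` — for one gene, every distinct expression value inside
  a quantile window is tried as a high/low cutoff, the best split is
  the one minimizing the raw log-rank p, and a Bonferroni factor equal
  to the number of cutoffs actually tested corrects the optimism of the
  scan.  The scan depends on expression only through ranks, so it is
  invariant to monotone transforms.
* metagene construction — candidate relapse-regulated genes whose scan
  survives correction and whose risk direction is concordant with their
  differential-expression direction are pooled into an "unfavorable"
  (relapse-up, high expression harmful) and a "favorable" (relapse-down,
  high expression protective) set; the per-sample metagene score is the
  mean z-scored log2 RPKM over members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .matrix_io import ExpressionMatrix, MatrixIOError

logger = logging.getLogger(__name__)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise MatrixIOError(f"survival records need a {col!r} column")
    rec = records.dropna(subset=["time", "event"])
    dropped = len(records) - len(rec)
    if dropped:
        logger.warning("dropped %d records with missing time/event", dropped)
    if (rec["time"] < 0).any():
        raise MatrixIOError("negative survival time")
    if not rec["event"].isin([0, 1]).all():
        raise MatrixIOError("event indicator must be 0/1")
    if rec.empty:
        raise MatrixIOError("no usable survival records")
    return rec


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve with Greenwood standard errors.

    Returns one row per distinct event/censoring time: S(t), number at
    risk, events, and the Greenwood SE of S(t).
    """
    rec = _validate_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(rec["time"], rec["event"])
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    d, n = table["observed"].to_numpy(float), table["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    greenwood_var = surv.to_numpy() ** 2 * np.cumsum(terms)
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(float),
            "survival": surv.to_numpy(),
            "at_risk": n.astype(int),
            "events": d.astype(int),
            "greenwood_se": np.sqrt(greenwood_var),
        }
    )


def logrank_test(records: pd.DataFrame, groups: pd.Series | np.ndarray) -> dict[str, float]:
    """k-sample log-rank test; chi-square with k-1 df."""
    rec = _validate_records(records)
    g = pd.Series(np.asarray(groups), index=records.index).loc[rec.index]
    k = g.nunique()
    if k < 2:
        raise MatrixIOError("log-rank test needs >=2 groups")
    res = multivariate_logrank_test(rec["time"], g, rec["event"])
    return {
        "chi2": float(res.test_statistic),
        "df": int(k - 1),
        "p": float(res.p_value),
    }


@dataclass
class ScanResult:
    gene: str
    best_cutoff: float
    logrank_chi2: float
    p_raw: float
    p_bonferroni: float
    n_cutoffs_tested: int
    direction: int  # +1: high expression = higher risk; -1: protective
    valid: bool = True

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "best_cutoff": self.best_cutoff,
            "logrank_chi2": self.logrank_chi2,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "n_cutoffs_tested": self.n_cutoffs_tested,
            "direction": self.direction,
            "valid": self.valid,
        }


def two_group_logrank(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float, float]:
    """Two-sample log-rank statistic (chi2, p, O-E of group 1).

    Direct risk-table computation used inside the cutoff scan, where
    thousands of splits are evaluated; agrees with the lifelines
    statistic (the standalone ``logrank_test`` uses lifelines).
    """
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], in_group1[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        nj = float(at_risk.sum())
        n1j = float((at_risk & g).sum())
        dying = (t == et) & (e == 1)
        dj = float(dying.sum())
        d1j = float((dying & g).sum())
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var <= 0:
        return 0.0, 1.0, o_minus_e
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1)), float(o_minus_e)


def kaplan_scan(
    expr: pd.Series,
    records: pd.DataFrame,
    quantile_window: tuple[float, float] = (0.1, 0.9),
    min_group: int = 5,
) -> ScanResult:
    """Expression-cutoff scan minimizing the log-rank p, Bonferroni corrected.

    Every distinct expression value within the quantile window whose
    high/low split leaves at least ``min_group`` samples on each side is
    tried; samples with expression > cutoff form the high group.  The
    Bonferroni-corrected p is min(1, p_raw * n_cutoffs_tested).  The
    risk direction is the sign of the high group's observed-minus-
    expected event count at the best split (+1: high expression risky).
    Because only the ordering of expression values matters, the scan is
    invariant to monotone transforms of expression.
    """
    rec = _validate_records(records)
    common = rec.index.intersection(expr.dropna().index)
    rec = rec.loc[common]
    if len(rec) < 8 or rec["event"].sum() == 0:
        raise MatrixIOError("cutoff scan needs >=8 records with >=1 event")
    x = expr.loc[common].to_numpy(dtype=float)
    time = rec["time"].to_numpy(dtype=float)
    event = rec["event"].to_numpy(dtype=int)
    lo, hi = np.quantile(x, quantile_window)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    gene = str(expr.name) if expr.name is not None else "gene"
    best = None
    n_tested = 0
    for cut in candidates:
        high = x > cut
        n_high = int(high.sum())
        if n_high < min_group or len(x) - n_high < min_group:
            continue
        n_tested += 1
        chi2, p, ome = two_group_logrank(time, event, high)
        if best is None or p < best[0]:
            best = (p, float(cut), chi2, ome)
    if best is None:
        return ScanResult(gene, np.nan, np.nan, np.nan, np.nan, 0, 0, valid=False)
    p_raw, cutoff, chi2, ome = best
    direction = 1 if ome >= 0 else -1
    return ScanResult(
        gene=gene,
        best_cutoff=cutoff,
        logrank_chi2=chi2,
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_tested),
        n_cutoffs_tested=n_tested,
        direction=direction,
    )


@dataclass
class MetageneSet:
    name: str  # "unfavorable" or "favorable"
    genes: list[str] = field(default_factory=list)

    def score(self, mat: ExpressionMatrix) -> pd.Series:
        """Per-sample mean of z-scored (across samples) member expression."""
        if not self.genes:
            raise MatrixIOError(f"metagene set {self.name!r} is empty")
        sub = mat.values.loc[self.genes]
        sd = sub.std(axis=1, ddof=1).replace(0, 1.0)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        return z.mean(axis=0).rename(f"{self.name}_metagene")


def build_metagene(
    mat: ExpressionMatrix,
    records: pd.DataFrame,
    relapse_up: list[str],
    relapse_down: list[str],
    alpha: float = 0.05,
    quantile_window: tuple[float, float] = (0.1, 0.9),
    min_group: int = 5,
) -> tuple[MetageneSet, MetageneSet, pd.DataFrame]:
    """Scan candidate DEGs and pool the prognostic, direction-concordant ones.

    ``relapse_up``/``relapse_down`` are the top differentially expressed
    gene lists.  A relapse-up gene joins the unfavorable set when its
    corrected scan p < alpha and high expression carries risk; a
    relapse-down gene joins the favorable set when high expression is
    protective.  Returns both sets plus the full scan table.
    """
    scan_rows = []
    unfavorable, favorable = [], []
    for gene, want_dir, bucket in (
        *((g, 1, unfavorable) for g in relapse_up),
        *((g, -1, favorable) for g in relapse_down),
    ):
        if gene not in mat.values.index:
            logger.warning("candidate gene %s absent from matrix; skipped", gene)
            continue
        expr = mat.values.loc[gene]
        expr.name = gene
        try:
            res = kaplan_scan(expr, records, quantile_window, min_group)
        except MatrixIOError:
            continue
        scan_rows.append(res.as_dict())
        if res.valid and res.p_bonferroni < alpha and res.direction == want_dir:
            bucket.append(gene)
    table = pd.DataFrame(scan_rows)
    return MetageneSet("unfavorable", unfavorable), MetageneSet("favorable", favorable), table


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    ``records`` must carry ``time``, ``event`` and the covariate
    columns.  Returns per-covariate beta, HR, 95% CI, Wald p, plus the
    model partial log-likelihood in ``DataFrame.attrs['loglik']``.
    Separation or non-convergence raises an explicit error.
    """
    rec = _validate_records(records)
    covariates = covariates or [c for c in rec.columns if c not in ("time", "event")]
    rec = rec.dropna(subset=covariates)
    n_events = int(rec["event"].sum())
    if n_events < 5 * len(covariates):
        warnings.warn(
            f"{n_events} events for {len(covariates)} covariates (<5 per covariate)",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            # separation shows up as a lifelines convergence warning; promote it
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(
                rec[["time", "event", *covariates]],
                duration_col="time",
                event_col="event",
            )
    except (ConvergenceError, ConvergenceWarning, np.linalg.LinAlgError) as exc:
        raise MatrixIOError(f"Cox model failed to converge: {exc}") from exc
    if (cph.summary["se(coef)"] > 1e3).any() or (cph.params_.abs() > 50).any():
        raise MatrixIOError("Cox model shows monotone likelihood (separation)")
    summary = cph.summary
    out = pd.DataFrame(
        {
            "beta": summary["coef"],
            "HR": summary["exp(coef)"],
            "ci_low": np.exp(summary["coef"] - 1.96 * summary["se(coef)"]),
            "ci_high": np.exp(summary["coef"] + 1.96 * summary["se(coef)"]),
            "se": summary["se(coef)"],
            "p": summary["p"],
        }
    )
    out.attrs["loglik"] = float(cph.log_likelihood_)
    return out


def association_tests(
    ann: pd.DataFrame, factor_pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Chi-squared / Fisher association between categorical factor pairs.

    Fisher's exact test is used for 2x2 tables with any expected cell
    below 5; otherwise the chi-squared test.  Larger sparse tables fall
    back to chi-squared with a warning (no exact RxC test is attempted).
    """
    rows = []
    for f1, f2 in factor_pairs:
        sub = ann[[f1, f2]].dropna()
        table = pd.crosstab(sub[f1], sub[f2])
        if table.shape[0] < 2 or table.shape[1] < 2:
            raise MatrixIOError(f"factor pair ({f1}, {f2}) is degenerate (single level)")
        obs = table.to_numpy()
        expected = stats.contingency.expected_freq(obs)
        small = (expected < 5).any()
        if small and obs.shape == (2, 2):
            _, p = stats.fisher_exact(obs)
            method = "fisher"
        else:
            if small:
                warnings.warn(
                    f"({f1}, {f2}): sparse table larger than 2x2; chi-squared used",
                    stacklevel=2,
                )
            chi2, p, _, _ = stats.chi2_contingency(obs)
            method = "chi2"
        rows.append({"factor1": f1, "factor2": f2, "method": method, "p": float(p)})
    return pd.DataFrame(rows)
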