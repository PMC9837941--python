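"""SNV-fingerprint verification of sample identity.

Paired primary/relapse expression profiles should originate from the
same patient; genotype calls at polymorphic sites provide a fingerprint.
Variant allele fractions (VAF) from RNA-seq are thresholded into
genotype codes (0 = hom ref, 1 = het, 2 = hom alt) and a pair is
verified when the fraction of matching calls over jointly covered sites
reaches a threshold.  Concordance on codes rather than raw VAF is
robust to the heavy VAF noise of degraded (FFPE) material.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix_io import CohortAnnotation, MatrixIOError, pair_index

MIN_SITES_DEFAULT = 20


def genotype_calls(
    vaf: pd.DataFrame,
    hom_ref_max: float = 0.1,
    hom_alt_min: float = 0.9,
) -> pd.DataFrame:
    """Threshold a site x sample VAF table into genotype codes.

    VAF < hom_ref_max -> 0; VAF > hom_alt_min -> 2; else 1 (strict
    inequalities, so a VAF exactly at a threshold is called het).
    Missing VAF stays missing.
    """
    if not hom_ref_max < hom_alt_min:
        raise MatrixIOError(
            f"thresholds inverted: hom_ref_max={hom_ref_max} >= hom_alt_min={hom_alt_min}"
        )
    vals = vaf.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if ((vals[finite] < 0) | (vals[finite] > 1)).any():
        raise MatrixIOError("VAF values must lie in [0, 1]")
    calls = np.full(vals.shape, np.nan)
    calls[finite & (vals < hom_ref_max)] = 0
    calls[finite & (vals > hom_alt_min)] = 2
    calls[finite & (vals >= hom_ref_max) & (vals <= hom_alt_min)] = 1
    return pd.DataFrame(calls, index=vaf.index, columns=vaf.columns)


def pair_concordance(
    calls: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    match_threshold: float = 0.8,
    min_sites: int = MIN_SITES_DEFAULT,
) -> dict:
    """Fraction of matching genotype calls between two samples.

    Symmetric in its arguments.  Fewer than ``min_sites`` jointly called
    sites yields verdict ``indeterminate``; otherwise ``match`` iff the
    matching fraction reaches ``match_threshold``.
    """
    for s in (sample_a, sample_b):
        if s not in calls.columns:
            raise MatrixIOError(f"sample {s!r} missing from call table")
    a = calls[sample_a].to_numpy(dtype=float)
    b = calls[sample_b].to_numpy(dtype=float)
    joint = np.isfinite(a) & np.isfinite(b)
    n = int(joint.sum())
    if n < min_sites:
        return {"fraction_matching": np.nan, "n_sites": n, "verdict": "indeterminate"}
    frac = float(np.mean(a[joint] == b[joint]))
    return {
        "fraction_matching": frac,
        "n_sites": n,
        "verdict": "match" if frac >= match_threshold else "mismatch",
    }


def verify_cohort(
    vaf: pd.DataFrame,
    ann: CohortAnnotation,
    hom_ref_max: float = 0.1,
    hom_alt_min: float = 0.9,
    match_threshold: float = 0.8,
    min_sites: int = MIN_SITES_DEFAULT,
) -> pd.DataFrame:
    """Concordance report for every annotated primary/relapse pair."""
    calls = genotype_calls(vaf, hom_ref_max, hom_alt_min)
    rows = []
    for patient, prim, rel in pair_index(ann):
        res = pair_concordance(calls, prim, rel, match_threshold, min_sites)
        rows.append({"patient_id": patient, "primary": prim, "relapse": rel, **res})
    return pd.DataFrame(rows)
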