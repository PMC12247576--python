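"""Paired comparisons between pooling schemes.

Every contrast reduces to :func:`compare_schemes`: for each morphometric
measure the per-subject percent errors under two schemes are compared with a
paired two-sided test across subjects (Wilcoxon signed-rank by default,
paired t optional), and the per-measure deltas are summarized as a mean
improvement, a fraction of measures improved (ties counted half) and a
fraction significant at alpha (uncorrected by default; Benjamini-Hochberg
adjusted p-values are attached for reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .precision import (
    MEASURE_COLUMNS,
    AlignmentError,
    PoolingScheme,
    break_pair,
    cs1mm_first_k,
    expected_sqrt_curve,
    multires4,
    no_break_pair,
    relative_reduction,
    scheme_errors,
    summarize_errors,
)

__all__ = [
    "ContrastSummary",
    "compare_schemes",
    "pooling_curve",
    "break_contrast",
    "multires_contrast",
    "subgroup_summaries",
]

logger = logging.getLogger(__name__)

#: Exact signed-rank p-values up to this many paired subjects, then the
#: normal approximation with continuity correction.
_EXACT_N_MAX = 25


@dataclass(frozen=True)
class ContrastSummary:
    """Summary of a paired scheme comparison over all measures."""

    reference: str
    candidate: str
    mean_delta_pct_points: float
    mean_percent_reduction: float
    fraction_improved_pct: float
    fraction_significant_pct: float
    alpha: float
    n_measures: int
    n_subjects: int


def _paired_pvalues(diffs: np.ndarray, test: str) -> np.ndarray:
    """Two-sided paired p-values per column of an (n_subjects, n_measures)
    difference matrix.  All-zero columns get p = 1 (no evidence convention)."""
    n_subj, n_meas = diffs.shape
    pvals = np.ones(n_meas)
    nonzero_any = (diffs != 0).any(axis=0)
    if not nonzero_any.any():
        return pvals
    cols = np.flatnonzero(nonzero_any)
    if test == "ttest":
        res = stats.ttest_rel(diffs[:, cols], np.zeros_like(diffs[:, cols]), axis=0)
        pvals[cols] = np.nan_to_num(res.pvalue, nan=1.0)
        return pvals
    if test != "wilcoxon":
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    has_zeros = (diffs[:, cols] == 0).any(axis=0)
    if n_subj <= _EXACT_N_MAX:
        for j, col in enumerate(cols):
            x = diffs[:, col]
            method = "approx" if has_zeros[j] else "exact"
            pvals[col] = stats.wilcoxon(
                x, method=method, correction=(method == "approx")
            ).pvalue
    else:
        res = stats.wilcoxon(diffs[:, cols], method="approx", correction=True, axis=0)
        pvals[cols] = res.pvalue
    return pvals


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compare_schemes(
    err_reference: pd.DataFrame,
    err_candidate: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> tuple[pd.DataFrame, ContrastSummary]:
    """Paired per-measure comparison of two schemes' error records.

    Both inputs are frames from :func:`morphopool.precision.scheme_errors`
    over the same subjects and measures.  Per measure, delta = mean reference
    error - mean candidate error across subjects (positive favors the
    candidate) with a paired two-sided test on the per-subject errors.
    Measures with identical errors under both schemes count as half-improved.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ref_label = str(err_reference["scheme"].iloc[0])
    cand_label = str(err_candidate["scheme"].iloc[0])
    idx = ["subject_id", *MEASURE_COLUMNS]
    ref = err_reference.set_index(idx)["percent_error"].sort_index()
    cand = err_candidate.set_index(idx)["percent_error"].sort_index()
    if not ref.index.equals(cand.index):
        raise AlignmentError("schemes cover different subjects/measures")

    diff = (ref - cand).unstack(MEASURE_COLUMNS)  # subjects x measures
    measures = diff.columns
    n_subj = diff.shape[0]
    if n_subj < 2:
        logger.warning("fewer than 2 paired subjects: tests skipped, p set to 1")
        pvals = np.ones(diff.shape[1])
    else:
        pvals = _paired_pvalues(diff.to_numpy(), test)

    delta = diff.mean(axis=0).to_numpy()
    improved = np.where(delta > 0, 1.0, np.where(delta == 0, 0.5, 0.0))
    n_ties = int((delta == 0).sum())
    if n_ties:
        logger.info("%d tied measure(s) counted as half-improved", n_ties)

    per_measure = pd.DataFrame(
        {
            "structure": measures.get_level_values("structure"),
            "hemisphere": measures.get_level_values("hemisphere"),
            "measure_class": measures.get_level_values("measure_class"),
            "delta_pct_points": delta,
            "p_value": pvals,
            "p_bh": _bh_adjust(pvals),
            "n_subjects": n_subj,
        }
    )
    _, red = relative_reduction(err_reference, err_candidate)
    summary = ContrastSummary(
        reference=ref_label,
        candidate=cand_label,
        mean_delta_pct_points=red["mean_delta_pct_points"],
        mean_percent_reduction=red["mean_percent_reduction"],
        fraction_improved_pct=100.0 * float(improved.mean()),
        fraction_significant_pct=100.0 * float((pvals < alpha).mean()),
        alpha=alpha,
        n_measures=len(measures),
        n_subjects=n_subj,
    )
    return per_measure, summary


def pooling_curve(
    table: pd.DataFrame,
    reference: PoolingScheme | None = None,
    ks: tuple[int, ...] = (1, 2, 4, 8),
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Mean error of first-k CS 1.0 mm pooling vs a reference scheme.

    Returns a per-k curve table — mean/SD error, the 1/sqrt(k) expectation
    anchored at the measured k=1 error, and the contrast vs the reference —
    plus the per-measure contrast frames.
    """
    from .precision import scheme_adni  # local to avoid cycle at import time

    if reference is None:
        reference = scheme_adni()
    err_ref = scheme_errors(table, reference)
    ref_summary = summarize_errors(err_ref, "overall")
    e1 = None
    rows = []
    per_measure: dict[int, pd.DataFrame] = {}
    for k in ks:
        err_k = scheme_errors(table, cs1mm_first_k(k))
        summ = summarize_errors(err_k, "overall")
        mean_err = float(summ["mean_pct"].iloc[0])
        if e1 is None:
            err_1 = err_k if k == 1 else scheme_errors(table, cs1mm_first_k(1))
            e1 = float(summarize_errors(err_1, "overall")["mean_pct"].iloc[0])
        contrast_df, contrast = compare_schemes(err_ref, err_k, alpha=alpha, test=test)
        per_measure[k] = contrast_df
        rows.append(
            {
                "k": k,
                "scheme": f"CS 1.0mm x{k}",
                "mean_pct": mean_err,
                "sd_pct": float(summ["sd_pct"].iloc[0]),
                "sem_pct": float(summ["sem_pct"].iloc[0]),
                "expected_sqrt_pct": expected_sqrt_curve(e1, k),
                "reference_mean_pct": float(ref_summary["mean_pct"].iloc[0]),
                "mean_delta_pct_points": contrast.mean_delta_pct_points,
                "mean_percent_reduction": contrast.mean_percent_reduction,
                "fraction_improved_pct": contrast.fraction_improved_pct,
                "fraction_significant_pct": contrast.fraction_significant_pct,
            }
        )
    return pd.DataFrame(rows), per_measure


def break_contrast(
    table: pd.DataFrame, alpha: float = 0.05, test: str = "wilcoxon"
) -> tuple[pd.DataFrame, ContrastSummary]:
    """Pooling across the repositioning break vs within one head position.

    Reference: CS 1.0 mm scans 1+2 (no break); candidate: scans 1+5 (break).
    A positive delta means the break pair is more precise.
    """
    err_nb = scheme_errors(table, no_break_pair())
    err_b = scheme_errors(table, break_pair())
    return compare_schemes(err_nb, err_b, alpha=alpha, test=test)


def multires_contrast(
    table: pd.DataFrame, alpha: float = 0.05, test: str = "wilcoxon"
) -> tuple[pd.DataFrame, ContrastSummary]:
    """Four mixed-resolution CS scans vs four CS 1.0 mm scans.

    Reference: CS 1.0 mm scans 1-4; candidate: one scan each at 0.8, 0.9,
    1.1 and 1.2 mm.  A positive delta favors multi-resolution pooling.
    """
    err_ref = scheme_errors(table, cs1mm_first_k(4))
    err_mr = scheme_errors(table, multires4())
    return compare_schemes(err_ref, err_mr, alpha=alpha, test=test)


def subgroup_summaries(
    records: pd.DataFrame,
    reference_records: pd.DataFrame | None = None,
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-group error summaries, optionally with reductions vs a reference.

    ``records`` (and ``reference_records``) are error-record frames carrying
    a ``group`` column.  Empty groups are dropped with a warning.
    """
    if groups is None:
        groups = tuple(sorted(records["group"].unique()))
    rows = []
    for g in groups:
        sub = records[records["group"] == g]
        if len(sub) == 0:
            logger.warning("empty group %r dropped", g)
            continue
        summ = summarize_errors(sub, "overall").iloc[0].to_dict()
        summ["group"] = g
        summ["grouping"] = "per-group"
        if reference_records is not None:
            ref_sub = reference_records[reference_records["group"] == g]
            _, red = relative_reduction(ref_sub, sub)
            summ["reference_mean_pct"] = red["mean_reference_pct"]
            summ["mean_percent_reduction"] = red["mean_percent_reduction"]
        rows.append(summ)
    return pd.DataFrame(rows)
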