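"""Core precision statistics: pooling, percent error, summaries, benchmarks.

The test-retest precision statistic throughout is the percent error

    100 * |v1 - v2| / ((v1 + v2) / 2)

between a measure estimated from Session 1 and from Session 2, where each
session's estimate may first be pooled (arithmetic mean) over several scans
selected by a :class:`PoolingScheme`.  Pooling k scans with mutually
uncorrelated errors shrinks the expected error by 1/sqrt(k); shared (session
or head-position) error components make the scans' errors equicorrelated and
dampen the benefit, which the closed form :func:`equicorr_pooled_sd` and the
estimator :func:`estimate_rho` quantify.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morpho_io import scan_duration_registry

__all__ = [
    "PoolingScheme",
    "scheme_adni",
    "cs1mm_first_k",
    "break_pair",
    "no_break_pair",
    "multires4",
    "scheme_by_name",
    "pool",
    "percent_error",
    "scheme_errors",
    "summarize_errors",
    "expected_sqrt_curve",
    "relative_reduction",
    "equicorr_pooled_sd",
    "estimate_rho",
    "RhoEstimate",
    "scheme_duration",
    "SchemeError",
    "EmptySelectionError",
    "AlignmentError",
    "EstimationError",
    "MEASURE_COLUMNS",
]

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = ("structure", "hemisphere", "measure_class")


class SchemeError(ValueError):
    """A pooling scheme is inconsistent with the table it is applied to."""


class EmptySelectionError(SchemeError):
    """A pooling scheme matched no scans."""


class AlignmentError(ValueError):
    """Two error-record sets do not cover the same measures/subjects."""


class EstimationError(RuntimeError):
    """An estimator reached a degenerate state."""


@dataclass(frozen=True)
class PoolingScheme:
    """A named rule selecting which scans of each session are averaged.

    Scans are filtered by ``scan_type``, ``resolutions`` and ``blocks`` (None
    means no constraint), then by label: ``first_k`` keeps type_index <= k
    (Fig-style scan labels, not acquisition order), or ``type_indices`` keeps
    an explicit label set.  ``k`` is the number of scans the selector must
    match in every session.
    """

    label: str
    k: int
    scan_type: str | None = None
    resolutions: frozenset[float] | None = None
    blocks: frozenset[str] | None = None
    first_k: int | None = None
    type_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.first_k is not None and self.type_indices is not None:
            raise ValueError("give first_k or type_indices, not both")

    def select(self, table: pd.DataFrame) -> pd.Series:
        """Boolean mask of table rows matched by this scheme."""
        mask = pd.Series(True, index=table.index)
        if self.scan_type is not None:
            mask &= table["scan_type"] == self.scan_type
        if self.resolutions is not None:
            mask &= table["resolution_mm"].round(4).isin([round(r, 4) for r in self.resolutions])
        if self.blocks is not None:
            mask &= table["block"].isin(self.blocks)
        if self.first_k is not None:
            mask &= table["type_index"] <= self.first_k
        if self.type_indices is not None:
            mask &= table["type_index"].isin(self.type_indices)
        return mask


def scheme_adni() -> PoolingScheme:
    """The single reference ADNI scan."""
    return PoolingScheme(label="ADNI", k=1, scan_type="ADNI")


def cs1mm_first_k(k: int) -> PoolingScheme:
    """Pool the first k CS 1.0 mm scans by label (labels 1-4 pre-break)."""
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    return PoolingScheme(
        label=f"CS 1.0mm x{k}",
        k=k,
        scan_type="CS",
        resolutions=frozenset({1.0}),
        first_k=k,
    )


def no_break_pair() -> PoolingScheme:
    """Two consecutive CS 1.0 mm scans within one head position (labels 1, 2)."""
    return PoolingScheme(
        label="CS 1.0mm pair (no break)",
        k=2,
        scan_type="CS",
        resolutions=frozenset({1.0}),
        type_indices=(1, 2),
    )


def break_pair() -> PoolingScheme:
    """One CS 1.0 mm scan before and one after the break (labels 1, 5)."""
    return PoolingScheme(
        label="CS 1.0mm pair (break)",
        k=2,
        scan_type="CS",
        resolutions=frozenset({1.0}),
        type_indices=(1, 5),
    )


def multires4() -> PoolingScheme:
    """The first scan of each non-1.0 mm CS resolution (0.8/0.9/1.1/1.2 mm)."""
    return PoolingScheme(
        label="CS multi-resolution x4",
        k=4,
        scan_type="CS",
        resolutions=frozenset({0.8, 0.9, 1.1, 1.2}),
        type_indices=(1,),
    )


_NAMED_SCHEMES = {
    "ADNI": lambda: scheme_adni(),
    "cs1mm_first_1": lambda: cs1mm_first_k(1),
    "cs1mm_first_2": lambda: cs1mm_first_k(2),
    "cs1mm_first_4": lambda: cs1mm_first_k(4),
    "cs1mm_first_8": lambda: cs1mm_first_k(8),
    "no_break_pair": no_break_pair,
    "break_pair": break_pair,
    "multires4": multires4,
}


def scheme_by_name(name: str) -> PoolingScheme:
    """Resolve a config-file scheme name (e.g. ``cs1mm_first_4``)."""
    if name.startswith("cs1mm_first_"):
        return cs1mm_first_k(int(name.rsplit("_", 1)[1]))
    try:
        return _NAMED_SCHEMES[name]()
    except KeyError:
        raise KeyError(f"unknown scheme name {name!r}") from None


# ---------------------------------------------------------------------------
# Pooling and percent error
# ---------------------------------------------------------------------------

def pool(table: pd.DataFrame, scheme: PoolingScheme) -> pd.DataFrame:
    """Pooled (mean) value of the scheme's scans per subject, session, measure.

    Subjects whose sessions do not all contain exactly ``scheme.k`` matching
    scans are dropped with a logged warning (no imputation).  Returns columns
    subject_id, group, session, structure, hemisphere, measure_class, value.
    """
    sel = table.loc[scheme.select(table)]
    if len(sel) == 0:
        raise EmptySelectionError(f"scheme {scheme.label!r} matched no scans")

    group_cols = ["subject_id", "group", "session", *MEASURE_COLUMNS]
    agg = sel.groupby(group_cols, sort=False, observed=True)["value"].agg(["mean", "size"])
    bad_counts = set(agg["size"].unique()) - {scheme.k}
    if bad_counts:
        bad_subjects = (
            agg.loc[agg["size"] != scheme.k].index.get_level_values("subject_id").unique()
        )
        logger.warning(
            "scheme %r: dropping %d subject(s) with %s matched scans instead of %d: %s",
            scheme.label, len(bad_subjects), sorted(bad_counts), scheme.k,
            ", ".join(bad_subjects[:5]),
        )
        agg = agg[~agg.index.get_level_values("subject_id").isin(bad_subjects)]
        if len(agg) == 0:
            raise SchemeError(
                f"scheme {scheme.label!r}: no subject has {scheme.k} matching scans"
            )
    pooled = agg["mean"].rename("value").reset_index()
    return pooled


def percent_error(v1, v2):
    """Test-retest percent error: 100 |v1 - v2| / mean(v1, v2).

    Symmetric, non-negative, zero iff the two estimates agree, and invariant
    to rescaling both arguments.  Accepts scalars or arrays.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    mean = (v1 + v2) / 2.0
    if np.any(~np.isfinite(v1)) or np.any(~np.isfinite(v2)):
        raise ValueError("percent_error requires finite inputs")
    if np.any(mean <= 0):
        raise ValueError("percent_error undefined for non-positive mean")
    out = 100.0 * np.abs(v1 - v2) / mean
    return float(out) if out.ndim == 0 else out


def scheme_errors(table: pd.DataFrame, scheme: PoolingScheme) -> pd.DataFrame:
    """Per-subject, per-measure percent error of a scheme's pooled estimates.

    Pools within each session, then applies :func:`percent_error` to the
    Session-1 vs Session-2 pooled values.  Subjects missing a session are
    excluded with a logged warning.  Returns columns subject_id, group,
    structure, hemisphere, measure_class, scheme, percent_error.
    """
    pooled = pool(table, scheme)
    sessions = sorted(pooled["session"].unique())
    if len(sessions) < 2:
        raise SchemeError("need two sessions to compute test-retest error")
    s1, s2 = sessions[:2]
    wide = pooled.pivot_table(
        index=["subject_id", "group", *MEASURE_COLUMNS],
        columns="session",
        values="value",
        observed=True,
    )
    complete = wide[[s1, s2]].notna().all(axis=1)
    if not complete.all():
        dropped = wide.index[~complete].get_level_values("subject_id").unique()
        logger.warning(
            "scheme %r: excluding %d subject(s) missing a session: %s",
            scheme.label, len(dropped), ", ".join(dropped[:5]),
        )
        wide = wide[complete]
    records = wide.reset_index()
    records["scheme"] = scheme.label
    records["percent_error"] = percent_error(
        records[s1].to_numpy(), records[s2].to_numpy()
    )
    return records[
        ["subject_id", "group", *MEASURE_COLUMNS, "scheme", "percent_error"]
    ]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _measure_means(records: pd.DataFrame) -> pd.DataFrame:
    return (
        records.groupby(list(MEASURE_COLUMNS), sort=False, observed=True)["percent_error"]
        .mean()
        .reset_index()
    )


def _agg_block(values: np.ndarray) -> dict[str, float]:
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if n == 1:
        logger.warning("summary over a single value: SD reported as 0")
    return {"mean_pct": mean, "sd_pct": sd, "sem_pct": sd / math.sqrt(n), "n": n}


def summarize_errors(
    records: pd.DataFrame,
    grouping: str = "overall",
    mode: str = "measures",
) -> pd.DataFrame:
    """Aggregate error records into mean/SD/SEM summaries.

    ``grouping`` is one of ``overall``, ``per-measure``, ``per-group`` or
    ``per-measure-class``.  The default aggregation ``mode="measures"`` first
    averages each measure's error across subjects and then summarizes across
    measures (so n counts measures); ``mode="records"`` summarizes the raw
    subject-by-measure records directly.
    """
    if len(records) == 0:
        raise ValueError("no error records to summarize")
    if mode not in ("measures", "records"):
        raise ValueError("mode must be 'measures' or 'records'")

    def block(sub: pd.DataFrame) -> dict[str, float]:
        vals = (
            _measure_means(sub)["percent_error"].to_numpy()
            if mode == "measures"
            else sub["percent_error"].to_numpy()
        )
        return _agg_block(vals)

    scheme = records["scheme"].iloc[0] if "scheme" in records.columns else ""
    rows: list[dict[str, object]] = []
    if grouping == "overall":
        rows.append({"scheme": scheme, "grouping": "overall"} | block(records))
    elif grouping == "per-measure":
        for key, sub in records.groupby(list(MEASURE_COLUMNS), sort=True, observed=True):
            vals = sub["percent_error"].to_numpy()
            rows.append(
                {"scheme": scheme, "grouping": "per-measure"}
                | dict(zip(MEASURE_COLUMNS, key))
                | _agg_block(vals)
            )
    elif grouping == "per-group":
        for group, sub in records.groupby("group", sort=True, observed=True):
            if len(sub) == 0:
                logger.warning("empty group %r dropped from summary", group)
                continue
            rows.append({"scheme": scheme, "grouping": "per-group", "group": group} | block(sub))
    elif grouping == "per-measure-class":
        for mclass, sub in records.groupby("measure_class", sort=True, observed=True):
            rows.append(
                {"scheme": scheme, "grouping": "per-measure-class", "measure_class": mclass}
                | block(sub)
            )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return pd.DataFrame(rows)


def expected_sqrt_curve(e1: float, k: int) -> float:
    """Expected pooled error under fully uncorrelated errors: e1 / sqrt(k)."""
    if e1 < 0:
        raise ValueError("e1 must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    return e1 / math.sqrt(k)


def relative_reduction(
    reference: pd.DataFrame, candidate: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-measure and mean error reduction of a candidate scheme vs a reference.

    Both inputs are error-record frames over the same measures.  Per measure,
    delta = reference mean error - candidate mean error (percentage points;
    positive favors the candidate) and percent reduction = 100 * delta /
    reference.  The summary's mean reduction is computed on the mean errors,
    matching how headline "x% lower error" figures are quoted.
    """
    ref = _measure_means(reference).set_index(list(MEASURE_COLUMNS))
    cand = _measure_means(candidate).set_index(list(MEASURE_COLUMNS))
    if set(ref.index) != set(cand.index):
        raise AlignmentError("reference and candidate cover different measures")
    cand = cand.reindex(ref.index)
    out = pd.DataFrame(
        {
            "reference_pct": ref["percent_error"],
            "candidate_pct": cand["percent_error"],
        }
    )
    out["delta_pct_points"] = out["reference_pct"] - out["candidate_pct"]
    with np.errstate(divide="ignore", invalid="ignore"):
        red = 100.0 * out["delta_pct_points"] / out["reference_pct"]
    # zero reference with zero delta (noiseless data): reduction is 0, not 0/0
    out["percent_reduction"] = red.where(out["reference_pct"] > 0, 0.0)
    mean_ref = float(out["reference_pct"].mean())
    mean_cand = float(out["candidate_pct"].mean())
    mean_delta = mean_ref - mean_cand
    summary = {
        "mean_reference_pct": mean_ref,
        "mean_candidate_pct": mean_cand,
        "mean_delta_pct_points": mean_delta,
        "mean_percent_reduction": 100.0 * mean_delta / mean_ref if mean_ref > 0 else 0.0,
    }
    return out.reset_index(), summary


# ---------------------------------------------------------------------------
# Equicorrelation closed forms and autocorrelation estimation
# ---------------------------------------------------------------------------

def equicorr_pooled_sd(sigma: float, rho: float, k: int) -> float:
    """SD of the mean of k errors with common SD sigma and pairwise correlation rho.

    sigma * sqrt((1 + (k-1) rho) / k); reduces to sigma/sqrt(k) at rho=0 and
    to sigma at rho=1.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return sigma * math.sqrt((1.0 + (k - 1) * rho) / k)


@dataclass(frozen=True)
class RhoEstimate:
    """Result of :func:`estimate_rho`."""

    rho: float
    ci_low: float
    ci_high: float
    rho_unclipped: float
    shared_var: float  # intercept a = 2 sigma^2 rho
    scan_var: float  # slope b = 2 sigma^2 (1 - rho)
    max_k: int
    n_subjects: int


def _pooled_session_diffs(
    table: pd.DataFrame, max_k: int, measure: tuple[str, str, str] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Relative session differences of first-k pooled CS 1.0 mm values.

    Returns (subjects array of shape (n_records,), diffs of shape
    (n_records, max_k)) where diffs[:, k-1] is the session difference of the
    k-scan pooled value divided by the two-session mean.
    """
    sel = table[
        (table["scan_type"] == "CS")
        & (table["resolution_mm"].round(4) == 1.0)
        & (table["type_index"] <= max_k)
    ]
    if measure is not None:
        s, h, c = measure
        sel = sel[
            (sel["structure"] == s)
            & (sel["hemisphere"] == h)
            & (sel["measure_class"] == c)
        ]
    if len(sel) == 0:
        raise EmptySelectionError("no CS 1.0 mm scans found")
    wide = sel.pivot_table(
        index=["subject_id", *MEASURE_COLUMNS],
        columns=["session", "type_index"],
        values="value",
        observed=True,
    )
    if wide.isna().any().any() or wide.shape[1] != 2 * max_k:
        raise SchemeError(f"every subject needs {max_k} CS 1.0 mm scans in both sessions")
    sessions = sorted({s for s, _ in wide.columns})
    arr = np.stack(
        [wide[[(s, i) for i in range(1, max_k + 1)]].to_numpy() for s in sessions[:2]]
    )  # (2, n_records, max_k)
    cum = np.cumsum(arr, axis=2) / np.arange(1, max_k + 1)  # running pooled means
    diffs = (cum[0] - cum[1]) / ((cum[0] + cum[1]) / 2.0)
    subjects = wide.index.get_level_values("subject_id").to_numpy()
    return subjects, diffs


def estimate_rho(
    table: pd.DataFrame,
    measure: tuple[str, str, str] | None = None,
    max_k: int = 8,
    n_boot: int = 200,
    ci_level: float = 0.95,
    seed: int = 0,
) -> RhoEstimate:
    """Estimate the inter-scan error autocorrelation from pooled-error decay.

    Under the equicorrelation model the mean squared relative session
    difference of a k-scan pooled estimate is E[D_k^2] = a + b/k with
    a = 2 sigma^2 rho and b = 2 sigma^2 (1 - rho), so rho = a / (a + b).
    Fits that line by least squares over k = 1..max_k using the CS 1.0 mm
    scans (optionally restricted to one measure), clips rho to [0, 1]
    (unclipped value retained) and attaches a percentile bootstrap CI over
    subjects.
    """
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    subjects, diffs = _pooled_session_diffs(table, max_k, measure)

    inv_k = 1.0 / np.arange(1, max_k + 1)

    def fit(d2_means: np.ndarray) -> tuple[float, float, float]:
        b, a = np.polyfit(inv_k, d2_means, 1)
        if a + b <= 0:
            raise EstimationError("degenerate fit: a + b <= 0")
        return a / (a + b), a, b

    rho_raw, a, b = fit((diffs**2).mean(axis=0))
    rho = min(1.0, max(0.0, rho_raw))

    unique_subjects = np.unique(subjects)
    rng = np.random.default_rng(seed)
    # pre-split record indices per subject for resampling
    idx_by_subject = {s: np.flatnonzero(subjects == s) for s in unique_subjects}
    boots = []
    for _ in range(n_boot):
        draw = rng.choice(unique_subjects, size=len(unique_subjects), replace=True)
        idx = np.concatenate([idx_by_subject[s] for s in draw])
        try:
            r, _, _ = fit((diffs[idx] ** 2).mean(axis=0))
        except EstimationError:
            continue
        boots.append(min(1.0, max(0.0, r)))
    if boots:
        lo, hi = np.percentile(boots, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
    else:
        lo = hi = float("nan")
    return RhoEstimate(
        rho=rho,
        ci_low=float(lo),
        ci_high=float(hi),
        rho_unclipped=float(rho_raw),
        shared_var=float(a),
        scan_var=float(b),
        max_k=max_k,
        n_subjects=len(unique_subjects),
    )


# ---------------------------------------------------------------------------
# Scan-time accounting
# ---------------------------------------------------------------------------

def scheme_duration(
    scheme: PoolingScheme, registry: dict[tuple[str, float], int] | None = None
) -> int:
    """Total acquisition seconds of one session's scans under a scheme."""
    if registry is None:
        registry = scan_duration_registry()
    scan_type = scheme.scan_type or "CS"
    resolutions = sorted(scheme.resolutions) if scheme.resolutions else [1.0]
    if scheme.type_indices is not None:
        per_resolution = len(scheme.type_indices)
    elif scheme.first_k is not None:
        per_resolution = scheme.first_k
    else:
        per_resolution = max(1, scheme.k // len(resolutions))
    total = 0
    for res in resolutions:
        try:
            total += per_resolution * registry[(scan_type, float(res))]
        except KeyError:
            raise KeyError(
                f"no registered duration for ({scan_type}, {res})"
            ) from None
    return total
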