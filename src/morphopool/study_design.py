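"""Translate measurement precision into longitudinal design quantities.

A morphometric percent error of e% per timepoint implies, under a normal
error model, a per-timepoint SD of relative values of sigma_tp = e *
sqrt(pi/2) (the mean of a folded normal is sigma * sqrt(2/pi)).  Change over
follow-up is measured by differencing two timepoints, so the
measurement-error floor on the SD of observed change is sigma_change =
sqrt(2) * sigma_tp.  The required sample size to detect an annual change d%
over t years then follows the standard normal-approximation formula

    n = ceil( (z_{1-alpha/2} + z_{power})^2 * m * sigma_change^2 / (d t)^2 )

with design multiplier m = 1 for a one-group change test and m = 2 per group
for a two-group change-difference test.  Biological between-subject variance
in change rates is deliberately excluded by default (this module quantifies
the measurement-error floor only) but can be added via ``extra_change_sd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .morpho_io import scan_duration_registry
from .precision import equicorr_pooled_sd

__all__ = ["PowerSpec", "error_to_sd", "required_n", "precision_budget"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a longitudinal power calculation (percent-error scale)."""

    annual_change: float  # % of the measure per year
    per_timepoint_error: float  # mean percent error per timepoint
    followup_years: float = 1.0
    alpha: float = 0.05
    power: float = 0.80
    design: str = "one-group"  # or "two-group"
    extra_change_sd: float = 0.0  # additional SD of true change, % units

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.followup_years <= 0:
            raise ValueError("follow-up must be > 0")
        if self.per_timepoint_error < 0 or self.extra_change_sd < 0:
            raise ValueError("error terms must be >= 0")
        if self.design not in ("one-group", "two-group"):
            raise ValueError("design must be 'one-group' or 'two-group'")


def error_to_sd(percent_error_mean: float) -> float:
    """SD of the session-difference of relative values implied by a mean
    percent error, via the folded-normal link: sigma = e * sqrt(pi/2)."""
    if percent_error_mean < 0:
        raise ValueError("percent error must be >= 0")
    return percent_error_mean * math.sqrt(math.pi / 2.0)


def required_n(spec: PowerSpec) -> int:
    """Subjects per group needed to detect the specified change.

    Normal-approximation z-formula (documented in the module docstring);
    slightly anticonservative below n ~ 10 where a t-based formula would add
    1-2 subjects.
    """
    effect = spec.annual_change * spec.followup_years
    if effect <= 0:
        raise ValueError("annual_change * followup_years must be > 0")
    sigma_tp = error_to_sd(spec.per_timepoint_error)
    sigma_change_sq = 2.0 * sigma_tp**2 + spec.extra_change_sd**2
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    multiplier = 1.0 if spec.design == "one-group" else 2.0
    n = (z_a + z_b) ** 2 * multiplier * sigma_change_sq / effect**2
    return int(math.ceil(n))


def precision_budget(
    duration_budget_s: float,
    rho: float,
    single_scan_error: float,
    registry: dict[tuple[str, float], int] | None = None,
) -> tuple[int, float]:
    """Best CS 1.0 mm pooling depth within a scan-time budget.

    Returns (k, expected pooled percent error), where k = floor(budget /
    per-scan duration) and the expected error scales the single-scan error by
    the equicorrelated pooling factor sqrt((1 + (k-1) rho) / k).  The factor
    is non-increasing in k for rho <= 1, so the largest feasible k is best.
    """
    if registry is None:
        registry = scan_duration_registry()
    per_scan = registry[("CS", 1.0)]
    k = int(duration_budget_s // per_scan)
    if k < 1:
        raise ValueError(
            f"budget {duration_budget_s} s is below one CS 1.0 mm scan ({per_scan} s)"
        )
    expected = single_scan_error * equicorr_pooled_sd(1.0, rho, k)
    return k, expected
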