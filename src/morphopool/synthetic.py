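"""Synthetic test-retest morphometry with hierarchical multiplicative error.

The generator emulates a two-session cluster-scanning protocol: in each
session every subject receives one reference ADNI MPRAGE and sixteen rapid
compressed-sensing (CS) scans — eight at 1.0 mm (four before and four after a
repositioning break) and eight at mixed resolutions (0.8/0.9/1.1/1.2 mm,
twice each).  Each observed value is the subject's true regional value times
independent multiplicative error components that are shared at the session,
block (head position) and scan level:

    v = T * (1 + session) * (1 + block) * bias_res * (1 + scan * scale_res)

Shared components induce an equicorrelated error structure across the scans
of a session; the implied inter-scan error correlation is available in closed
form from :func:`implied_rho`.  All error components are drawn independently
per measure, so different regions carry independent information (a
simplification relative to real data, where head motion correlates errors
across regions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morpho_io import (
    TABLE_COLUMNS,
    UNITS_BY_CLASS,
    MeasureKey,
    default_measure_registry,
    scan_duration_registry,
)

__all__ = [
    "ScanSlot",
    "StudyDesign",
    "NoiseModel",
    "default_design",
    "default_region_means",
    "default_group_shifts",
    "default_noise_model",
    "implied_rho",
    "simulate_study",
    "sigma_from_mean_error",
    "GROUP_LABELS",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = ("YA-CU", "OA-CU", "MCI/AD")

#: Temporal-lobe parcels used for the default MCI/AD thickness shift.
TEMPORAL_PARCELS = (
    "bankssts",
    "entorhinal",
    "fusiform",
    "inferiortemporal",
    "middletemporal",
    "parahippocampal",
    "superiortemporal",
    "temporalpole",
    "transversetemporal",
)


@dataclass(frozen=True)
class ScanSlot:
    """One slot of the per-session scan plan (identical in every session)."""

    scan_type: str
    resolution_mm: float
    block: str
    order_index: int
    type_index: int


@dataclass(frozen=True)
class StudyDesign:
    """Cohort composition and the ordered per-session scan plan."""

    groups: tuple[tuple[str, int], ...]
    sessions: int = 2
    scan_plan: tuple[ScanSlot, ...] = ()

    def __post_init__(self) -> None:
        orders = [s.order_index for s in self.scan_plan]
        if len(set(orders)) != len(orders):
            raise ValueError("order indices must be unique within a session")
        for scan_type, res in {(s.scan_type, s.resolution_mm) for s in self.scan_plan}:
            key = [s.type_index for s in self.scan_plan
                   if (s.scan_type, s.resolution_mm) == (scan_type, res)]
            if sorted(key) != list(range(1, len(key) + 1)):
                raise ValueError(
                    f"type indices for {scan_type} {res} mm must be 1..{len(key)}"
                )

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)


def default_design() -> StudyDesign:
    """The full cluster-scanning protocol.

    Per session: one ADNI scan, then — around a repositioning break — eight
    CS 1.0 mm scans (labels 1-4 pre-break, 5-8 post-break) and eight
    multi-resolution CS scans (0.8/0.9/1.1/1.2 mm, one of each per block).
    Cohort: 12 younger adults, 18 cognitively unimpaired older adults, 10
    MCI/AD, two sessions each.
    """
    plan: list[ScanSlot] = []
    order = 1

    def add(scan_type: str, res: float, block: str, type_index: int) -> None:
        nonlocal order
        plan.append(ScanSlot(scan_type, res, block, order, type_index))
        order += 1

    add("ADNI", 1.0, "pre", 1)
    add("CS", 1.2, "pre", 1)
    add("CS", 0.8, "pre", 1)
    for i in range(1, 5):
        add("CS", 1.0, "pre", i)
    add("CS", 1.1, "pre", 1)
    add("CS", 0.9, "pre", 1)
    add("CS", 1.2, "post", 2)
    add("CS", 0.8, "post", 2)
    for i in range(5, 9):
        add("CS", 1.0, "post", i)
    add("CS", 1.1, "post", 2)
    add("CS", 0.9, "post", 2)

    return StudyDesign(
        groups=(("YA-CU", 12), ("OA-CU", 18), ("MCI/AD", 10)),
        sessions=2,
        scan_plan=tuple(plan),
    )


def default_region_means() -> dict[MeasureKey, float]:
    """Plausible adult regional means in native units.

    Percent error is scale-free, so only rough realism matters: subcortical
    volumes in mm3, a uniform 2.5 mm cortical thickness and a 1.25
    gray/white intensity ratio.
    """
    volumes = {
        "Amygdala": 1700.0,
        "Accumbens-area": 600.0,
        "Pallidum": 1900.0,
        "Caudate": 3600.0,
        "Hippocampus": 4200.0,
        "Putamen": 5100.0,
        "Thalamus": 7200.0,
        "VentralDC": 4000.0,
    }
    means: dict[MeasureKey, float] = {}
    for key in default_measure_registry():
        if key.measure_class == "volume":
            means[key] = volumes[key.structure]
        elif key.measure_class == "thickness":
            means[key] = 2.5
        else:
            means[key] = 1.25
    return means


def default_group_shifts() -> dict[tuple[str, str, str], float]:
    """Multiplicative true-value shifts per (group, structure, measure class).

    Defaults model medial-temporal atrophy in the MCI/AD group: -15%
    hippocampal and amygdala volume, -8% temporal-lobe thickness.  These are
    configurable placeholders, not literature estimates.
    """
    shifts: dict[tuple[str, str, str], float] = {}
    for s in ("Hippocampus", "Amygdala"):
        shifts[("MCI/AD", s, "volume")] = -0.15
    for p in TEMPORAL_PARCELS:
        shifts[("MCI/AD", p, "thickness")] = -0.08
    return shifts


def sigma_from_mean_error(mean_percent_error: float) -> float:
    """Per-session total error SD (fraction) giving a target mean percent error.

    The session difference of two relative errors with per-session SD sigma is
    N(0, 2 sigma^2); its folded mean is 2 sigma / sqrt(pi), so
    sigma = (e/100) * sqrt(pi) / 2.
    """
    if mean_percent_error < 0:
        raise ValueError("mean percent error must be >= 0")
    return mean_percent_error / 100.0 * math.sqrt(math.pi) / 2.0


@dataclass(frozen=True)
class NoiseModel:
    """Generative parameters for synthetic estimate tables.

    All error SDs are fractions of the true value (multiplicative error).
    ``sigma_session`` is shared by every scan in a session, ``sigma_block``
    by every scan in the same pre- or post-break block, and ``sigma_scan``
    (or ``sigma_scan_adni`` for the ADNI scan type) is independent per scan.
    ``resolution_bias`` and ``resolution_noise_scale`` apply a multiplicative
    bias and a per-scan-SD multiplier per CS resolution.
    """

    region_means: dict[MeasureKey, float] = field(default_factory=default_region_means)
    subject_cv: float = 0.10
    group_shift: dict[tuple[str, str, str], float] = field(
        default_factory=default_group_shifts
    )
    sigma_session: float = 0.0
    sigma_block: float = 0.0
    sigma_scan: float = 0.0
    sigma_scan_adni: float = 0.0
    resolution_bias: dict[float, float] = field(default_factory=dict)
    resolution_noise_scale: dict[float, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_cv", "sigma_session", "sigma_block", "sigma_scan",
                     "sigma_scan_adni"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.region_means.values()):
            raise ValueError("region means must be > 0")
        if any(b <= 0 for b in self.resolution_bias.values()):
            raise ValueError("resolution biases must be > 0")


def default_noise_model(
    target_cs_error: float = 3.01,
    target_adni_error: float = 2.87,
    rho_same: float = 0.2,
    seed: int = 0,
) -> NoiseModel:
    """Noise model tuned so a single CS 1.0 mm scan yields the target mean
    percent error and the ADNI scan its own target, with same-block error
    correlation ``rho_same`` split evenly between session and block
    components.
    """
    if not 0.0 <= rho_same < 1.0:
        raise ValueError("rho_same must lie in [0, 1)")
    sigma_total = sigma_from_mean_error(target_cs_error)
    shared_var = rho_same * sigma_total**2
    sigma_session = math.sqrt(shared_var / 2.0)
    sigma_block = math.sqrt(shared_var / 2.0)
    sigma_scan = math.sqrt(sigma_total**2 - shared_var)
    adni_var = sigma_from_mean_error(target_adni_error) ** 2 - shared_var
    if adni_var <= 0:
        raise ValueError("ADNI target error too small for the shared components")
    return NoiseModel(
        sigma_session=sigma_session,
        sigma_block=sigma_block,
        sigma_scan=sigma_scan,
        sigma_scan_adni=math.sqrt(adni_var),
        seed=seed,
    )


def implied_rho(model: NoiseModel, same_block: bool = True) -> float:
    """Closed-form inter-scan error correlation implied by the model.

    Same-block pairs share session and block components; cross-block pairs
    share only the session component.  Uses the CS per-scan SD.
    """
    s2 = model.sigma_session**2
    b2 = model.sigma_block**2
    e2 = model.sigma_scan**2
    total = s2 + b2 + e2
    if total == 0:
        raise ValueError("all error SDs are zero; correlation undefined")
    return (s2 + b2) / total if same_block else s2 / total


_MAX_RESAMPLE = 100


def simulate_study(
    model: NoiseModel,
    design: StudyDesign | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a long-format estimate table for one test-retest study.

    True values are drawn once per subject and measure around the regional
    means (between-subject CV ``subject_cv``) and shifted multiplicatively per
    group; error components are then applied per session, block and scan as
    described in the module docstring.  Deterministic given (model, design,
    seed): each subject consumes an independent substream keyed by
    ``SeedSequence([seed, subject_index])``, so enlarging the cohort does not
    reshuffle earlier subjects.

    Values that come out non-positive (pathologically large SDs) have their
    per-scan error redrawn, up to 100 times per cell, before failing.
    """
    if design is None:
        design = default_design()
    if seed is None:
        seed = model.seed
    if seed < 0:
        raise ValueError("seed must be non-negative")

    keys = sorted(model.region_means)
    means = np.array([model.region_means[k] for k in keys])
    n_meas = len(keys)
    structures = np.array([k.structure for k in keys])
    hemis = np.array([k.hemisphere for k in keys])
    classes = np.array([k.measure_class for k in keys])
    units = np.array([UNITS_BY_CLASS[c] for c in classes])

    plan = design.scan_plan
    n_scans = len(plan)
    n_sessions = design.sessions
    durations = scan_duration_registry()
    scan_cols = {
        "scan_type": np.array([s.scan_type for s in plan]),
        "resolution_mm": np.array([s.resolution_mm for s in plan]),
        "block": np.array([s.block for s in plan]),
        "type_index": np.array([s.type_index for s in plan]),
        "order_index": np.array([s.order_index for s in plan]),
        "duration_s": np.array(
            [durations[(s.scan_type, s.resolution_mm)] for s in plan]
        ),
    }
    # per-scan error SD and bias
    scan_sigma = np.array(
        [
            model.sigma_scan_adni
            if s.scan_type == "ADNI"
            else model.sigma_scan * model.resolution_noise_scale.get(s.resolution_mm, 1.0)
            for s in plan
        ]
    )
    scan_bias = np.array(
        [
            1.0
            if s.scan_type == "ADNI"
            else model.resolution_bias.get(s.resolution_mm, 1.0)
            for s in plan
        ]
    )
    # block index per scan: 0 = pre (and n/a), 1 = post
    block_idx = np.array([1 if s.block == "post" else 0 for s in plan])

    shift_by_group = {
        g: np.array(
            [1.0 + model.group_shift.get((g, s, c), 0.0) for s, c in zip(structures, classes)]
        )
        for g, _ in design.groups
    }

    subject_rows = n_sessions * n_scans * n_meas
    chunks: dict[str, list[np.ndarray]] = {c: [] for c in TABLE_COLUMNS}
    subject_index = 0
    for group, n_in_group in design.groups:
        for _ in range(n_in_group):
            rng = np.random.default_rng(np.random.SeedSequence([seed, subject_index]))
            subject_id = f"sub-{subject_index + 1:03d}"

            true = rng.normal(means, model.subject_cv * means)
            for _try in range(_MAX_RESAMPLE + 1):
                bad = true <= 0
                if not bad.any():
                    break
                if _try == _MAX_RESAMPLE:
                    raise RuntimeError("true-value resampling failed; SDs too large")
                logger.warning("resampling %d non-positive true values", bad.sum())
                true[bad] = rng.normal(means[bad], model.subject_cv * means[bad])
            true = true * shift_by_group[group]

            delta = rng.normal(0.0, model.sigma_session, size=(n_sessions, 1, n_meas))
            beta = rng.normal(0.0, model.sigma_block, size=(n_sessions, 2, n_meas))
            eps = rng.normal(0.0, 1.0, size=(n_sessions, n_scans, n_meas))

            base = (
                true[None, None, :]
                * (1.0 + delta)
                * (1.0 + beta[:, block_idx, :])
                * scan_bias[None, :, None]
            )
            values = base * (1.0 + eps * scan_sigma[None, :, None])
            for _try in range(_MAX_RESAMPLE + 1):
                bad = values <= 0
                if not bad.any():
                    break
                if _try == _MAX_RESAMPLE:
                    raise RuntimeError(
                        "per-scan resampling failed after 100 attempts; SDs too large"
                    )
                logger.warning("resampling %d non-positive simulated values", bad.sum())
                eps[bad] = rng.normal(0.0, 1.0, size=int(bad.sum()))
                values = base * (1.0 + eps * scan_sigma[None, :, None])

            chunks["subject_id"].append(np.repeat(subject_id, subject_rows))
            chunks["group"].append(np.repeat(group, subject_rows))
            chunks["session"].append(
                np.repeat(np.arange(1, n_sessions + 1), n_scans * n_meas)
            )
            for col, arr in scan_cols.items():
                chunks[col].append(np.tile(np.repeat(arr, n_meas), n_sessions))
            chunks["structure"].append(np.tile(structures, n_sessions * n_scans))
            chunks["hemisphere"].append(np.tile(hemis, n_sessions * n_scans))
            chunks["measure_class"].append(np.tile(classes, n_sessions * n_scans))
            chunks["units"].append(np.tile(units, n_sessions * n_scans))
            chunks["value"].append(values.ravel())
            subject_index += 1

    if subject_index == 0:
        return pd.DataFrame(columns=list(TABLE_COLUMNS))
    table = pd.DataFrame(
        {col: np.concatenate(parts) for col, parts in chunks.items()},
        columns=list(TABLE_COLUMNS),
    )
    table["session"] = table["session"].astype(int)
    table["type_index"] = table["type_index"].astype(int)
    table["order_index"] = table["order_index"].astype(int)
    table["duration_s"] = table["duration_s"].astype(int)
    return table
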