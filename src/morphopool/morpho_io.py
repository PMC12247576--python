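"""Morphometric estimate tables: registries, FreeSurfer stats readers, long CSV.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
(one row per subject x session x scan x measure) with the columns in
:data:`TABLE_COLUMNS`.  Readers for the FreeSurfer ``aseg.stats``,
``?h.aparc.stats`` and ``?h.w-g.pct.stats`` dialects emit rows in the same
schema, so real recon-all output and synthetic tables flow through identical
downstream code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "MeasureKey",
    "ScanRecord",
    "TABLE_COLUMNS",
    "SUBCORTICAL_STRUCTURES",
    "DK_PARCELS",
    "default_measure_registry",
    "scan_duration_registry",
    "scheme_duration_lookup",
    "read_aseg_stats",
    "read_aparc_stats",
    "read_long_csv",
    "write_long_csv",
    "validate_table",
    "rows_to_frame",
    "write_aseg_fixture",
    "write_aparc_fixture",
    "IntegrityError",
    "IncompleteTableError",
    "StatsParseError",
]

Hemisphere = Literal["left", "right"]
MeasureClass = Literal["volume", "thickness", "gwr"]

#: Units implied by each measure class.
UNITS_BY_CLASS: dict[str, str] = {"volume": "mm3", "thickness": "mm", "gwr": "ratio"}

#: Aseg subcortical structures analyzed bilaterally (canonical names follow
#: the Aseg conventions, e.g. "Accumbens-area", "VentralDC").
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "Amygdala",
    "Accumbens-area",
    "Pallidum",
    "Caudate",
    "Hippocampus",
    "Putamen",
    "Thalamus",
    "VentralDC",
)

#: The 34 Desikan-Killiany cortical parcels (per hemisphere).
DK_PARCELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Canonical column order of the long-format estimate table.
TABLE_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "session",
    "scan_type",
    "resolution_mm",
    "block",
    "type_index",
    "order_index",
    "duration_s",
    "structure",
    "hemisphere",
    "measure_class",
    "units",
    "value",
)

#: Columns that identify one scan-level observation of one measure.
KEY_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "session",
    "scan_type",
    "resolution_mm",
    "type_index",
    "structure",
    "hemisphere",
    "measure_class",
)


class IntegrityError(ValueError):
    """Estimate table violates a schema invariant (duplicates, non-finite values)."""


class IncompleteTableError(ValueError):
    """A stats file is missing structures the measure registry requires."""


class StatsParseError(ValueError):
    """A FreeSurfer stats file could not be parsed."""


@dataclass(frozen=True, order=True)
class MeasureKey:
    """Identity of one morphometric measure.

    Parameters
    ----------
    structure
        Anatomical name, e.g. ``"Hippocampus"`` or ``"superiorfrontal"``.
    hemisphere
        ``"left"`` or ``"right"``.
    measure_class
        ``"volume"`` (mm3), ``"thickness"`` (mm) or ``"gwr"`` (ratio).
    """

    structure: str
    hemisphere: str
    measure_class: str

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"invalid hemisphere: {self.hemisphere!r}")
        if self.measure_class not in UNITS_BY_CLASS:
            raise ValueError(f"invalid measure_class: {self.measure_class!r}")

    @property
    def units(self) -> str:
        return UNITS_BY_CLASS[self.measure_class]


@dataclass(frozen=True)
class ScanRecord:
    """One acquired scan of one subject in one session."""

    subject_id: str
    group: str
    session: int
    scan_type: str  # "ADNI" or "CS"
    resolution_mm: float
    block: str  # "pre", "post" or "n/a"
    order_index: int
    type_index: int
    duration_s: int = 0

    def __post_init__(self) -> None:
        if self.scan_type not in ("ADNI", "CS"):
            raise ValueError(f"invalid scan_type: {self.scan_type!r}")
        if self.block not in ("pre", "post", "n/a"):
            raise ValueError(f"invalid block: {self.block!r}")
        if self.scan_type == "ADNI" and (self.resolution_mm != 1.0 or self.type_index != 1):
            raise ValueError("ADNI scans are 1.0 mm with type_index 1")


def default_measure_registry() -> list[MeasureKey]:
    """The 152-measure registry: 16 subcortical volumes, 68 thickness and 68
    GWR measures over the Desikan-Killiany parcellation."""
    keys: list[MeasureKey] = []
    for hemi in ("left", "right"):
        for s in SUBCORTICAL_STRUCTURES:
            keys.append(MeasureKey(s, hemi, "volume"))
    for mclass in ("thickness", "gwr"):
        for hemi in ("left", "right"):
            for p in DK_PARCELS:
                keys.append(MeasureKey(p, hemi, mclass))
    return keys


def scan_duration_registry() -> dict[tuple[str, float], int]:
    """Acquisition durations in seconds per (scan_type, resolution_mm).

    ADNI MPRAGE runs 5'12"; the compressed-sensing variants run 1'49" (0.8 mm),
    1'26" (0.9 mm), 1'12" (1.0 mm), 1'01" (1.1 mm) and 0'49" (1.2 mm).
    """
    return {
        ("ADNI", 1.0): 312,
        ("CS", 0.8): 109,
        ("CS", 0.9): 86,
        ("CS", 1.0): 72,
        ("CS", 1.1): 61,
        ("CS", 1.2): 49,
    }


def scheme_duration_lookup(scan_type: str, resolution_mm: float) -> int:
    registry = scan_duration_registry()
    try:
        return registry[(scan_type, float(resolution_mm))]
    except KeyError:
        raise KeyError(
            f"no registered duration for scan_type={scan_type!r}, "
            f"resolution={resolution_mm} mm"
        ) from None


# ---------------------------------------------------------------------------
# FreeSurfer structure-name normalization (shipped as data)
# ---------------------------------------------------------------------------

def _load_fs_name_table() -> dict[str, tuple[str, str]]:
    path = resources.files("morphopool").joinpath("data/fs_structure_names.csv")
    table: dict[str, tuple[str, str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["fs_name"]] = (row["structure"], row["hemisphere"])
    return table


FS_NAME_TABLE: dict[str, tuple[str, str]] = _load_fs_name_table()


# ---------------------------------------------------------------------------
# Stats-file parsing
# ---------------------------------------------------------------------------

def _parse_stats_body(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Split a FreeSurfer stats file into column headers and data rows.

    The dialect is '#'-prefixed comment lines, one of which is
    ``# ColHeaders <name> <name> ...``, followed by whitespace-separated rows.
    """
    headers: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("ColHeaders"):
                    headers = stripped.split()[1:]
                continue
            rows.append(line.split())
    if headers is None:
        raise StatsParseError(f"{path}: no '# ColHeaders' line found")
    for row in rows:
        if len(row) != len(headers):
            raise StatsParseError(
                f"{path}: row has {len(row)} fields, expected {len(headers)}: "
                f"{' '.join(row[:6])}..."
            )
    return headers, rows


def _scan_fields(scan: ScanRecord) -> dict[str, object]:
    return {
        "subject_id": scan.subject_id,
        "group": scan.group,
        "session": scan.session,
        "scan_type": scan.scan_type,
        "resolution_mm": scan.resolution_mm,
        "block": scan.block,
        "type_index": scan.type_index,
        "order_index": scan.order_index,
        "duration_s": scan.duration_s,
    }


def read_aseg_stats(path: str | Path, scan: ScanRecord) -> pd.DataFrame:
    """Read subcortical volumes from an ``aseg.stats`` file.

    Only the 16 registry structures are extracted; other segments (ventricles,
    white matter, etc.) are ignored.  Raises :class:`IncompleteTableError` if
    any registry structure is absent.
    """
    headers, rows = _parse_stats_body(path)
    try:
        i_name = headers.index("StructName")
        i_vol = headers.index("Volume_mm3")
    except ValueError as exc:
        raise StatsParseError(f"{path}: missing required column: {exc}") from None

    wanted = {
        (s, h): MeasureKey(s, h, "volume")
        for h in ("left", "right")
        for s in SUBCORTICAL_STRUCTURES
    }
    out: list[dict[str, object]] = []
    seen: set[tuple[str, str]] = set()
    base = _scan_fields(scan)
    for row in rows:
        mapped = FS_NAME_TABLE.get(row[i_name])
        if mapped is None or mapped not in wanted:
            continue
        key = wanted[mapped]
        seen.add(mapped)
        out.append(
            base
            | {
                "structure": key.structure,
                "hemisphere": key.hemisphere,
                "measure_class": "volume",
                "units": "mm3",
                "value": float(row[i_vol]),
            }
        )
    missing = sorted(set(wanted) - seen)
    if missing:
        names = ", ".join(f"{h.capitalize()}-{s}" for s, h in missing)
        raise IncompleteTableError(f"{path}: missing structures: {names}")
    return pd.DataFrame(out, columns=list(TABLE_COLUMNS))


def _hemisphere_from_path(path: str | Path) -> str | None:
    name = Path(path).name
    if name.startswith("lh."):
        return "left"
    if name.startswith("rh."):
        return "right"
    return None


def read_aparc_stats(
    path: str | Path,
    scan: ScanRecord,
    measure_class: str,
    hemisphere: str | None = None,
    convert_pct: bool = True,
) -> pd.DataFrame:
    """Read per-parcel cortical measures from one hemisphere's stats file.

    ``measure_class="thickness"`` expects the ``?h.aparc.stats`` dialect and
    takes the ``ThickAvg`` column.  ``measure_class="gwr"`` expects the
    ``?h.w-g.pct.stats`` dialect; its ``Mean`` column holds the white-gray
    percent contrast ``100*(W-G)/W``, converted to a gray/white intensity
    ratio via ``gwr = 1/(1 - pct/100)`` unless ``convert_pct=False`` (in which
    case ``Mean`` is assumed to already be a ratio).

    The hemisphere is taken from the ``lh.``/``rh.`` filename prefix when
    ``hemisphere`` is not given.
    """
    if measure_class not in ("thickness", "gwr"):
        raise ValueError("measure_class must be 'thickness' or 'gwr'")
    if hemisphere is None:
        hemisphere = _hemisphere_from_path(path)
        if hemisphere is None:
            raise ValueError(
                f"{path}: hemisphere not given and filename has no lh./rh. prefix"
            )

    headers, rows = _parse_stats_body(path)
    value_col = "ThickAvg" if measure_class == "thickness" else "Mean"
    try:
        i_name = headers.index("StructName")
        i_val = headers.index(value_col)
    except ValueError:
        raise StatsParseError(f"{path}: missing required column {value_col!r}") from None

    parcels = set(DK_PARCELS)
    base = _scan_fields(scan)
    out: list[dict[str, object]] = []
    seen: set[str] = set()
    for row in rows:
        name = row[i_name]
        # mri_segstats prefixes w-g.pct rows with the hemisphere label
        bare = name.split("_", 1)[1] if name.startswith(("lh_", "rh_")) else name
        if bare in ("unknown", "corpuscallosum"):
            continue
        if bare not in parcels:
            raise StatsParseError(f"{path}: unknown parcel {name!r}")
        value = float(row[i_val])
        if measure_class == "gwr" and convert_pct:
            value = 1.0 / (1.0 - value / 100.0)
        seen.add(bare)
        out.append(
            base
            | {
                "structure": bare,
                "hemisphere": hemisphere,
                "measure_class": measure_class,
                "units": UNITS_BY_CLASS[measure_class],
                "value": value,
            }
        )
    missing = sorted(parcels - seen)
    if missing:
        raise IncompleteTableError(f"{path}: missing parcels: {', '.join(missing)}")
    return pd.DataFrame(out, columns=list(TABLE_COLUMNS))


# ---------------------------------------------------------------------------
# Long CSV
# ---------------------------------------------------------------------------

def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate estimate-table invariants; returns the table unchanged.

    Checks: canonical columns present, at most one value per
    (subject, session, scan, measure), all values finite, volume/thickness
    values strictly positive.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"missing columns: {missing}")
    if len(table) == 0:
        return table
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise IntegrityError("non-finite values present")
    dup = table.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        first = table.loc[dup.idxmax(), list(KEY_COLUMNS)].to_dict()
        raise IntegrityError(f"duplicate rows for key {first}")
    sized = table["measure_class"].isin(["volume", "thickness"])
    if (table.loc[sized, "value"] <= 0).any():
        raise IntegrityError("non-positive volume/thickness value")
    return table


def write_long_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write an estimate table as canonical long CSV (UTF-8, '.' decimal).

    Floats are written with repr-level precision so that a read-back
    reproduces the table bit-for-bit.
    """
    validate_table(table)
    table = table[list(TABLE_COLUMNS)]
    table.to_csv(path, index=False)


_TABLE_DTYPES = {
    "subject_id": str,
    "group": str,
    "session": int,
    "scan_type": str,
    "resolution_mm": float,
    "block": str,
    "type_index": int,
    "order_index": int,
    "duration_s": int,
    "structure": str,
    "hemisphere": str,
    "measure_class": str,
    "units": str,
    "value": float,
}


def read_long_csv(path: str | Path) -> pd.DataFrame:
    """Read a canonical long CSV and validate its invariants."""
    table = pd.read_csv(path, dtype=_TABLE_DTYPES)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"{path}: missing columns: {missing}")
    table = table[list(TABLE_COLUMNS)]
    return validate_table(table)


def rows_to_frame(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate reader outputs into one validated estimate table."""
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=list(TABLE_COLUMNS))
    return validate_table(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Fixture writers (synthetic stats files for reader tests)
# ---------------------------------------------------------------------------

# preferred FreeSurfer spelling per structure (first CSV entry wins, which
# keeps the classic "Thalamus-Proper" name for fixtures)
_FS_NAME_BY_KEY: dict[tuple[str, str], str] = {}
for _n, _key in FS_NAME_TABLE.items():
    _FS_NAME_BY_KEY.setdefault(_key, _n)


def write_aseg_fixture(values: dict[tuple[str, str], float], path: str | Path) -> None:
    """Write a syntactically valid synthetic ``aseg.stats`` file.

    ``values`` maps (structure, hemisphere) to Volume_mm3.  Intended for
    testing the reader; this is not FreeSurfer output.
    """
    lines = [
        "# Title Segmentation Statistics (synthetic fixture)",
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean",
    ]
    for i, ((structure, hemi), vol) in enumerate(sorted(values.items()), start=1):
        fs_name = _FS_NAME_BY_KEY.get((structure, hemi), f"{hemi.capitalize()}-{structure}")
        lines.append(f"{i:3d} {i + 9:4d} {1000 + i:6d} {vol!r} {fs_name} 100.0")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_aparc_fixture(
    values: dict[str, float],
    path: str | Path,
    measure_class: str = "thickness",
) -> None:
    """Write a synthetic ``?h.aparc.stats`` or ``?h.w-g.pct.stats`` file.

    ``values`` maps parcel name to ThickAvg (thickness) or Mean percent
    contrast (gwr).  Intended for testing the reader.
    """
    if measure_class == "thickness":
        lines = [
            "# Table of FreeSurfer cortical parcellation anatomical statistics (synthetic fixture)",
            "# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd",
        ]
        for i, (parcel, thick) in enumerate(sorted(values.items())):
            lines.append(f"{parcel} {2000 + i} {1400 + i} {4000 + i} {thick!r} 0.5")
    elif measure_class == "gwr":
        lines = [
            "# Title W-G percent contrast statistics (synthetic fixture)",
            "# ColHeaders Index SegId NVoxels Volume_mm3 StructName Mean StdDev Min Max Range",
        ]
        for i, (parcel, pct) in enumerate(sorted(values.items()), start=1):
            lines.append(
                f"{i:3d} {1000 + i:5d} {2000 + i:6d} {1800.0 + i} {parcel} {pct!r} 2.0 10.0 30.0 20.0"
            )
    else:
        raise ValueError("measure_class must be 'thickness' or 'gwr'")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
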