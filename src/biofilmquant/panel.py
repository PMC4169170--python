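"""Phenotype-panel data model, adhesion scoring and figure transforms.

The panel is a long-format table with one row per (strain, ploidy,
phenotype, replicate) holding a quantitative value and/or an ordinal 0-5
score. Quantitative phenotypes are the settling ratio (flocculation), the
background-corrected invasion intensity and the crystal-violet OD570
adhesion read-out; colony, mat and filamentous-growth complexity are
consumed as ordinal scores assigned by eye against a 0 (smooth) to 5
(very strong) rubric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

PANEL_COLUMNS = [
    "strain",
    "ploidy",
    "phenotype",
    "replicate_type",
    "replicate_id",
    "value",
    "ordinal_score",
]
PLOIDIES = {"haploid", "diploid", "cured"}
REPLICATE_TYPES = {"technical", "biological"}
PHENOTYPES = {"colony", "mat", "flocculation", "invasion", "adhesion", "filamentous"}
#: Phenotypes whose quantitative values are physically nonnegative.
NONNEGATIVE_PHENOTYPES = {"flocculation", "invasion", "adhesion"}


@dataclass(frozen=True)
class AdhesionMeasurement:
    """Crystal-violet adhesion: per-well OD570 values and their mean."""

    per_well_od570: tuple[float, ...]

    @property
    def score(self) -> float:
        return float(np.mean(self.per_well_od570))


def adhesion_score(
    wells: Sequence[float], blank: float | None = None
) -> AdhesionMeasurement:
    """Average OD570 across technical replicate wells (typically 2-3).

    An optional blank absorbance is subtracted from each well first;
    negative readings are clamped to 0 with a warning.
    """
    vals = np.asarray(wells, dtype=float)
    if vals.size == 0:
        raise ValidationError("at least one well reading is required")
    vals = vals - (blank or 0.0)
    if np.any(vals < 0):
        warnings.warn("negative OD570 after blank subtraction; clamped to 0")
        vals = np.clip(vals, 0.0, None)
    return AdhesionMeasurement(per_well_od570=tuple(float(v) for v in vals))


def linear_normalize(values: Sequence[float]) -> np.ndarray:
    """Linearly rescale per-strain values onto [0, 5].

    ``x -> 5 (x - min) / (max - min)``; a constant vector maps to all
    zeros (no phenotype signal to spread).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot normalize an empty vector")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros_like(vals)
    return 5.0 * (vals - lo) / (hi - lo)


def bin_quantitative(values: Sequence[float], k: int = 5) -> np.ndarray:
    """Assign equal-width bins 1..k over [min, max].

    The maximum lands in bin ``k``; a constant vector lands entirely in
    bin 1. Used for the 5-level color intensities of score heat-strips.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot bin an empty vector")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.ones(vals.shape, dtype=int)
    bins = np.floor((vals - lo) / (hi - lo) * k).astype(int) + 1
    return np.minimum(bins, k)


def group_by_score(
    quantitative: pd.Series, scores: pd.Series
) -> pd.DataFrame:
    """Mean quantitative value per ordinal score level.

    Both series are indexed by strain; the index sets must match. Returns
    a frame indexed by score with columns ``mean`` and ``count`` (levels
    with no strains are absent).
    """
    if set(quantitative.index) != set(scores.index):
        raise ValidationError("strain sets of values and scores differ")
    scores = scores.reindex(quantitative.index)
    grouped = quantitative.groupby(scores).agg(["mean", "count"])
    grouped.index.name = "score"
    return grouped


def aggregate_replicates(panel: pd.DataFrame, level: str = "technical") -> pd.DataFrame:
    """Collapse one replicate level of a panel by arithmetic mean.

    Rows of the requested ``replicate_type`` are averaged per (strain,
    ploidy, phenotype); rows of other replicate types pass through
    unchanged. Missing values are ignored (mean of available replicates).
    """
    if level not in REPLICATE_TYPES:
        raise ValidationError(f"unknown replicate level {level!r}")
    if panel.empty:
        raise ValidationError("panel is empty")
    at_level = panel[panel["replicate_type"] == level]
    if at_level.empty:
        raise ValidationError(f"panel has no {level} replicates")
    rest = panel[panel["replicate_type"] != level]
    collapsed = (
        at_level.groupby(["strain", "ploidy", "phenotype"], as_index=False)
        .agg(value=("value", "mean"), ordinal_score=("ordinal_score", "first"))
        .assign(replicate_type=level, replicate_id=1)
    )
    out = pd.concat([collapsed[PANEL_COLUMNS], rest[PANEL_COLUMNS]], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------


def validate_panel(panel: pd.DataFrame) -> None:
    """Schema-check a long-format panel; raises :class:`SchemaError` with
    1-based row numbers on the first violation of each kind."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing columns {missing}")
    problems: list[str] = []

    def rows(mask: pd.Series) -> str:
        idx = (np.flatnonzero(mask.to_numpy()) + 1)[:5]
        return ", ".join(map(str, idx))

    bad = ~panel["ploidy"].isin(PLOIDIES)
    if bad.any():
        problems.append(f"invalid ploidy at rows {rows(bad)}")
    bad = ~panel["replicate_type"].isin(REPLICATE_TYPES)
    if bad.any():
        problems.append(f"invalid replicate_type at rows {rows(bad)}")
    score = pd.to_numeric(panel["ordinal_score"], errors="coerce")
    bad = panel["ordinal_score"].notna() & (
        score.isna() | (score < 0) | (score > 5) | (score % 1 != 0)
    )
    if bad.any():
        problems.append(f"ordinal_score outside 0..5 at rows {rows(bad)}")
    quant = panel["phenotype"].isin(NONNEGATIVE_PHENOTYPES)
    value = pd.to_numeric(panel["value"], errors="coerce")
    bad = quant & panel["value"].notna() & (value < 0)
    if bad.any():
        problems.append(f"negative quantitative value at rows {rows(bad)}")
    key = ["strain", "ploidy", "phenotype", "replicate_type", "replicate_id"]
    dup = panel.duplicated(subset=key, keep=False)
    if dup.any():
        problems.append(f"duplicate replicate key at rows {rows(dup)}")
    if problems:
        raise SchemaError("; ".join(problems))


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format panel CSV/TSV (by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    panel = pd.read_csv(path, sep=sep)
    validate_panel(panel)
    return panel


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    panel[PANEL_COLUMNS].to_csv(path, sep=sep, index=False)


def read_plate_reader(path: str | Path) -> pd.DataFrame:
    """Read a plate-reader export CSV with columns plate, well, OD570."""
    table = pd.read_csv(path)
    required = {"plate", "well", "OD570"}
    if not required.issubset(table.columns):
        raise SchemaError(f"plate-reader table needs columns {sorted(required)}")
    return table
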