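"""Internal-standard GC-MS quantification of volatile compounds.

A known volume ``V`` (μL) of an internal standard at mass concentration
``C1`` (μg/μL) is spiked into a sample of mass ``m`` (g). The absolute
content of an analyte with peak area ``A`` against the internal-standard
peak area ``A1`` is

    C = unit_factor * C1 * V * A / (A1 * m)

which is μg/g for unit_factor = 1 and μg/kg for the default
unit_factor = 1000. Per-stage contents are replicate aggregates (mean by
default). Class-level summaries (per chemical class x stage, with row,
column and grand totals) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign

CHEM_CLASSES = frozenset(
    {"aldehyde", "ketone", "acid", "ester", "alcohol", "hydrocarbon", "other"}
)


class QuantificationError(ValueError):
    """Invalid quantification input (non-positive standard area or mass)."""


@dataclass(frozen=True)
class QuantParams:
    """Constants of the internal-standard equation.

    c1 : internal-standard mass concentration, μg/μL (> 0)
    v : spiked internal-standard volume, μL (> 0)
    m : sample mass, g (> 0)
    unit_factor : multiplier from μg/g to the output unit (1000 -> μg/kg)
    """

    c1: float
    v: float
    m: float
    unit_factor: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("c1", "v", "m", "unit_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"QuantParams.{name} must be > 0")


@dataclass(frozen=True)
class CompoundRecord:
    """Compound metadata: chemical class and optional odor threshold (μg/kg)."""

    name: str
    chem_class: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(
                f"unknown chemical class {self.chem_class!r} for {self.name!r}; "
                f"expected one of {sorted(CHEM_CLASSES)}"
            )
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError(f"threshold for {self.name!r} must be > 0")


@dataclass
class PeakTable:
    """Peak areas per compound x sample plus the internal-standard area.

    ``area`` is a compound x sample DataFrame of analyte peak areas (>= 0);
    ``is_area`` is a per-sample Series of internal-standard peak areas (> 0).
    """

    area: pd.DataFrame
    is_area: pd.Series

    def __post_init__(self) -> None:
        self.is_area = self.is_area.reindex(self.area.columns)
        if self.is_area.isna().any():
            missing = list(self.is_area.index[self.is_area.isna()])
            raise ValueError(f"internal-standard area missing for samples {missing}")
        if (self.area.to_numpy() < 0).any():
            raise ValueError("peak areas must be >= 0")

    @property
    def compounds(self) -> list[str]:
        return list(self.area.index)

    @property
    def samples(self) -> list[str]:
        return list(self.area.columns)


@dataclass
class ContentMatrix:
    """Absolute contents (compound x stage, μg/kg) with a detection mask.

    Not-detected is stored as an exact 0 with ``detected`` False, because
    class-level sums treat missing cells as zero.
    """

    values: pd.DataFrame
    detected: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = self.values > 0
        if (self.values.to_numpy() < 0).any():
            raise ValueError("contents must be >= 0")
        if not self.detected.index.equals(self.values.index) or not (
            self.detected.columns.equals(self.values.columns)
        ):
            raise ValueError("detection mask must be aligned with values")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)


def _stage_map(design: StageDesign | pd.DataFrame, samples: list[str]) -> pd.Series:
    """Map sample id -> stage label, validating coverage."""
    frame = design.to_frame() if isinstance(design, StageDesign) else design
    missing = [s for s in samples if s not in frame.index]
    if missing:
        raise ValueError(f"samples not present in design: {missing}")
    return frame.loc[samples, "stage"]


def compute_absolute_content(
    peaks: PeakTable,
    params: QuantParams,
    design: StageDesign | pd.DataFrame,
    replicate_rule: str = "mean",
) -> ContentMatrix:
    """Convert peak areas to per-stage absolute contents (μg/kg).

    Per sample: C = unit_factor * c1 * v * A / (A1 * m); the per-stage
    value aggregates replicates by ``replicate_rule`` ('mean' or 'median').
    A zero peak area yields content 0 flagged not-detected; a compound is
    flagged detected in a stage if any replicate has a positive area.
    """
    if replicate_rule not in ("mean", "median"):
        raise ValueError("replicate_rule must be 'mean' or 'median'")
    bad = peaks.is_area[peaks.is_area <= 0]
    if len(bad):
        raise QuantificationError(
            f"non-positive internal-standard area for samples {list(bad.index)}"
        )

    scale = params.unit_factor * params.c1 * params.v / params.m
    per_sample = peaks.area.div(peaks.is_area, axis=1) * scale

    stages = _stage_map(design, peaks.samples)
    grouped = per_sample.T.groupby(stages.values, sort=False)
    agg = grouped.mean() if replicate_rule == "mean" else grouped.median()
    values = agg.T
    detected = (peaks.area > 0).T.groupby(stages.values, sort=False).any().T

    stage_order = (
        [s for s in design.stages if s in values.columns]
        if isinstance(design, StageDesign)
        else list(dict.fromkeys(stages))
    )
    values = values[stage_order]
    detected = detected[stage_order]
    return ContentMatrix(values=values, detected=detected)


def aggregate_by_class(
    content: ContentMatrix, records: list[CompoundRecord]
) -> pd.DataFrame:
    """Sum contents per chemical class and stage, with marginal totals.

    Returns a class x stage DataFrame with an extra ``Total`` column (per
    class across stages) and a ``Total`` row (per stage across classes);
    the bottom-right cell is the grand total. Class rows appear in the
    canonical class order; only classes present among the records appear.
    """
    by_name = {r.name: r for r in records}
    missing = [c for c in content.compounds if c not in by_name]
    if missing:
        raise ValueError(f"no class record for compounds: {missing}")
    classes = pd.Series(
        {c: by_name[c].chem_class for c in content.compounds}, name="chem_class"
    )
    table = content.values.groupby(classes, sort=False).sum()
    order = [
        c
        for c in ("aldehyde", "ketone", "acid", "ester", "alcohol", "hydrocarbon", "other")
        if c in table.index
    ]
    table = table.loc[order]
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def count_detected(
    content: ContentMatrix, records: list[CompoundRecord]
) -> pd.DataFrame:
    """Number of detected compounds per (class, stage), plus per-stage totals."""
    by_name = {r.name: r for r in records}
    missing = [c for c in content.compounds if c not in by_name]
    if missing:
        raise ValueError(f"no class record for compounds: {missing}")
    classes = pd.Series({c: by_name[c].chem_class for c in content.compounds})
    counts = content.detected.groupby(classes, sort=False).sum().astype(int)
    counts.loc["Total"] = counts.sum(axis=0)
    return counts


def records_from_frame(df: pd.DataFrame) -> list[CompoundRecord]:
    """Build CompoundRecords from a frame with compound/chem_class[/threshold]."""
    recs = []
    for _, row in df.iterrows():
        thr = row.get("threshold_ug_per_kg")
        thr = None if thr is None or pd.isna(thr) else float(thr)
        recs.append(
            CompoundRecord(
                name=str(row["compound"]),
                chem_class=str(row["chem_class"]),
                threshold=thr,
            )
        )
    return recs
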