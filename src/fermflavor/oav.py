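"""Odor activity value (OAV) scoring and key-compound selection.

OAV = content / odor threshold (both μg/kg), per compound and stage. A
compound with OAV >= 1 somewhere is a key flavor contributor; the larger
the OAV, the larger its contribution to perceived aroma. Compounds without
a published threshold cannot be scored and are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .quant import CompoundRecord, ContentMatrix


@dataclass
class OavMatrix:
    """Compound x stage OAV values with a detection mask and provenance.

    OAV is 0 exactly where the content is 0 (not detected); ``excluded``
    lists compounds dropped for lack of a threshold.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    thresholds: pd.Series
    excluded: list[str] = field(default_factory=list)

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class KeyCompoundSet:
    """Key compounds ordered by descending max OAV with the argmax stage."""

    table: pd.DataFrame  # index compound; columns max_oav, argmax_stage

    @property
    def compounds(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, name: str) -> bool:
        return name in self.table.index


def compute_oav(content: ContentMatrix, records: list[CompoundRecord]) -> OavMatrix:
    """Elementwise OAV = content / threshold for compounds with a threshold.

    Compounds lacking a threshold are excluded (with a warning), not an
    error; a non-positive threshold is a validation error.
    """
    by_name = {r.name: r for r in records}
    missing_record = [c for c in content.compounds if c not in by_name]
    if missing_record:
        raise ValueError(f"no compound record for: {missing_record}")

    scored, excluded = [], []
    for c in content.compounds:
        thr = by_name[c].threshold
        if thr is None:
            excluded.append(c)
        else:
            scored.append(c)
    if excluded:
        warnings.warn(
            f"{len(excluded)} compound(s) without odor threshold excluded "
            f"from OAV scoring: {excluded}",
            stacklevel=2,
        )

    thresholds = pd.Series({c: by_name[c].threshold for c in scored}, dtype=float)
    values = content.values.loc[scored].div(thresholds, axis=0)
    return OavMatrix(
        values=values,
        detected=content.detected.loc[scored],
        thresholds=thresholds,
        excluded=excluded,
    )


def select_key_compounds(
    oav: OavMatrix,
    rule: str = "any_stage_ge_1",
    cutoff: float = 1.0,
    listed: list[str] | None = None,
) -> KeyCompoundSet:
    """Select key compounds from an OAV matrix.

    rule = 'any_stage_ge_1' keeps compounds whose maximum OAV over stages
    is >= 1; 'max_ge' uses ``cutoff`` instead of 1; 'listed' keeps an
    explicit compound list regardless of OAV. Ordering is by descending
    max OAV, ties broken by compound name. An empty selection is valid.
    """
    if oav.values.empty:
        raise ValueError("empty OAV matrix")
    max_oav = oav.values.max(axis=1)
    argmax_stage = oav.values.idxmax(axis=1)

    if rule == "any_stage_ge_1":
        keep = max_oav[max_oav >= 1.0].index
    elif rule == "max_ge":
        keep = max_oav[max_oav >= cutoff].index
    elif rule == "listed":
        if listed is None:
            raise ValueError("rule 'listed' requires an explicit compound list")
        unknown = [c for c in listed if c not in oav.values.index]
        if unknown:
            raise ValueError(f"listed compounds not in OAV matrix: {unknown}")
        keep = pd.Index(listed)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")

    table = pd.DataFrame(
        {"max_oav": max_oav.loc[keep], "argmax_stage": argmax_stage.loc[keep]}
    )
    # descending max OAV, ties broken by ascending name
    table = (
        table.reset_index(names="compound")
        .sort_values(["max_oav", "compound"], ascending=[False, True], kind="mergesort")
        .set_index("compound")
    )
    return KeyCompoundSet(table=table)


def stage_profile(oav: OavMatrix, stage: str, top_k: int = 10) -> pd.Series:
    """Top-k compounds by OAV at one stage, descending (name breaks ties)."""
    if stage not in oav.values.columns:
        raise KeyError(f"unknown stage: {stage!r}")
    col = oav.values[stage]
    ranked = col.iloc[
        sorted(range(len(col)), key=lambda i: (-col.iloc[i], col.index[i]))
    ]
    return ranked.head(top_k)
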