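"""Stage/replicate experimental design for staged fermentation studies.

A processing run is an ordered sequence of stages (raw material, salting,
washing/drying, fermentation, maturation ...), each sampled by a fixed
number of parallel replicates. Downstream modules use the design to map
sample ids to (stage, replicate) and to aggregate replicates per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_STAGES = tuple(f"HT{i}" for i in range(1, 10))


@dataclass(frozen=True)
class StageDesign:
    """Ordered processing stages with a fixed replicate count per stage.

    Parameters
    ----------
    stages
        Ordered, unique stage labels. Defaults to the nine-stage ham
        processing sequence HT1..HT9 (raw material through 3-year maturity).
    replicates_per_stage
        Number of parallel samples per stage (default 3).
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    _sep: str = field(default="-", repr=False)

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("at least one stage required")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if self.replicates_per_stage < 1:
            raise ValueError("replicates_per_stage must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.stages) * self.replicates_per_stage

    def sample_ids(self) -> list[str]:
        """Sample ids in stage-major order, e.g. HT1-1, HT1-2, HT1-3, HT2-1, ..."""
        return [
            f"{stage}{self._sep}{rep}"
            for stage in self.stages
            for rep in range(1, self.replicates_per_stage + 1)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Design table: index sample id, columns ``stage`` and ``replicate``."""
        rows = [
            (f"{stage}{self._sep}{rep}", stage, rep)
            for stage in self.stages
            for rep in range(1, self.replicates_per_stage + 1)
        ]
        df = pd.DataFrame(rows, columns=["sample", "stage", "replicate"])
        return df.set_index("sample")

    def stage_of(self, sample: str) -> str:
        stage = self.to_frame().loc[sample, "stage"]
        return str(stage)

    def samples_of(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise KeyError(f"unknown stage: {stage!r}")
        return [
            f"{stage}{self._sep}{rep}"
            for rep in range(1, self.replicates_per_stage + 1)
        ]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StageDesign":
        """Rebuild a design from a (sample, stage, replicate) table.

        Stage order follows first appearance; the replicate count must be
        identical across stages.
        """
        if "stage" not in df.columns:
            raise ValueError("design frame needs a 'stage' column")
        stages = tuple(dict.fromkeys(df["stage"]))
        counts = df.groupby("stage", sort=False).size()
        if counts.nunique() != 1:
            raise ValueError("unbalanced design: unequal replicates per stage")
        return cls(stages=stages, replicates_per_stage=int(counts.iloc[0]))
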