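"""OTU count table and taxonomy containers shared by the community modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"


@dataclass
class OtuTable:
    """Integer OTU x sample count matrix with a sample design.

    ``counts``: DataFrame, index OTU ids, columns sample ids, values
    non-negative integers. ``design``: DataFrame indexed by sample with
    columns ``stage`` and ``replicate``; every count column must appear.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate OTU or sample ids")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.design.loc[self.sample_ids, "stage"]))

    def sample_stage(self) -> pd.Series:
        """sample id -> stage label, in column order."""
        return self.design.loc[self.sample_ids, "stage"]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            zero = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero total counts: {zero}")
        return self.counts / totals


class TaxonomyMap:
    """OTU id -> ranked lineage (kingdom..genus), 'unclassified' sentinel.

    Backed by a DataFrame with one column per rank; unresolved ranks hold
    the sentinel. Lineages may also be parsed from/formatted to the
    semicolon-joined "k__...;p__...;...;g__..." convention.
    """

    PREFIXES = dict(zip(RANKS, ("k", "p", "c", "o", "f", "g")))

    def __init__(self, frame: pd.DataFrame):
        missing_cols = [r for r in RANKS if r not in frame.columns]
        if missing_cols:
            raise ValueError(f"taxonomy frame missing ranks: {missing_cols}")
        self.frame = frame[list(RANKS)].fillna(UNCLASSIFIED)

    def rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unsupported rank {rank!r}")
        return self.frame[rank]

    def for_otus(self, otu_ids) -> "TaxonomyMap":
        missing = [o for o in otu_ids if o not in self.frame.index]
        if missing:
            raise ValueError(f"OTUs without taxonomy entry: {missing}")
        return TaxonomyMap(self.frame.loc[otu_ids])

    def to_lineage_strings(self) -> pd.Series:
        parts = [
            self.frame[r].map(lambda v, p=self.PREFIXES[r]: f"{p}__{v}") for r in RANKS
        ]
        return pd.Series(
            [";".join(row) for row in zip(*(p.tolist() for p in parts))],
            index=self.frame.index,
            name="lineage",
        )

    @classmethod
    def from_lineage_strings(cls, lineages: pd.Series) -> "TaxonomyMap":
        rows = []
        for s in lineages:
            fields = {r: UNCLASSIFIED for r in RANKS}
            for token in str(s).split(";"):
                token = token.strip()
                if "__" in token:
                    prefix, value = token.split("__", 1)
                    for r, p in cls.PREFIXES.items():
                        if prefix == p:
                            fields[r] = value or UNCLASSIFIED
            rows.append(fields)
        return cls(pd.DataFrame(rows, index=lineages.index))
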