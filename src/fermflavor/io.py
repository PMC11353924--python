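"""Plain-text I/O for the pipeline's tables.

Conventions: OTU tables are TSV with a "#OTU ID" first column and one
column per sample; taxonomy is TSV with semicolon-joined lineages
("k__...;p__...;...;g__..."); everything else is CSV with UTF-8 and "."
decimals. "-" encodes not-detected on read and is written back for cells
that are zero with a False detection mask.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import StageDesign
from .otu import OtuTable, TaxonomyMap
from .quant import ContentMatrix, PeakTable

IS_ROW = "__internal_standard__"
ND = "-"


# ---- OTU table -------------------------------------------------------------

def write_otu_table(otus: OtuTable, path: str | Path) -> None:
    df = otus.counts.copy()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def read_otu_table(path: str | Path, design: pd.DataFrame) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return OtuTable(counts=df, design=design)


# ---- taxonomy --------------------------------------------------------------

def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    out = tax.to_lineage_strings().to_frame()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TaxonomyMap.from_lineage_strings(df["lineage"])


# ---- design ----------------------------------------------------------------

def write_design(design: StageDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


# ---- peak table ------------------------------------------------------------

def write_peak_table(peaks: PeakTable, path: str | Path) -> None:
    """Compound x sample areas with a reserved internal-standard row."""
    df = peaks.area.copy()
    df.loc[IS_ROW] = peaks.is_area
    df.index.name = "compound"
    df.to_csv(path)


def read_peak_table(path: str | Path) -> PeakTable:
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    if IS_ROW not in df.index:
        raise ValueError(f"peak table lacks the reserved {IS_ROW!r} row")
    is_area = df.loc[IS_ROW]
    is_area.name = None
    return PeakTable(area=df.drop(index=IS_ROW), is_area=is_area)


# ---- content matrices ------------------------------------------------------

def write_content(content: ContentMatrix, path: str | Path) -> None:
    """Write contents with "-" for not-detected cells."""
    out = content.values.astype(object).copy()
    out[~content.detected] = ND
    out.index.name = "compound"
    out.to_csv(path)


def read_content(path: str | Path) -> ContentMatrix:
    raw = pd.read_csv(path, index_col=0)
    raw.index.name = None
    values = raw.replace(ND, 0.0).astype(float)
    # "-" and explicit zeros both mean not-detected
    return ContentMatrix(values=values, detected=values > 0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str | None = None) -> None:
    out = df.copy()
    if index_name:
        out.index.name = index_name
    out.to_csv(path)
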