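"""Packaged reference tables from the Mianning-ham processing study.

Three small fixtures transcribed from the study's printed tables ship with
the package:

- class-level absolute contents (seven chemical classes x nine stages,
  μg/kg) — the class-aggregation reference;
- the key-compound OAV matrix with odor thresholds (27 compounds x nine
  stages) — thresholds are reusable as a starting threshold set;
- bacterial and fungal alpha-diversity summaries (mean ± sd per stage) —
  regression references only: they derive from the study's raw reads,
  which this package does not process.

"-" cells mean not detected and load as 0 with a False detection mask.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quant import CompoundRecord, ContentMatrix

STAGES = tuple(f"HT{i}" for i in range(1, 10))


def _data_path(name: str):
    return resources.files("fermflavor.data").joinpath(name)


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def load_class_content() -> tuple[ContentMatrix, list[CompoundRecord]]:
    """Class x stage absolute contents (μg/kg) with one record per class row."""
    df = _read("table3_class_content.csv").set_index("compound")
    values = df[list(STAGES)].replace("-", 0.0).astype(float)
    records = [
        CompoundRecord(name=str(name), chem_class=str(row["chem_class"]))
        for name, row in df.iterrows()
    ]
    return ContentMatrix(values=values, detected=values > 0), records


def load_key_compound_oav() -> pd.DataFrame:
    """Key-compound OAV matrix: index compound, threshold + stage columns.

    Stage cells are floats with NaN for not-detected ("-"); printed zeros
    stay 0.0 (also not detected).
    """
    df = _read("table4_oav.csv").set_index("compound")
    for c in STAGES:
        df[c] = pd.to_numeric(df[c].replace("-", float("nan")))
    df["threshold_ug_per_kg"] = df["threshold_ug_per_kg"].astype(float)
    return df


def load_thresholds() -> pd.DataFrame:
    """Odor thresholds (compound, threshold_ug_per_kg) from the OAV fixture."""
    return (
        load_key_compound_oav()["threshold_ug_per_kg"]
        .rename_axis("compound")
        .reset_index()
    )


def load_alpha_reference(kingdom: str = "bacteria") -> pd.DataFrame:
    """Stage-level alpha-diversity summaries (mean/sd), regression reference."""
    name = {
        "bacteria": "table1_bacterial_alpha.csv",
        "fungi": "table2_fungal_alpha.csv",
    }.get(kingdom)
    if name is None:
        raise ValueError("kingdom must be 'bacteria' or 'fungi'")
    return _read(name).set_index("group")


def oav_fixture_as_content() -> tuple[ContentMatrix, list[CompoundRecord]]:
    """Reconstruct contents as OAV x threshold from the key-compound fixture.

    Inverts the OAV definition cell-by-cell, giving a compound x stage
    content matrix (μg/kg) whose re-scoring round-trips to the printed
    OAV values.
    """
    df = load_key_compound_oav()
    thr = df["threshold_ug_per_kg"]
    oav = df[list(STAGES)]
    values = oav.mul(thr, axis=0).fillna(0.0)
    detected = oav.notna() & (oav > 0)
    records = [
        CompoundRecord(name=str(c), chem_class="other", threshold=float(thr[c]))
        for c in df.index
    ]
    return ContentMatrix(values=values, detected=detected), records
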