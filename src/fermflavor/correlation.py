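"""Taxa x flavor-compound Pearson correlation with significance stars.

The integrative step: each dominant taxon's abundance trajectory is
correlated against each key compound's content (or OAV — Pearson r is
invariant to the per-compound positive rescaling between the two) across
the shared axis, by default the ordered processing stages. p-values are
two-sided from the t transform t = r sqrt(n-2) / sqrt(1 - r^2) on n-2
degrees of freedom; cells are starred "*" for p < 0.05 and "**" for
p < 0.01 (configurable), mirroring the usual
"significant / extremely significant" heatmap annotation. Constant
vectors yield an undefined-correlation flag (blank cell), never r = 0.
Benjamini-Hochberg adjustment is available but off by default, matching
how such heatmaps are conventionally presented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import RESERVED_LABELS
from .oav import KeyCompoundSet
from .quant import ContentMatrix


@dataclass
class CorrelationResult:
    """(taxon, compound) grid of r, p and stars plus the pairing used."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int
    pairing: str
    star_thresholds: tuple[float, float] = (0.05, 0.01)

    def long_format(self) -> pd.DataFrame:
        rows = []
        for taxon in self.r.index:
            for compound in self.r.columns:
                rows.append(
                    {
                        "taxon": taxon,
                        "compound": compound,
                        "r": self.r.loc[taxon, compound],
                        "p": self.p.loc[taxon, compound],
                        "stars": self.stars.loc[taxon, compound],
                        "n": self.n,
                    }
                )
        return pd.DataFrame(rows)


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Returns (nan, nan) — the undefined-correlation flag — when either
    vector is constant. |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-15:
        return (float(np.sign(r)), 0.0)
    return (float(r), float(p))


def build_feature_sets(
    phylum_comp: pd.DataFrame,
    genus_comp: pd.DataFrame,
    content: ContentMatrix,
    keys: KeyCompoundSet | list[str] | None = None,
    n_phyla: int = 3,
    n_genera: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dominant-taxa and key-compound feature matrices on the stage axis.

    Taxa features stack the top ``n_phyla`` phyla over the top ``n_genera``
    genera by mean abundance (reserved labels excluded) — the conventional
    "3 phyla rows above 10 genus rows" heatmap layout. Compound features
    are the key compounds' per-stage values. Requesting more taxa than
    exist returns what exists with a warning.
    """
    import warnings

    def top(comp: pd.DataFrame, k: int, kind: str) -> pd.DataFrame:
        known = comp.drop(index=[t for t in RESERVED_LABELS if t in comp.index])
        if k > len(known):
            warnings.warn(
                f"requested {k} {kind} but only {len(known)} available",
                stacklevel=3,
            )
            k = len(known)
        order = known.mean(axis=1).sort_values(ascending=False, kind="mergesort")
        return known.loc[order.index[:k]]

    taxa = pd.concat(
        [top(phylum_comp, n_phyla, "phyla"), top(genus_comp, n_genera, "genera")]
    )
    if keys is None:
        names = list(content.compounds)
    elif isinstance(keys, KeyCompoundSet):
        names = keys.compounds
    else:
        names = list(keys)
    missing = [c for c in names if c not in content.values.index]
    if missing:
        raise ValueError(f"key compounds absent from content matrix: {missing}")
    compounds = content.values.loc[names]
    return taxa, compounds


def correlation_grid(
    taxa: pd.DataFrame,
    compounds: pd.DataFrame,
    pairing: str = "stage_means",
    star_thresholds: tuple[float, float] = (0.05, 0.01),
    bh_adjust: bool = False,
) -> CorrelationResult:
    """Pearson r/p/stars for every (taxon, compound) pair on a shared axis.

    Both feature frames must share their column axis (stages for the
    default 'stage_means' pairing, samples for 'per_sample'). Stars:
    "*" iff p < star_thresholds[0], "**" iff p < star_thresholds[1].
    ``bh_adjust`` applies Benjamini-Hochberg to the defined p-values
    before starring.
    """
    if pairing not in ("stage_means", "per_sample"):
        raise ValueError("pairing must be 'stage_means' or 'per_sample'")
    if list(taxa.columns) != list(compounds.columns):
        only_t = [c for c in taxa.columns if c not in compounds.columns]
        only_c = [c for c in compounds.columns if c not in taxa.columns]
        raise ValueError(
            "taxa and compound features are not aligned; "
            f"taxa-only columns {only_t}, compound-only columns {only_c}"
        )
    n = taxa.shape[1]
    if n < 3:
        raise ValueError("shared axis must have length >= 3")

    r = pd.DataFrame(index=taxa.index, columns=compounds.index, dtype=float)
    p = pd.DataFrame(index=taxa.index, columns=compounds.index, dtype=float)
    for t in taxa.index:
        xv = taxa.loc[t].to_numpy(dtype=float)
        for c in compounds.index:
            r.loc[t, c], p.loc[t, c] = pearson_r_p(xv, compounds.loc[c].to_numpy())

    p_star = p.copy()
    if bh_adjust:
        flat = p.to_numpy().ravel()
        defined = ~np.isnan(flat)
        adj = flat.copy()
        adj[defined] = stats.false_discovery_control(flat[defined], method="bh")
        p_star = pd.DataFrame(
            adj.reshape(p.shape), index=p.index, columns=p.columns
        )

    lo, hi = star_thresholds
    stars = p_star.map(
        lambda v: "" if pd.isna(v) else ("**" if v < hi else "*" if v < lo else "")
    )
    return CorrelationResult(
        r=r, p=p_star, stars=stars, n=n, pairing=pairing,
        star_thresholds=star_thresholds,
    )
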