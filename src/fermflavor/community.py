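"""Community-structure summaries: group presence/Venn, taxonomy stacks.

Presence follows the tag-count rule used for shared/unique OTU Venn
analyses of staged fermentations: an OTU is present in a group when its
mean raw tag count over the group's samples is strictly greater than 1.
Composition tables aggregate counts to a taxonomic rank as relative
abundances; stacked-bar preparation keeps the top-k known taxa, pools the
remaining known taxa into "Others" and keeps "unclassified" as its own band.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import pandas as pd

from .otu import UNCLASSIFIED, OtuTable, TaxonomyMap

OTHERS = "Others"
RESERVED_LABELS = (OTHERS, UNCLASSIFIED)


def group_presence(
    otus: OtuTable, grouping: pd.Series | None = None, threshold: float = 1.0
) -> dict[str, set[str]]:
    """OTU presence per group: mean tag count over group samples > threshold.

    ``grouping`` maps sample id -> group label; default is the design's
    stage. The strict inequality makes (3, 0, 0) absent (mean exactly 1).
    """
    if grouping is None:
        grouping = otus.sample_stage()
    unassigned = [s for s in otus.sample_ids if s not in grouping.index]
    if unassigned:
        raise ValueError(f"samples without group assignment: {unassigned}")
    grouping = grouping.loc[otus.sample_ids]
    if grouping.isna().any():
        raise ValueError("grouping contains missing labels")
    means = otus.counts.T.groupby(grouping.values, sort=False).mean().T
    return {
        str(g): set(means.index[means[g] > threshold]) for g in means.columns
    }


def venn_counts(presence: dict[str, set[str]]) -> dict:
    """Core/unique counts and the membership-pattern lattice.

    Returns ``core`` (size of the intersection of all groups), ``unique``
    (per group, members in no other group), and — for up to 6 groups —
    ``regions``: exclusive region sizes keyed by the tuple of member
    groups (inclusion–exclusion consistent: region sizes sum to the union).
    Above 6 groups only core/unique/pairwise are reported.
    """
    groups = list(presence)
    if len(groups) < 2:
        raise ValueError("venn analysis needs at least 2 groups")
    sets = {g: set(presence[g]) for g in groups}
    universe = set().union(*sets.values())

    core = set.intersection(*sets.values())
    unique = {
        g: sets[g] - set().union(*(sets[h] for h in groups if h != g)) for g in groups
    }
    out = {
        "core": len(core),
        "unique": {g: len(unique[g]) for g in groups},
        "union": len(universe),
        "pairwise": {
            (a, b): len(sets[a] & sets[b]) for a, b in combinations(groups, 2)
        },
    }
    if len(groups) <= 6:
        regions: dict[tuple[str, ...], int] = {}
        for otu in universe:
            member = tuple(g for g in groups if otu in sets[g])
            regions[member] = regions.get(member, 0) + 1
        out["regions"] = regions
    return out


def aggregate_taxonomy(
    otus: OtuTable, tax: TaxonomyMap, rank: str = "genus"
) -> pd.DataFrame:
    """Relative abundance per taxon label at a rank (taxon x sample).

    Counts are summed per label and divided by the sample total; OTUs
    unresolved at the rank pool into "unclassified". Samples with zero
    total are dropped with a warning. Columns sum to 1.
    """
    labels = tax.for_otus(otus.otu_ids).rank(rank)
    totals = otus.counts.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        warnings.warn(f"dropping zero-total samples: {zero}", stacklevel=2)
    counts = otus.counts.drop(columns=zero)
    agg = counts.groupby(labels.values, sort=False).sum()
    comp = agg / agg.sum(axis=0)
    return comp


def collapse_to_stages(comp: pd.DataFrame, otus: OtuTable) -> pd.DataFrame:
    """Average per-sample compositions into per-stage compositions."""
    stages = otus.sample_stage().loc[comp.columns]
    return comp.T.groupby(stages.values, sort=False).mean().T


def top_taxa_stack(comp: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Stacked-bar table: top-k known taxa + "Others" + "unclassified".

    Ranking is by mean abundance across all columns; "unclassified" never
    competes for a top-k slot and is shown as its own band. Column sums
    are preserved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    known = comp.drop(index=[t for t in RESERVED_LABELS if t in comp.index])
    order = known.mean(axis=1).sort_values(ascending=False, kind="mergesort")
    top = list(order.index[:k])
    rest = [t for t in known.index if t not in top]

    rows = comp.loc[top]
    if rest:
        rows = pd.concat(
            [rows, comp.loc[rest].sum(axis=0).rename(OTHERS).to_frame().T]
        )
    elif OTHERS in comp.index:
        rows = pd.concat([rows, comp.loc[[OTHERS]]])
    if UNCLASSIFIED in comp.index:
        rows = pd.concat([rows, comp.loc[[UNCLASSIFIED]]])
    return rows


def dominant_taxon(comp: pd.DataFrame, stage: str) -> tuple[str, float]:
    """Most abundant non-reserved taxon in one column (ties: alphabetical)."""
    if stage not in comp.columns:
        raise KeyError(f"unknown stage/column: {stage!r}")
    col = comp[stage].drop(index=[t for t in RESERVED_LABELS if t in comp.index])
    if col.empty:
        raise ValueError("no non-reserved taxa in composition")
    best = col.max()
    winners = sorted(col.index[col == best])
    if len(winners) > 1:
        warnings.warn(
            f"dominance tie at {stage!r} between {winners}; "
            "returning the alphabetically first",
            stacklevel=2,
        )
    return winners[0], float(best)
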