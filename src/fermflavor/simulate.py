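"""Synthetic stage-structured OTU and GC-MS experiments with known truth.

Emulates the data layout of a staged fermentation study — nine ordered
processing stages sampled in triplicate — so every downstream analysis is
testable without sequencing data:

- Community: each replicate's composition is a Dirichlet draw centered on
  its stage profile; counts are multinomial at a negative-binomial library
  size (uneven sequencing depth). Stage profiles drift smoothly across
  stages (succession); specific taxa can be planted as stage dominants at
  a target relative abundance.
- Flavor: compound contents per stage are baselines plus Gaussian noise;
  a linked (taxon, compound) pair makes the compound's stage-mean content
  an affine function of the taxon's stage-mean relative abundance, with
  the slope calibrated from the noise so the population Pearson
  correlation equals the target r. Peak areas are constructed by
  inverting the internal-standard equation, so quantification recovers
  the ground-truth content matrix exactly.

All randomness flows through one seeded generator per call; identical
seeds give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign
from .otu import RANKS, UNCLASSIFIED, OtuTable, TaxonomyMap
from .quant import CHEM_CLASSES, ContentMatrix, PeakTable, QuantParams

CLASS_CYCLE = ("aldehyde", "ketone", "acid", "ester", "alcohol", "hydrocarbon", "other")


@dataclass
class CommunitySimParams:
    """Parameters of the community generator.

    stage_profiles maps stage -> base composition on the simplex; None
    draws smoothly drifting succession profiles at generation time.
    dirichlet_concentration scales replicate-level noise (larger = tighter
    around the stage profile; math.inf = no replicate noise).
    planted_dominants re-weight a stage's profile so one taxon holds a
    target relative abundance.
    """

    n_otus: int = 150
    library_size_mean: int = 20_000
    library_size_dispersion: float = 5.0
    stage_profiles: dict[str, np.ndarray] | None = None
    dirichlet_concentration: float = 200.0
    planted_dominants: list[tuple[str, int, float]] = field(default_factory=list)
    unclassified_fraction: float = 0.1
    n_phyla: int = 4
    n_genera: int = 40

    def validate(self, design: StageDesign) -> None:
        if self.n_otus <= 0:
            raise ValueError("n_otus must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.library_size_dispersion <= 0:
            raise ValueError("library_size_dispersion must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if not 0 <= self.unclassified_fraction <= 1:
            raise ValueError("unclassified_fraction must be in [0, 1]")
        if self.stage_profiles is not None:
            for stage in design.stages:
                if stage not in self.stage_profiles:
                    raise ValueError(f"no stage profile for {stage!r}")
                p = np.asarray(self.stage_profiles[stage], dtype=float)
                if p.shape != (self.n_otus,):
                    raise ValueError(f"profile for {stage!r} has wrong length")
                if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise ValueError(
                        f"profile for {stage!r} must be on the simplex (sum 1)"
                    )
        for stage, idx, target in self.planted_dominants:
            if stage not in design.stages:
                raise ValueError(f"planted dominant references unknown stage {stage!r}")
            if not 0 <= idx < self.n_otus:
                raise ValueError(f"planted dominant taxon index {idx} out of range")
            if not 0 < target < 1:
                raise ValueError("planted target abundance must be in (0, 1)")


def succession_profiles(
    stages: tuple[str, ...], n_otus: int, rng: np.random.Generator, drift: float = 0.6
) -> dict[str, np.ndarray]:
    """Smoothly drifting stage compositions via a log-space random walk."""
    log_w = rng.normal(0.0, 1.0, size=n_otus)
    profiles = {}
    for stage in stages:
        w = np.exp(log_w)
        profiles[stage] = w / w.sum()
        log_w = log_w + rng.normal(0.0, drift, size=n_otus)
    return profiles


def _plant_dominant(profile: np.ndarray, idx: int, target: float) -> np.ndarray:
    """Set taxon idx to `target`, rescale the rest to 1 - target."""
    out = profile.copy()
    others = 1.0 - out[idx]
    out[idx] = 0.0
    if others > 0:
        out *= (1.0 - target) / others
    out[idx] = target
    return out / out.sum()


def generate_otu_experiment(
    design: StageDesign, params: CommunitySimParams, seed: int
) -> tuple[OtuTable, TaxonomyMap]:
    """Draw a stage-structured OTU count table and matching taxonomy."""
    params.validate(design)
    rng = np.random.default_rng(seed)

    profiles = (
        {s: np.asarray(p, dtype=float) for s, p in params.stage_profiles.items()}
        if params.stage_profiles is not None
        else succession_profiles(design.stages, params.n_otus, rng)
    )
    for stage, idx, target in params.planted_dominants:
        profiles[stage] = _plant_dominant(profiles[stage], idx, target)

    mean = params.library_size_mean
    k = params.library_size_dispersion
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(params.n_otus)]

    columns = {}
    for stage in design.stages:
        base = profiles[stage]
        for rep in range(1, design.replicates_per_stage + 1):
            size = max(int(rng.negative_binomial(k, k / (k + mean))), 1)
            if math.isinf(params.dirichlet_concentration):
                comp = base
            else:
                alpha = np.clip(params.dirichlet_concentration * base, 1e-8, None)
                comp = rng.dirichlet(alpha)
            columns[f"{stage}-{rep}"] = rng.multinomial(size, comp)

    counts = pd.DataFrame(columns, index=otu_ids)
    table = OtuTable(counts=counts, design=design.to_frame())

    phylum_pool = [f"Phylum_{i + 1:02d}" for i in range(params.n_phyla)]
    genus_pool = [f"Genus_{i + 1:03d}" for i in range(params.n_genera)]
    phyla = rng.choice(phylum_pool, size=params.n_otus)
    genera = rng.choice(genus_pool, size=params.n_otus)
    unknown = rng.random(params.n_otus) < params.unclassified_fraction
    genera = np.where(unknown, UNCLASSIFIED, genera)
    tax = TaxonomyMap(
        pd.DataFrame(
            {
                "kingdom": "Bacteria",
                "phylum": phyla,
                "class": UNCLASSIFIED,
                "order": UNCLASSIFIED,
                "family": UNCLASSIFIED,
                "genus": genera,
            },
            index=otu_ids,
        )[list(RANKS)]
    )
    return table, tax


@dataclass
class FlavorSimParams:
    """Parameters of the flavor-compound generator.

    baseline_content is a compound x stage matrix of μg/kg baselines
    (None draws lognormal per-compound levels at generation time).
    linked_pairs plant (taxon index, compound index, target Pearson r)
    correlations on the stage-mean axis; the slope is calibrated from
    noise_sd so the population correlation equals the target. |r| = 1
    requires noise_sd = 0 (and vice versa for 0 < |r| < 1) — anything
    else is unreachable and rejected.
    """

    n_compounds: int = 30
    class_assignment: dict[int, str] | None = None
    baseline_content: pd.DataFrame | None = None
    linked_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 5.0
    quant: QuantParams = field(default_factory=lambda: QuantParams(c1=1.0, v=1.0, m=3.0))
    internal_standard_area: float = 1.0e6
    baseline_level: float = 150.0

    def validate(self, n_taxa: int) -> None:
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.internal_standard_area <= 0:
            raise ValueError("internal_standard_area must be positive")
        for taxon, compound, r in self.linked_pairs:
            if not 0 <= taxon < n_taxa:
                raise ValueError(f"linked taxon index {taxon} out of range")
            if not 0 <= compound < self.n_compounds:
                raise ValueError(f"linked compound index {compound} out of range")
            if abs(r) > 1:
                raise ValueError("target correlation must satisfy |r| <= 1")
            if abs(r) == 1 and self.noise_sd > 0:
                raise ValueError(
                    "target |r| = 1 with noise_sd > 0 is unreachable"
                )
            if 0 < abs(r) < 1 and self.noise_sd == 0:
                raise ValueError(
                    "target 0 < |r| < 1 with noise_sd = 0 is unreachable"
                )
        if self.class_assignment is not None:
            bad = set(self.class_assignment.values()) - CHEM_CLASSES
            if bad:
                raise ValueError(f"unknown chemical classes: {sorted(bad)}")


def generate_flavor_experiment(
    design: StageDesign,
    otus: OtuTable,
    params: FlavorSimParams,
    seed: int,
) -> tuple[PeakTable, pd.DataFrame, ContentMatrix]:
    """Draw a peak-area experiment whose quantification recovers the truth.

    Returns (peak table, threshold table, ground-truth content matrix).
    The threshold table assigns each compound its median stage content as
    the odor threshold (so OAVs straddle 1), with a positive floor.
    """
    params.validate(n_taxa=len(otus.otu_ids))
    rng = np.random.default_rng(seed)
    stages = list(design.stages)
    names = [f"compound_{j + 1:03d}" for j in range(params.n_compounds)]

    if params.baseline_content is not None:
        baseline = params.baseline_content.to_numpy(dtype=float)
        if baseline.shape != (params.n_compounds, len(stages)):
            raise ValueError("baseline_content has wrong shape")
        if (baseline < 0).any():
            raise ValueError("baseline contents must be >= 0")
    else:
        levels = rng.lognormal(np.log(params.baseline_level), 0.5, params.n_compounds)
        baseline = np.tile(levels[:, None], (1, len(stages)))

    truth = baseline + rng.normal(0.0, params.noise_sd, size=baseline.shape)

    rel = otus.relative_abundance()
    stage_of = otus.sample_stage()
    stage_means = rel.T.groupby(stage_of.values, sort=False).mean().T[stages]

    for taxon, compound, r in params.linked_pairs:
        x = stage_means.iloc[taxon].to_numpy(dtype=float)
        sd_x = float(np.std(x, ddof=1))
        if sd_x == 0:
            raise ValueError(
                f"linked taxon {taxon} has constant stage-mean abundance"
            )
        if abs(r) == 1:
            slope = math.copysign(params.baseline_level / (2 * sd_x), r)
            eps = np.zeros(len(stages))
        elif r == 0:
            slope = 0.0
            eps = rng.normal(0.0, params.noise_sd, size=len(stages))
        else:
            slope = params.noise_sd * r / (sd_x * math.sqrt(1.0 - r * r))
            eps = rng.normal(0.0, params.noise_sd, size=len(stages))
        signal = slope * (x - x.mean())
        # intercept far enough above zero that clipping is ~impossible
        intercept = max(
            float(baseline[compound].mean()),
            6.0 * (params.noise_sd + abs(slope) * sd_x),
        )
        truth[compound] = intercept + signal + eps

    truth = np.clip(truth, 0.0, None)
    truth_df = pd.DataFrame(truth, index=names, columns=stages)

    if params.class_assignment is not None:
        classes = [
            params.class_assignment.get(j, CLASS_CYCLE[j % len(CLASS_CYCLE)])
            for j in range(params.n_compounds)
        ]
    else:
        classes = [CLASS_CYCLE[j % len(CLASS_CYCLE)] for j in range(params.n_compounds)]

    med = np.median(truth, axis=1)
    thresholds = pd.DataFrame(
        {
            "compound": names,
            "chem_class": classes,
            "threshold_ug_per_kg": np.maximum(med, 1e-3),
        }
    )

    # invert C = unit_factor * c1 * v * A / (A1 * m): replicates share the
    # stage truth, so the replicate mean recovers it exactly
    q = params.quant
    sample_ids = design.sample_ids()
    is_area = pd.Series(params.internal_standard_area, index=sample_ids)
    stage_idx = {s: i for i, s in enumerate(stages)}
    frame = design.to_frame()
    area = {}
    for sample in sample_ids:
        i = stage_idx[str(frame.loc[sample, "stage"])]
        c = truth[:, i]
        area[sample] = c * is_area[sample] * q.m / (q.unit_factor * q.c1 * q.v)
    peaks = PeakTable(area=pd.DataFrame(area, index=names), is_area=is_area)

    return peaks, thresholds, ContentMatrix(values=truth_df)
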