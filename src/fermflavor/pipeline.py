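"""End-to-end orchestration: simulate/ingest -> quantify -> OAV ->
diversity -> community -> ordination -> correlation -> report.

Configuration is a YAML mapping validated up front (unknown keys rejected,
all violations reported together, defaults injected explicitly). A run
writes every stage's tables as CSV/TSV into an output directory plus a
JSON report with a checksum manifest; identical config + seed reproduces
byte-identical payloads. Stages degrade gracefully: without a taxonomy the
community and correlation stages are skipped while quantification, OAV and
diversity still complete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import community as community_mod
from . import io as fio
from .correlation import build_feature_sets, correlation_grid
from .design import StageDesign
from .diversity import alpha_diversity_table, stage_summary
from .oav import compute_oav, select_key_compounds
from .ordination import pca
from .otu import OtuTable, TaxonomyMap
from .quant import (
    QuantParams,
    aggregate_by_class,
    compute_absolute_content,
    count_detected,
    records_from_frame,
)
from .simulate import (
    CommunitySimParams,
    FlavorSimParams,
    generate_flavor_experiment,
    generate_otu_experiment,
)

log = logging.getLogger("fermflavor")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "fermflavor_run",
    "design": {
        "stages": [f"HT{i}" for i in range(1, 10)],
        "replicates_per_stage": 3,
    },
    "simulate": {
        "enabled": True,
        "community": {
            "n_otus": 150,
            "library_size_mean": 20000,
            "library_size_dispersion": 5.0,
            "dirichlet_concentration": 200.0,
            "unclassified_fraction": 0.1,
            "n_phyla": 4,
            "n_genera": 40,
            "planted_dominants": [],
        },
        "flavor": {
            "n_compounds": 30,
            "noise_sd": 5.0,
            "baseline_level": 150.0,
            "linked_pairs": [],
            "internal_standard_area": 1.0e6,
        },
    },
    "inputs": {
        "otu_table": None,
        "taxonomy": None,
        "design_csv": None,
        "peak_table": None,
        "thresholds": None,
    },
    "quant": {"c1": 1.0, "v": 1.0, "m": 3.0, "unit_factor": 1000.0},
    "options": {
        "replicate_rule": "mean",
        "shannon_base": 2,
        "simpson_variant": "plugin",
        "chao1_variant": "bias_corrected",
        "selection_rule": "any_stage_ge_1",
        "transform": "relative",
        "pairing": "stage_means",
        "star_thresholds": [0.05, 0.01],
        "rank_top_k": 10,
        "n_phyla": 3,
        "n_genera": 10,
    },
}

_CHOICES = {
    ("options", "replicate_rule"): ("mean", "median"),
    ("options", "simpson_variant"): ("plugin", "unbiased"),
    ("options", "chao1_variant"): ("bias_corrected", "classic"),
    ("options", "selection_rule"): ("any_stage_ge_1", "max_ge", "listed"),
    ("options", "transform"): ("relative", "hellinger", "clr_pseudocount"),
    ("options", "pairing"): ("stage_means", "per_sample"),
}


@dataclass
class PipelineConfig:
    """Validated configuration with every default made explicit."""

    data: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


def _merge(defaults: dict, raw: dict, path: str, errors: list[str]) -> dict:
    out = {}
    for key, default in defaults.items():
        if key in raw:
            value = raw[key]
            if isinstance(default, dict) and not isinstance(value, dict):
                errors.append(f"{path}{key}: expected a mapping")
                out[key] = default
            elif isinstance(default, dict):
                out[key] = _merge(default, value, f"{path}{key}.", errors)
            else:
                out[key] = value
        else:
            out[key] = json.loads(json.dumps(default))  # deep copy
    for key in raw:
        if key not in defaults:
            errors.append(f"unknown configuration key: {path}{key}")
    return out


def validate_config(raw: dict | None) -> PipelineConfig:
    """Validate + default-fill a raw config mapping.

    All violations are collected and reported in a single ConfigError
    rather than failing on the first. An empty/None input yields the full
    default configuration with the simulator enabled.
    """
    errors: list[str] = []
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    data = _merge(_DEFAULTS, raw, "", errors)

    if not isinstance(data["seed"], int):
        errors.append("seed: must be an integer")
    d = data["design"]
    if not isinstance(d["replicates_per_stage"], int) or d["replicates_per_stage"] < 1:
        errors.append("design.replicates_per_stage: must be a positive integer")
    if not d["stages"] or len(set(d["stages"])) != len(d["stages"]):
        errors.append("design.stages: must be a non-empty list of unique labels")
    sim = data["simulate"]["community"]
    for key in ("n_otus", "library_size_mean"):
        if not isinstance(sim[key], int) or sim[key] <= 0:
            errors.append(f"simulate.community.{key}: must be a positive integer")
    for key in ("library_size_dispersion", "dirichlet_concentration"):
        if sim[key] <= 0:
            errors.append(f"simulate.community.{key}: must be positive")
    if not 0 <= sim["unclassified_fraction"] <= 1:
        errors.append("simulate.community.unclassified_fraction: must be in [0, 1]")
    fl = data["simulate"]["flavor"]
    if not isinstance(fl["n_compounds"], int) or fl["n_compounds"] <= 0:
        errors.append("simulate.flavor.n_compounds: must be a positive integer")
    if fl["noise_sd"] < 0:
        errors.append("simulate.flavor.noise_sd: must be >= 0")
    for key in ("c1", "v", "m", "unit_factor"):
        if data["quant"][key] <= 0:
            errors.append(f"quant.{key}: must be positive")
    for (section, key), choices in _CHOICES.items():
        if data[section][key] not in choices:
            errors.append(f"{section}.{key}: must be one of {choices}")
    st = data["options"]["star_thresholds"]
    if len(st) != 2 or not all(0 < v < 1 for v in st) or st[1] > st[0]:
        errors.append(
            "options.star_thresholds: must be two probabilities (loose, strict)"
        )
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return PipelineConfig(data=data)


def load_config(path: str | Path | None) -> PipelineConfig:
    raw = None
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return validate_config(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunReport:
    outdir: Path
    manifest: dict[str, str] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"manifest": self.manifest, "summary": self.summary}, indent=2, sort_keys=True
        )


def run(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full analysis described by a validated config."""
    cfg = config.data
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    opts = cfg["options"]
    seed = cfg["seed"]
    design = StageDesign(
        stages=tuple(cfg["design"]["stages"]),
        replicates_per_stage=cfg["design"]["replicates_per_stage"],
    )
    report = RunReport(outdir=out)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index_label: str | None = None) -> None:
        path = out / name
        tmp = df.copy()
        if index_label:
            tmp.index.name = index_label
        tmp.to_csv(path, sep="\t" if name.endswith(".tsv") else ",")
        written.append(path)
        log.info("wrote %s (%d x %d)", path, *df.shape)

    # ---- obtain inputs -----------------------------------------------------
    inputs = cfg["inputs"]
    tax: TaxonomyMap | None = None
    if inputs["otu_table"]:
        design_frame = (
            fio.read_design(inputs["design_csv"])
            if inputs["design_csv"]
            else design.to_frame()
        )
        otus = fio.read_otu_table(inputs["otu_table"], design_frame)
        if inputs["taxonomy"]:
            tax = fio.read_taxonomy(inputs["taxonomy"])
    elif cfg["simulate"]["enabled"]:
        sim = cfg["simulate"]["community"]
        cparams = CommunitySimParams(
            n_otus=sim["n_otus"],
            library_size_mean=sim["library_size_mean"],
            library_size_dispersion=sim["library_size_dispersion"],
            dirichlet_concentration=sim["dirichlet_concentration"],
            unclassified_fraction=sim["unclassified_fraction"],
            n_phyla=sim["n_phyla"],
            n_genera=sim["n_genera"],
            planted_dominants=[tuple(p) for p in sim["planted_dominants"]],
        )
        otus, tax = generate_otu_experiment(design, cparams, seed=seed)
        fio.write_otu_table(otus, out / "otu_table.tsv")
        fio.write_taxonomy(tax, out / "taxonomy.tsv")
        fio.write_design(design, out / "design.csv")
        written += [out / "otu_table.tsv", out / "taxonomy.tsv", out / "design.csv"]
    else:
        raise ConfigError("no OTU input configured and simulator disabled")

    qp = QuantParams(**cfg["quant"])
    if inputs["peak_table"]:
        peaks = fio.read_peak_table(inputs["peak_table"])
        thresholds = pd.read_csv(inputs["thresholds"]) if inputs["thresholds"] else None
    else:
        fl = cfg["simulate"]["flavor"]
        fparams = FlavorSimParams(
            n_compounds=fl["n_compounds"],
            noise_sd=fl["noise_sd"],
            baseline_level=fl["baseline_level"],
            linked_pairs=[tuple(p) for p in fl["linked_pairs"]],
            internal_standard_area=fl["internal_standard_area"],
            quant=qp,
        )
        peaks, thresholds, truth = generate_flavor_experiment(
            design, otus, fparams, seed=seed + 1
        )
        fio.write_peak_table(peaks, out / "peak_table.csv")
        thresholds.to_csv(out / "thresholds.csv", index=False)
        fio.write_content(truth, out / "ground_truth_content.csv")
        written += [
            out / "peak_table.csv",
            out / "thresholds.csv",
            out / "ground_truth_content.csv",
        ]

    # ---- quantification + OAV ---------------------------------------------
    content = compute_absolute_content(
        peaks, qp, design, replicate_rule=opts["replicate_rule"]
    )
    path = out / "content.csv"
    fio.write_content(content, path)
    written.append(path)

    if thresholds is not None:
        if "chem_class" not in thresholds.columns:
            thresholds = thresholds.assign(chem_class="other")
        records = records_from_frame(thresholds)
        class_table = aggregate_by_class(content, records)
        save(class_table, "class_content.csv", "chem_class")
        save(count_detected(content, records), "detected_counts.csv", "chem_class")
        oav = compute_oav(content, records)
        save(oav.values, "oav.csv", "compound")
        keys = select_key_compounds(oav, rule=opts["selection_rule"])
        save(keys.table, "key_compounds.csv", "compound")
        report.summary["n_key_compounds"] = len(keys)
    else:
        records, oav, keys = None, None, None
        log.warning("no thresholds available; OAV stage skipped")

    # ---- alpha diversity ---------------------------------------------------
    alpha = alpha_diversity_table(
        otus.counts,
        shannon_base=opts["shannon_base"],
        simpson_variant=opts["simpson_variant"],
        chao1_variant=opts["chao1_variant"],
    )
    save(alpha, "alpha_diversity.csv", "sample")
    save(stage_summary(alpha, otus.design), "alpha_diversity_by_stage.csv", "stage")

    # ---- community structure ----------------------------------------------
    phylum_stage = genus_stage = None
    if tax is not None:
        presence = community_mod.group_presence(otus)
        venn = community_mod.venn_counts(presence)
        (out / "presence_sets.txt").write_text(
            "".join(
                f"{g}\t{','.join(sorted(members))}\n" for g, members in presence.items()
            )
        )
        written.append(out / "presence_sets.txt")
        report.summary["venn_core"] = venn["core"]
        report.summary["venn_unique"] = venn["unique"]
        for rank in ("phylum", "genus"):
            comp = community_mod.aggregate_taxonomy(otus, tax, rank=rank)
            stage_comp = community_mod.collapse_to_stages(comp, otus)
            stack = community_mod.top_taxa_stack(stage_comp, k=opts["rank_top_k"])
            save(stack, f"composition_{rank}.csv", rank)
            if rank == "phylum":
                phylum_stage = stage_comp
            else:
                genus_stage = stage_comp
    else:
        log.warning("no taxonomy available; community stage skipped")

    # ---- ordination --------------------------------------------------------
    result = pca(otus, transform=opts["transform"], n_components=2)
    scores = result.scores.copy()
    scores.insert(0, "stage", otus.sample_stage().values)
    save(scores, "pca_scores.csv", "sample")
    save(
        result.explained_variance_ratio.to_frame("explained_variance_ratio"),
        "pca_variance.csv",
        "component",
    )
    report.summary["pc1_variance"] = float(result.explained_variance_ratio.iloc[0])

    # ---- correlation -------------------------------------------------------
    if tax is not None and keys is not None and len(keys):
        taxa, compounds = build_feature_sets(
            phylum_stage,
            genus_stage,
            content,
            keys,
            n_phyla=opts["n_phyla"],
            n_genera=opts["n_genera"],
        )
        grid = correlation_grid(
            taxa,
            compounds,
            pairing=opts["pairing"],
            star_thresholds=tuple(opts["star_thresholds"]),
        )
        save(grid.r, "correlation_r.csv", "taxon")
        save(grid.p, "correlation_p.csv", "taxon")
        save(grid.long_format().set_index("taxon"), "correlation_long.csv", "taxon")
        report.summary["n_starred"] = int((grid.stars.to_numpy() != "").sum())
    else:
        log.warning("community or key-compound stage unavailable; correlation skipped")

    # ---- report ------------------------------------------------------------
    report.manifest = {p.name: _sha256(p) for p in sorted(set(written))}
    report.summary["seed"] = seed
    report.summary["version"] = __version__
    report.summary["config"] = cfg
    (out / "report.json").write_text(report.to_json())
    return report
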