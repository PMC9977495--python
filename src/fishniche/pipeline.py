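"""End-to-end orchestration: simulate -> detect -> map/type/measure -> compare.

A single :class:`RunConfig` drives one of three modes:

* ``section`` — lung-section RNA-FISH fields: simulate per-animal fields,
  detect puncta in every channel, compute nearest distances from each source
  channel to the anchor (AT2/Sftpc) channel, aggregate per animal, and run
  the condition comparisons;
* ``cytospin`` — isolated-fibroblast fields: simulate, type every cell into
  the four Wnt2/Wnt5a subtypes, summarize cohort fractions per animal, and
  compare conditions per subtype;
* ``organoid`` — organoid cultures: simulate disk fields from a diameter
  distribution, segment, apply the 50 um colony rule, and report CFE and
  median colony diameter per culture.

Experimental conditions are expressed purely as overrides of the simulation
config (e.g. a smaller Wnt5a offset mean under hypercapnia); there is no
condition-specific code path.  The global seed is expanded into independent,
order-invariant per-field streams with ``numpy.random.SeedSequence`` spawn
keys, so identical config + seed reproduces every output table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_typing import subtype_fractions, type_cytospin_field
from .image_io import write_table
from .organoid_morphometrics import (
    measure_organoids,
    segment_organoids,
    summarize_culture,
)
from .spatial_mapping import (
    aggregate_by_animal,
    compare_conditions,
    nearest_distances,
)
from .spot_detection import SpotDetectionParams, detect_spots
from .synthetic_data import (
    SUBTYPES,
    CytospinSimConfig,
    SectionSimConfig,
    simulate_cytospin_field,
    simulate_organoid_image,
    simulate_section_field,
)

logger = logging.getLogger(__name__)

MODES = ("section", "cytospin", "organoid")

#: Default condition deltas.  Normocapnia is the base config; hypercapnia
#: moves the Wnt5a signal closer to the AT2 anchors and raises its abundance
#: (section mode) and shifts cells toward the double-positive subtype
#: (cytospin mode), the direction of the effect the analysis must detect.
DEFAULT_SECTION_CONDITIONS: dict[str, dict] = {
    "normocapnia": {},
    "hypercapnia": {
        "wnt5a_offset_mean_um": 6.0,
        "wnt_counts": {"Wnt2": 200, "Wnt5a": 260},
    },
}
DEFAULT_CYTOSPIN_CONDITIONS: dict[str, dict] = {
    "normocapnia": {},
    "hypercapnia": {"subtype_probs": (0.22, 0.20, 0.38, 0.20)},
}
DEFAULT_ORGANOID_CONDITIONS: dict[str, dict] = {
    "normocapnia": {},
    "hypercapnia": {"median_diameter_um": 55.0},
}


class ConfigError(ValueError):
    """Raised when a run configuration is invalid, before any computation."""


@dataclass
class RunConfig:
    """One reproducible end-to-end run."""

    mode: str
    seed: int = 0
    output_dir: str = "fishniche_results"
    n_animals: int = 3
    fields_per_animal: int = 3
    conditions: dict[str, dict] | None = None
    # section mode
    anchor_channel: str = "Sftpc"
    source_channels: tuple[str, ...] = ("Wnt2", "Wnt5a", "Pdgfra")
    bin_width_um: float = 6.0
    section: dict = field(default_factory=dict)
    # cytospin mode
    cytospin: dict = field(default_factory=dict)
    pdgfra_dilation_um: float = 5.0
    wnt_dilation_um: float = 4.0
    # organoid mode
    organoid: dict = field(default_factory=dict)
    n_seeded: int = 5000
    # detection
    detection: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "source_channels" in raw:
            raw["source_channels"] = tuple(raw["source_channels"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["source_channels"] = list(d["source_channels"])
        return d


def _field_seed(seed: int, *spawn_key: int) -> int:
    """Counter-based substream: order-independent and below 2**31."""
    ss = np.random.SeedSequence(seed, spawn_key=spawn_key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _validate(config: RunConfig) -> dict[str, dict]:
    if config.mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {config.mode!r}")
    if config.n_animals < 1 or config.fields_per_animal < 1:
        raise ConfigError("n_animals and fields_per_animal must be >= 1")
    defaults = {
        "section": DEFAULT_SECTION_CONDITIONS,
        "cytospin": DEFAULT_CYTOSPIN_CONDITIONS,
        "organoid": DEFAULT_ORGANOID_CONDITIONS,
    }[config.mode]
    conditions = config.conditions if config.conditions is not None else defaults
    if not conditions:
        raise ConfigError("at least one condition is required")

    if config.mode == "section":
        for cond, overrides in conditions.items():
            merged = {**config.section, **overrides}
            wnt_counts = merged.get("wnt_counts", {"Wnt2": 200, "Wnt5a": 200})
            channels = {"Sftpc", "Pdgfra"} | set(wnt_counts)
            if config.anchor_channel not in channels:
                raise ConfigError(
                    f"anchor channel {config.anchor_channel!r} not among "
                    f"simulated channels {sorted(channels)} (condition {cond!r})"
                )
            missing = set(config.source_channels) - channels
            if missing:
                raise ConfigError(
                    f"source channels {sorted(missing)} not among simulated "
                    f"channels {sorted(channels)} (condition {cond!r})"
                )
    return conditions


def _detection_params(config: RunConfig) -> SpotDetectionParams:
    return SpotDetectionParams(**config.detection)


def _write_metadata(config: RunConfig, conditions: dict, outdir: Path) -> None:
    cfg = config.to_dict()
    cfg["conditions"] = conditions
    blob = json.dumps(cfg, sort_keys=True, default=str)
    meta = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "fishniche": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def run_section(config: RunConfig, conditions: dict[str, dict], outdir: Path):
    params = _detection_params(config)
    spot_frames, distance_tables = [], []
    for ci, (cond, overrides) in enumerate(sorted(conditions.items())):
        for ai in range(config.n_animals):
            animal = f"{cond}-m{ai + 1}"
            for fi in range(config.fields_per_animal):
                t0 = time.perf_counter()
                sim_kwargs = {**config.section, **overrides}
                sim = SectionSimConfig(
                    seed=_field_seed(config.seed, ci, ai, fi),
                    field_id=f"{animal}-f{fi + 1}",
                    animal_id=animal,
                    condition=cond,
                    **sim_kwargs,
                )
                image, _ = simulate_section_field(sim)
                detected = {}
                for chan in image.channel_names:
                    _, spots = detect_spots(image, chan, params)
                    detected[chan] = spots
                    spot_frames.append(spots.to_frame())
                anchor = detected[config.anchor_channel]
                if len(anchor) == 0:
                    logger.warning(
                        "field %s: no %s spots; dropping field from mapping",
                        sim.field_id, config.anchor_channel,
                    )
                    continue
                for src in config.source_channels:
                    distance_tables.append(nearest_distances(detected[src], anchor))
                logger.info(
                    "section field %s: %.2fs", sim.field_id, time.perf_counter() - t0
                )

    spots_df = pd.concat(spot_frames, ignore_index=True)
    distances_df = pd.concat([t.to_frame() for t in distance_tables], ignore_index=True)
    summaries = aggregate_by_animal(distance_tables, bin_width_um=config.bin_width_um)

    stats_rows = []
    # Within-condition contrast between the two Wnt channels.
    for cond in sorted(conditions):
        sub = summaries[summaries["condition"] == cond]
        for metric in ("mean_um", "pct_within_first_bin"):
            pairs = {
                src: sub[sub["source_channel"] == src][metric].to_numpy()
                for src in config.source_channels
            }
            for a, b in [("Wnt2", "Wnt5a")]:
                if a in pairs and b in pairs and len(pairs[a]) >= 2 and len(pairs[b]) >= 2:
                    res = compare_conditions(pairs[a], pairs[b])
                    stats_rows.append(
                        {
                            "comparison": f"{a} vs {b} ({cond})",
                            "metric": metric,
                            "mean_a": float(np.mean(pairs[a])),
                            "mean_b": float(np.mean(pairs[b])),
                            "t": res.t, "p": res.p, "df": res.df,
                        }
                    )
    # Across-condition comparison per source channel.
    conds = sorted(conditions)
    if len(conds) >= 2:
        a_cond, b_cond = conds[0], conds[1]
        for src in config.source_channels:
            for metric in ("mean_um", "pct_within_first_bin"):
                ga = summaries.query(
                    "condition == @a_cond and source_channel == @src"
                )[metric].to_numpy()
                gb = summaries.query(
                    "condition == @b_cond and source_channel == @src"
                )[metric].to_numpy()
                if len(ga) >= 2 and len(gb) >= 2:
                    res = compare_conditions(ga, gb)
                    stats_rows.append(
                        {
                            "comparison": f"{src}: {a_cond} vs {b_cond}",
                            "metric": metric,
                            "mean_a": float(np.mean(ga)),
                            "mean_b": float(np.mean(gb)),
                            "t": res.t, "p": res.p, "df": res.df,
                        }
                    )
    stats_df = pd.DataFrame(
        stats_rows, columns=["comparison", "metric", "mean_a", "mean_b", "t", "p", "df"]
    )

    write_table(spots_df, outdir / "spots.csv")
    write_table(distances_df, outdir / "distances.csv")
    write_table(summaries, outdir / "summaries.csv")
    write_table(stats_df, outdir / "stats.csv")
    return {
        "spots": spots_df,
        "distances": distances_df,
        "summaries": summaries,
        "stats": stats_df,
    }


def run_cytospin(config: RunConfig, conditions: dict[str, dict], outdir: Path):
    params = _detection_params(config)
    results = []
    for ci, (cond, overrides) in enumerate(sorted(conditions.items())):
        for ai in range(config.n_animals):
            animal = f"{cond}-m{ai + 1}"
            for fi in range(config.fields_per_animal):
                sim_kwargs = {**config.cytospin, **overrides}
                if "subtype_probs" in sim_kwargs:
                    sim_kwargs["subtype_probs"] = tuple(sim_kwargs["subtype_probs"])
                sim = CytospinSimConfig(
                    seed=_field_seed(config.seed, ci, ai, fi),
                    field_id=f"{animal}-f{fi + 1}",
                    animal_id=animal,
                    condition=cond,
                    **sim_kwargs,
                )
                image, _ = simulate_cytospin_field(sim)
                results.append(
                    type_cytospin_field(
                        image,
                        detection_params=params,
                        pdgfra_dilation_um=config.pdgfra_dilation_um,
                        wnt_dilation_um=config.wnt_dilation_um,
                    )
                )

    cells_df = pd.concat([r.cells for r in results], ignore_index=True)
    fractions = subtype_fractions(results)

    stats_rows = []
    conds = sorted(conditions)
    if len(conds) >= 2:
        a_cond, b_cond = conds[0], conds[1]
        for s in SUBTYPES:
            ga = fractions.query("condition == @a_cond")[f"pct_{s}"].to_numpy()
            gb = fractions.query("condition == @b_cond")[f"pct_{s}"].to_numpy()
            if len(ga) >= 2 and len(gb) >= 2:
                res = compare_conditions(ga, gb)
                stats_rows.append(
                    {
                        "comparison": f"{s}: {a_cond} vs {b_cond}",
                        "metric": "pct",
                        "mean_a": float(np.mean(ga)),
                        "mean_b": float(np.mean(gb)),
                        "t": res.t, "p": res.p, "df": res.df,
                    }
                )
    stats_df = pd.DataFrame(
        stats_rows, columns=["comparison", "metric", "mean_a", "mean_b", "t", "p", "df"]
    )

    write_table(cells_df, outdir / "cells.csv")
    write_table(fractions, outdir / "fractions.csv")
    write_table(stats_df, outdir / "stats.csv")
    return {"cells": cells_df, "fractions": fractions, "stats": stats_df}


def run_organoid(config: RunConfig, conditions: dict[str, dict], outdir: Path):
    base = {
        "n_organoids": 20,
        "median_diameter_um": 72.0,
        "sigma_log": 0.35,
        "min_diameter_um": 15.0,
        "field_um": 1500.0,
        "pixel_size_um": 2.0,
    }
    object_rows, culture_rows = [], []
    for ci, (cond, overrides) in enumerate(sorted(conditions.items())):
        for ai in range(config.n_animals):
            culture = f"{cond}-c{ai + 1}"
            p = {**base, **config.organoid, **overrides}
            rng = np.random.default_rng(_field_seed(config.seed, ci, ai))
            diameters = np.exp(
                rng.normal(np.log(p["median_diameter_um"]), p["sigma_log"], p["n_organoids"])
            )
            diameters = np.clip(diameters, p["min_diameter_um"], None)
            image, _, _ = simulate_organoid_image(
                seed=_field_seed(config.seed, ci, ai, 999),
                diameters_um=diameters,
                field_um=p["field_um"],
                pixel_size_um=p["pixel_size_um"],
                condition=cond,
            )
            mask = segment_organoids(image, "organoid")
            table = measure_organoids(mask)
            summary = summarize_culture(table, n_seeded=config.n_seeded)
            for _, row in table.iterrows():
                object_rows.append({"condition": cond, "culture": culture, **row})
            culture_rows.append(
                {
                    "condition": cond,
                    "culture": culture,
                    "n_objects": summary.n_objects,
                    "n_colonies": summary.n_colonies,
                    "n_seeded": summary.n_seeded,
                    "cfe_percent": summary.cfe_percent,
                    "median_diameter_um": summary.median_diameter_um,
                }
            )
    organoids_df = pd.DataFrame(object_rows)
    cultures_df = pd.DataFrame(culture_rows)

    stats_rows = []
    conds = sorted(conditions)
    if len(conds) >= 2:
        a_cond, b_cond = conds[0], conds[1]
        for metric in ("cfe_percent", "median_diameter_um"):
            ga = cultures_df.query("condition == @a_cond")[metric].dropna().to_numpy()
            gb = cultures_df.query("condition == @b_cond")[metric].dropna().to_numpy()
            if len(ga) >= 2 and len(gb) >= 2:
                res = compare_conditions(ga, gb)
                stats_rows.append(
                    {
                        "comparison": f"{metric}: {a_cond} vs {b_cond}",
                        "metric": metric,
                        "mean_a": float(np.mean(ga)),
                        "mean_b": float(np.mean(gb)),
                        "t": res.t, "p": res.p, "df": res.df,
                    }
                )
    stats_df = pd.DataFrame(
        stats_rows, columns=["comparison", "metric", "mean_a", "mean_b", "t", "p", "df"]
    )

    write_table(organoids_df, outdir / "organoids.csv")
    write_table(cultures_df, outdir / "culture_summary.csv")
    write_table(stats_df, outdir / "stats.csv")
    return {"organoids": organoids_df, "culture_summary": cultures_df, "stats": stats_df}


def run(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Validate, execute the configured mode, and write all outputs.

    Returns the result tables keyed by name; everything returned is also
    written as CSV under ``config.output_dir`` together with a metadata JSON
    recording the config hash, seed, and library versions.
    """
    conditions = _validate(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = {
        "section": run_section,
        "cytospin": run_cytospin,
        "organoid": run_organoid,
    }[config.mode]
    try:
        tables = runner(config, conditions, outdir)
    except Exception as exc:  # annotate with the stage for diagnosis
        raise RuntimeError(f"{config.mode} run failed: {exc}") from exc
    _write_metadata(config, conditions, outdir)
    return tables
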