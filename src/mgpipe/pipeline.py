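"""End-to-end experiment recipes: simulate -> register -> detect -> traces ->
statistics, with a reproducibility manifest.

Four recipes mirror the experiment families the pipeline is built for:

``planar_contrast``
    Planar movies per fly and layer, two odours; paired mean-peak and
    pooled-peak KS comparisons per layer.
``apl_on_off``
    KC-claw movies with intact vs silenced APL; two-factor
    (condition x odour) ANOVA with Tukey contrasts.
``volumetric_locality``
    5-slice APL movies with odour-specific z-gradients; ratio profiles and
    slope comparison between a segregated and a colocalized odour pair.
``connectome_audit``
    Synthetic APL-hub synapse table; region filtering, reciprocal weights,
    weight correlations and compartment fractions.

Library functions here are deliberately thin and deterministic given
(config, seed); the CLI wraps them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (compartment_fractions, filter_region,
                         reciprocal_weights, subtype_localization_compare,
                         weight_correlation)
from .io_formats import MovieStack, StimulusProtocol, write_movie, write_protocol
from .registration import register_movie
from .roi_detection import detect_active_rois, min_image, normalize_to_min
from .stats import ks_compare, paired_compare, two_factor_compare
from .synthetic_data import (APL_BODY_ID, APL_GLOBAL, KC_CLAW_APL_OFF,
                             KC_CLAW_APL_ON, PN_BOUTON, LayerModel,
                             SimulationConfig, ZGradientSpec,
                             simulate_calyx_movie, simulate_synapse_table,
                             simulate_volumetric_movie)
from .traces import corrected_peaks, extract_traces, summarize_trial
from .volumetric import compare_slopes, ratio_profile, zslice_peaks

log = logging.getLogger("mgpipe.pipeline")

__all__ = [
    "RunConfig",
    "planar_experiment_config",
    "volumetric_experiment_config",
    "locality_gradients",
    "analyse_planar_fly",
    "run_layer_contrast",
    "run_apl_on_off",
    "run_locality",
    "expected_ratio_slope",
    "run_connectome_audit",
    "run_experiment",
    "RECIPES",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


# ---------------------------------------------------------------------------
# default experiment problem sizes
#
# Stimulus timing, sampling rates and blob geometry are the study
# conditions; field size, MG count and puffs per odour are scaled to keep a
# full multi-fly Monte-Carlo run at desk scale (see the methods note).


def planar_experiment_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(field_px=(112, 112), n_mg=30,
                            n_puffs_per_odour=1, rng_seed=seed)


def volumetric_experiment_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(field_px=(64, 64), n_z_slices=5,
                            frame_rate_hz=16.0, n_puffs_per_odour=1,
                            rng_seed=seed)


def locality_gradients(low: float = 0.3) -> dict[str, ZGradientSpec]:
    """Bouton-distribution gradients for the locality experiment.

    PA-responding boutons concentrate posteriorly (amplitude rising with
    slice index); MP- and FA-responding boutons share an anterior
    distribution, modelled as uniform profiles, so PA/MP is the segregated
    pair and FA/MP the colocalized control.
    """
    return {
        "PA": ZGradientSpec("PA", kind="linear", low=low),
        "MP": ZGradientSpec("MP", kind="uniform"),
        "FA": ZGradientSpec("FA", kind="uniform"),
    }


# ---------------------------------------------------------------------------
# per-fly analysis


def analyse_planar_fly(
    movie: MovieStack,
    protocol: StimulusProtocol,
    fly_id: str,
    expected_diameter_um: float = 5.0,
    register: bool = True,
    correct_dilution: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run registration, detection and trace extraction for one fly.

    Returns ``(summaries, pooled)``: one summary row per odour trial
    (fly, odour, trial, active_roi_count, mean_peak) and the pooled per-ROI
    peak table (fly, odour, trial, dff_max) feeding distribution tests.
    """
    if register:
        movie, _ = register_movie(movie, protocol)
    m = min_image(movie)
    normalized = normalize_to_min(movie, m)
    summary_rows, pooled_rows = [], []
    for idx, trial in enumerate(protocol.trials):
        roiset = detect_active_rois(movie, protocol, trial,
                                    expected_diameter_um=expected_diameter_um,
                                    min_img=m, normalized=normalized)
        traceset = extract_traces(movie, roiset, protocol)
        peaks = None
        if correct_dilution and len(traceset):
            peaks = corrected_peaks(traceset, roiset, trial, m,
                                    movie.pixel_size_um)
        summary = summarize_trial(traceset, trial, fly_id=fly_id,
                                  trial_index=idx, peaks=peaks)
        summary_rows.append(summary.to_row())
        for p in summary.peaks:
            pooled_rows.append({"fly": fly_id, "odour": trial.odour,
                                "trial": idx, "dff_max": float(p)})
    return pd.DataFrame(summary_rows), pd.DataFrame(pooled_rows)


def _simulate_fly(config: SimulationConfig, layer_name: str,
                  odours: Sequence[str], seed: int):
    cfg = dataclasses.replace(config, rng_seed=seed)
    layer = LayerModel.default(layer_name, odours)
    return cfg, simulate_calyx_movie(cfg, layer, odours)


# ---------------------------------------------------------------------------
# recipes (library form)


def run_layer_contrast(
    layer_name: str,
    n_flies: int = 10,
    odours: Sequence[str] = ("Mch", "Oct"),
    config: SimulationConfig | None = None,
    seed: int = 0,
    keep_artifacts: bool = False,
) -> dict:
    """Simulate ``n_flies`` planar movies for one layer and compare odours.

    Output dict carries per-trial summaries, pooled ROI peaks, the paired
    mean-peak comparison, the paired active-count comparison and the KS
    comparison of pooled peak distributions.
    """
    config = config or planar_experiment_config()
    seeds = _child_seeds(seed, n_flies)
    summaries, pooled, artifacts = [], [], []
    for i in range(n_flies):
        cfg, (movie, protocol, truth) = _simulate_fly(
            config, layer_name, odours, seeds[i])
        s, p = analyse_planar_fly(movie, protocol, f"fly{i:02d}")
        summaries.append(s)
        pooled.append(p)
        if keep_artifacts:
            artifacts.append((movie, protocol, truth))
    summaries = pd.concat(summaries, ignore_index=True)
    pooled = pd.concat(pooled, ignore_index=True)

    a, b = odours[0], odours[1]
    per_fly_peak = summaries.groupby(["fly", "odour"])["mean_peak"].mean().unstack()
    per_fly_count = summaries.groupby(["fly", "odour"])["active_roi_count"] \
        .mean().unstack()
    paired_peak = paired_compare(per_fly_peak[a], per_fly_peak[b])
    paired_count = paired_compare(per_fly_count[a], per_fly_count[b])
    ks = ks_compare(pooled.loc[pooled["odour"] == a, "dff_max"],
                    pooled.loc[pooled["odour"] == b, "dff_max"])
    out = {
        "layer": layer_name,
        "odours": (a, b),
        "summaries": summaries,
        "pooled_peaks": pooled,
        "paired_peak": paired_peak,
        "paired_count": paired_count,
        "ks": ks,
    }
    if keep_artifacts:
        out["artifacts"] = artifacts
    return out


def run_apl_on_off(
    n_flies: int = 10,
    odours: Sequence[str] = ("Mch", "Oct"),
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> dict:
    """APL-silencing contrast: KC-claw responses with the APL output intact
    (ON) vs blocked (OFF), analysed as condition x odour."""
    seeds = _child_seeds(seed, 2)
    on = run_layer_contrast(KC_CLAW_APL_ON, n_flies, odours, config, seeds[0])
    off = run_layer_contrast(KC_CLAW_APL_OFF, n_flies, odours, config, seeds[1])
    cells = pd.concat([
        on["summaries"].assign(condition="APL_ON"),
        off["summaries"].assign(condition="APL_OFF"),
    ], ignore_index=True)
    per_fly = (cells.groupby(["condition", "fly", "odour"], as_index=False)
               [["mean_peak", "active_roi_count"]].mean())
    anova_peak, contrasts_peak = two_factor_compare(per_fly, value="mean_peak")
    anova_count, contrasts_count = two_factor_compare(per_fly,
                                                      value="active_roi_count")
    return {
        "cells": per_fly,
        "anova_peak": anova_peak,
        "contrasts_peak": contrasts_peak,
        "anova_count": anova_count,
        "contrasts_count": contrasts_count,
        "on": on,
        "off": off,
    }


def expected_ratio_slope(
    layer: LayerModel,
    gradients: Mapping[str, ZGradientSpec],
    odour_a: str,
    odour_b: str,
    n_slices: int = 5,
) -> float:
    """Ground-truth OLS slope of the expected per-fly ratio profile.

    For log-normal amplitudes the expected amplitude ratio is
    ``exp(mu_a - mu_b + (sd_a^2 + sd_b^2)/2)``; the profile is that constant
    times the multiplier ratio, and the slope is its OLS fit on the slice
    grid.
    """
    mu_a = layer.effective_log_mean(odour_a)
    mu_b = layer.effective_log_mean(odour_b)
    sa, sb = layer.odour_log_sd[odour_a], layer.odour_log_sd[odour_b]
    e_ratio = math.exp(mu_a - mu_b + 0.5 * (sa ** 2 + sb ** 2))
    z = np.arange(1, n_slices + 1, dtype=float)
    prof = e_ratio * gradients[odour_a].multipliers(n_slices) \
        / gradients[odour_b].multipliers(n_slices)
    slope = np.polyfit(z, prof, 1)[0]
    return float(slope)


def run_locality(
    n_flies: int = 7,
    config: SimulationConfig | None = None,
    gradients: Mapping[str, ZGradientSpec] | None = None,
    seed: int = 0,
    segregated: tuple[str, str] = ("PA", "MP"),
    colocalized: tuple[str, str] = ("FA", "MP"),
) -> dict:
    """Volumetric locality experiment on ``n_flies`` APL flies.

    Returns the two ratio profiles, their slope comparison and the
    ground-truth slope of the segregated pair.
    """
    config = config or volumetric_experiment_config()
    gradients = gradients or locality_gradients()
    odours = sorted({*segregated, *colocalized})
    layer = LayerModel.default(APL_GLOBAL, odours)
    seeds = _child_seeds(seed, n_flies)
    peaks = []
    for i in range(n_flies):
        cfg = dataclasses.replace(config, rng_seed=seeds[i])
        movie, protocol, truth = simulate_volumetric_movie(
            cfg, layer, gradients, odour_sequence=odours)
        movie, _ = register_movie(movie, protocol)
        peaks.append(zslice_peaks(movie, protocol, fly_id=f"fly{i:02d}"))
    peaks = pd.concat(peaks, ignore_index=True)
    prof_seg = ratio_profile(peaks, *segregated)
    prof_col = ratio_profile(peaks, *colocalized)
    comparison = compare_slopes(prof_seg, prof_col)
    return {
        "peaks": peaks,
        "profile_segregated": prof_seg,
        "profile_colocalized": prof_col,
        "comparison": comparison,
        "true_segregated_slope": expected_ratio_slope(
            layer, gradients, *segregated, n_slices=config.n_z_slices),
    }


def run_connectome_audit(
    seed: int = 0,
    region_label: str = "CA(R)",
    **table_kwargs,
) -> dict:
    """Full connectome analysis of one synthetic APL-hub synapse table."""
    table, metadata, truth = simulate_synapse_table(rng_seed=seed,
                                                    **table_kwargs)
    calyx = filter_region(table, region_label)
    weights = reciprocal_weights(calyx, APL_BODY_ID, metadata)
    pn_corr = weight_correlation(weights, cell_class="PN")
    kc_corr = weight_correlation(weights, cell_class="KC")
    bouton = compartment_fractions(calyx, APL_BODY_ID, "bouton",
                                   metadata, cell_class="PN")
    claw = compartment_fractions(calyx, APL_BODY_ID, "claw",
                                 metadata, cell_class="KC")
    pn_w = weights[weights["cell_class"] == "PN"]
    kc_w = weights[weights["cell_class"] == "KC"]
    return {
        "table": table,
        "metadata": metadata,
        "truth": truth,
        "weights": weights,
        "pn_correlation": pn_corr,
        "kc_correlation": kc_corr,
        "bouton_fractions": bouton,
        "claw_fractions": claw,
        "n_interacting": {
            "PN": int(pn_w["interacting"].sum()),
            "KC": int(kc_w["interacting"].sum()),
        },
    }


# ---------------------------------------------------------------------------
# config-file driven runs


@dataclass
class RunConfig:
    """Single-file configuration for ``mgpipe run``."""

    out_dir: str = "mgpipe_run"
    seed: int = 0
    n_flies: int = 10
    odours: tuple[str, ...] = ("Mch", "Oct")
    layers: tuple[str, ...] = (PN_BOUTON, KC_CLAW_APL_ON)
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    locality_low: float = 0.3
    connectome: dict = field(default_factory=dict)   # simulate_synapse_table kwargs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("odours", "layers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        sim = raw.get("simulation") or {}
        if "field_px" in sim:
            sim["field_px"] = tuple(sim["field_px"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["odours"] = list(d["odours"])
        d["layers"] = list(d["layers"])
        if "field_px" in d["simulation"]:
            d["simulation"]["field_px"] = list(d["simulation"]["field_px"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def simulation_config(self, seed: int, volumetric: bool = False) -> SimulationConfig:
        base = (volumetric_experiment_config(seed) if volumetric
                else planar_experiment_config(seed))
        return dataclasses.replace(base, **self.simulation)


def _report(report) -> dict:
    return report.to_dict()


def _write_manifest(outdir: Path, config: RunConfig, recipe: str) -> None:
    payload = {
        "recipe": recipe,
        "config": config.to_dict(),
        "seed": config.seed,
        "mgpipe_version": __version__,
        "numpy_version": np.__version__,
    }
    blob = json.dumps(payload, sort_keys=True)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=1))


def run_experiment(recipe: str, config: RunConfig, write_movies: bool = True) -> Path:
    """Execute a named recipe and write its artefacts under ``out_dir``.

    Every statistic in the stats report derives from an intermediate CSV
    written alongside it.  Re-running with the same config and seed
    reproduces the outputs exactly.
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {sorted(RECIPES)}")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stats_report: dict = {"recipe": recipe, "seed": config.seed}
    try:
        if recipe == "planar_contrast":
            sim = config.simulation_config(config.seed)
            for layer in config.layers:
                res = run_layer_contrast(layer, config.n_flies, config.odours,
                                         sim, seed=config.seed,
                                         keep_artifacts=write_movies)
                res["summaries"].to_csv(outdir / f"summaries_{layer}.csv",
                                        index=False)
                res["pooled_peaks"].to_csv(outdir / f"peaks_{layer}.csv",
                                           index=False)
                if write_movies:
                    for i, (movie, protocol, _) in enumerate(res["artifacts"]):
                        write_movie(outdir / f"movie_{layer}_fly{i:02d}.tif", movie)
                        write_protocol(
                            outdir / f"protocol_{layer}_fly{i:02d}.json", protocol)
                stats_report[layer] = {
                    "paired_peak": _report(res["paired_peak"]),
                    "paired_count": _report(res["paired_count"]),
                    "ks": _report(res["ks"]),
                }
        elif recipe == "apl_on_off":
            sim = config.simulation_config(config.seed)
            res = run_apl_on_off(config.n_flies, config.odours, sim,
                                 seed=config.seed)
            res["cells"].to_csv(outdir / "cells.csv", index=False)
            res["anova_peak"].to_csv(outdir / "anova_peak.csv")
            res["contrasts_peak"].to_csv(outdir / "contrasts_peak.csv",
                                         index=False)
            res["anova_count"].to_csv(outdir / "anova_count.csv")
            res["contrasts_count"].to_csv(outdir / "contrasts_count.csv",
                                          index=False)
            stats_report["contrasts_peak"] = res["contrasts_peak"] \
                .to_dict("records")
            stats_report["contrasts_count"] = res["contrasts_count"] \
                .to_dict("records")
        elif recipe == "volumetric_locality":
            sim = config.simulation_config(config.seed, volumetric=True)
            res = run_locality(config.n_flies, sim,
                               locality_gradients(config.locality_low),
                               seed=config.seed)
            res["peaks"].to_csv(outdir / "zslice_peaks.csv", index=False)
            res["profile_segregated"].to_frame().to_csv(
                outdir / "profile_segregated.csv", index=False)
            res["profile_colocalized"].to_frame().to_csv(
                outdir / "profile_colocalized.csv", index=False)
            stats_report["slope_comparison"] = res["comparison"].to_dict()
            stats_report["true_segregated_slope"] = res["true_segregated_slope"]
        elif recipe == "connectome_audit":
            res = run_connectome_audit(seed=config.seed, **config.connectome)
            from .io_formats import write_synapse_table

            write_synapse_table(outdir / "synapse_table.csv", res["table"])
            res["metadata"].to_csv(outdir / "neuron_metadata.csv", index=False)
            res["weights"].to_csv(outdir / "reciprocal_weights.csv", index=False)
            res["bouton_fractions"].per_neuron.to_csv(
                outdir / "bouton_fractions.csv", index=False)
            res["claw_fractions"].per_neuron.to_csv(
                outdir / "claw_fractions.csv", index=False)
            stats_report.update({
                "pn_correlation": res["pn_correlation"].to_dict(),
                "kc_correlation": res["kc_correlation"].to_dict(),
                "bouton_fraction_mean": res["bouton_fractions"].mean,
                "bouton_fraction_sem": res["bouton_fractions"].sem,
                "claw_fraction_mean": res["claw_fractions"].mean,
                "n_interacting": res["n_interacting"],
            })
    except Exception as exc:
        raise RuntimeError(f"recipe {recipe!r} failed: {exc}") from exc

    (outdir / "stats.json").write_text(json.dumps(stats_report, indent=1,
                                                  default=float))
    _write_manifest(outdir, config, recipe)
    return outdir


RECIPES = ("planar_contrast", "apl_on_off", "volumetric_locality",
           "connectome_audit")
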