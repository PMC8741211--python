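"""Volumetric locality analysis.

For each fly, odour and z-slice a whole-slice peak dF/F0 is measured over
the slice's signal mask; slice profiles are averaged across animals and the
per-slice ratio between an odour pair is formed (average first, then ratio).
Spatially segregated odour pairs produce a ratio profile that changes with
depth; slope differences between odour pairs are tested through the
group x slice interaction of a pooled linear model on per-fly ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MovieStack, StimulusProtocol
from .roi_detection import global_signal_mask
from .stats import ols_slope_interaction

log = logging.getLogger("mgpipe.volumetric")

__all__ = ["ZRatioProfile", "SlopeComparison", "zslice_peaks", "ratio_profile",
           "compare_slopes"]


def zslice_peaks(
    movie: MovieStack,
    protocol: StimulusProtocol,
    fly_id: str = "fly0",
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-slice peak dF/F0 per odour for one fly.

    Each slice's trace is the mean over its signal mask (Otsu of the
    temporal-mean image, the same policy as the whole-calyx ROI); F0 is the
    slice's baseline-window mean, and the per-odour value averages the
    within-trial peaks over that odour's trials.  Slices whose mask is empty
    are excluded with a warning.  Returns columns
    ``fly, odour, z, dff_max``.
    """
    protocol.validate_against(movie.n_frames)
    if mask is None:
        mask = global_signal_mask(movie)
    rows = []
    for z in range(movie.n_slices):
        m = mask[z]
        if not m.any():
            log.warning("zslice_peaks: slice %d has no signal pixels; excluded", z)
            continue
        trace = movie.data[:, z, m].mean(axis=1)
        f0 = trace[:protocol.baseline_frames].mean()
        if f0 <= 0:
            log.warning("zslice_peaks: slice %d has non-positive F0; excluded", z)
            continue
        dff = 100.0 * (trace - f0) / f0
        for odour in protocol.odours():
            peaks = [dff[t.window].max() for t in protocol.trials_for(odour)]
            rows.append({"fly": fly_id, "odour": odour, "z": z + 1,
                         "dff_max": float(np.mean(peaks))})
    return pd.DataFrame(rows)


@dataclass
class ZRatioProfile:
    """Across-animal ratio profile for one odour pair."""

    odour_a: str
    odour_b: str
    slices: np.ndarray           # 1-based slice index
    mean_a: np.ndarray           # across-fly mean dff_max per slice
    mean_b: np.ndarray
    ratio: np.ndarray            # mean_a / mean_b (ratio of means)
    sem_ratio: np.ndarray        # SEM of the per-fly ratios
    per_fly: pd.DataFrame        # fly, z, ratio

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "z": self.slices,
            f"mean_{self.odour_a}": self.mean_a,
            f"mean_{self.odour_b}": self.mean_b,
            "ratio": self.ratio,
            "sem": self.sem_ratio,
        })


def ratio_profile(peaks: pd.DataFrame, odour_a: str, odour_b: str) -> ZRatioProfile:
    """Across-fly ratio profile: average peaks per slice first, then divide.

    The per-fly ratios are retained (for dispersion and slope testing);
    slices whose denominator mean is not positive are marked undefined
    (NaN ratio).
    """
    wide = peaks.pivot_table(index=["fly", "z"], columns="odour",
                             values="dff_max").reset_index()
    for od in (odour_a, odour_b):
        if od not in wide.columns:
            raise ValueError(f"odour {od!r} not present in the peak table")
    wide = wide.dropna(subset=[odour_a, odour_b])
    by_z = wide.groupby("z")
    slices = np.array(sorted(wide["z"].unique()))
    mean_a = by_z[odour_a].mean().loc[slices].to_numpy()
    mean_b = by_z[odour_b].mean().loc[slices].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_b > 0, mean_a / mean_b, np.nan)
    if np.isnan(ratio).any():
        log.warning("ratio_profile(%s/%s): %d slices undefined (denominator <= 0)",
                    odour_a, odour_b, int(np.isnan(ratio).sum()))
    per_fly = wide.assign(ratio=wide[odour_a] / wide[odour_b])[["fly", "z", "ratio"]]
    sem = (per_fly.groupby("z")["ratio"].sem().reindex(slices).to_numpy())
    return ZRatioProfile(odour_a=odour_a, odour_b=odour_b, slices=slices,
                         mean_a=mean_a, mean_b=mean_b, ratio=ratio,
                         sem_ratio=sem, per_fly=per_fly)


@dataclass
class SlopeComparison:
    slope_1: float
    slope_2: float
    p_interaction: float
    profile_1: str
    profile_2: str

    def to_dict(self) -> dict:
        return {
            "profile_1": self.profile_1, "slope_1": self.slope_1,
            "profile_2": self.profile_2, "slope_2": self.slope_2,
            "p_interaction": self.p_interaction,
        }


def compare_slopes(profile_1: ZRatioProfile, profile_2: ZRatioProfile) -> SlopeComparison:
    """OLS slope of ratio vs slice index per profile, and the p-value of
    their difference (group x slice interaction in the pooled model on
    per-fly ratio values).

    The covariate is the slice index (unit: one z-step), so slopes read as
    ratio change per section.
    """
    if not np.array_equal(profile_1.slices, profile_2.slices):
        raise ValueError("profiles must share the same slice grid")
    if len(profile_1.slices) < 2:
        raise ValueError("slope comparison needs at least 2 distinct slices")
    d1 = profile_1.per_fly.dropna(subset=["ratio"])
    d2 = profile_2.per_fly.dropna(subset=["ratio"])
    s1, s2, p = ols_slope_interaction(
        d1["z"].to_numpy(float), d1["ratio"].to_numpy(float),
        d2["z"].to_numpy(float), d2["ratio"].to_numpy(float),
    )
    return SlopeComparison(
        slope_1=s1, slope_2=s2, p_interaction=p,
        profile_1=f"{profile_1.odour_a}/{profile_1.odour_b}",
        profile_2=f"{profile_2.odour_a}/{profile_2.odour_b}",
    )
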