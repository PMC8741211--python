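"""Synthetic two-photon movies and synapse tables with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: ~5 um microglomerular (MG) blobs inside an elliptical calyx-shaped
field, 5 s odour puffs separated by 20 s of clean air, ~9 Hz planar or
~16 Hz / 5-slice volumetric sampling, odour- and layer-dependent log-normal
response amplitudes, and an APL-hub synapse table with a linear reciprocal
weight relation plus noise.  Every dataset is emitted together with its
machine-readable ground truth so that each analysis stage can be scored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_formats import MovieStack, StimulusProtocol, SynapseTable, Trial

log = logging.getLogger("mgpipe.synthetic")

__all__ = [
    "PN_BOUTON",
    "KC_CLAW_APL_ON",
    "KC_CLAW_APL_OFF",
    "APL_GLOBAL",
    "LAYERS",
    "LayerModel",
    "SimulationConfig",
    "ZGradientSpec",
    "MGGroundTruth",
    "VolumetricTruth",
    "WeightModel",
    "FractionModel",
    "SynapseTableTruth",
    "ConfigurationError",
    "transient_kernel",
    "simulate_calyx_movie",
    "simulate_volumetric_movie",
    "simulate_synapse_table",
    "noise_sd_for_r2",
    "APL_BODY_ID",
]

PN_BOUTON = "PN_BOUTON"
KC_CLAW_APL_ON = "KC_CLAW_APL_ON"
KC_CLAW_APL_OFF = "KC_CLAW_APL_OFF"
APL_GLOBAL = "APL_GLOBAL"
LAYERS = (PN_BOUTON, KC_CLAW_APL_ON, KC_CLAW_APL_OFF, APL_GLOBAL)


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# layer amplitude models


@dataclass
class LayerModel:
    """Per-odour response-amplitude model for one imaged cell layer.

    Peak amplitudes (percent dF/F0) are log-normal per odour; each MG is
    active for an odour with probability ``active_fraction``.  For the
    KC layer under intact APL inhibition, a normalization gain shifts every
    odour's log-mean onto their common mean, modelling the across-odour
    equalization of postsynaptic responses.
    """

    layer: str
    odour_log_mean: dict[str, float]
    odour_log_sd: dict[str, float]
    active_fraction: dict[str, float]
    amplitude_floor: float = 1.0  # percent dF/F0

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        for o, f in self.active_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"active fraction for {o} outside [0, 1]")
        for o, s in self.odour_log_sd.items():
            if s < 0:
                raise ValueError(f"log-sd for {o} must be >= 0")

    @property
    def odours(self) -> list[str]:
        return list(self.odour_log_mean)

    def normalization_gain(self) -> dict[str, float]:
        """Multiplicative gain per odour (identity except for KC_CLAW_APL_ON)."""
        if self.layer != KC_CLAW_APL_ON:
            return {o: 1.0 for o in self.odours}
        common = float(np.mean(list(self.odour_log_mean.values())))
        return {o: math.exp(common - m) for o, m in self.odour_log_mean.items()}

    def effective_log_mean(self, odour: str) -> float:
        return self.odour_log_mean[odour] + math.log(self.normalization_gain()[odour])

    def draw_amplitudes(
        self, odour: str, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` (amplitude, active) pairs for one odour.

        Inactive MGs get amplitude 0; active ones a log-normal draw (floored
        so that activity and amplitude stay consistent).
        """
        active = rng.random(n) < self.active_fraction[odour]
        amps = np.zeros(n)
        mu = self.effective_log_mean(odour)
        sd = self.odour_log_sd[odour]
        draws = np.exp(mu + sd * rng.standard_normal(n))
        draws = np.maximum(draws, self.amplitude_floor * 1.001)
        amps[active] = draws[active]
        return amps, active

    @classmethod
    def default(
        cls, layer: str, odours: Sequence[str] = ("Mch", "Oct")
    ) -> "LayerModel":
        """Study-condition defaults for each imaged layer.

        PN boutons respond ~1.6x stronger to Oct than to Mch (and weakest to
        d-DL); KC claws under intact APL share one distribution across
        odours; with APL output blocked the KC layer mirrors the PN
        contrast.  The APL whole-calyx response is a single diffuse signal
        per odour with low across-fly dispersion.
        """
        if layer == PN_BOUTON:
            base = {"Mch": math.log(50.0), "Oct": math.log(80.0), "dDL": math.log(30.0)}
            sd, frac = 0.40, 0.5
        elif layer in (KC_CLAW_APL_ON, KC_CLAW_APL_OFF):
            base = {"Mch": math.log(40.0), "Oct": math.log(64.0), "dDL": math.log(24.0)}
            sd, frac = 0.35, 0.5
        elif layer == APL_GLOBAL:
            base = {
                "Mch": math.log(100.0),
                "Oct": math.log(145.0),
                "dDL": math.log(69.0),
                "PA": math.log(100.0),
                "MP": math.log(100.0),
                "FA": math.log(100.0),
            }
            sd, frac = 0.15, 1.0
        else:
            raise ValueError(f"unknown layer {layer!r}")
        missing = [o for o in odours if o not in base]
        if missing:
            raise ValueError(f"no default amplitudes for odours {missing}")
        return cls(
            layer=layer,
            odour_log_mean={o: base[o] for o in odours},
            odour_log_sd={o: sd for o in odours},
            active_fraction={o: frac for o in odours},
        )


# ---------------------------------------------------------------------------
# acquisition / field configuration


@dataclass
class SimulationConfig:
    """Field geometry, stimulus timing, kinetics and noise for one movie.

    Defaults follow the acquisition this pipeline targets: 0.5 um pixels,
    9 Hz planar scanning (16 Hz split over 5 slices when volumetric),
    5 s odour puffs separated by 20 s of clean air, two puffs per odour and
    a 30-sample baseline preceding the first puff.
    """

    field_px: tuple[int, int] = (176, 176)
    pixel_size_um: float = 0.5
    frame_rate_hz: float = 9.0
    n_z_slices: int = 1
    z_step_um: float = 8.0
    n_mg: int = 80
    mg_radius_um: float = 2.5
    min_spacing_factor: float = 2.0  # centre spacing >= factor * radius
    puff_duration_s: float = 5.0
    inter_puff_s: float = 20.0
    n_puffs_per_odour: int = 2
    baseline_frames: int = 30
    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.0
    baseline_level: float = 1000.0
    baseline_heterogeneity: float = 0.2
    background_level: float = 300.0
    photon_gain: float = 1.0
    read_noise_sd: float = 3.0
    bleach_rate_per_frame: float = 0.0
    max_drift_px: int = 0
    randomize_order: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_z_slices not in (1, 5):
            raise ConfigurationError("n_z_slices must be 1 (planar) or 5 (volumetric)")
        for name in ("pixel_size_um", "frame_rate_hz", "puff_duration_s",
                     "rise_tau_s", "decay_tau_s", "baseline_level"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.baseline_frames <= 0:
            raise ConfigurationError("baseline_frames must be > 0")
        if self.rise_tau_s >= self.decay_tau_s:
            raise ConfigurationError("rise tau must be shorter than decay tau")

    @property
    def sample_rate_hz(self) -> float:
        """Time samples per second (volume rate when volumetric)."""
        return self.frame_rate_hz / self.n_z_slices

    @property
    def mg_radius_px(self) -> float:
        return self.mg_radius_um / self.pixel_size_um

    def calyx_semiaxes_px(self) -> tuple[float, float]:
        return 0.45 * self.field_px[0], 0.45 * self.field_px[1]


@dataclass
class ZGradientSpec:
    """Per-slice amplitude multiplier profile for one odour.

    Multipliers live in (0, 1]; ``low`` is the profile minimum.  ``linear``
    rises from ``low`` (slice 1) to 1.0 (slice Z); ``logistic`` follows
    ``low + (1 - low) / (1 + exp(-steepness * (i - midpoint)))`` at 1-based
    slice index ``i``; ``reverse`` flips the direction.
    """

    odour: str
    kind: str = "uniform"
    low: float = 1.0
    midpoint: float = 3.0
    steepness: float = 1.5
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "linear", "logistic"):
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        if not 0.0 < self.low <= 1.0:
            raise ValueError("gradient low must be in (0, 1]")

    def multipliers(self, n_slices: int) -> np.ndarray:
        i = np.arange(1, n_slices + 1, dtype=float)
        if self.kind == "uniform":
            m = np.full(n_slices, self.low)
        elif self.kind == "linear":
            m = self.low + (1.0 - self.low) * (i - 1) / (n_slices - 1)
        else:  # logistic
            k = -self.steepness if self.reverse else self.steepness
            m = self.low + (1.0 - self.low) / (1.0 + np.exp(-k * (i - self.midpoint)))
            return np.clip(m, 1e-9, 1.0)
        if self.reverse and self.kind == "linear":
            m = m[::-1].copy()
        return m


@dataclass
class MGGroundTruth:
    """True location and per-odour response of one simulated unit."""

    mg_id: int
    center_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float
    amplitudes: dict[str, float]  # percent dF/F0, 0 when inactive
    active: dict[str, bool]

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        for o, a in self.amplitudes.items():
            if a < 0:
                raise ValueError("amplitudes must be >= 0")

    def center_px(self, pixel_size_um: float) -> tuple[float, float]:
        return self.center_um[1] / pixel_size_um, self.center_um[2] / pixel_size_um


@dataclass
class VolumetricTruth:
    """Ground truth for a volumetric movie: units plus slice profiles."""

    mgs: list[MGGroundTruth]
    slice_multipliers: dict[str, np.ndarray]
    expected_slice_amplitude: dict[str, np.ndarray]

    def expected_ratio_profile(self, odour_a: str, odour_b: str) -> np.ndarray:
        return self.expected_slice_amplitude[odour_a] / self.expected_slice_amplitude[odour_b]


# ---------------------------------------------------------------------------
# building blocks


def transient_kernel(t_s: np.ndarray, rise_tau_s: float, decay_tau_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, normalized to unit peak.

    The analytic peak time is ``t* = tr*td/(td-tr) * ln(td/tr)``; dividing by
    the kernel value there makes a transient of amplitude ``a`` peak exactly
    at ``a`` in continuous time.
    """
    tr, td = rise_tau_s, decay_tau_s
    t = np.asarray(t_s, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / td) - np.exp(-t / tr), 0.0)
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    return raw / peak


def build_protocol(config: SimulationConfig, odour_sequence: Sequence[str],
                   rng: np.random.Generator | None = None) -> StimulusProtocol:
    """Lay out puff trials on the sample grid.

    Round-robin over the odour sequence, ``n_puffs_per_odour`` rounds, each
    puff preceded by an ``inter_puff_s`` clean-air gap; the movie starts with
    ``baseline_frames`` stimulus-free samples.
    """
    rate = config.sample_rate_hz
    puff = max(1, round(config.puff_duration_s * rate))
    gap = max(1, round(config.inter_puff_s * rate))
    trials = []
    cursor = config.baseline_frames
    for round_i in range(config.n_puffs_per_odour):
        order = list(odour_sequence)
        if config.randomize_order and rng is not None:
            rng.shuffle(order)
        for od in order:
            onset = cursor + gap
            trials.append(Trial(od, onset, onset + puff))
            cursor = onset + puff
    return StimulusProtocol(
        trials=tuple(trials),
        baseline_frames=config.baseline_frames,
        randomized=config.randomize_order,
    )


def _calyx_mask(config: SimulationConfig) -> np.ndarray:
    ny, nx = config.field_px
    ay, ax = config.calyx_semiaxes_px()
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((yy - ny / 2) / ay) ** 2 + ((xx - nx / 2) / ax) ** 2 <= 1.0


def _baseline_image(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Heterogeneous baseline: bright soft-edged calyx over a dim background."""
    soft = gaussian_filter(_calyx_mask(config).astype(float), sigma=2.0)
    texture = gaussian_filter(rng.standard_normal(config.field_px), sigma=4.0)
    peak = np.max(np.abs(texture))
    if peak > 0:
        texture /= peak
    b = config.background_level + (config.baseline_level - config.background_level) \
        * soft * (1.0 + config.baseline_heterogeneity * texture)
    return np.maximum(b, 1.0)


def place_mg_centers(config: SimulationConfig, rng: np.random.Generator,
                     max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample MG centres (y, x in px) inside the elliptical calyx.

    Centres keep a minimum spacing of ``min_spacing_factor * radius`` so that
    blobs may touch but are never fully merged.  Raises
    :class:`ConfigurationError` when the field cannot accommodate ``n_mg``.
    """
    ny, nx = config.field_px
    ay, ax = config.calyx_semiaxes_px()
    r_px = config.mg_radius_px
    min_d = config.min_spacing_factor * r_px
    margin = 0.85  # keep blobs inside the bright region
    for _attempt in range(10):  # dart throwing can dead-end; restart fresh
        centers: list[tuple[float, float]] = []
        tries = 0
        while len(centers) < config.n_mg and tries < max_tries:
            tries += 1
            y = ny / 2 + (2 * rng.random() - 1) * ay * margin
            x = nx / 2 + (2 * rng.random() - 1) * ax * margin
            if ((y - ny / 2) / (ay * margin)) ** 2 \
                    + ((x - nx / 2) / (ax * margin)) ** 2 > 1:
                continue
            if any((y - cy) ** 2 + (x - cx) ** 2 < min_d ** 2
                   for cy, cx in centers):
                continue
            centers.append((y, x))
        if len(centers) == config.n_mg:
            return np.asarray(centers)
    raise ConfigurationError(
        f"field too small for {config.n_mg} MGs at spacing {min_d:.1f} px"
    )


def _mg_footprint(center_yx: tuple[float, float], sigma_px: float,
                  shape: tuple[int, int]) -> tuple[slice, slice, np.ndarray]:
    """Isotropic Gaussian footprint (peak 1 at the centre) on a local crop."""
    cy, cx = center_yx
    cut = int(math.ceil(3.5 * sigma_px)) + 1
    y0, y1 = max(0, int(cy) - cut), min(shape[0], int(cy) + cut + 1)
    x0, x1 = max(0, int(cx) - cut), min(shape[1], int(cx) + cut + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px ** 2))
    return slice(y0, y1), slice(x0, x1), g


def footprint_sigma_px(diameter_um: float, pixel_size_um: float) -> float:
    """Gaussian sigma for a blob whose full visible extent (~+-2 sigma)
    spans the expected MG diameter.

    The compact choice (sigma = diameter/4) keeps densely packed blobs
    punctate, as boutons appear in real calyx recordings; a
    half-maximum-based width would carpet the neuropil with overlapping
    tails.
    """
    return diameter_um / pixel_size_um / 4.0


def _random_walk(n: int, max_drift: int, rng: np.random.Generator,
                 still_frames: int = 0) -> np.ndarray:
    """Integer-pixel random-walk drift, clipped at ``max_drift``.

    The first ``still_frames`` samples stay at (0, 0): drift accumulates
    during the recording, so the baseline epoch used as the registration
    reference is motion-free by construction.
    """
    steps = rng.integers(-1, 2, size=(n, 2))
    steps[:still_frames] = 0
    walk = np.cumsum(steps, axis=0)
    return np.clip(walk, -max_drift, max_drift)


def _shift_frame(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.roll(frame, (dy, dx), axis=(-2, -1))
    if dy > 0:
        out[..., :dy, :] = fill
    elif dy < 0:
        out[..., dy:, :] = fill
    if dx > 0:
        out[..., :, :dx] = fill
    elif dx < 0:
        out[..., :, dx:] = fill
    return out


# ---------------------------------------------------------------------------
# movie simulation


def _simulate(
    config: SimulationConfig,
    layer: LayerModel,
    odour_sequence: Sequence[str],
    gradients: Mapping[str, ZGradientSpec] | None,
    centers_px: np.ndarray | None,
    amplitude_overrides: Mapping[str, np.ndarray] | None,
) -> tuple[MovieStack, StimulusProtocol, list[MGGroundTruth], dict[str, np.ndarray], np.ndarray, np.ndarray]:
    odours = list(odour_sequence)
    if len(set(odours)) != len(odours):
        raise ValueError("odour labels must be distinct")
    rng = np.random.default_rng(config.rng_seed)
    protocol = build_protocol(config, odours, rng)
    n_t = protocol.trials[-1].offset
    n_z = config.n_z_slices
    ny, nx = config.field_px
    t_s = np.arange(n_t) / config.sample_rate_hz
    onsets_s = {tr: tr.onset / config.sample_rate_hz for tr in protocol.trials}

    baseline = _baseline_image(config, rng)
    mults = {o: np.ones(n_z) for o in odours}
    if gradients is not None:
        for o in odours:
            if o not in gradients:
                raise ValueError(f"no gradient spec for odour {o!r}")
            mults[o] = gradients[o].multipliers(n_z)

    diffuse = layer.layer == APL_GLOBAL
    if diffuse:
        n_units = 1
        soft = gaussian_filter(_calyx_mask(config).astype(float), sigma=2.0)
        soft /= soft.max()
    else:
        n_units = config.n_mg
        if centers_px is None:
            centers_px = place_mg_centers(config, rng)
        sigma = footprint_sigma_px(2 * config.mg_radius_um, config.pixel_size_um)
        home_z = rng.integers(0, n_z, size=n_units)

    # per-unit, per-odour amplitudes (percent dF/F0)
    amps = np.zeros((n_units, len(odours)))
    act = np.zeros((n_units, len(odours)), dtype=bool)
    for j, od in enumerate(odours):
        a, flag = layer.draw_amplitudes(od, n_units, rng)
        amps[:, j], act[:, j] = a, flag
    if amplitude_overrides is not None:
        for od, values in amplitude_overrides.items():
            j = odours.index(od)
            amps[:, j] = np.asarray(values, dtype=float)
            act[:, j] = amps[:, j] > layer.amplitude_floor

    # per-unit dF/F0 time courses (fractional), one column per odour
    dff = np.zeros((len(odours), n_t))
    for j, od in enumerate(odours):
        for tr in protocol.trials_for(od):
            dff[j] += transient_kernel(t_s - onsets_s[tr], config.rise_tau_s,
                                       config.decay_tau_s)

    signal = np.zeros((n_t, n_z, ny, nx), dtype=np.float32)
    truth: list[MGGroundTruth] = []
    ps = config.pixel_size_um
    if diffuse:
        for j, od in enumerate(odours):
            for z in range(n_z):
                amp = amps[0, j] / 100.0 * mults[od][z]
                if amp > 0:
                    signal[:, z] += np.multiply.outer(amp * dff[j], soft)
        truth.append(MGGroundTruth(
            mg_id=0,
            center_um=((n_z - 1) / 2 * config.z_step_um, ny / 2 * ps, nx / 2 * ps),
            radius_um=config.calyx_semiaxes_px()[0] * ps,
            amplitudes={od: float(amps[0, j]) for j, od in enumerate(odours)},
            active={od: bool(act[0, j]) for j, od in enumerate(odours)},
        ))
    else:
        for i in range(n_units):
            ys, xs, g = _mg_footprint(tuple(centers_px[i]), sigma, (ny, nx))
            z = int(home_z[i])
            for j, od in enumerate(odours):
                amp = amps[i, j] / 100.0 * mults[od][z]
                if amp > 0:
                    signal[:, z, ys, xs] += np.multiply.outer(amp * dff[j], g)
            truth.append(MGGroundTruth(
                mg_id=i,
                center_um=(z * config.z_step_um, centers_px[i, 0] * ps,
                           centers_px[i, 1] * ps),
                radius_um=config.mg_radius_um,
                amplitudes={od: float(amps[i, j]) for j, od in enumerate(odours)},
                active={od: bool(act[i, j]) for j, od in enumerate(odours)},
            ))

    clean = signal  # reuse the buffer: clean = B * bleach * (1 + signal)
    clean += 1.0
    clean *= baseline[None, None].astype(np.float32)
    if config.bleach_rate_per_frame > 0:
        bleach = np.exp(-config.bleach_rate_per_frame * np.arange(n_t),
                        dtype=np.float64).astype(np.float32)
        clean *= bleach[:, None, None, None]

    shifts = np.zeros((n_t, 2), dtype=int)
    if config.max_drift_px > 0:
        shifts = _random_walk(n_t, config.max_drift_px, rng,
                              still_frames=config.baseline_frames)
        for tindex in range(n_t):
            dy, dx = shifts[tindex]
            if dy or dx:
                clean[tindex] = _shift_frame(clean[tindex], dy, dx,
                                             config.background_level)

    if config.photon_gain > 0 or config.read_noise_sd > 0:
        noise = rng.standard_normal(clean.shape, dtype=np.float32)
        noise *= np.sqrt(config.photon_gain * clean + config.read_noise_sd ** 2,
                         dtype=np.float32)
        movie_data = clean
        movie_data += noise
        np.clip(movie_data, 0.0, None, out=movie_data)
    else:
        movie_data = clean

    movie = MovieStack(
        data=movie_data,
        pixel_size_um=config.pixel_size_um,
        frame_rate_hz=config.frame_rate_hz,
        z_step_um=config.z_step_um if n_z > 1 else 0.0,
    )
    return movie, protocol, truth, mults, baseline, shifts


def simulate_calyx_movie(
    config: SimulationConfig,
    layer: LayerModel,
    odour_sequence: Sequence[str],
    centers_px: np.ndarray | None = None,
    amplitude_overrides: Mapping[str, np.ndarray] | None = None,
    return_extras: bool = False,
):
    """Simulate a planar calyx movie.

    Pixel model: ``F(t,x) = B(x) * bleach(t) * (1 + sum_mg dff_mg(t) * G_mg(x))
    + noise`` with a heterogeneous baseline ``B``, unit-peak Gaussian
    footprints ``G`` (FWHM = MG diameter) and unit-peak difference-of-
    exponentials transients launched at each puff onset for active MGs.

    Returns ``(movie, protocol, ground_truth)``; with ``return_extras`` a
    fourth dict carries the true baseline image and motion shifts.
    """
    movie, protocol, truth, _, baseline, shifts = _simulate(
        config, layer, odour_sequence, None, centers_px, amplitude_overrides
    )
    if return_extras:
        return movie, protocol, truth, {"baseline": baseline, "shifts": shifts}
    return movie, protocol, truth


def simulate_volumetric_movie(
    config: SimulationConfig,
    layer: LayerModel,
    gradients: Sequence[ZGradientSpec] | Mapping[str, ZGradientSpec],
    odour_sequence: Sequence[str] | None = None,
    return_extras: bool = False,
):
    """Simulate a 5-slice volumetric movie with per-odour z-gradients.

    The amplitude of a unit for odour ``o`` at slice ``z`` is its base
    amplitude times ``gradient multiplier(z)``.  Returns
    ``(movie, protocol, VolumetricTruth)``.
    """
    if config.n_z_slices < 2:
        raise ConfigurationError("volumetric simulation requires n_z_slices > 1")
    if not isinstance(gradients, Mapping):
        gradients = {g.odour: g for g in gradients}
    if odour_sequence is None:
        odour_sequence = list(gradients)
    movie, protocol, truth, mults, baseline, shifts = _simulate(
        config, layer, odour_sequence, gradients, None, None
    )
    expected = {}
    for j, od in enumerate(odour_sequence):
        mean_amp = float(np.mean([m.amplitudes[od] for m in truth]))
        expected[od] = mean_amp * mults[od]
    vtruth = VolumetricTruth(
        mgs=truth, slice_multipliers=dict(mults), expected_slice_amplitude=expected
    )
    if return_extras:
        return movie, protocol, vtruth, {"baseline": baseline, "shifts": shifts}
    return movie, protocol, vtruth


# ---------------------------------------------------------------------------
# synapse tables

APL_BODY_ID = 1_000_000
_PN_ID0 = 2_000_000
_KC_ID0 = 3_000_000
KC_SUBTYPES = ("gamma", "alpha_beta", "alpha_prime_beta_prime")


@dataclass
class WeightModel:
    """Linear reciprocal-weight law ``w_from = round(slope*w_to + intercept + eps)``."""

    slope: float = 0.8
    intercept: float = 50.0
    noise_sd: float = 21.2
    w_min: int = 10
    w_max: int = 130

    def __post_init__(self) -> None:
        if self.w_min < 1 or self.w_max < self.w_min:
            raise ValueError("weight range must satisfy 1 <= w_min <= w_max")


@dataclass
class FractionModel:
    """Beta-distributed per-neuron compartment fraction with given mean/sd."""

    mean: float = 0.84
    sd: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0 or self.sd < 0:
            raise ValueError("fraction mean in (0,1), sd >= 0 required")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        max_var = self.mean * (1 - self.mean)
        var = min(self.sd ** 2, 0.95 * max_var)
        nu = max_var / var - 1.0
        return rng.beta(self.mean * nu, (1 - self.mean) * nu, size=n)


def noise_sd_for_r2(slope: float, w_sd: float, r2: float) -> float:
    """Additive-noise sd that yields a target population r-squared for the
    linear reciprocal-weight law (``r2 = var(slope*w) / (var(slope*w)+sd^2)``)."""
    if not 0.0 < r2 < 1.0:
        raise ValueError("r2 must be in (0, 1)")
    return abs(slope) * w_sd * math.sqrt(1.0 / r2 - 1.0)


def uniform_int_sd(w_min: int, w_max: int) -> float:
    n = w_max - w_min + 1
    return math.sqrt((n ** 2 - 1) / 12.0)


@dataclass
class SynapseTableTruth:
    """Generator bookkeeping for one synthetic synapse table."""

    weights: pd.DataFrame  # neuron_id, cell_class, kc_subtype, w_to_apl, w_from_apl, ...
    realized_r2: dict[str, float]
    n_interacting: dict[str, int]
    n_total: dict[str, int]
    n_region_rows: dict[str, int]
    clipped_weights: int
    bouton_fraction_true_mean: float
    claw_fraction_true_mean: dict[str, float]


def _realized_r2(w_to: np.ndarray, w_from: np.ndarray) -> float:
    ok = (w_to > 0) & (w_from > 0)
    if ok.sum() < 3 or np.std(w_to[ok]) == 0 or np.std(w_from[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(w_to[ok], w_from[ok])[0, 1] ** 2)


def simulate_synapse_table(
    n_pn: int = 136,
    n_kc: int = 300,
    weight_model: WeightModel | None = None,
    bouton_fraction_model: FractionModel | None = None,
    kc_weight_model: WeightModel | None = None,
    claw_fraction_models: Mapping[str, FractionModel] | None = None,
    n_pn_one_directional: int = 4,
    n_pn_absent: int = 6,
    n_kc_one_directional: int = 5,
    n_kc_absent: int = 3,
    decoy_fraction: float = 0.10,
    region_label: str = "CA(R)",
    decoy_label: str = "LH(R)",
    rng_seed: int = 0,
) -> tuple[SynapseTable, pd.DataFrame, SynapseTableTruth]:
    """Generate an APL-hub synapse table plus neuron metadata and ground truth.

    Per partner neuron the APL->neuron weight follows a linear law on the
    neuron->APL weight plus Gaussian noise (negative rounded weights clipped
    to 0 and counted).  Each APL->PN row carries a bouton/dendrite tag drawn
    from the neuron's true bouton fraction (claw/dendrite for KCs, with
    subtype-specific fraction models).  A ``decoy_fraction`` of extra rows
    carries a non-calyx region label and must be excluded by region
    filtering.  Returns ``(table, neuron_metadata, truth)``.
    """
    wm = weight_model or WeightModel()
    kwm = kc_weight_model or WeightModel(slope=0.9, intercept=20.0, noise_sd=8.5,
                                         w_min=1, w_max=40)
    bfm = bouton_fraction_model or FractionModel(0.84, 0.10)
    cfm = dict(claw_fraction_models or {
        "gamma": FractionModel(0.80, 0.08),
        "alpha_prime_beta_prime": FractionModel(0.80, 0.08),
        "alpha_beta": FractionModel(0.60, 0.10),
    })
    rng = np.random.default_rng(rng_seed)

    def draw_weights(n: int, model: WeightModel, n_onedir: int, n_absent: int):
        n_onedir = min(n_onedir, max(0, n - 3))  # keep >= 3 reciprocal
        n_absent = min(n_absent, max(0, n - 3 - n_onedir))
        w_to = rng.integers(model.w_min, model.w_max + 1, size=n).astype(int)
        eps = model.noise_sd * rng.standard_normal(n)
        w_from = np.round(model.slope * w_to + model.intercept + eps).astype(int)
        clipped = int((w_from < 0).sum())
        w_from = np.maximum(w_from, 0)
        status = np.array(["reciprocal"] * n, dtype=object)
        special = rng.choice(n, size=n_onedir + n_absent, replace=False)
        onedir, absent = special[:n_onedir], special[n_onedir:]
        w_to[onedir] = 0
        w_from[onedir] = rng.integers(1, 11, size=n_onedir)
        status[onedir] = "one_directional"
        w_to[absent] = 0
        w_from[absent] = 0
        status[absent] = "absent"
        return w_to, w_from, status, clipped

    pn_to, pn_from, pn_status, clip_pn = draw_weights(
        n_pn, wm, n_pn_one_directional, n_pn_absent)
    kc_to, kc_from, kc_status, clip_kc = draw_weights(
        n_kc, kwm, n_kc_one_directional, n_kc_absent)

    pn_ids = _PN_ID0 + np.arange(n_pn)
    kc_ids = _KC_ID0 + np.arange(n_kc)
    kc_subtype = rng.choice(KC_SUBTYPES, size=n_kc)
    pn_frac = bfm.draw(n_pn, rng)
    kc_frac = np.empty(n_kc)
    for st, model in cfm.items():
        sel = kc_subtype == st
        kc_frac[sel] = model.draw(int(sel.sum()), rng)

    rows: list[pd.DataFrame] = []

    def emit(neuron_id: int, w_to_n: int, w_from_n: int, frac: float, on_tag: str):
        n_rows = w_to_n + w_from_n
        if n_rows == 0:
            return
        pre = np.concatenate([np.full(w_to_n, neuron_id), np.full(w_from_n, APL_BODY_ID)])
        post = np.concatenate([np.full(w_to_n, APL_BODY_ID), np.full(w_from_n, neuron_id)])
        on = rng.random(n_rows) < frac
        tags = np.where(on, on_tag, "dendrite")
        rows.append(pd.DataFrame({
            "pre_id": pre.astype(int),
            "post_id": post.astype(int),
            "x": rng.uniform(0, 40000, n_rows),
            "y": rng.uniform(0, 40000, n_rows),
            "z": rng.uniform(0, 40000, n_rows),
            "region_label": region_label,
            "compartment_tag": tags,
        }))

    for i in range(n_pn):
        emit(int(pn_ids[i]), int(pn_to[i]), int(pn_from[i]), float(pn_frac[i]), "bouton")
    for i in range(n_kc):
        emit(int(kc_ids[i]), int(kc_to[i]), int(kc_from[i]), float(kc_frac[i]), "claw")

    ca = pd.concat(rows, ignore_index=True)
    n_decoy = int(round(decoy_fraction * len(ca)))
    if n_decoy:
        all_ids = np.concatenate([pn_ids, kc_ids])
        partner = rng.choice(all_ids, size=n_decoy)
        as_pre = rng.random(n_decoy) < 0.5
        rows.append(pd.DataFrame({
            "pre_id": np.where(as_pre, partner, APL_BODY_ID).astype(int),
            "post_id": np.where(as_pre, APL_BODY_ID, partner).astype(int),
            "x": rng.uniform(40000, 80000, n_decoy),
            "y": rng.uniform(40000, 80000, n_decoy),
            "z": rng.uniform(0, 40000, n_decoy),
            "region_label": decoy_label,
            "compartment_tag": "other",
        }))
    df = pd.concat(rows, ignore_index=True)
    if clip_pn + clip_kc:
        log.info("simulate_synapse_table: clipped %d negative weights to 0",
                 clip_pn + clip_kc)

    metadata = pd.DataFrame({
        "neuron_id": np.concatenate([[APL_BODY_ID], pn_ids, kc_ids]).astype(int),
        "cell_class": ["other"] + ["PN"] * n_pn + ["KC"] * n_kc,
        "kc_subtype": ["unknown"] * (1 + n_pn) + list(kc_subtype),
    })

    weights = pd.DataFrame({
        "neuron_id": np.concatenate([pn_ids, kc_ids]).astype(int),
        "cell_class": ["PN"] * n_pn + ["KC"] * n_kc,
        "kc_subtype": ["unknown"] * n_pn + list(kc_subtype),
        "w_to_apl": np.concatenate([pn_to, kc_to]),
        "w_from_apl": np.concatenate([pn_from, kc_from]),
        "status": np.concatenate([pn_status, kc_status]),
        "fraction_true": np.concatenate([pn_frac, kc_frac]),
    })
    truth = SynapseTableTruth(
        weights=weights,
        realized_r2={"PN": _realized_r2(pn_to, pn_from),
                     "KC": _realized_r2(kc_to, kc_from)},
        n_interacting={"PN": int(((pn_to > 0) & (pn_from > 0)).sum()),
                       "KC": int(((kc_to > 0) & (kc_from > 0)).sum())},
        n_total={"PN": n_pn, "KC": n_kc},
        n_region_rows={region_label: len(ca), decoy_label: n_decoy},
        clipped_weights=clip_pn + clip_kc,
        bouton_fraction_true_mean=float(np.mean(pn_frac)),
        claw_fraction_true_mean={
            st: (float(np.mean(kc_frac[kc_subtype == st]))
                 if (kc_subtype == st).any() else float("nan"))
            for st in cfm
        },
    )
    return SynapseTable(df=df), metadata, truth
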