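"""Rigid, translation-only motion correction.

Each time sample is aligned to a reference image (the mean of the baseline
window) by integer-pixel cross-correlation.  Sub-pixel interpolation is
deliberately avoided: the downstream detector thresholds a maximum image of
~10 px blobs, where integer shifts are sufficient and interpolation would
only blur the response.  Volumetric stacks share one shift per volume,
estimated on the z-mean image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .io_formats import MovieStack, StimulusProtocol

log = logging.getLogger("mgpipe.registration")

__all__ = ["ShiftSeries", "register_movie", "apply_shifts"]


@dataclass
class ShiftSeries:
    """Per-sample correction shifts (dy, dx) applied to align each frame."""

    shifts: np.ndarray  # (T, 2) int
    reference: str
    clamped: np.ndarray  # (T,) bool, True where the estimate hit max_shift

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        self.clamped = np.asarray(self.clamped, dtype=bool)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frame": np.arange(len(self.shifts)),
            "dy": self.shifts[:, 0],
            "dx": self.shifts[:, 1],
            "clamped": self.clamped,
        })


def _shift_fill(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
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


def apply_shifts(movie: MovieStack, shifts: np.ndarray) -> MovieStack:
    """Translate every sample by its (dy, dx); out-of-field pixels take the
    sample's median value."""
    data = movie.data.copy()
    for t, (dy, dx) in enumerate(np.asarray(shifts, dtype=int)):
        if dy or dx:
            data[t] = _shift_fill(movie.data[t], int(dy), int(dx),
                                  float(np.median(movie.data[t])))
    return movie.with_data(data)


def register_movie(
    movie: MovieStack,
    protocol: StimulusProtocol | None = None,
    max_shift_px: int = 10,
    baseline_frames: int | None = None,
) -> tuple[MovieStack, ShiftSeries]:
    """Estimate and apply integer translation per time sample.

    The reference is the mean over the baseline window (lower-noise template
    than any single frame).  Estimated shifts larger than ``max_shift_px``
    are clamped component-wise and flagged.
    """
    if movie.n_frames < 2:
        raise ValueError("registration requires at least two time samples")
    if baseline_frames is None:
        baseline_frames = protocol.baseline_frames if protocol else min(
            30, movie.n_frames)
    baseline_frames = min(baseline_frames, movie.n_frames)

    planes = movie.data.mean(axis=1)  # z-mean, (T, Y, X)
    reference = planes[:baseline_frames].mean(axis=0)

    n_t = movie.n_frames
    shifts = np.zeros((n_t, 2), dtype=int)
    clamped = np.zeros(n_t, dtype=bool)
    for t in range(n_t):
        est, _, _ = phase_cross_correlation(reference, planes[t],
                                            upsample_factor=1,
                                            normalization=None)
        dy, dx = int(round(est[0])), int(round(est[1]))
        if abs(dy) > max_shift_px or abs(dx) > max_shift_px:
            clamped[t] = True
            dy = int(np.clip(dy, -max_shift_px, max_shift_px))
            dx = int(np.clip(dx, -max_shift_px, max_shift_px))
        shifts[t] = (dy, dx)
    if clamped.any():
        log.warning("register_movie: %d/%d frames exceeded max_shift=%d px "
                    "(clamped)", int(clamped.sum()), n_t, max_shift_px)

    registered = apply_shifts(movie, shifts)
    series = ShiftSeries(shifts=shifts, clamped=clamped,
                         reference=f"mean of first {baseline_frames} samples")
    return registered, series
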