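"""Active-microglomerulus detection.

The detector reproduces the minimum-image macro logic: normalize the whole
recording to its pixelwise minimum image, build one response image per odour
trial (temporal maximum of the normalized stack over the trial window, after
a short boxcar smoothing), threshold it with Otsu's method and keep
8-connected components whose area matches the expected ~5 um ROI diameter
within a configurable band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .io_formats import MovieStack, StimulusProtocol, Trial

log = logging.getLogger("mgpipe.detection")

__all__ = [
    "DegenerateImageError",
    "RoiRecord",
    "RoiSet",
    "min_image",
    "normalize_to_min",
    "otsu_threshold",
    "response_image",
    "detect_active_rois",
    "global_signal_mask",
    "score_detections",
    "expected_disc_area_px",
]


class DegenerateImageError(ValueError):
    """An image without intensity structure (constant) cannot be thresholded."""


def min_image(movie: MovieStack | np.ndarray) -> np.ndarray:
    """Pixelwise minimum over time, per z-slice; shape (Z, Y, X)."""
    data = movie.data if isinstance(movie, MovieStack) else np.asarray(movie)
    if data.ndim == 3:
        data = data[:, None]
    return data.min(axis=0)


def normalize_to_min(
    movie: MovieStack | np.ndarray, min_img: np.ndarray, eps: float | None = None
) -> np.ndarray:
    """Divisive normalization ``N = (F - M) / (M + eps)``.

    Divisive (rather than subtractive) normalization makes detection
    invariant to illumination scale.  By default ``eps`` is the mean of the
    minimum image: besides guarding the division, this pedestal damps the
    dark, low-information pixels whose relative fluctuations would
    otherwise dominate the normalized stack (the field-mean choice keeps
    the result invariant to an overall intensity scale).  Pass a small
    explicit ``eps`` for a pure dF/F scale.
    """
    if eps is None:
        eps = 0.25 * float(np.mean(min_img))
    if eps <= 0:
        eps = 1e-6
    data = movie.data if isinstance(movie, MovieStack) else np.asarray(movie)
    if data.ndim == 3:
        data = data[:, None]
    if data.shape[1:] != min_img.shape:
        raise ValueError("minimum image shape does not match the movie")
    return (data - min_img[None]) / (min_img[None] + eps)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on an ``nbins``-bin histogram over [min, max].

    Returns the bin edge that maximizes the between-class variance; pixels
    strictly above the returned value belong to the foreground class.  Exact
    ties (e.g. the empty gap of a well-separated bimodal histogram, where
    the criterion is constant) resolve to the middle of the tied plateau.
    Raises :class:`DegenerateImageError` for constant images.
    """
    values = np.asarray(image, dtype=float).ravel()
    lo, hi = float(values.min()), float(values.max())
    if not hi > lo:
        raise DegenerateImageError("constant image has no threshold")
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    counts = counts.astype(float)
    w0 = np.cumsum(counts)[:-1]              # pixels in bins 0..k
    w1 = counts.sum() - w0
    centers = (edges[:-1] + edges[1:]) / 2.0
    mass = np.cumsum(counts * centers)[:-1]
    total = (counts * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, mass / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (total - mass) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    if not np.isfinite(between).any():
        raise DegenerateImageError("histogram collapsed to a single bin")
    tied = np.flatnonzero(between == between.max())
    k = int(tied[len(tied) // 2])            # centre of the tied plateau
    return float(edges[k + 1])


def response_image(
    normalized: np.ndarray, trial: Trial, smoothing_frames: int = 3
) -> np.ndarray:
    """Per-trial response image: temporal max of the normalized stack.

    A short boxcar along time (default 3 samples) suppresses the
    noise-driven inflation of a pixelwise maximum without blunting the
    ~1 s calcium transients.
    """
    window = normalized[trial.onset:trial.offset]
    if smoothing_frames > 1:
        window = uniform_filter1d(window, size=smoothing_frames, axis=0,
                                  mode="nearest")
    return window.max(axis=0)


def expected_disc_area_px(expected_diameter_um: float, pixel_size_um: float) -> float:
    r_px = expected_diameter_um / 2.0 / pixel_size_um
    return math.pi * r_px ** 2


@dataclass
class RoiRecord:
    roi_id: int
    z: int
    area_px: int
    centroid: tuple[float, float]  # (y, x) px
    equiv_diameter_um: float


@dataclass
class RoiSet:
    """Detected active ROIs for one odour trial."""

    labels: np.ndarray  # (Z, Y, X) int, 0 = background
    rois: list[RoiRecord]
    threshold: float
    trial: Trial | None
    expected_diameter_um: float
    dropped_components: int = 0

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def is_empty(self) -> bool:
        return not self.rois

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "roi_id": [r.roi_id for r in self.rois],
            "z": [r.z for r in self.rois],
            "area_px": [r.area_px for r in self.rois],
            "centroid_y": [r.centroid[0] for r in self.rois],
            "centroid_x": [r.centroid[1] for r in self.rois],
            "equiv_diameter_um": [r.equiv_diameter_um for r in self.rois],
            "odour": self.trial.odour if self.trial else "",
        })


def detect_active_rois(
    movie: MovieStack,
    protocol: StimulusProtocol,
    trial: Trial,
    expected_diameter_um: float = 5.0,
    area_band: tuple[float, float] = (0.25, 4.0),
    eps: float | None = None,
    smoothing_frames: int = 3,
    min_img: np.ndarray | None = None,
    normalized: np.ndarray | None = None,
) -> RoiSet:
    """Detect the active MG mask for one odour trial.

    Pipeline: minimum image over the whole recording -> divisive
    normalization -> per-trial response image -> Otsu threshold ->
    8-connected components per z-slice -> keep components whose area lies in
    ``area_band`` times the disc area of the expected diameter.  An empty
    result is a valid outcome, not an error.  ``min_img``/``normalized`` can
    be passed in to amortize work across the trials of one movie.
    """
    protocol.validate_against(movie.n_frames)
    if min_img is None:
        min_img = min_image(movie)
    if normalized is None:
        normalized = normalize_to_min(movie, min_img, eps=eps)
    resp = response_image(normalized, trial, smoothing_frames=smoothing_frames)

    try:
        thr = otsu_threshold(resp)
    except DegenerateImageError:
        log.warning("degenerate response image for trial %s; no active ROIs",
                    trial)
        return RoiSet(np.zeros_like(min_img, dtype=int), [], float("nan"),
                      trial, expected_diameter_um)

    disc = expected_disc_area_px(expected_diameter_um, movie.pixel_size_um)
    lo, hi = area_band[0] * disc, area_band[1] * disc
    labels = np.zeros(resp.shape, dtype=int)
    rois: list[RoiRecord] = []
    dropped = 0
    next_id = 1
    for z in range(resp.shape[0]):
        cc = cc_label(resp[z] > thr, connectivity=2)
        for prop in regionprops(cc):
            if lo <= prop.area <= hi:
                labels[z][cc == prop.label] = next_id
                rois.append(RoiRecord(
                    roi_id=next_id,
                    z=z,
                    area_px=int(prop.area),
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                    equiv_diameter_um=float(prop.equivalent_diameter_area
                                            * movie.pixel_size_um),
                ))
                next_id += 1
            else:
                dropped += 1
    return RoiSet(labels=labels, rois=rois, threshold=thr, trial=trial,
                  expected_diameter_um=expected_diameter_um,
                  dropped_components=dropped)


def global_signal_mask(movie: MovieStack) -> np.ndarray:
    """Whole-calyx signal mask: pixels above the Otsu threshold of the
    temporal-mean image, per z-slice.

    This is the automated stand-in for a manually drawn ROI around the
    entire GCaMP-expressing calycal region, used for whole-structure (APL)
    traces and for the per-slice volumetric readout.
    """
    mean_img = movie.data.mean(axis=0)  # (Z, Y, X)
    mask = np.zeros(mean_img.shape, dtype=bool)
    for z in range(mean_img.shape[0]):
        thr = otsu_threshold(mean_img[z])
        mask[z] = mean_img[z] > thr
    return mask


def score_detections(
    roiset: RoiSet,
    ground_truth,
    odour: str,
    pixel_size_um: float,
) -> tuple[float, float]:
    """Sensitivity/precision of a detection against generator ground truth.

    A true active MG counts as recovered when some detected centroid lies
    within one MG radius of its centre (same slice); a detection counts as
    correct when it lies within one radius of some active MG.  Matching is
    many-to-one in both directions: adjacent blobs may legitimately merge
    into one component that accounts for two true MGs.
    """
    active = [m for m in ground_truth if m.active.get(odour, False)]
    if not active:
        return float("nan"), (1.0 if roiset.is_empty else 0.0)
    true_yx = np.array([[m.center_um[1] / pixel_size_um,
                         m.center_um[2] / pixel_size_um] for m in active])
    radius_px = np.array([m.radius_um / pixel_size_um for m in active])
    det_yx = np.array([r.centroid for r in roiset.rois]) if roiset.rois else \
        np.empty((0, 2))

    covered = np.zeros(len(active), dtype=bool)
    correct = np.zeros(len(det_yx), dtype=bool)
    for j, (dy, dx) in enumerate(det_yx):
        d = np.hypot(true_yx[:, 0] - dy, true_yx[:, 1] - dx)
        hit = d <= radius_px
        covered |= hit
        correct[j] = bool(hit.any())
    sensitivity = float(covered.mean())
    precision = float(correct.mean()) if len(correct) else float("nan")
    return sensitivity, precision
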