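"""Per-ROI fluorescence traces and dF/F0 peak statistics.

F0 is the mean of the first ``baseline_frames`` samples of the recording
(a global baseline, matching the percent dF/F0 convention used throughout);
``dff_max`` is the raw within-trial maximum of the percent dF/F0 trace, with
no smoothing.  A footprint-dilution correction is provided for comparing
ROI-mean peaks against point amplitudes: averaging a Gaussian blob over its
suprathreshold mask dilutes the peak by the (baseline-weighted) mean of the
footprint over the mask, a factor that can be computed from the data alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MovieStack, StimulusProtocol, Trial
from .roi_detection import RoiSet

log = logging.getLogger("mgpipe.traces")

__all__ = [
    "TraceSet",
    "TrialSummary",
    "extract_traces",
    "summarize_trial",
    "footprint_dilution_factor",
    "corrected_peaks",
]


@dataclass
class TraceSet:
    """Mean-intensity traces and dF/F0 for a set of ROIs."""

    roi_ids: np.ndarray          # (R,)
    f: np.ndarray                # (R, T) raw mean intensity
    f0: np.ndarray               # (R,)
    dff: np.ndarray              # (R, T) percent dF/F0
    protocol: StimulusProtocol
    excluded_rois: list[int]

    def __len__(self) -> int:
        return len(self.roi_ids)

    def dff_max(self, trial: Trial) -> np.ndarray:
        """Peak percent dF/F0 within the trial window, per ROI."""
        if len(self) == 0:
            return np.empty(0)
        return self.dff[:, trial.window].max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n_t = self.f.shape[1]
        return pd.DataFrame({
            "roi": np.repeat(self.roi_ids, n_t),
            "frame": np.tile(np.arange(n_t), len(self.roi_ids)),
            "F": self.f.ravel(),
            "dff_pct": self.dff.ravel(),
        })


@dataclass
class TrialSummary:
    fly_id: str
    odour: str
    trial_index: int
    active_roi_count: int
    peaks: np.ndarray            # per-ROI dff_max, percent
    mean_peak: float             # NaN when no active ROI

    def to_row(self) -> dict:
        return {
            "fly": self.fly_id,
            "odour": self.odour,
            "trial": self.trial_index,
            "active_roi_count": self.active_roi_count,
            "mean_peak": self.mean_peak,
        }


def extract_traces(
    movie: MovieStack,
    roiset: RoiSet,
    protocol: StimulusProtocol,
) -> TraceSet:
    """Unweighted ROI-mean intensity over time, F0 and percent dF/F0.

    ROIs with non-positive F0 are excluded (flagged in
    ``excluded_rois``) — they cannot support a ratiometric measure.
    """
    protocol.validate_against(movie.n_frames)
    data = movie.data  # (T, Z, Y, X)
    ids = [r.roi_id for r in roiset.rois]
    f_rows = []
    for rec in roiset.rois:
        mask = roiset.labels[rec.z] == rec.roi_id
        f_rows.append(data[:, rec.z, mask].mean(axis=1))
    f = np.array(f_rows) if f_rows else np.empty((0, movie.n_frames))
    f0 = f[:, :protocol.baseline_frames].mean(axis=1) if len(ids) else np.empty(0)

    ok = f0 > 0
    excluded = [i for i, good in zip(ids, ok) if not good]
    if excluded:
        log.warning("extract_traces: excluding %d ROIs with F0 <= 0", len(excluded))
    f, f0 = f[ok], f0[ok]
    kept = np.asarray(ids)[ok] if len(ids) else np.empty(0, dtype=int)
    dff = 100.0 * (f - f0[:, None]) / f0[:, None] if len(kept) else \
        np.empty((0, movie.n_frames))
    return TraceSet(roi_ids=kept, f=f, f0=f0, dff=dff, protocol=protocol,
                    excluded_rois=excluded)


def summarize_trial(
    traceset: TraceSet,
    trial: Trial,
    fly_id: str = "fly0",
    trial_index: int = 0,
    peaks: np.ndarray | None = None,
) -> TrialSummary:
    """Mean peak response among the active ROIs of one odour exposure.

    ``peaks`` may be supplied (e.g. dilution-corrected values); otherwise
    the raw per-ROI ``dff_max`` is used.  With no active ROIs the count is 0
    and the mean peak is NaN.
    """
    if peaks is None:
        peaks = traceset.dff_max(trial)
    peaks = np.asarray(peaks, dtype=float)
    mean_peak = float(peaks.mean()) if peaks.size else float("nan")
    return TrialSummary(
        fly_id=fly_id,
        odour=trial.odour,
        trial_index=trial_index,
        active_roi_count=int(peaks.size),
        peaks=peaks,
        mean_peak=mean_peak,
    )


def footprint_dilution_factor(
    mask_yx: np.ndarray,
    centroid: tuple[float, float],
    sigma_px: float,
    weights: np.ndarray | None = None,
) -> float:
    """Mean of a unit-peak Gaussian footprint over an ROI's pixels.

    ``mask_yx`` is an (N, 2) array of pixel coordinates; ``weights`` (e.g.
    the minimum image sampled at those pixels) reproduces the
    baseline-weighting inherent in an ROI-mean dF/F trace.
    """
    dy = mask_yx[:, 0] - centroid[0]
    dx = mask_yx[:, 1] - centroid[1]
    g = np.exp(-(dy ** 2 + dx ** 2) / (2.0 * sigma_px ** 2))
    if weights is None:
        return float(g.mean())
    w = np.asarray(weights, dtype=float)
    return float((g * w).sum() / w.sum())


def corrected_peaks(
    traceset: TraceSet,
    roiset: RoiSet,
    trial: Trial,
    min_img: np.ndarray,
    pixel_size_um: float,
) -> np.ndarray:
    """Dilution-corrected dF/F0 peaks (estimates of the blob's point peak).

    Assumes each ROI is a Gaussian blob whose visible extent (~+-2 sigma)
    spans the detector's expected diameter, centred at the ROI centroid,
    and divides each raw ``dff_max`` by the baseline-weighted mean
    footprint over its own mask.
    """
    sigma = roiset.expected_diameter_um / pixel_size_um / 4.0
    raw = traceset.dff_max(trial)
    out = np.empty_like(raw)
    recs = {r.roi_id: r for r in roiset.rois}
    for i, roi_id in enumerate(traceset.roi_ids):
        rec = recs[int(roi_id)]
        yx = np.argwhere(roiset.labels[rec.z] == rec.roi_id)
        w = min_img[rec.z][yx[:, 0], yx[:, 1]]
        factor = footprint_dilution_factor(yx.astype(float), rec.centroid,
                                           sigma, weights=w)
        out[i] = raw[i] / factor if factor > 0 else np.nan
    return out
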