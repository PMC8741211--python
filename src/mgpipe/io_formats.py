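"""Readers and writers for every artefact the pipeline touches.

Movies are multi-page TIFFs with a JSON sidecar carrying spatial/temporal
calibration; stimulus protocols are JSON; synapse tables are delimited text
with a header.  Frame indexing is 0-based throughout and trial windows are
half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("mgpipe.io")

__all__ = [
    "MovieStack",
    "Trial",
    "StimulusProtocol",
    "SynapseTable",
    "FormatError",
    "SchemaError",
    "read_movie",
    "write_movie",
    "read_protocol",
    "write_protocol",
    "read_synapse_table",
    "write_synapse_table",
    "COMPARTMENT_TAGS",
    "SYNAPSE_COLUMNS",
]


class FormatError(ValueError):
    """A file does not have the structure its format promises."""


class SchemaError(ValueError):
    """A delimited table is missing required columns."""


@dataclass
class MovieStack:
    """A fluorescence movie with calibration.

    ``data`` is always 4-D ``(T, Z, Y, X)``; planar movies have ``Z == 1``.
    ``frame_rate_hz`` is the scanner's frame rate (individual 2-D frames per
    second); for volumetric movies the volume rate is ``frame_rate_hz / Z``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_rate_hz: float
    z_step_um: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 3:  # accept (T, Y, X) and promote
            arr = arr[:, None, :, :]
        if arr.ndim != 4:
            raise ValueError(f"movie data must be 3-D or 4-D, got shape {arr.shape}")
        self.data = arr
        if not (self.pixel_size_um > 0 and self.frame_rate_hz > 0):
            raise ValueError("calibration fields must be positive")
        if self.n_slices > 1 and not self.z_step_um > 0:
            raise ValueError("volumetric movie requires z_step_um > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def is_volumetric(self) -> bool:
        return self.n_slices > 1

    @property
    def sample_rate_hz(self) -> float:
        """Rate of time samples (volumes per second for volumetric data)."""
        return self.frame_rate_hz / self.n_slices

    def with_data(self, data: np.ndarray) -> "MovieStack":
        return replace(self, data=data)

    def validate(self) -> None:
        if np.any(self.data < 0):
            raise ValueError("fluorescence values must be non-negative")


@dataclass(frozen=True)
class Trial:
    odour: str
    onset: int
    offset: int  # exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise ValueError(f"invalid trial window [{self.onset}, {self.offset})")

    @property
    def window(self) -> slice:
        return slice(self.onset, self.offset)


@dataclass
class StimulusProtocol:
    """Ordered odour trials plus the baseline definition (first N samples)."""

    trials: tuple[Trial, ...]
    baseline_frames: int = 30
    randomized: bool = False

    def __post_init__(self) -> None:
        self.trials = tuple(
            t if isinstance(t, Trial) else Trial(*t) for t in self.trials
        )
        if self.baseline_frames <= 0:
            raise ValueError("baseline_frames must be positive")
        if self.trials:
            if self.baseline_frames > self.trials[0].onset:
                raise ValueError("baseline window must precede the first puff onset")
            for a, b in zip(self.trials, self.trials[1:]):
                if b.onset < a.offset:
                    raise ValueError("trial windows must not overlap")

    def odours(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.odour, None)
        return list(seen)

    def trials_for(self, odour: str) -> list[Trial]:
        return [t for t in self.trials if t.odour == odour]

    def validate_against(self, n_frames: int) -> None:
        if self.trials and self.trials[-1].offset > n_frames:
            raise ValueError("trial windows extend past the end of the movie")
        if n_frames <= self.baseline_frames:
            raise ValueError("movie shorter than the baseline window")

    def to_dict(self) -> dict:
        return {
            "baseline_frames": self.baseline_frames,
            "randomized": self.randomized,
            "trials": [
                {"odour": t.odour, "onset": t.onset, "offset": t.offset}
                for t in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            trials=tuple(
                Trial(t["odour"], int(t["onset"]), int(t["offset"]))
                for t in d["trials"]
            ),
            baseline_frames=int(d["baseline_frames"]),
            randomized=bool(d.get("randomized", False)),
        )


COMPARTMENT_TAGS = ("bouton", "claw", "dendrite", "other", "unknown")
SYNAPSE_COLUMNS = ("pre_id", "post_id", "x", "y", "z", "region_label")


@dataclass
class SynapseTable:
    """One row per annotated synaptic connection.

    Coordinates are treated as nanometres when no unit is declared (the
    hemibrain convention for deposited synapse exports).
    """

    df: pd.DataFrame
    coordinate_units: str = "nm"
    normalization_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SYNAPSE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"synapse table missing required columns: {missing}")
        if "compartment_tag" not in self.df.columns:
            self.df = self.df.assign(compartment_tag="unknown")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# movies


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(path: str | Path, movie: MovieStack) -> Path:
    """Write a movie as a multi-page TIFF plus a JSON calibration sidecar.

    Volumetric data is stored Z-fastest: page ``t * Z + z`` holds frame
    ``(t, z)``.
    """
    path = Path(path)
    t, z, y, x = movie.data.shape
    tifffile.imwrite(path, movie.data.reshape(t * z, y, x),
                     photometric="minisblack")
    meta = {
        "n_z_slices": z,
        "pixel_size_um": movie.pixel_size_um,
        "frame_rate_hz": movie.frame_rate_hz,
        "z_step_um": movie.z_step_um,
        "page_order": "z_fastest",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path, calibration: dict | None = None) -> MovieStack:
    """Read a multi-page TIFF movie back into a :class:`MovieStack`.

    ``calibration`` overrides/replaces the JSON sidecar; it must at least
    provide ``pixel_size_um`` and ``frame_rate_hz`` when no sidecar exists.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if calibration:
        meta.update(calibration)
    if "pixel_size_um" not in meta or "frame_rate_hz" not in meta:
        raise FormatError(f"no calibration for {path}: sidecar missing and none given")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_z = int(meta.get("n_z_slices", 1))
    if pages.shape[0] % n_z != 0:
        raise FormatError(
            f"page count {pages.shape[0]} not divisible by declared Z={n_z}"
        )
    t = pages.shape[0] // n_z
    data = pages.reshape(t, n_z, pages.shape[1], pages.shape[2])
    return MovieStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        z_step_um=float(meta.get("z_step_um", 0.0)),
    )


def write_protocol(path: str | Path, protocol: StimulusProtocol) -> Path:
    path = Path(path)
    path.write_text(json.dumps(protocol.to_dict(), indent=1))
    return path


def read_protocol(path: str | Path) -> StimulusProtocol:
    return StimulusProtocol.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# synapse tables


def write_synapse_table(path: str | Path, table: SynapseTable, sep: str = ",") -> Path:
    path = Path(path)
    table.df.to_csv(path, sep=sep, index=False)
    return path


def read_synapse_table(path: str | Path, sep: str | None = None) -> SynapseTable:
    """Read a delimited synapse table (header required).

    Compartment tags are case-folded; tags outside the known vocabulary are
    mapped to ``"unknown"``.  Every normalization is counted in the table's
    ``normalization_log`` — nothing is silently coerced.
    """
    path = Path(path)
    if sep is None:
        head = path.open().readline()
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    norm_log: dict[str, int] = {"case_folded_tags": 0, "unknown_tags": 0}
    if "compartment_tag" in df.columns:
        raw = df["compartment_tag"].astype(str)
        folded = raw.str.lower().str.strip()
        norm_log["case_folded_tags"] = int((raw != folded).sum())
        bad = ~folded.isin(COMPARTMENT_TAGS)
        norm_log["unknown_tags"] = int(bad.sum())
        df = df.assign(compartment_tag=folded.where(~bad, "unknown"))
    else:
        df = df.assign(compartment_tag="unknown")
    for key, n in norm_log.items():
        if n:
            log.info("read_synapse_table(%s): %s = %d", path.name, key, n)
    bad_coord = ~np.isfinite(df[["x", "y", "z"]]).all(axis=1)
    if bad_coord.any():
        norm_log["dropped_nonfinite_coordinates"] = int(bad_coord.sum())
        log.warning(
            "read_synapse_table(%s): dropping %d rows with non-finite coordinates",
            path.name,
            int(bad_coord.sum()),
        )
        df = df.loc[~bad_coord]
    return SynapseTable(df=df.reset_index(drop=True), normalization_log=norm_log)
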