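"""Reading and writing IRM time-lapse movies, annotations, traces and config.

Conventions used throughout the package:

* pixel and frame indices are 0-based, half-open (``row_min:row_max`` etc.);
* time in seconds is always ``frame_index * frame_interval``;
* intensities are kept in native camera units — no rescaling on load, because
  both the pooled Otsu threshold and the background SD thresholds act on raw
  intensities, and the IRM contrast convention (darker = closer to the
  substrate) is part of the analysis contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "IRMSequence",
    "PlateletROI",
    "PhaseAnnotation",
    "BackgroundROI",
    "ENDPOINT_CLASSES",
    "load_sequence",
    "save_sequence",
    "load_annotations",
    "save_annotations",
    "export_traces",
    "load_config",
    "DEFAULT_CONFIG",
]

ENDPOINT_CLASSES = ("no_attach", "filopodial", "fully_spread")

#: configuration keys understood by the pipeline, with defaults
DEFAULT_CONFIG: dict = {
    "frame_interval": 5.0,
    "active_sd_multiplier": 1.0,
    "bin_size": 3,
    "seed": 0,
}

ANNOTATION_COLUMNS = [
    "platelet_id",
    "row_min", "col_min", "row_max", "col_max",
    "frame_first", "frame_last",
    "onset", "filopodia_onset", "lamellipodia_onset", "spread",
    "endpoint_class",
    "bg_row_min", "bg_col_min", "bg_row_max", "bg_col_max",
    "index_base",
]


@dataclass(frozen=True)
class IRMSequence:
    """A single-channel IRM time-lapse stack.

    Higher intensity = brighter = farther from the substrate; darker pixels
    are in closer contact.  ``frames`` has shape (T, H, W) with T >= 2.
    """

    frames: np.ndarray
    frame_interval: float = 5.0
    origin_time: float = 0.0
    source_id: str = ""

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) stack, got ndim={frames.ndim}"
            )
        if frames.shape[0] < 2:
            raise ValueError(f"need at least 2 frames, got T={frames.shape[0]}")
        if not np.all(np.isfinite(frames.astype(np.float64, copy=False))):
            raise ValueError("frames contain non-finite intensities")
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        object.__setattr__(self, "frames", frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        """Time of each frame in seconds."""
        return self.origin_time + np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class PlateletROI:
    """Bounding box and frame range of one platelet, 0-based half-open."""

    platelet_id: str
    box: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max)
    frame_range: tuple[int, int]    # (first, last), half-open

    def __post_init__(self):
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1) or min(r0, c0) < 0:
            raise ValueError(f"empty or negative box {self.box} "
                             f"for platelet {self.platelet_id!r}")
        f0, f1 = self.frame_range
        if not (0 <= f0 < f1):
            raise ValueError(f"empty frame_range {self.frame_range} "
                             f"for platelet {self.platelet_id!r}")

    def validate_against(self, seq: IRMSequence) -> None:
        _, h, w = seq.shape
        r0, c0, r1, c1 = self.box
        if r1 > h or c1 > w:
            raise ValueError(
                f"box {self.box} exceeds image bounds ({h}, {w}) "
                f"for platelet {self.platelet_id!r}"
            )
        if self.frame_range[1] > seq.n_frames:
            raise ValueError(
                f"frame_range {self.frame_range} exceeds T={seq.n_frames} "
                f"for platelet {self.platelet_id!r}"
            )

    def crop(self, frames: np.ndarray) -> np.ndarray:
        """Crop a (T, H, W) or (H, W) array to this box (frame range untouched)."""
        r0, c0, r1, c1 = self.box
        return frames[..., r0:r1, c0:c1]

    def slice_frames(self, frames: np.ndarray) -> np.ndarray:
        """Crop in both time (frame_range) and space (box)."""
        f0, f1 = self.frame_range
        return self.crop(frames[f0:f1])


@dataclass(frozen=True)
class BackgroundROI:
    """An empty region close to the platelet, used to calibrate noise."""

    box: tuple[int, int, int, int]

    def __post_init__(self):
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1) or min(r0, c0) < 0:
            raise ValueError(f"empty or negative background box {self.box}")

    def disjoint_from(self, roi: PlateletROI) -> bool:
        r0, c0, r1, c1 = self.box
        R0, C0, R1, C1 = roi.box
        return r1 <= R0 or R1 <= r0 or c1 <= C0 or C1 <= c0

    def crop(self, frames: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.box
        return frames[..., r0:r1, c0:c1]


@dataclass(frozen=True)
class PhaseAnnotation:
    """Manually recorded stage time points of one platelet.

    Frames are indices into the movie; ``onset_frame`` is the platelet's
    first appearance (time zero of its spreading clock).  Stage onsets must
    be non-decreasing in the order onset -> filopodia -> lamellipodia ->
    spread; absent stages are ``None`` (an arrested platelet simply lacks a
    lamellipodia onset).
    """

    platelet_id: str
    onset_frame: int
    filopodia_onset_frame: int | None = None
    lamellipodia_onset_frame: int | None = None
    spread_frame: int | None = None
    endpoint_class: str = "no_attach"

    def __post_init__(self):
        if self.endpoint_class not in ENDPOINT_CLASSES:
            raise ValueError(
                f"unknown endpoint_class {self.endpoint_class!r} "
                f"for platelet {self.platelet_id!r}; expected one of {ENDPOINT_CLASSES}"
            )
        seq = [self.onset_frame, self.filopodia_onset_frame,
               self.lamellipodia_onset_frame, self.spread_frame]
        present = [v for v in seq if v is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(
                f"phase onsets out of order for platelet {self.platelet_id!r}: {seq}"
            )

    def validate_against(self, roi: PlateletROI) -> None:
        f0, f1 = roi.frame_range
        for name, v in [("onset", self.onset_frame),
                        ("filopodia_onset", self.filopodia_onset_frame),
                        ("lamellipodia_onset", self.lamellipodia_onset_frame),
                        ("spread", self.spread_frame)]:
            if v is not None and not (f0 <= v < f1):
                raise ValueError(
                    f"{name} frame {v} outside frame_range {roi.frame_range} "
                    f"for platelet {self.platelet_id!r}"
                )


# ---------------------------------------------------------------------------
# movies


def load_sequence(path, frame_interval: float = 5.0, *,
                  origin_time: float = 0.0) -> IRMSequence:
    """Read a single-channel multi-page TIFF as an :class:`IRMSequence`.

    Intensities are preserved bit-exactly; no rescaling or dtype conversion.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    ValueError
        for multi-channel pages, fewer than two pages, or pages whose
        shapes disagree (the offending page index is reported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such movie file: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if len(pages) < 2:
        raise ValueError(f"{path}: need at least 2 pages, got {len(pages)}")
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise ValueError(
                f"{path}: multi-channel input at page {i} (shape {page.shape}); "
                "expected single-channel grayscale"
            )
        if page.shape != pages[0].shape:
            raise ValueError(
                f"{path}: page {i} shape {page.shape} differs from "
                f"page 0 shape {pages[0].shape}"
            )
    frames = np.stack(pages)
    return IRMSequence(frames, frame_interval=frame_interval,
                       origin_time=origin_time, source_id=path.name)


def save_sequence(seq: IRMSequence, path) -> None:
    """Write a sequence as a multi-page TIFF, one page per frame.

    ``photometric`` is pinned so narrow frames are never misread as
    samples-per-pixel.
    """
    tifffile.imwrite(str(path), seq.frames, photometric="minisblack")


# ---------------------------------------------------------------------------
# annotations


def _opt_int(value, base: int) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value) - base


def load_annotations(path, seq: IRMSequence
                     ) -> list[tuple[PlateletROI, PhaseAnnotation, BackgroundROI]]:
    """Read per-platelet annotations (CSV or JSON) and validate against *seq*.

    The CSV dialect has one row per platelet with the columns in
    :data:`ANNOTATION_COLUMNS`; empty cells mean "absent".  ``index_base``
    (0 or 1) declares the indexing convention of the file; everything is
    converted to 0-based on load.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        records = df.to_dict(orient="records")

    out = []
    seen: set[str] = set()
    for rec in records:
        pid = str(rec["platelet_id"])
        if pid in seen:
            raise ValueError(f"duplicate platelet_id {pid!r}")
        seen.add(pid)
        base = int(rec.get("index_base", 0) or 0)
        if base not in (0, 1):
            raise ValueError(f"platelet {pid!r}: index_base must be 0 or 1, got {base}")

        # bounds stay half-open in either base; index_base only shifts the
        # origin (lower bounds and onsets), so upper bounds shift identically
        box = tuple(int(rec[k]) - base for k in
                    ("row_min", "col_min", "row_max", "col_max"))
        frame_first = int(rec["frame_first"]) - base
        frame_last = int(rec["frame_last"]) - base
        roi = PlateletROI(pid, box, (frame_first, frame_last))
        roi.validate_against(seq)

        ann = PhaseAnnotation(
            platelet_id=pid,
            onset_frame=int(rec["onset"]) - base,
            filopodia_onset_frame=_opt_int(rec.get("filopodia_onset"), base),
            lamellipodia_onset_frame=_opt_int(rec.get("lamellipodia_onset"), base),
            spread_frame=_opt_int(rec.get("spread"), base),
            endpoint_class=str(rec["endpoint_class"]),
        )
        ann.validate_against(roi)

        bg = BackgroundROI(tuple(
            int(rec[k]) - base for k in
            ("bg_row_min", "bg_col_min", "bg_row_max", "bg_col_max")))
        if not bg.disjoint_from(roi):
            raise ValueError(
                f"background box {bg.box} overlaps platelet box {roi.box} "
                f"for platelet {pid!r}")
        _, h, w = seq.shape
        if bg.box[2] > h or bg.box[3] > w:
            raise ValueError(f"background box {bg.box} exceeds image bounds "
                             f"for platelet {pid!r}")
        out.append((roi, ann, bg))
    return out


def save_annotations(records: Sequence[tuple[PlateletROI, PhaseAnnotation, BackgroundROI]],
                     path) -> None:
    """Write annotations in the CSV dialect read by :func:`load_annotations`."""
    rows = []
    for roi, ann, bg in records:
        rows.append({
            "platelet_id": roi.platelet_id,
            "row_min": roi.box[0], "col_min": roi.box[1],
            "row_max": roi.box[2], "col_max": roi.box[3],
            "frame_first": roi.frame_range[0], "frame_last": roi.frame_range[1],
            "onset": ann.onset_frame,
            "filopodia_onset": ann.filopodia_onset_frame,
            "lamellipodia_onset": ann.lamellipodia_onset_frame,
            "spread": ann.spread_frame,
            "endpoint_class": ann.endpoint_class,
            "bg_row_min": bg.box[0], "bg_col_min": bg.box[1],
            "bg_row_max": bg.box[2], "bg_col_max": bg.box[3],
            "index_base": 0,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# traces and config


def export_traces(traces: Mapping[str, Sequence[float]], path, *,
                  frame_interval: float, origin_time: float = 0.0,
                  first_frame: int = 0) -> None:
    """Write named per-frame series to CSV with a leading ``time_seconds`` column.

    All series must share one length; column order is the mapping's insertion
    order (deterministic).  Values are written with full ``repr`` precision so
    a read-back round trip is lossless.
    """
    names = list(traces)
    if not names:
        raise ValueError("no traces to export")
    lengths = {name: len(traces[name]) for name in names}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"trace length mismatch: {lengths}")
    n = lengths[names[0]]
    times = origin_time + (first_frame + np.arange(n)) * frame_interval
    df = pd.DataFrame({"time_seconds": times})
    for name in names:
        df[name] = np.asarray(traces[name], dtype=np.float64)
    # 17 significant digits round-trip any float64 exactly (read back with
    # float_precision="round_trip")
    df.to_csv(path, index=False, float_format="%.17g")


def load_config(path) -> dict:
    """Read a YAML config; unknown keys rejected, missing keys defaulted."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(raw)
    if not float(cfg["frame_interval"]) > 0:
        raise ValueError("frame_interval must be > 0")
    return cfg
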