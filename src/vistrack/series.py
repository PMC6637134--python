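"""Speed-quantile behavioural time series.

The per-frame distribution of matched-landmark speeds is summarised by
its 10th, 30th, 50th, 70th and 90th percentiles (Q10..Q90).  Each
quantile from each camera is one channel of a multivariate behavioural
time series; low quantiles respond to part-body movement (a head turn
moves the fastest landmarks only), high quantiles to whole-body
locomotion.  For speed statistics the quantiles are averaged across
cameras; for changepoint detection the channels are kept separate and
segmented independently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import MatchedPairs

__all__ = [
    "DEFAULT_QUANTILE_LEVELS",
    "SpeedDistribution",
    "TrialSeries",
    "landmark_speeds",
    "speed_quantiles",
    "assemble_trial",
    "truncated_log",
]

DEFAULT_QUANTILE_LEVELS = (0.10, 0.30, 0.50, 0.70, 0.90)
DEFAULT_LOG_FLOOR = 0.5  # px/frame; half a pixel per frame


@dataclass
class SpeedDistribution:
    frame_index: int
    speeds: np.ndarray  # px/frame, one per matched landmark

    @property
    def empty(self) -> bool:
        return len(self.speeds) == 0


@dataclass
class TrialSeries:
    """Multivariate speed series aligned to a stimulus onset.

    ``values`` is (n_frames, n_channels); ``channel_names`` identifies
    each column (e.g. ``cam1_q10`` or camera-averaged ``q50``).
    """

    values: np.ndarray
    channel_names: list[str]
    framerate: float
    onset_frame: int
    quantile_levels: tuple[float, ...] = DEFAULT_QUANTILE_LEVELS
    transform: str = "raw"

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Seconds relative to stimulus onset."""
        return (np.arange(self.n_frames) - self.onset_frame) / self.framerate

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        df.insert(0, "time_s", self.times)
        df.insert(0, "frame", np.arange(self.n_frames))
        return df

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "framerate": self.framerate,
            "onset_frame": self.onset_frame,
            "quantile_levels": list(self.quantile_levels),
            "transform": self.transform,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, csv_path: str | Path) -> "TrialSeries":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta_path = csv_path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        channels = [c for c in df.columns if c not in ("frame", "time_s")]
        return cls(
            values=df[channels].to_numpy(float),
            channel_names=channels,
            framerate=float(meta.get("framerate", 15.0)),
            onset_frame=int(meta.get("onset_frame", 0)),
            quantile_levels=tuple(meta.get("quantile_levels", DEFAULT_QUANTILE_LEVELS)),
            transform=meta.get("transform", "raw"),
        )


def landmark_speeds(matches: MatchedPairs, framerate: float | None = None) -> SpeedDistribution:
    """Euclidean displacement of each matched landmark, px/frame.

    Pass ``framerate`` to convert to px/s; the pipeline works in
    px/frame throughout.  Empty matches yield an empty (flagged)
    distribution.
    """
    if len(matches) == 0:
        return SpeedDistribution(frame_index=matches.frame_index, speeds=np.empty(0))
    speeds = np.linalg.norm(matches.displacements, axis=1)
    if framerate is not None:
        speeds = speeds * framerate
    return SpeedDistribution(frame_index=matches.frame_index, speeds=speeds)


def speed_quantiles(
    dist: SpeedDistribution, levels: tuple[float, ...] = DEFAULT_QUANTILE_LEVELS
) -> np.ndarray:
    """Empirical quantiles by linear interpolation of the order statistics.

    An empty distribution yields a NaN vector (carried as missing, not
    raised).
    """
    levels = tuple(levels)
    if not all(0 < l < 1 for l in levels) or list(levels) != sorted(levels) or len(
        set(levels)
    ) != len(levels):
        raise ValueError("levels must be strictly increasing in (0, 1)")
    if dist.empty:
        return np.full(len(levels), np.nan)
    return np.quantile(dist.speeds, levels, method="linear")


def assemble_trial(
    per_camera_quantiles: list[np.ndarray],
    onset_frame: int,
    framerate: float = 15.0,
    quantile_levels: tuple[float, ...] = DEFAULT_QUANTILE_LEVELS,
    average_cameras: bool = True,
    bridge_missing: bool = True,
) -> TrialSeries:
    """Stack per-camera (n_frames, n_levels) quantile arrays into a trial.

    ``average_cameras=True`` averages the matching quantile channels
    across cameras (the form used for speed statistics);
    ``average_cameras=False`` concatenates them (5 x n_cameras channels,
    the form segmented independently by changepoint detection).  Frames
    with missing values (no matched landmarks) are bridged by the
    previous valid value so the segmentation input is complete.
    """
    arrays = [np.asarray(q, float) for q in per_camera_quantiles]
    if not arrays:
        raise ValueError("need at least one camera")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("cameras must share frame count and quantile levels")
    if not 0 <= onset_frame < shape[0]:
        raise ValueError("onset_frame outside recording")
    if average_cameras:
        stacked = np.stack(arrays)
        with warnings.catch_warnings():
            # all-NaN frames (no matches on any camera) stay NaN silently
            warnings.simplefilter("ignore", RuntimeWarning)
            values = np.nanmean(stacked, axis=0)
        names = [f"q{int(round(l * 100))}" for l in quantile_levels]
    else:
        values = np.concatenate(arrays, axis=1)
        names = [
            f"cam{c + 1}_q{int(round(l * 100))}"
            for c in range(len(arrays))
            for l in quantile_levels
        ]
    if bridge_missing:
        values = (
            pd.DataFrame(values).ffill().bfill().to_numpy()
        )
    return TrialSeries(
        values=values,
        channel_names=names,
        framerate=framerate,
        onset_frame=onset_frame,
        quantile_levels=tuple(quantile_levels),
        transform="raw",
    )


def truncated_log(series: TrialSeries, floor: float = DEFAULT_LOG_FLOOR) -> TrialSeries:
    """v -> ln(max(v, floor)).

    Raw speed distributions are positively skewed (locomotion bursts),
    which biases mean-shift changepoints toward detecting movement
    increases; the truncated log compresses the upper tail so decreases
    (freezes) stand out.  The floor keeps zero speeds finite.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    values = np.log(np.maximum(series.values, floor))
    return replace(series, values=values, transform="truncated_log")
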