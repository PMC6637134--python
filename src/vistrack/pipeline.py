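"""End-to-end orchestration: video -> landmarks -> series -> changepoints -> stats.

Two entry points exist.  Video mode runs the whole chain on frame
stacks (or PNG directories) against a static background frame.  Series
mode starts from pre-tracked speed-quantile CSVs and runs only the
changepoint/statistics half, which needs no imaging dependencies.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import changepoint as cp
from . import fixtures, motion, series, stats, tracking

__all__ = [
    "PipelineConfig",
    "track_trial",
    "trial_penalty_path_support",
    "fit_trial_knee",
    "segment_trial",
    "analyse_trials",
    "run_synthetic_experiment",
    "load_frames",
]

log = logging.getLogger("vistrack")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default.

    Defaults are either values fixed by the recording protocol (15 Hz,
    onset 6 s in, inlier threshold 10 px, K in [1, 5] with 10 k-means
    restarts, 0.6 s / 0.53 s statistic windows) or documented
    engineering choices (Harris/matching parameters, sigma floor, log
    floor).
    """

    # foreground / tracking
    diff_threshold: float = tracking.DEFAULT_DIFF_THRESHOLD
    opening_radius: int = tracking.DEFAULT_OPENING_RADIUS
    patch_radius: int = tracking.DEFAULT_PATCH_RADIUS
    search_radius: float = tracking.DEFAULT_SEARCH_RADIUS
    min_correlation: float = tracking.DEFAULT_MIN_CORRELATION
    # motion model
    inlier_threshold: float = motion.DEFAULT_INLIER_THRESHOLD
    ransac_iterations: int = motion.DEFAULT_RANSAC_ITERATIONS
    k_range: tuple[int, int] = motion.DEFAULT_K_RANGE
    n_restarts: int = motion.DEFAULT_N_RESTARTS
    sigma_min: float = motion.SIGMA_MIN
    mu_zero: bool = False
    # series
    quantile_levels: tuple[float, ...] = series.DEFAULT_QUANTILE_LEVELS
    framerate: float = 15.0
    onset_frame: int = 90
    transform: str = "raw"  # or "truncated_log"
    log_floor: float = series.DEFAULT_LOG_FLOOR
    # changepoints
    min_seg: int = 1
    beta: float | None = None  # fixed penalty; None = knee-derived
    beta_range: tuple[float, float] | None = None  # None = data-driven
    # statistics
    chp_window_s: float = stats.DEFAULT_CHP_WINDOW_S
    speed_window_s: float = stats.DEFAULT_SPEED_WINDOW_S
    literal_sign: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "quantile_levels", "beta_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_frames(directory: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a trial from a directory of PNGs plus ``background.png``."""
    import imageio.v3 as iio

    directory = Path(directory)
    background = iio.imread(directory / "background.png")
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise ValueError(f"no frame_*.png in {directory}")
    frames = np.stack([iio.imread(p) for p in paths])
    return frames, background


def track_trial(
    frames: np.ndarray,
    background: np.ndarray,
    config: PipelineConfig | None = None,
    trial_seed: int = 0,
) -> np.ndarray:
    """Track one trial and return per-frame speed quantiles.

    For each consecutive frame pair: extract the foreground box, detect
    pyramid Harris landmarks, match them by patch correlation, fit the
    MDL-selected clustered rigid-motion model and drop its outlier
    matches, then summarise the surviving landmark speeds by quantiles.
    Frame 0 (no predecessor) and frames without usable matches are NaN.
    """
    cfg = config or PipelineConfig()
    n = len(frames)
    levels = cfg.quantile_levels
    out = np.full((n, len(levels)), np.nan)
    seed_seq = np.random.SeedSequence([trial_seed, cfg.seed])
    frame_seeds = seed_seq.generate_state(n)
    prev_lm = None
    prev_frame = None
    for t in range(n):
        frame = frames[t]
        fg = tracking.compute_foreground(
            frame, background, cfg.diff_threshold, cfg.opening_radius
        )
        if fg.empty:
            prev_lm, prev_frame = None, None
            continue
        lm = tracking.detect_landmarks(frame, fg.bbox, mask=fg.mask, frame_index=t)
        if prev_lm is not None and len(prev_lm) and len(lm):
            matches = tracking.match_landmarks(
                prev_lm,
                lm,
                prev_frame,
                frame,
                patch_radius=cfg.patch_radius,
                search_radius=cfg.search_radius,
                min_correlation=cfg.min_correlation,
            )
            if len(matches) >= 4:
                x0, y0, x1, y1 = fg.bbox
                keep = np.ones(len(matches), dtype=bool)
                try:
                    model, _ = motion.select_motion_model(
                        matches,
                        K_range=cfg.k_range,
                        n_restarts=cfg.n_restarts,
                        inlier_threshold=cfg.inlier_threshold,
                        seed=int(frame_seeds[t] % (2**31)),
                        n_iterations=cfg.ransac_iterations,
                        sigma_min=cfg.sigma_min,
                        mu_zero=cfg.mu_zero,
                        bbox_area=float((x1 - x0) * (y1 - y0)),
                    )
                    if (model.labels >= 0).sum() >= 4:
                        keep = model.labels >= 0
                except motion.InfeasibleModelError:
                    pass
                kept = tracking.MatchedPairs(
                    prev=matches.prev[keep],
                    curr=matches.curr[keep],
                    correlation=matches.correlation[keep],
                    frame_index=t,
                )
                dist = series.landmark_speeds(kept)
                out[t] = series.speed_quantiles(dist, levels)
        prev_lm, prev_frame = lm, frame
    return out


def segment_trial(
    trial: series.TrialSeries, beta: float, min_seg: int = 1
) -> tuple[list[cp.Segmentation], cp.PooledChangepoints]:
    """PELT each channel independently at one penalty, then pool."""
    segs = [
        cp.pelt_segment(trial.values[:, c], beta, min_seg)
        for c in range(trial.n_channels)
    ]
    return segs, cp.pool_changepoints(segs, trial.n_frames)


def trial_penalty_path_support(
    trial: series.TrialSeries,
    beta_range: tuple[float, float] | None = None,
    min_seg: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (beta, total m across channels) support for knee fitting.

    Each channel gets its own CROPS path over a common penalty range;
    the per-channel changepoint counts are summed at the union of all
    channels' support penalties.
    """
    if beta_range is None:
        ranges = [cp.default_beta_range(trial.values[:, c]) for c in range(trial.n_channels)]
        beta_range = (min(r[0] for r in ranges), max(r[1] for r in ranges))
    paths = [
        cp.crops_path(trial.values[:, c], beta_range[0], beta_range[1], min_seg)
        for c in range(trial.n_channels)
    ]
    support = np.linspace(beta_range[0], beta_range[1], 101)
    m_total = np.zeros_like(support)
    for p in paths:
        m_total += [p.segmentation_at(b).m for b in support]
    return support, m_total


def fit_trial_knee(
    trial: series.TrialSeries,
    beta_range: tuple[float, float] | None = None,
    min_seg: int = 1,
) -> cp.KneeFit:
    """Knee of the trial's changepoint-count-vs-penalty curve."""
    support, m_total = trial_penalty_path_support(trial, beta_range, min_seg)
    return cp.fit_knee((support, m_total))


def analyse_trials(
    trials: list[series.TrialSeries],
    labels: list[str] | None = None,
    animals: list[str] | None = None,
    blocks: list[int] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Changepoint + speed statistics for a set of trials.

    Unless the config fixes a penalty, each trial's knee is estimated
    from its CROPS path and the study penalty is the median knee.
    Returns the per-trial table and a summary dict (chosen penalty, knee
    distribution, per-stimulus response table).
    """
    cfg = config or PipelineConfig()
    if not trials:
        raise ValueError("empty trial list")
    labels = labels or ["stimulus"] * len(trials)
    animals = animals or [""] * len(trials)
    blocks = blocks or [0] * len(trials)

    knees: list[float] = []
    if cfg.beta is None:
        for trial in trials:
            knee = fit_trial_knee(trial, cfg.beta_range, cfg.min_seg)
            if knee.converged and not knee.degenerate:
                knees.append(knee.psi)
        if not knees:
            raise ValueError("no trial produced a usable knee; set config.beta")
        beta = cp.choose_penalty(knees)
    else:
        beta = cfg.beta
    log.info("penalty beta=%.4g (from %d knees)", beta, len(knees))

    responses: list[stats.TrialResponse] = []
    rows = []
    for i, trial in enumerate(trials):
        segs, pooled = segment_trial(trial, beta, cfg.min_seg)
        delta = stats.changepoint_rate_delta(
            pooled,
            trial.onset_frame,
            cfg.chp_window_s,
            trial.framerate,
            literal_sign=cfg.literal_sign,
        )
        sp = stats.speed_response(
            trial, window_s=cfg.speed_window_s, literal_sign=cfg.literal_sign
        )
        resp = stats.TrialResponse(
            trial_index=i,
            stimulus_label=labels[i],
            delta_chp_rate=delta,
            speed_delta=sp,
            classification=stats.classify_trial(delta),
            block_index=blocks[i],
            animal=animals[i],
        )
        responses.append(resp)
        rows.append(
            {
                "trial": i,
                "animal": animals[i],
                "stimulus": labels[i],
                "block": blocks[i],
                "delta_chp_rate": delta,
                "speed_delta": sp,
                "class": resp.classification,
                "n_changepoints": pooled.total,
            }
        )
        log.debug("trial %d: %d pooled changepoints, delta=%.3f", i, pooled.total, delta)
    table = pd.DataFrame(rows)
    summary = {
        "beta": float(beta),
        "knees": [float(k) for k in knees],
        "by_stimulus": stats.response_table(responses),
    }
    return table, summary


def run_synthetic_experiment(
    n_freeze: int = 20,
    n_flight: int = 0,
    seed: int = 0,
    config: PipelineConfig | None = None,
    arena_size: tuple[int, int] = (640, 640),
    n_frames: int = 200,
    onset_frame: int = 90,
) -> tuple[pd.DataFrame, dict]:
    """Render, track and analyse a batch of scripted synthetic trials.

    Freeze trials (locomotion then an abrupt stop at onset, the
    looming-type response) are analysed on the truncated-log series;
    flight trials (quiescence then a locomotion burst, the flash-type
    response) on the raw series, matching how each transform biases the
    detector toward decreases and increases respectively.
    """
    cfg = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(n_freeze + n_flight)
    trials: list[series.TrialSeries] = []
    labels: list[str] = []
    pooled_list = []
    for i in range(n_freeze + n_flight):
        tseed = int(trial_seeds[i] % (2**31))
        kind = "freeze" if i < n_freeze else "flight"
        script = (
            fixtures.freeze_script(
                onset_frame, n_frames, arena_size=arena_size, framerate=cfg.framerate, seed=tseed
            )
            if kind == "freeze"
            else fixtures.flight_script(
                onset_frame, n_frames, arena_size=arena_size, framerate=cfg.framerate, seed=tseed
            )
        )
        rendered = fixtures.render_synthetic_trial(script, seed=tseed)
        quant = track_trial(rendered.frames, rendered.background, cfg, trial_seed=tseed)
        trial = series.assemble_trial(
            [quant],
            onset_frame=onset_frame,
            framerate=cfg.framerate,
            quantile_levels=cfg.quantile_levels,
        )
        if kind == "freeze":
            trial = series.truncated_log(trial, cfg.log_floor)
        trials.append(trial)
        labels.append(kind)
        log.info("rendered+tracked trial %d (%s)", i, kind)
    table, summary = analyse_trials(trials, labels=labels, config=cfg)
    return table, summary
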