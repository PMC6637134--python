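"""Event-aligned trial statistics.

A trial's response to a stimulus is summarised by (i) the change in the
pooled changepoint rate between a short window after and a short window
before stimulus onset (delta #chp/s, default 0.6 s windows), and (ii)
the change in mean landmark speed over matched windows (default
0.53 s).  Significance across trials uses the exact two-sided sign
test; habituation across stimulus repetitions uses a permutation test
that shuffles trial order within each animal.

Sign convention: positive values always mean an INCREASE after the
stimulus (post minus pre).  Some reports print the difference the other
way round ("pre - post"); pass ``literal_sign=True`` to reproduce that
orientation.  Both rates and speeds use half-open, frame-aligned
windows: pre covers [onset - w, onset), post covers [onset, onset + w),
with w the window length rounded to whole frames (0.6 s at 15 Hz is
exactly 9 frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .changepoint import PooledChangepoints
from .series import TrialSeries

__all__ = [
    "TrialResponse",
    "ProtocolSpec",
    "changepoint_rate_delta",
    "speed_response",
    "classify_trial",
    "sign_test",
    "habituation_permutation_test",
    "onset_concentration",
    "response_table",
]

DEFAULT_CHP_WINDOW_S = 0.6
DEFAULT_SPEED_WINDOW_S = 0.53


@dataclass
class TrialResponse:
    trial_index: int
    stimulus_label: str
    delta_chp_rate: float  # changepoints/s, positive = increase after onset
    speed_delta: float  # speed units, positive = movement increase
    classification: str  # increase / decrease / none
    block_index: int = 0
    animal: str = ""


@dataclass(frozen=True)
class ProtocolSpec:
    """Block-randomised stimulation protocol metadata.

    Defaults mirror a 7-block protocol with 73 s inter-stimulus
    interval, each trial recorded from 6 s before to 7 s after onset at
    15 Hz (200 frames, onset at frame 90).
    """

    n_blocks: int = 7
    stimuli_per_block: tuple[str, ...] = ("dim", "mid", "bright")
    isi_s: float = 73.0
    pre_s: float = 6.0
    post_s: float = 7.0
    framerate: float = 15.0
    randomisation_seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round((self.pre_s + self.post_s) * self.framerate)) + 5

    @property
    def onset_frame(self) -> int:
        return int(round(self.pre_s * self.framerate))

    def trial_order(self) -> list[tuple[int, str]]:
        """(block, stimulus) sequence with independent within-block shuffles."""
        rng = np.random.default_rng(self.randomisation_seed)
        out = []
        for b in range(self.n_blocks):
            order = rng.permutation(len(self.stimuli_per_block))
            out.extend((b, self.stimuli_per_block[i]) for i in order)
        return out


def _windows(onset_frame: int, window_s: float, framerate: float, n: int):
    w = int(round(window_s * framerate))
    if w < 1:
        raise ValueError("window shorter than one frame")
    pre = (onset_frame - w, onset_frame)
    post = (onset_frame, onset_frame + w)
    if pre[0] < 0 or post[1] > n:
        raise ValueError("window exceeds the recording")
    return pre, post, w


def changepoint_rate_delta(
    pooled: PooledChangepoints,
    onset_frame: int,
    window_s: float = DEFAULT_CHP_WINDOW_S,
    framerate: float = 15.0,
    literal_sign: bool = False,
) -> float:
    """Difference in pooled changepoint rate around stimulus onset (1/s)."""
    counts = pooled.counts
    pre, post, _ = _windows(onset_frame, window_s, framerate, len(counts))
    rate_pre = counts[pre[0] : pre[1]].sum() / window_s
    rate_post = counts[post[0] : post[1]].sum() / window_s
    delta = rate_post - rate_pre
    return float(-delta if literal_sign else delta)


def speed_response(
    series: TrialSeries,
    onset_frame: int | None = None,
    window_s: float = DEFAULT_SPEED_WINDOW_S,
    literal_sign: bool = False,
) -> float:
    """Mean speed (over channels and frames) after minus before onset."""
    onset = series.onset_frame if onset_frame is None else onset_frame
    pre, post, _ = _windows(onset, window_s, series.framerate, series.n_frames)
    mean_pre = float(np.nanmean(series.values[pre[0] : pre[1]]))
    mean_post = float(np.nanmean(series.values[post[0] : post[1]]))
    delta = mean_post - mean_pre
    return float(-delta if literal_sign else delta)


def classify_trial(delta_chp_rate: float) -> str:
    """Sign trichotomy: increase / decrease / none (exact zero)."""
    if not np.isfinite(delta_chp_rate):
        raise ValueError("delta must be finite")
    if delta_chp_rate > 0:
        return "increase"
    if delta_chp_rate < 0:
        return "decrease"
    return "none"


def sign_test(deltas) -> float:
    """Exact two-sided sign test on per-trial response values.

    Zeros are dropped (conventional exact sign test); with k positives
    among n nonzero values, p = 2 min(P(X <= k), P(X >= k)) capped at 1
    for X ~ Binomial(n, 1/2).  All-zero input returns p = 1.
    """
    d = np.asarray(deltas, float)
    if d.size == 0 or not np.all(np.isfinite(d)):
        raise ValueError("need finite, non-empty deltas")
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return 1.0
    k = int((nz > 0).sum())
    p = 2.0 * min(sps.binom.cdf(k, n, 0.5), sps.binom.sf(k - 1, n, 0.5))
    return float(min(p, 1.0))


def habituation_permutation_test(
    values,
    trial_order,
    early_set: tuple[int, ...] = (1, 2),
    late_set: tuple[int, ...] = (6, 7),
    n_perm: int = 100_000,
    seed: int = 0,
    animals=None,
) -> tuple[float, float]:
    """Permutation test for response habituation across repetitions.

    The statistic is mean(values on early repetitions) - mean(values on
    late repetitions); habituation (responses fading with repetition)
    makes it positive.  The null is built by shuffling the repetition
    labels -- within each animal when ``animals`` is given, preserving
    per-animal trial counts -- and the one-sided p-value is the fraction
    of surrogate statistics >= the observed one.
    """
    values = np.asarray(values, float)
    order = np.asarray(trial_order, int)
    if values.shape != order.shape or values.size == 0:
        raise ValueError("values and trial_order must be equal-length, non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    early = np.isin(order, early_set)
    late = np.isin(order, late_set)
    if not early.any() or not late.any():
        raise ValueError("early/late repetition sets not represented in the data")
    observed = float(values[early].mean() - values[late].mean())

    rng = np.random.default_rng(seed)
    if animals is None:
        groups = [np.arange(values.size)]
    else:
        animals = np.asarray(animals)
        groups = [np.flatnonzero(animals == a) for a in np.unique(animals)]
    # shuffling repetition labels within an animal is the same null as
    # shuffling that animal's values while keeping the labels fixed
    e_idx = np.flatnonzero(early)
    l_idx = np.flatnonzero(late)
    count = 0
    vperm = values.copy()
    for _ in range(n_perm):
        for g in groups:
            vperm[g] = values[g][rng.permutation(len(g))]
        stat = vperm[e_idx].mean() - vperm[l_idx].mean()
        if stat >= observed:
            count += 1
    return observed, count / n_perm


def onset_concentration(
    pooled: PooledChangepoints, onset_frame: int, halfwidth: int = 2
) -> bool:
    """Do pooled changepoints concentrate at the stimulus onset?

    True when no sliding window of the same width anywhere in the trial
    collects more pooled changepoints than the window centred on the
    onset (+/- ``halfwidth`` frames).
    """
    counts = np.asarray(pooled.counts, float)
    width = 2 * halfwidth + 1
    sums = np.convolve(counts, np.ones(width), mode="valid")  # centre = i + halfwidth
    onset_sum = counts[max(onset_frame - halfwidth, 0) : onset_frame + halfwidth + 1].sum()
    return bool(onset_sum >= sums.max())


def response_table(trials: list[TrialResponse], group_by: str = "stimulus_label") -> pd.DataFrame:
    """Per-stimulus summary: n, % increase/decrease/none, mean +/- sem.

    Reproduces the reporting style of per-stimulus response panels.
    """
    if not trials:
        raise ValueError("need at least one trial")
    df = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "stimulus_label": [t.stimulus_label for t in trials],
            "block_index": [t.block_index for t in trials],
            "animal": [t.animal for t in trials],
            "delta_chp_rate": [t.delta_chp_rate for t in trials],
            "speed_delta": [t.speed_delta for t in trials],
            "classification": [t.classification for t in trials],
        }
    )
    rows = []
    for label, g in df.groupby(group_by, sort=True):
        n = len(g)
        cls = g["classification"].value_counts()
        sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        rows.append(
            {
                group_by: label,
                "n": n,
                "pct_increase": 100.0 * cls.get("increase", 0) / n,
                "pct_decrease": 100.0 * cls.get("decrease", 0) / n,
                "pct_none": 100.0 * cls.get("none", 0) / n,
                "mean_delta_chp_rate": float(g["delta_chp_rate"].mean()),
                "sem_delta_chp_rate": sem(g["delta_chp_rate"]),
                "mean_speed_delta": float(g["speed_delta"].mean()),
                "sem_speed_delta": sem(g["speed_delta"]),
                "sign_test_p_speed": sign_test(g["speed_delta"].to_numpy()),
                "sign_test_p_chp": sign_test(g["delta_chp_rate"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)
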