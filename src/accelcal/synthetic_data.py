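"""Synthetic activity-session generator and analytic threshold oracle.

Real calibration studies pair a hip-worn accelerometer with momentary time
sampling direct observation during semi-structured activity sessions.  This
module emulates that design end to end so the calibration pipeline can be
exercised and checked against known ground truth:

* each session follows a phase plan (warm-up, instruction games, obstacle
  games, team games) with a target behaviour-category mix per phase;
* each participant's per-second behaviour trace is a renewal process of
  bouts: category drawn from the phase mix, duration exponential with a
  configurable mean dwell;
* 10-s count epochs are emitted from a right-skewed (lognormal) count
  distribution conditioned on the category occupying the majority of the
  window, with a multiplicative vector-magnitude factor >= 1 and an optional
  per-participant activity multiplier (lognormal, mean 1);
* observation codes follow the momentary sampling scheme: one code per 20-s
  interval taken at the final second of the 10-s observe window (3
  observations per minute), with the higher code recorded on a transition,
  an adjacent-category mislabel probability standing in for imperfect rater
  reliability, and an out-of-hall probability flagging intervals invalid.

The analytic oracle computes, from the same configuration, the
Youden-optimal threshold, maximal J and AUC for the idealized model in which
a 20-s count is the sum of two independent 10-s draws from the recorded
category's count distribution (mislabeling folded in through the confusion
kernel).  It is the independent reference for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import signal
from scipy import stats as _sps

from accelcal.calibration import DEFAULT_SCHEME, DIRECTIONS, POSITIVE_LOW, BinaryCodingScheme

logger = logging.getLogger(__name__)

CATEGORIES = (1, 2, 3, 4, 5)  # lying down, sitting, standing, walking, very active

# rng stream identifiers per participant
_STREAM_TRACE, _STREAM_COUNTS, _STREAM_OBSERVE, _STREAM_MULTIPLIER = 0, 1, 2, 3


class LognormalParams(BaseModel):
    """Right-skewed positive distribution parameterized by median and log-SD.

    Draws are ``median * exp(sigma * Z)``; ``median = 0`` degenerates to a
    point mass at zero and ``sigma = 0`` to a point mass at the median, which
    keeps the random stream layout identical across configurations.
    """

    median: float = Field(ge=0)
    sigma: float = Field(ge=0)

    model_config = {"frozen": True}

    @property
    def mean(self) -> float:
        return self.median * float(np.exp(self.sigma**2 / 2))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        z = rng.standard_normal(size)
        return self.median * np.exp(self.sigma * z)


class Phase(BaseModel):
    """One session phase: name, duration and target behaviour mix."""

    name: str
    duration_min: float = Field(gt=0)
    mix: Dict[int, float]

    model_config = {"frozen": True}

    @field_validator("mix")
    @classmethod
    def _check_mix(cls, v: Dict[int, float]) -> Dict[int, float]:
        if not v:
            raise ValueError("phase mix must be nonempty")
        if not set(v) <= set(CATEGORIES):
            raise ValueError("phase mix keys must be categories 1..5")
        if any(p < 0 for p in v.values()):
            raise ValueError("phase mix probabilities must be nonnegative")
        total = sum(v.values())
        if total <= 0:
            raise ValueError("phase mix must have positive total mass")
        return {c: p / total for c, p in v.items()}


def _default_phase_plan() -> List[Phase]:
    # 10 + 10 + 10 + 15 min; mixes chosen so the session marginal roughly
    # matches observed per-category session percentages (few % lying, ~20%
    # sitting, ~20% standing, ~30% walking, ~20% very active).
    return [
        Phase(name="warm_up", duration_min=10,
              mix={1: 0.05, 2: 0.20, 3: 0.25, 4: 0.40, 5: 0.10}),
        Phase(name="instruction_games", duration_min=10,
              mix={1: 0.04, 2: 0.22, 3: 0.24, 4: 0.35, 5: 0.15}),
        Phase(name="obstacle_games", duration_min=10,
              mix={1: 0.03, 2: 0.22, 3: 0.20, 4: 0.27, 5: 0.28}),
        Phase(name="team_games", duration_min=15,
              mix={1: 0.04, 2: 0.24, 3: 0.17, 4: 0.25, 5: 0.30}),
    ]


def _default_count_params() -> Dict[int, LognormalParams]:
    # 10-s vertical-axis count distributions per category; medians chosen so
    # the 20-s sums bracket typical sedentary/moderate/vigorous boundaries
    # (sedentary classes well below ~170 counts/20-s, standing in the light
    # band, walking in the moderate band, very active above ~770).
    return {
        1: LognormalParams(median=4, sigma=1.0),
        2: LognormalParams(median=40, sigma=0.8),
        3: LognormalParams(median=120, sigma=0.6),
        4: LognormalParams(median=260, sigma=0.5),
        5: LognormalParams(median=700, sigma=0.5),
    }


class SimulationConfig(BaseModel):
    """Full configuration of the synthetic study.

    Defaults emulate a seven-session school-based protocol with 50 children
    (session sizes 8, 8, 9, 7, 7, 5, 6), a four-phase 45-min activity plan,
    sporadic behaviour bouts (mean dwell 15 s), ~10% adjacent-category coding
    error (matching rater reliabilities in the 80-90% range) and a 2%
    out-of-hall rate.
    """

    n_sessions: int = Field(default=7, ge=1)
    participants_per_session: Union[int, Tuple[int, ...]] = (8, 8, 9, 7, 7, 5, 6)
    phase_plan: List[Phase] = Field(default_factory=_default_phase_plan)
    category_count_params: Dict[int, LognormalParams] = Field(default_factory=_default_count_params)
    vm_ratio_params: LognormalParams = LognormalParams(median=2.5, sigma=0.3)
    dwell_mean_s: float = Field(default=15.0, gt=0)
    participant_sd: float = Field(default=0.15, ge=0)
    mislabel_prob: float = Field(default=0.10, ge=0, le=1)
    out_of_hall_prob: float = Field(default=0.02, ge=0, le=1)
    seed: int = Field(default=0, ge=0)

    @field_validator("phase_plan")
    @classmethod
    def _check_phase_plan(cls, v):
        if not v:
            raise ValueError("phase plan must contain at least one phase")
        return v

    @field_validator("category_count_params")
    @classmethod
    def _check_categories(cls, v):
        if set(v) != set(CATEGORIES):
            raise ValueError("category_count_params must cover categories 1..5")
        means = {c: v[c].mean for c in CATEGORIES}
        ordered = max(means[1], means[2]) < means[3] < means[4] < means[5]
        if not ordered:
            raise ValueError(
                "category count means must increase strictly from categories 1/2 through 5"
            )
        return v

    @field_validator("vm_ratio_params")
    @classmethod
    def _check_vm_ratio(cls, v: LognormalParams) -> LognormalParams:
        if v.median < 1:
            raise ValueError("vector-magnitude ratio median must be >= 1")
        return v

    @model_validator(mode="after")
    def _check_sessions(self):
        if isinstance(self.participants_per_session, tuple):
            if len(self.participants_per_session) != self.n_sessions:
                raise ValueError("participants_per_session list must have n_sessions entries")
            if any(n < 1 for n in self.participants_per_session):
                raise ValueError("each session needs at least one participant")
        elif self.participants_per_session < 1:
            raise ValueError("participants_per_session must be positive")
        return self

    def session_sizes(self) -> List[int]:
        if isinstance(self.participants_per_session, tuple):
            return list(self.participants_per_session)
        return [int(self.participants_per_session)] * self.n_sessions

    def session_duration_s(self) -> int:
        return int(round(sum(p.duration_min * 60 for p in self.phase_plan)))


def category_weights(config: SimulationConfig) -> np.ndarray:
    """Phase-duration-weighted marginal probability of each category (index 0 = category 1)."""
    w = np.zeros(5)
    for phase in config.phase_plan:
        for c, p in phase.mix.items():
            w[c - 1] += phase.duration_min * p
    return w / w.sum()


def _participant_rng(config: SimulationConfig, session_id: int, participant_index: int,
                     stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, session_id, participant_index, stream])


def participant_ids(session_id: int, n: int) -> List[str]:
    return [f"S{session_id:02d}P{i + 1:02d}" for i in range(n)]


def generate_behaviour_sequence(config: SimulationConfig, session_id: int) -> Dict[str, np.ndarray]:
    """Per-second behaviour traces for every participant in one session.

    Within each phase, categories are drawn per bout from the phase mix and
    bout durations (rounded, >= 1 s) from an exponential with mean
    ``dwell_mean_s``; the phase is filled until its duration is reached.  The
    marginal category distribution therefore approaches the phase mix as the
    phase grows long.
    """
    if not config.phase_plan:
        raise ValueError("empty phase plan")
    if not 1 <= session_id <= config.n_sessions:
        raise ValueError(f"session_id must be in 1..{config.n_sessions}")
    n = config.session_sizes()[session_id - 1]
    traces: Dict[str, np.ndarray] = {}
    for i, pid in enumerate(participant_ids(session_id, n)):
        rng = _participant_rng(config, session_id, i, _STREAM_TRACE)
        parts = []
        for phase in config.phase_plan:
            dur = int(round(phase.duration_min * 60))
            cats = np.array(sorted(phase.mix), dtype=np.int64)
            probs = np.array([phase.mix[c] for c in cats])
            out = np.empty(dur, dtype=np.int64)
            filled = 0
            while filled < dur:
                c = rng.choice(cats, p=probs)
                length = max(1, int(round(rng.exponential(config.dwell_mean_s))))
                out[filled: filled + length] = c
                filled += length
            parts.append(out)
        traces[pid] = np.concatenate(parts)
    return traces


def _majority_category(window: np.ndarray) -> int:
    """Majority category of a 10-s window; ties go to the later bout."""
    counts = np.bincount(window, minlength=6)
    m = counts.max()
    tied = np.flatnonzero(counts == m)
    if len(tied) == 1:
        return int(tied[0])
    return int(max(tied, key=lambda c: np.flatnonzero(window == c)[-1]))


def emit_counts(trace: np.ndarray, config: SimulationConfig,
                rng: np.random.Generator | None = None,
                activity_multiplier: float = 1.0) -> pd.DataFrame:
    """Emit 10-s count epochs (vertical and vector magnitude) from a trace.

    The trace is truncated to the last complete 20-s interval so count epochs
    always pair up with observation intervals.  Each epoch's vertical count
    is drawn from the distribution of the category occupying the majority of
    its window (scaled by the participant's activity multiplier); the
    vector-magnitude count is the vertical count times a sampled factor >= 1,
    rounded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n20 = len(trace) // 20
    trace = np.asarray(trace)[: 20 * n20]
    n_epochs = 2 * n20
    if n_epochs == 0:
        return pd.DataFrame({"offset_s": [], "vertical_counts": [], "vm_counts": []})

    windows = trace.reshape(-1, 10)
    cats = np.array([_majority_category(w) for w in windows])
    medians = np.array([config.category_count_params[c].median for c in cats])
    sigmas = np.array([config.category_count_params[c].sigma for c in cats])
    z = rng.standard_normal(n_epochs)
    vertical = np.rint(activity_multiplier * medians * np.exp(sigmas * z)).astype(np.int64)

    excess_median = config.vm_ratio_params.median - 1.0
    zf = rng.standard_normal(n_epochs)
    factor = 1.0 + excess_median * np.exp(config.vm_ratio_params.sigma * zf)
    vm = np.rint(vertical * factor).astype(np.int64)

    return pd.DataFrame(
        {
            "offset_s": np.arange(n_epochs, dtype=np.int64) * 10,
            "vertical_counts": vertical,
            "vm_counts": vm,
        }
    )


def observe_sofit(trace: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Momentary-time-sampling observation of a behaviour trace.

    One record per 20-s interval: the code is the behaviour at the final
    second of the 10-s observe window; if the behaviour changed at that
    instant the higher of the two codes is recorded (e.g. lying down ->
    sitting is coded sitting).  With probability ``mislabel_prob`` the code
    is replaced by an adjacent category; with probability
    ``out_of_hall_prob`` the record is flagged invalid.  Returns columns
    interval, true_category, category, valid.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trace = np.asarray(trace)
    n20 = len(trace) // 20
    if n20 == 0:
        raise ValueError("trace shorter than one 20-s interval")
    t = trace[: 20 * n20]

    idx = 20 * np.arange(n20) + 9  # final second of each observe window
    current = t[idx]
    previous = t[idx - 1]
    true_cat = current
    recorded = np.maximum(current, previous)  # higher code on transition

    mislabel = rng.random(n20) < config.mislabel_prob
    step = rng.integers(0, 2, n20) * 2 - 1
    adjacent = np.where(recorded == 1, 2, np.where(recorded == 5, 4, recorded + step))
    recorded = np.where(mislabel, adjacent, recorded)
    valid = rng.random(n20) >= config.out_of_hall_prob

    return pd.DataFrame(
        {
            "interval": np.arange(n20, dtype=np.int64),
            "true_category": true_cat.astype(np.int64),
            "category": recorded.astype(np.int64),
            "valid": valid,
        }
    )


@dataclass
class SimulationResult:
    """In-memory study data: count epochs, observation log and ground truth."""

    config: SimulationConfig
    counts: pd.DataFrame  # participant, session, offset_s, vertical_counts, vm_counts
    sofit: pd.DataFrame  # participant, session, interval, category, valid
    ground_truth: pd.DataFrame  # + true_category, recorded_category


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Generate the full multi-session study deterministically from the seed."""
    count_frames, sofit_frames, truth_frames = [], [], []
    for session_id in range(1, config.n_sessions + 1):
        traces = generate_behaviour_sequence(config, session_id)
        for i, (pid, trace) in enumerate(traces.items()):
            m_rng = _participant_rng(config, session_id, i, _STREAM_MULTIPLIER)
            sd = config.participant_sd
            multiplier = float(np.exp(sd * m_rng.standard_normal() - sd**2 / 2))
            counts = emit_counts(
                trace, config, _participant_rng(config, session_id, i, _STREAM_COUNTS), multiplier
            )
            obs = observe_sofit(trace, config, _participant_rng(config, session_id, i, _STREAM_OBSERVE))
            counts.insert(0, "participant", pid)
            counts.insert(1, "session", session_id)
            obs.insert(0, "participant", pid)
            obs.insert(1, "session", session_id)
            count_frames.append(counts)
            sofit_frames.append(obs)
    counts = pd.concat(count_frames, ignore_index=True)
    obs = pd.concat(sofit_frames, ignore_index=True)
    truth = obs.rename(columns={"category": "recorded_category"})[
        ["participant", "session", "interval", "true_category", "recorded_category", "valid"]
    ]
    sofit = obs[["participant", "session", "interval", "category", "valid"]]
    return SimulationResult(config=config, counts=counts, sofit=sofit, ground_truth=truth)


def write_study(result: SimulationResult, outdir) -> Dict[str, Path]:
    """Write the generated study in the delimited formats the readers ingest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.csv",
        "sofit": outdir / "sofit.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    counts = result.counts.rename(columns={"vertical_counts": "axis1", "vm_counts": "vm"})
    counts.to_csv(paths["counts"], index=False)
    sofit = result.sofit.copy()
    sofit["valid"] = sofit["valid"].astype(int)
    sofit.to_csv(paths["sofit"], index=False)
    truth = result.ground_truth.copy()
    truth["valid"] = truth["valid"].astype(int)
    truth.to_csv(paths["ground_truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

def _pmf_10s(params: LognormalParams, qtail: float = 1e-10) -> np.ndarray:
    """Integer pmf of a rounded lognormal 10-s count draw."""
    if params.median == 0:
        return np.array([1.0])
    if params.sigma == 0:
        k = int(round(params.median))
        pmf = np.zeros(k + 1)
        pmf[k] = 1.0
        return pmf
    dist = _sps.lognorm(s=params.sigma, scale=params.median)
    kmax = int(np.ceil(dist.ppf(1 - qtail)))
    edges = np.arange(kmax + 1) + 0.5
    cdf = dist.cdf(edges)
    pmf = np.diff(np.concatenate(([0.0], cdf)))
    pmf[-1] += 1 - cdf[-1]
    return pmf


def _sum_two(pmf: np.ndarray) -> np.ndarray:
    """pmf of the sum of two independent draws (20-s analysis epoch)."""
    if len(pmf) == 1:
        out = np.zeros(1)
        out[0] = 1.0
        return out
    s = signal.fftconvolve(pmf, pmf)
    s = np.clip(s, 0, None)
    return s / s.sum()


def _mislabel_kernel(p: float) -> np.ndarray:
    """5x5 matrix M[t, c] = P(recorded category c+1 | true category t+1)."""
    m = np.eye(5) * (1 - p)
    m[0, 1] += p
    m[4, 3] += p
    for t in (1, 2, 3):
        m[t, t - 1] += p / 2
        m[t, t + 1] += p / 2
    return m


def class_count_pmfs(config: SimulationConfig, intensity: str,
                     scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> tuple[np.ndarray, np.ndarray]:
    """pmfs of the 20-s count sum given a positive / negative recorded code.

    The recorded-code distribution mixes true categories through the
    adjacent-category mislabel kernel; conditioning on the recorded code
    being positive (respectively negative) yields a posterior mixture over
    true categories, each contributing the pmf of two independent 10-s
    draws.
    """
    w = category_weights(config)
    kernel = _mislabel_kernel(config.mislabel_prob)
    pos_cols = [c - 1 for c in sorted(scheme.positives(intensity))]
    p_pos_given_true = kernel[:, pos_cols].sum(axis=1)
    w_pos = w * p_pos_given_true
    w_neg = w * (1 - p_pos_given_true)
    if w_pos.sum() <= 0 or w_neg.sum() <= 0:
        raise ValueError("both classes required: a criterion class has zero probability")

    pmfs = [_sum_two(_pmf_10s(config.category_count_params[c])) for c in CATEGORIES]
    size = max(len(p) for p in pmfs)

    def _mix(weights: np.ndarray) -> np.ndarray:
        out = np.zeros(size)
        for wt, pmf in zip(weights / weights.sum(), pmfs):
            out[: len(pmf)] += wt * pmf
        return out

    return _mix(w_pos), _mix(w_neg)


def _optimal_from_pmfs(pmf_pos: np.ndarray, pmf_neg: np.ndarray,
                       direction: str) -> tuple[float, float]:
    """Youden-optimal integer threshold from two class pmfs.

    Returns (threshold, J).  When a plateau of thresholds attains the maximal
    J (e.g. disjoint class supports) the plateau midpoint is returned.
    """
    size = max(len(pmf_pos), len(pmf_neg))
    fp = np.zeros(size)
    fn = np.zeros(size)
    fp[: len(pmf_pos)] = pmf_pos
    fn[: len(pmf_neg)] = pmf_neg
    cdf_pos = np.cumsum(fp)
    cdf_neg = np.cumsum(fn)
    # positive-low: J(t) = F+(t) - F-(t) (positives classified at counts <= t)
    # positive-high: J(t) = F-(t-1) - F+(t-1) (positives at counts >= t)
    gain = cdf_pos - cdf_neg if direction == POSITIVE_LOW else cdf_neg - cdf_pos
    j_max = float(gain.max())
    if j_max < 1e-9:
        raise ValueError("no discriminating threshold: class distributions coincide")
    hits = np.flatnonzero(gain >= j_max - 1e-12)
    threshold = (float(hits[0]) + float(hits[-1])) / 2
    if direction != POSITIVE_LOW:
        threshold += 1
    return threshold, j_max


def analytic_optimal_threshold(config: SimulationConfig, intensity: str,
                               scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> float:
    """Threshold maximizing J for the idealized 20-s count-sum mixture model."""
    pmf_pos, pmf_neg = class_count_pmfs(config, intensity, scheme)
    threshold, _ = _optimal_from_pmfs(pmf_pos, pmf_neg, DIRECTIONS[intensity])
    return threshold


def analytic_youden(config: SimulationConfig, intensity: str,
                    scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> float:
    """Maximal Youden J for the idealized mixture model."""
    pmf_pos, pmf_neg = class_count_pmfs(config, intensity, scheme)
    _, j = _optimal_from_pmfs(pmf_pos, pmf_neg, DIRECTIONS[intensity])
    return j


def analytic_auc(config: SimulationConfig, intensity: str,
                 scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> float:
    """AUC of the idealized mixture model (ties counted one half)."""
    pmf_pos, pmf_neg = class_count_pmfs(config, intensity, scheme)
    size = max(len(pmf_pos), len(pmf_neg))
    fp = np.zeros(size)
    fn = np.zeros(size)
    fp[: len(pmf_pos)] = pmf_pos
    fn[: len(pmf_neg)] = pmf_neg
    cdf_neg = np.cumsum(fn)
    if DIRECTIONS[intensity] == POSITIVE_LOW:
        return float(np.sum(fp * (1 - cdf_neg + 0.5 * fn)))
    return float(np.sum(fp * (cdf_neg - 0.5 * fn)))


def sample_class_sums(config: SimulationConfig, intensity: str, n: int,
                      rng: np.random.Generator,
                      scheme: BinaryCodingScheme = DEFAULT_SCHEME) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo draws of 20-s sums from the oracle's class mixtures.

    Independent of the convolution machinery; used to check the numeric
    search against simulation.
    """
    w = category_weights(config)
    kernel = _mislabel_kernel(config.mislabel_prob)
    pos_cols = [c - 1 for c in sorted(scheme.positives(intensity))]
    p_pos_given_true = kernel[:, pos_cols].sum(axis=1)

    def _draw(weights: np.ndarray) -> np.ndarray:
        weights = weights / weights.sum()
        cats = rng.choice(np.array(CATEGORIES), size=n, p=weights)
        out = np.empty(n, dtype=np.int64)
        for c in CATEGORIES:
            mask = cats == c
            k = int(mask.sum())
            if k == 0:
                continue
            params = config.category_count_params[c]
            draws = np.rint(params.draw(rng, 2 * k)).reshape(k, 2).sum(axis=1)
            out[mask] = draws.astype(np.int64)
        return out

    return _draw(w * p_pos_given_true), _draw(w * (1 - p_pos_given_true))


def adjacent_count_spacing(observed_counts, threshold: float) -> float:
    """Spacing between the observed count values adjacent to *threshold*.

    The gap between the largest observed count strictly below and the
    smallest strictly above the threshold (clamped to the observed range);
    the resolution at which an empirical ROC sweep can localize a boundary.
    """
    u = np.unique(np.asarray(observed_counts))
    if len(u) < 2:
        return 1.0
    below = u[u < threshold]
    above = u[u > threshold]
    lo = below[-1] if len(below) else u[0]
    hi = above[0] if len(above) else u[-1]
    return float(max(hi - lo, 1))
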