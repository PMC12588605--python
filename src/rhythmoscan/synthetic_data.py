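"""Generative emulation of the auditory rhythmicity experiments.

Everything downstream is testable without real data: this module generates
(i) balanced experiment designs with uniformly sampled target delays,
(ii) observers whose SDT sensitivity/bias and reaction times optionally
oscillate with delay, (iii) 3-down-1-up staircases and the 69-80 %/4 %
adaptive-difficulty rule, (iv) the Gaussian-beta linear-model generator used to
calibrate the statistical approaches, and (v) trial-aligned gaze/pupil traces
with blinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glm_rhythm import UV_FREQ_HZ, WINDOW_MID_S
from .trial_data import DELAY_WINDOW_S, TrialTable

__all__ = [
    "DesignConfig",
    "generate_design",
    "RhythmComponent",
    "ObserverParams",
    "simulate_observer",
    "StaircaseConfig",
    "run_staircase",
    "AdaptiveRule",
    "adapt_difficulty",
    "SimConfig",
    "CalibrationSample",
    "simulate_calibration_dataset",
    "EyeParams",
    "simulate_eye_traces",
]

_EXPERIMENT_DEFAULTS = {
    "exp1": dict(n_blocks=8, trials_per_block=190, dual_task_blocks=0.0),
    "exp2": dict(n_blocks=8, trials_per_block=190, dual_task_blocks=0.0),
    "exp3": dict(n_blocks=8, trials_per_block=190, dual_task_blocks=0.0),
    "exp4": dict(n_blocks=16, trials_per_block=130, dual_task_blocks=0.5),
}


@dataclass
class DesignConfig:
    """Session layout of one experiment.

    Defaults reproduce the published designs: 8 blocks of 190 trials for
    experiments 1-3 (380 trials per ear x condition) and 16 blocks of 130
    trials with the dual task in half the blocks for experiment 4 (260 trials
    per ear x condition x task).
    """

    experiment: str = "exp1"
    n_blocks: int | None = None
    trials_per_block: int | None = None
    delay_window_s: tuple[float, float] = DELAY_WINDOW_S
    dual_task_blocks: float | None = None
    participant_id: str = "sim01"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENT_DEFAULTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        d = _EXPERIMENT_DEFAULTS[self.experiment]
        if self.n_blocks is None:
            self.n_blocks = d["n_blocks"]
        if self.trials_per_block is None:
            self.trials_per_block = d["trials_per_block"]
        if self.dual_task_blocks is None:
            self.dual_task_blocks = d["dual_task_blocks"]


def _balanced_cells(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Exactly balanced (ear, condition) labels for n trials, shuffled."""
    if n % 4:
        raise ValueError(f"{n} trials not divisible by #ears x #conditions = 4")
    ears = np.repeat(np.array(["L", "L", "R", "R"]), n // 4)
    conds = np.repeat(np.array(["f1", "f2", "f1", "f2"]), n // 4)
    order = rng.permutation(n)
    return ears[order], conds[order]


def generate_design(config: DesignConfig) -> TrialTable:
    """Generate one session: balanced cells, uniform delays in [0.3, 1.5] s.

    Ear x condition cells are exactly balanced over the session (and, for
    exp4, within each task half); every trial gets an independent uniform
    delay. Exp4 assigns the dual task to half the blocks and a fixation-dot
    intensity change to half the dual-task trials, at a time uniform between
    0.1 s after noise onset and the target.
    """
    rng = np.random.default_rng(config.seed)
    nb, tpb = config.n_blocks, config.trials_per_block
    n = nb * tpb
    n_dual_blocks = round(config.dual_task_blocks * nb)
    dual_block = np.zeros(nb, dtype=bool)
    dual_block[rng.choice(nb, size=n_dual_blocks, replace=False)] = True
    block_col = np.repeat(np.arange(1, nb + 1), tpb)
    dual_col = dual_block[block_col - 1]

    ears = np.empty(n, dtype=object)
    conds = np.empty(n, dtype=object)
    for flag in (False, True):
        m = dual_col == flag
        if m.any():
            ears[m], conds[m] = _balanced_cells(int(m.sum()), rng)

    lo, hi = config.delay_window_s
    delays = rng.uniform(lo, hi, size=n)

    dot_change = np.zeros(n, dtype=bool)
    dot_time = np.full(n, np.nan)
    if dual_col.any():
        dual_idx = np.flatnonzero(dual_col)
        chosen = rng.choice(dual_idx, size=len(dual_idx) // 2, replace=False)
        dot_change[chosen] = True
        # change time uniform in [noise onset + 0.1 s, target onset]
        dot_time[chosen] = rng.uniform(0.1, delays[chosen])

    df = pd.DataFrame({
        "participant_id": config.participant_id,
        "experiment": config.experiment,
        "block": block_col,
        "trial_index": np.concatenate([np.arange(1, tpb + 1)] * nb),
        "ear": ears.astype(str),
        "condition": conds.astype(str),
        "delay_s": delays,
        "response": "none",
        "correct": pd.array([pd.NA] * n, dtype="boolean"),
        "rt_s": np.nan,
        "stim_param": 1.0,
        "dual_task": pd.array(dual_col, dtype="boolean"),
        "dot_change": pd.array(dot_change, dtype="boolean"),
        "dot_response": "none",
        "dot_change_time_s": dot_time,
    })
    return TrialTable(df, metadata={"experiment": config.experiment,
                                    "seed": config.seed, "provenance": "generate_design"})


@dataclass(frozen=True)
class RhythmComponent:
    """One sinusoidal modulation: target metric, ear scope, frequency, phase."""

    target: str  # dprime | bias | rt
    freq_hz: float
    amplitude: float
    phase_rad: float = 0.0
    ear: str = "both"  # L | R | both

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 1.0 <= self.freq_hz <= 12.0:
            raise ValueError("freq_hz must lie in [1, 12]")
        if self.target not in ("dprime", "bias", "rt"):
            raise ValueError(f"unknown rhythm target {self.target!r}")
        if self.ear not in ("L", "R", "both"):
            raise ValueError(f"unknown ear scope {self.ear!r}")


@dataclass
class ObserverParams:
    """A simulated observer under the equal-variance Gaussian SDT model.

    Sensitivity d'(t) = d0 + sum of its rhythm components; criterion
    c(t) = c0 + components; reaction times are generated in sqrt-seconds
    (rt0 + drift + rhythm + noise, squared) so that the analysis-side
    square-root transform recovers approximately Gaussian residuals. Time t is
    the delay re-referenced to the start of the target-uncertainty window.
    ``threshold_db``/``psych_slope_db`` parameterise the psychometric function
    used by the staircase and adaptive-difficulty simulations.
    """

    d0: float | dict[tuple[str, str], float] = 1.5
    c0: float | dict[tuple[str, str], float] = 0.0
    rt0: float = 0.75  # sqrt-seconds: mean RT ~ 0.56 s
    rt_slope: float = 0.0
    rhythm: list[RhythmComponent] = field(default_factory=list)
    lapse_rate: float = 0.02
    rt_noise_sd: float = 0.12
    threshold_db: float | dict[tuple[str, str], float] = 0.0
    psych_slope_db: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")

    @staticmethod
    def _per_cell(value, ear: np.ndarray, cond: np.ndarray) -> np.ndarray:
        """Broadcast a scalar or per-(ear, condition) mapping over trials."""
        if not isinstance(value, dict):
            return np.full(ear.shape, float(value))
        out = np.empty(ear.shape, dtype=float)
        for (e, c), v in value.items():
            out[(ear == e) & (cond == c)] = v
        return out

    def _modulation(self, target: str, t: np.ndarray, ear: np.ndarray) -> np.ndarray:
        total = np.zeros_like(t)
        for comp in self.rhythm:
            if comp.target != target:
                continue
            scope = np.ones_like(t, dtype=bool) if comp.ear == "both" else (ear == comp.ear)
            total += scope * comp.amplitude * np.sin(
                2 * np.pi * comp.freq_hz * t + comp.phase_rad)
        return total

    def p_correct(self, stim_db: float, ear: str = "L", condition: str = "f1") -> float:
        """Psychometric function for staircase/adaptation: chance 0.5, rising
        with stimulus level; threshold may differ per ear x condition track."""
        theta = self.threshold_db
        if isinstance(theta, dict):
            theta = theta[(ear, condition)]
        return 0.5 + 0.5 * norm.cdf((stim_db - theta) / self.psych_slope_db)


def simulate_observer(
    design: TrialTable, params: ObserverParams, seed: int | None = None
) -> TrialTable:
    """Generate responses, correctness and reaction times for a design.

    Equal-variance SDT with symmetric placement: P(opt1 | f1) = Phi(d'/2 - c),
    P(opt1 | f2) = Phi(-d'/2 - c); a lapse responds uniformly at random.
    """
    rng = np.random.default_rng(seed)
    df = design.df.copy()
    t = df["delay_s"].to_numpy() - DELAY_WINDOW_S[0]
    ear = df["ear"].to_numpy()
    cond = df["condition"].to_numpy()

    dprime = params._per_cell(params.d0, ear, cond) \
        + params._modulation("dprime", t, ear)
    crit = params._per_cell(params.c0, ear, cond) \
        + params._modulation("bias", t, ear)
    mu = np.where(cond == "f1", dprime / 2.0, -dprime / 2.0) - crit
    p_opt1 = norm.cdf(mu)
    resp = np.where(rng.random(len(df)) < p_opt1, "opt1", "opt2")
    lapse = rng.random(len(df)) < params.lapse_rate
    resp[lapse] = np.where(rng.random(int(lapse.sum())) < 0.5, "opt1", "opt2")
    correct = (resp == "opt1") == (cond == "f1")

    rt_sqrt = (params.rt0 + params.rt_slope * t
               + params._modulation("rt", t, ear)
               + rng.normal(0.0, params.rt_noise_sd, len(df)))
    rt = np.maximum(rt_sqrt, 0.0) ** 2

    df["response"] = resp
    df["correct"] = pd.array(correct, dtype="boolean")
    df["rt_s"] = rt
    return design.copy_with(df, observer_seed=seed, provenance="simulate_observer")


@dataclass
class StaircaseConfig:
    """3-down-1-up staircase: three consecutive correct responses lower the
    level, one error raises it. The step starts at ``initial_step_db`` and
    halves at each of the first reversals down to ``floor_step_db``."""

    initial_step_db: float = 4.0
    floor_step_db: float = 1.0
    n_reversals_stop: int = 10
    n_reversals_average: int = 5
    start_db: float = 12.0
    max_trials_per_track: int = 400

    def __post_init__(self) -> None:
        if self.n_reversals_average > self.n_reversals_stop:
            raise ValueError("n_reversals_average must be <= n_reversals_stop")


class _Track:
    def __init__(self, cfg: StaircaseConfig):
        self.cfg = cfg
        self.level = cfg.start_db
        self.step = cfg.initial_step_db
        self.correct_run = 0
        self.last_dir = 0
        self.reversal_levels: list[float] = []
        self.n_trials = 0

    @property
    def done(self) -> bool:
        return (len(self.reversal_levels) >= self.cfg.n_reversals_stop
                or self.n_trials >= self.cfg.max_trials_per_track)

    def update(self, correct: bool) -> None:
        self.n_trials += 1
        move = 0
        if correct:
            self.correct_run += 1
            if self.correct_run == 3:
                move = -1
                self.correct_run = 0
        else:
            move = +1
            self.correct_run = 0
        if move == 0:
            return
        if self.last_dir and move != self.last_dir:
            self.reversal_levels.append(self.level)
            if len(self.reversal_levels) <= 2:
                self.step = max(self.step / 2.0, self.cfg.floor_step_db)
        self.last_dir = move
        self.level += move * self.step

    def threshold(self) -> float:
        k = self.cfg.n_reversals_average
        if len(self.reversal_levels) < k:
            warnings.warn(
                f"staircase stopped after {self.n_trials} trials with only "
                f"{len(self.reversal_levels)} reversals; partial threshold",
                stacklevel=3)
            levels = self.reversal_levels if self.reversal_levels else [self.level]
            return float(np.mean(levels))
        return float(np.mean(self.reversal_levels[-k:]))


def run_staircase(
    params: ObserverParams,
    config: StaircaseConfig = StaircaseConfig(),
    seed: int | None = None,
) -> dict[tuple[str, str], float]:
    """Four interleaved 3-down-1-up tracks (ear x condition).

    Threshold per track = mean level over the last ``n_reversals_average``
    reversals. The observer answers via its psychometric function.
    """
    rng = np.random.default_rng(seed)
    tracks = {(e, c): _Track(config) for e in ("L", "R") for c in ("f1", "f2")}
    while True:
        open_keys = [k for k, tr in tracks.items() if not tr.done]
        if not open_keys:
            break
        key = open_keys[rng.integers(len(open_keys))]
        tr = tracks[key]
        correct = rng.random() < params.p_correct(tr.level, *key)
        tr.update(correct)
    return {k: tr.threshold() for k, tr in tracks.items()}


@dataclass(frozen=True)
class AdaptiveRule:
    """Keep running accuracy inside [lower_pc, upper_pc] by 4 % level steps."""

    window_trials: int = 30
    lower_pc: float = 0.69
    upper_pc: float = 0.80
    step_fraction: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_pc < self.upper_pc < 1.0:
            raise ValueError("need 0 < lower_pc < upper_pc < 1")


def adapt_difficulty(
    history: np.ndarray, current: float, rule: AdaptiveRule = AdaptiveRule()
) -> float:
    """One adaptive-difficulty update from the recent correctness history.

    Accuracy over the last ``window_trials`` above the band makes the task
    harder (level * (1 - step_fraction)); below the band, easier
    (level * (1 + step_fraction)); inside, unchanged. No update until the
    window is full.
    """
    history = np.asarray(history, dtype=float)
    if history.size < rule.window_trials:
        return current
    acc = history[-rule.window_trials:].mean()
    if acc > rule.upper_pc:
        return current * (1.0 - rule.step_fraction)
    if acc < rule.lower_pc:
        return current * (1.0 + rule.step_fraction)
    return current


@dataclass
class SimConfig:
    """Calibration generator: Gaussian-beta linear model plus additive noise.

    Per participant, one beta vector is drawn from Gaussian priors
    (mean, SD): offset (1, 0.1), linear slope (0.1, 0.1), u/v (0.1, 0.1),
    sine at 4 Hz (0.2, 0.1), cosine at 4 Hz (0.2, 0.1); the trial outcome is
    y(t) = b0 + b1 t + b2 uv(t) + b3 sin(2 pi 4 t) + b4 cos(2 pi 4 t) + noise
    with t uniform on [0, 1.2]. ``with_effect=False`` zeroes the sine and
    cosine betas for every participant.
    """

    n_participants: int = 25
    n_trials: int = 700
    rhythm_freq_hz: float = 4.0
    noise_sd: float = 2.0
    with_effect: bool = True
    beta_priors: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "offset": (1.0, 0.1), "slope": (0.1, 0.1), "uv": (0.1, 0.1),
        "sin": (0.2, 0.1), "cos": (0.2, 0.1)})
    seed: int | None = None


@dataclass
class CalibrationSample:
    """One simulated virtual experiment."""

    delay_ref_s: np.ndarray  # (P, n_trials)
    y: np.ndarray  # (P, n_trials)
    betas: np.ndarray  # (P, 5) in column order offset, slope, uv, sin, cos
    config: SimConfig

    def as_scan_data(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.delay_ref_s[i], self.y[i]) for i in range(self.y.shape[0])]


def simulate_calibration_dataset(
    config: SimConfig, seed: int | np.random.Generator | None = None
) -> CalibrationSample:
    """Draw one virtual experiment from the calibration generator."""
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    P, n = config.n_participants, config.n_trials
    means = np.array([config.beta_priors[k][0] for k in ("offset", "slope", "uv", "sin", "cos")])
    sds = np.array([config.beta_priors[k][1] for k in ("offset", "slope", "uv", "sin", "cos")])
    betas = rng.normal(means, sds, size=(P, 5))
    if not config.with_effect:
        betas[:, 3:] = 0.0
    t = rng.uniform(0.0, 1.2, size=(P, n))
    w = 2 * np.pi * config.rhythm_freq_hz * t
    X = np.stack([np.ones_like(t), t,
                  np.cos(2 * np.pi * UV_FREQ_HZ * (t - WINDOW_MID_S)),
                  np.sin(w), np.cos(w)], axis=-1)  # (P, n, 5)
    y = np.einsum("pnk,pk->pn", X, betas)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=(P, n))
    return CalibrationSample(t, y, betas, config)


@dataclass
class EyeParams:
    """Gaze/pupil trace generator: fixation jitter + drift, a slow smooth pupil
    process with per-trial offsets, and blinks as missing segments."""

    sample_rate_hz: float = 500.0
    epoch_s: tuple[float, float] = (-0.4, 1.5)
    jitter_sd_mean_deg: float = 0.3
    jitter_sd_sd_deg: float = 0.1
    drift_sd_deg_per_s: float = 0.2
    pupil_slow_sd: float = 0.6
    pupil_trial_sd: float = 0.4
    pupil_smooth_s: float = 0.4
    blink_rate_hz: float = 0.05
    blink_duration_s: float = 0.2


def simulate_eye_traces(
    design: TrialTable, eye_params: EyeParams = EyeParams(), seed: int | None = None
) -> pd.DataFrame:
    """Per-trial gaze/pupil traces aligned to background-noise onset.

    Columns: participant_id, trial_id (design row position), t_s, x_deg, y_deg,
    pupil, valid. Blink samples are invalid with NaN signals.
    """
    rng = np.random.default_rng(seed)
    p = eye_params
    t0, t1 = p.epoch_s
    n_samp = int(round((t1 - t0) * p.sample_rate_hz)) + 1
    t = t0 + np.arange(n_samp) / p.sample_rate_hz
    n_trials = len(design.df)
    frames = []
    win = max(int(p.pupil_smooth_s * p.sample_rate_hz), 1)
    kernel = np.ones(win) / win
    for i in range(n_trials):
        sd = abs(rng.normal(p.jitter_sd_mean_deg, p.jitter_sd_sd_deg))
        drift = rng.normal(0.0, p.drift_sd_deg_per_s, size=2)
        x = rng.normal(0.0, sd, n_samp) + drift[0] * (t - t0)
        y = rng.normal(0.0, sd, n_samp) + drift[1] * (t - t0)
        raw = rng.normal(0.0, p.pupil_slow_sd, n_samp + win)
        pupil = np.convolve(raw, kernel, mode="same")[win // 2: win // 2 + n_samp] \
            * np.sqrt(win) + rng.normal(0.0, p.pupil_trial_sd)
        valid = np.ones(n_samp, dtype=bool)
        n_blinks = rng.poisson(p.blink_rate_hz * (t1 - t0))
        for _ in range(n_blinks):
            start = rng.uniform(t0, t1 - p.blink_duration_s)
            m = (t >= start) & (t < start + p.blink_duration_s)
            valid[m] = False
        x[~valid] = np.nan
        y[~valid] = np.nan
        pupil[~valid] = np.nan
        frames.append(pd.DataFrame({
            "participant_id": design.df["participant_id"].iloc[i],
            "trial_id": i, "t_s": t, "x_deg": x, "y_deg": y,
            "pupil": pupil, "valid": valid,
        }))
    return pd.concat(frames, ignore_index=True)
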