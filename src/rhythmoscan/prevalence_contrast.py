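"""Bootstrap prevalence, ear co-occurrence, condition contrasts, eye metrics.

Prevalence quantifies how reproducible a significant rhythmicity effect is
across random variations of the participant sample: cohorts are resampled with
replacement (sample size = pool size) and, for each resample, the group-level
percentile test is re-evaluated from the participants' precomputed actual and
surrogate statistics — no refitting inside the bootstrap. Condition contrasts
(dual task, pupil-size and fixation-stability median splits) compare
group-level vector strengths between two trial sets per participant with
paired t-tests, BH-corrected across the frequency grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm_rhythm import _gaussian_vs, frequency_grid
from .sdt_binning import BinGrid, compute_binned_metrics, compute_sdt
from .trial_data import TrialTable

__all__ = [
    "PrevalenceResult",
    "bootstrap_prevalence",
    "average_prevalence",
    "band_flags",
    "CoOccurrence",
    "cooccurrence_correlation",
    "EyeTrialMetrics",
    "compute_eye_metrics",
    "median_split",
    "ContrastResult",
    "contrast_conditions",
    "dual_task_summary",
    "difficulty_drift",
]


@dataclass
class PrevalenceResult:
    """Fraction of bootstrap cohorts significant at each frequency."""

    freqs_hz: np.ndarray
    prevalence: np.ndarray
    flags: np.ndarray = field(repr=False)  # (n_boot, F) significance per resample
    n_boot: int = 5000
    threshold: float = 0.05
    approach: str | None = None
    metric: str | None = None
    ear_set: str | None = None
    seed: int | None = None


def bootstrap_prevalence(
    actual: np.ndarray,
    surrogates: np.ndarray,
    threshold: float,
    n_boot: int = 5000,
    seed: int | None = None,
    freqs_hz: np.ndarray | None = None,
    **labels: str,
) -> PrevalenceResult:
    """Bootstrap prevalence of significant frequencies.

    actual: (P, F) per-participant statistic (vector strength or spectral
    amplitude); surrogates: (P, F, n_surr) the matching per-participant null
    statistics. Each resample draws P participants with replacement, forms the
    group mean and the index-wise group surrogate distribution from the drawn
    participants, and tests each frequency at the calibrated first-level
    ``threshold``.
    """
    actual = np.asarray(actual, dtype=float)
    surrogates = np.asarray(surrogates, dtype=float)
    if surrogates.ndim != 3 or surrogates.shape[:2] != actual.shape:
        raise ValueError("surrogates must be (P, F, n_surr) matching actual (P, F)")
    P, F = actual.shape
    n_surr = surrogates.shape[2]
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, P, size=(n_boot, P))
    W = np.zeros((n_boot, P))
    np.add.at(W, (np.arange(n_boot)[:, None], draws), 1.0)
    W /= P
    boot_actual = W @ actual  # (n_boot, F)
    flags = np.empty((n_boot, F), dtype=bool)
    for f in range(F):
        boot_surr = W @ surrogates[:, f, :]  # (n_boot, n_surr)
        exceed = (boot_surr >= boot_actual[:, [f]]).sum(axis=1)
        p = (1.0 + exceed) / (1.0 + n_surr)
        flags[:, f] = p <= threshold
    if freqs_hz is None:
        freqs_hz = np.arange(F, dtype=float)
    return PrevalenceResult(np.asarray(freqs_hz, dtype=float), flags.mean(axis=0),
                            flags, n_boot, threshold, seed=seed, **labels)


def average_prevalence(results: list[PrevalenceResult]) -> PrevalenceResult:
    """Unweighted mean prevalence across experiments (identical grids)."""
    if not results:
        raise ValueError("no prevalence results to average")
    freqs = results[0].freqs_hz
    for r in results[1:]:
        if r.freqs_hz.shape != freqs.shape or not np.allclose(r.freqs_hz, freqs):
            raise ValueError("frequency grid mismatch across experiments")
    prev = np.mean([r.prevalence for r in results], axis=0)
    return PrevalenceResult(freqs, prev, np.zeros((0, freqs.size), dtype=bool),
                            n_boot=results[0].n_boot,
                            threshold=results[0].threshold)


def band_flags(result: PrevalenceResult, band_hz: tuple[float, float]) -> np.ndarray:
    """Per-resample flag: any significant frequency inside the band."""
    m = (result.freqs_hz >= band_hz[0]) & (result.freqs_hz <= band_hz[1])
    if not m.any():
        raise ValueError(f"band {band_hz} contains no grid frequency")
    return result.flags[:, m].any(axis=1)


@dataclass
class CoOccurrence:
    """Correlation of significant-effect flags between two ear/frequency bands."""

    r: float
    p: float
    n: int
    band_a: tuple[float, float] | None = None
    band_b: tuple[float, float] | None = None
    defined: bool = True


def cooccurrence_correlation(
    flags_a: np.ndarray, flags_b: np.ndarray, **labels
) -> CoOccurrence:
    """Pearson correlation of two paired binary flag vectors.

    Two-sided p from the t-approximation with n-2 degrees of freedom; a
    constant flag vector yields an undefined correlation, reported as such.
    """
    a = np.asarray(flags_a, dtype=float)
    b = np.asarray(flags_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("flag vectors must be paired (same bootstrap samples)")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("a flag vector is constant; correlation undefined", stacklevel=2)
        return CoOccurrence(np.nan, np.nan, a.size, defined=False, **labels)
    r, p = stats.pearsonr(a, b)
    return CoOccurrence(float(r), float(p), a.size, **labels)


# ---------------------------------------------------------------------------
# eye metrics


@dataclass
class EyeTrialMetrics:
    """Tidy per-trial eye metrics plus the participant inclusion report."""

    per_trial: pd.DataFrame  # trial_id, participant_id, pupil_mean_z, fixation_stability, valid
    report: pd.DataFrame  # participant_id, n_valid, included


def compute_eye_metrics(
    traces: pd.DataFrame,
    table: TrialTable,
    gaze_limit_deg: float = 14.0,
    epoch_s: tuple[float, float] = (-0.4, 1.5),
    min_valid_trials: int = 600,
) -> EyeTrialMetrics:
    """Trial-wise pupil mean and fixation stability from epoched traces.

    An epoch is rejected if any sample in [-0.4, +1.5] s is invalid (blink,
    NaN, or gaze beyond +-``gaze_limit_deg`` on either axis). Pupil samples are
    z-scored within participant over all retained epochs; the per-trial pupil
    value is the mean z in [noise onset, target onset] and fixation stability
    the mean of SD(x) and SD(y) over the same interval. Participants with
    fewer than ``min_valid_trials`` valid epochs are flagged excluded.
    """
    tr = traces[(traces["t_s"] >= epoch_s[0]) & (traces["t_s"] <= epoch_s[1])].copy()
    bad = (~tr["valid"].astype(bool)
           | tr[["x_deg", "y_deg", "pupil"]].isna().any(axis=1)
           | (tr["x_deg"].abs() > gaze_limit_deg)
           | (tr["y_deg"].abs() > gaze_limit_deg))
    trial_ok = ~bad.groupby(tr["trial_id"]).any()
    delays = pd.Series(table.df["delay_s"].to_numpy(),
                       index=pd.RangeIndex(len(table.df)), name="delay_s")
    pid_by_trial = pd.Series(table.df["participant_id"].to_numpy(),
                             index=pd.RangeIndex(len(table.df)))

    rows = []
    for pid, sub in tr.groupby(tr["trial_id"].map(pid_by_trial)):
        ok_ids = [t for t in sub["trial_id"].unique() if trial_ok.get(t, False)]
        kept = sub[sub["trial_id"].isin(ok_ids)]
        mu = kept["pupil"].mean()
        sd = kept["pupil"].std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"participant {pid}: constant pupil; z-scores set to 0",
                          stacklevel=2)
            sd = np.inf
        for t_id, trial in kept.groupby("trial_id"):
            seg = trial[(trial["t_s"] >= 0) & (trial["t_s"] <= delays.loc[t_id])]
            stab = float((seg["x_deg"].std(ddof=0) + seg["y_deg"].std(ddof=0)) / 2.0)
            rows.append(dict(trial_id=t_id, participant_id=pid,
                             pupil_mean_z=float(((seg["pupil"] - mu) / sd).mean()),
                             fixation_stability=stab, valid=True))
        for t_id in sub["trial_id"].unique():
            if t_id not in ok_ids:
                rows.append(dict(trial_id=t_id, participant_id=pid,
                                 pupil_mean_z=np.nan, fixation_stability=np.nan,
                                 valid=False))
    per_trial = pd.DataFrame(rows).sort_values("trial_id").reset_index(drop=True)
    rep = (per_trial.groupby("participant_id")["valid"].sum()
           .rename("n_valid").reset_index())
    rep["included"] = rep["n_valid"] >= min_valid_trials
    return EyeTrialMetrics(per_trial, rep)


def median_split(
    metrics: pd.DataFrame,
    metric: str,
    min_per_half: int = 400,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-participant median split on a trial-wise eye metric.

    Returns (low, high) DataFrames; ties at the median go to the low half.
    Participants whose smaller half would hold fewer than ``min_per_half``
    valid trials are excluded (with a warning).
    """
    if metric not in metrics.columns:
        raise ValueError(f"unknown metric {metric!r}")
    valid = metrics[metrics["valid"] & metrics[metric].notna()]
    lows, highs = [], []
    for pid, sub in valid.groupby("participant_id"):
        med = sub[metric].median()
        low = sub[sub[metric] <= med]
        high = sub[sub[metric] > med]
        if len(high) == 0:
            warnings.warn(f"participant {pid}: all values tied at the median; "
                          "all trials in the low half", stacklevel=2)
        if min(len(low), len(high)) < min_per_half and len(high) > 0:
            warnings.warn(f"participant {pid} excluded from split "
                          f"({min(len(low), len(high))} < {min_per_half} trials per half)",
                          stacklevel=2)
            continue
        lows.append(low)
        highs.append(high)
    empty = valid.iloc[:0]
    return (pd.concat(lows) if lows else empty,
            pd.concat(highs) if highs else empty)


# ---------------------------------------------------------------------------
# condition contrasts


@dataclass
class ContrastResult:
    """Paired comparison of group vector strengths between two conditions."""

    freqs_hz: np.ndarray
    mean_diff: np.ndarray  # condition A minus condition B, per frequency
    t: np.ndarray
    p: np.ndarray
    p_bh: np.ndarray
    n_pairs: int
    prevalence: np.ndarray | None = None
    vs_a: np.ndarray | None = field(default=None, repr=False)  # (P, F)
    vs_b: np.ndarray | None = field(default=None, repr=False)


def _participant_vs(table: TrialTable, metric: str, freqs: np.ndarray,
                    grid: BinGrid) -> dict[str, np.ndarray]:
    """Binned-approach vector strength per participant (no permutations)."""
    binned = compute_binned_metrics(table, grid)
    centers = grid.centers_s
    out = {}
    col = {"dprime": "dprime", "bias": "bias", "rt": "mean_sqrt_rt"}[metric]
    for pid, by_ear in binned.items():
        series = getattr(by_ear["both"], col)
        ok = np.isfinite(series)
        if ok.sum() < 5:
            continue
        out[pid] = _gaussian_vs(centers[ok], series[ok][:, None], freqs)[:, 0]
    return out


def contrast_conditions(
    table_a: TrialTable,
    table_b: TrialTable,
    metric: str = "dprime",
    freqs: np.ndarray | None = None,
    grid: BinGrid = BinGrid(),
    n_boot: int = 0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ContrastResult:
    """Contrast rhythmicity between two paired trial sets.

    Per participant and condition, the binned-approach vector strength is
    computed at every grid frequency; conditions are compared with paired
    t-tests per frequency, BH-corrected across the grid. With ``n_boot > 0``
    the bootstrap prevalence of significant (BH-corrected) differences across
    participant resamples is added.
    """
    if freqs is None:
        freqs = frequency_grid("binned")
    vs_a = _participant_vs(table_a, metric, freqs, grid)
    vs_b = _participant_vs(table_b, metric, freqs, grid)
    shared = sorted(set(vs_a) & set(vs_b))
    dropped = set(vs_a) ^ set(vs_b)
    if dropped:
        warnings.warn(f"{len(dropped)} participants missing one condition; dropped",
                      stacklevel=2)
    if len(shared) < 2:
        raise ValueError("need at least 2 paired participants")
    A = np.array([vs_a[p] for p in shared])
    B = np.array([vs_b[p] for p in shared])

    def _tests(A: np.ndarray, B: np.ndarray):
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_rel(A, B, axis=0)
        p = np.where(np.isfinite(p), p, 1.0)
        return t, p, multipletests(p, alpha=alpha, method="fdr_bh")[1]

    t, p, p_bh = _tests(A, B)
    prevalence = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        flags = np.empty((n_boot, len(freqs)), dtype=bool)
        for b in range(n_boot):
            idx = rng.integers(0, len(shared), size=len(shared))
            _, _, pb = _tests(A[idx], B[idx])
            flags[b] = pb <= alpha
        prevalence = flags.mean(axis=0)
    return ContrastResult(np.asarray(freqs, float), (A - B).mean(axis=0), t, p,
                          p_bh, len(shared), prevalence, A, B)


# ---------------------------------------------------------------------------
# descriptive reports


def dual_task_summary(table: TrialTable) -> pd.DataFrame:
    """Overall d', bias and mean RT per participant and block type (dual task
    vs not), plus across-participant paired t-tests per metric."""
    rows = []
    for (pid, dual), sub in table.df.groupby(["participant_id", "dual_task"]):
        d, c = compute_sdt(sub["condition"].to_numpy(), sub["response"].to_numpy())
        rows.append(dict(participant_id=pid, dual_task=bool(dual), dprime=d,
                         bias=c, mean_rt_s=float(sub["rt_s"].mean())))
    per = pd.DataFrame(rows)
    out = []
    for col in ("dprime", "bias", "mean_rt_s"):
        wide = per.pivot(index="participant_id", columns="dual_task", values=col)
        if wide.shape[1] == 2 and len(wide.dropna()) >= 2:
            w = wide.dropna()
            t, p = stats.ttest_rel(w[True], w[False])
        else:
            t, p = np.nan, np.nan
        out.append(dict(metric=col,
                        mean_dual=per.loc[per.dual_task, col].mean(),
                        mean_single=per.loc[~per.dual_task, col].mean(),
                        t=float(t), p=float(p)))
    return pd.DataFrame(out)


def difficulty_drift(table: TrialTable) -> pd.DataFrame:
    """Start-to-end change of the stimulus level in decibels.

    Per participant, 20*log10(final/initial stimulus parameter) averaged over
    ear x condition tracks, with a one-sample t-test across participants.
    """
    rows = []
    for pid, sub in table.df.groupby("participant_id"):
        diffs = []
        for _, track in sub.groupby(["ear", "condition"]):
            s = track.sort_values(["block", "trial_index"])["stim_param"]
            if len(s) >= 2 and s.iloc[0] > 0 and s.iloc[-1] > 0:
                diffs.append(20.0 * np.log10(s.iloc[-1] / s.iloc[0]))
        if diffs:
            rows.append(dict(participant_id=pid, drift_db=float(np.mean(diffs))))
    per = pd.DataFrame(rows)
    if len(per) >= 2:
        t, p = stats.ttest_1samp(per["drift_db"], 0.0)
    else:
        t, p = np.nan, np.nan
    per.attrs["t"] = float(t)
    per.attrs["p"] = float(p)
    return per
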