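"""Delay-binned signal-detection metrics.

Trials are partitioned into 20 bins of 60 ms covering window-relative delays
0-1.2 s. Within each bin, sensitivity (d') and bias (criterion c) are computed
from the equal-variance Gaussian SDT model treating condition ``f1`` as the
signal class and response ``opt1`` as the signal response; extreme rates are
handled with the log-linear (Hautus) correction. Mean square-root reaction time
per bin is carried along as the third behavioural metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trial_data import TrialTable

__all__ = [
    "BinGrid",
    "BinnedMetrics",
    "assign_bins",
    "compute_sdt",
    "compute_binned_metrics",
    "binned_metrics_frame",
]

EAR_SETS = ("L", "R", "both")


@dataclass(frozen=True)
class BinGrid:
    """Equally spaced delay bins over the target-uncertainty window."""

    bin_width_s: float = 0.06
    window: tuple[float, float] = (0.0, 1.2)

    def __post_init__(self) -> None:
        n = (self.window[1] - self.window[0]) / self.bin_width_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window length must be an exact multiple of bin width")

    @property
    def n_bins(self) -> int:
        return round((self.window[1] - self.window[0]) / self.bin_width_s)

    @property
    def centers_s(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_s + self.window[0]

    @property
    def fs(self) -> float:
        """Sampling rate implied by the bin spacing (Hz)."""
        return 1.0 / self.bin_width_s


@dataclass
class BinnedMetrics:
    """Per participant x ear-set binned behavioural metrics.

    Vectors have one entry per bin; bins lacking a condition carry NaN.
    """

    participant_id: str
    ear_set: str
    grid: BinGrid
    dprime: np.ndarray
    bias: np.ndarray
    mean_sqrt_rt: np.ndarray
    n_per_bin: np.ndarray = field(repr=False)


def assign_bins(delay_ref_s: np.ndarray, grid: BinGrid = BinGrid()) -> np.ndarray:
    """Bin index per trial: half-open bins, right edge of the last bin closed."""
    d = np.asarray(delay_ref_s, dtype=float)
    lo, hi = grid.window
    if np.any((d < lo) | (d > hi)) or np.any(np.isnan(d)):
        raise ValueError(f"delays outside the bin window [{lo}, {hi}]")
    idx = np.floor((d - lo) / grid.bin_width_s).astype(int)
    return np.minimum(idx, grid.n_bins - 1)


def _loglinear_rates(n_sig: int, n_hit: int, n_noise: int, n_fa: int) -> tuple[float, float]:
    # add 0.5 to each cell, 1 to each denominator: defined for all counts
    h = (n_hit + 0.5) / (n_sig + 1.0)
    fa = (n_fa + 0.5) / (n_noise + 1.0)
    return h, fa


def compute_sdt(condition: np.ndarray, response: np.ndarray) -> tuple[float, float]:
    """d' and criterion c for one set of trials.

    Hits are ``opt1`` responses to ``f1`` (signal) trials, false alarms are
    ``opt1`` responses to ``f2`` (noise) trials:
    d' = z(H) - z(FA), c = -(z(H) + z(FA)) / 2. Returns (nan, nan) with a
    warning if either condition is absent.
    """
    condition = np.asarray(condition)
    response = np.asarray(response)
    sig = condition == "f1"
    n_sig = int(sig.sum())
    n_noise = int((~sig).sum())
    if n_sig == 0 or n_noise == 0:
        warnings.warn("bin lacks one condition; SDT metrics set to missing",
                      stacklevel=2)
        return np.nan, np.nan
    n_hit = int((sig & (response == "opt1")).sum())
    n_fa = int((~sig & (response == "opt1")).sum())
    h, fa = _loglinear_rates(n_sig, n_hit, n_noise, n_fa)
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    return float(zh - zfa), float(-(zh + zfa) / 2.0)


def compute_binned_metrics(
    table: TrialTable, grid: BinGrid = BinGrid()
) -> dict[str, dict[str, BinnedMetrics]]:
    """Binned d', bias and mean sqrt-RT per participant and ear set.

    The table must be filtered (``filter_outliers``), RT-transformed and
    delay-referenced. The ``both`` ear set pools left- and right-ear trials
    (it is not an average of the per-ear metrics).

    Returns ``{participant_id: {ear_set: BinnedMetrics}}``.
    """
    df = table.df
    for col in ("delay_ref_s", "rt_sqrt"):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} missing: run reference_delays/transform_rt first"
            )
    bins = assign_bins(df["delay_ref_s"].to_numpy(), grid)
    out: dict[str, dict[str, BinnedMetrics]] = {}
    for pid, pidx in df.groupby("participant_id", sort=False).indices.items():
        sub = df.iloc[pidx]
        sub_bins = bins[pidx]
        out[str(pid)] = {}
        for ear_set in EAR_SETS:
            mask = np.ones(len(sub), dtype=bool) if ear_set == "both" else (
                (sub["ear"] == ear_set).to_numpy()
            )
            out[str(pid)][ear_set] = _metrics_for(
                str(pid), ear_set, sub.loc[mask], sub_bins[mask], grid
            )
    return out


def _metrics_for(
    pid: str, ear_set: str, sub: pd.DataFrame, bins: np.ndarray, grid: BinGrid
) -> BinnedMetrics:
    nb = grid.n_bins
    dprime = np.full(nb, np.nan)
    bias = np.full(nb, np.nan)
    msr = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    cond = sub["condition"].to_numpy()
    resp = sub["response"].to_numpy()
    rts = sub["rt_sqrt"].to_numpy(dtype=float)
    for k in range(nb):
        m = bins == k
        n[k] = int(m.sum())
        if n[k] == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dprime[k], bias[k] = compute_sdt(cond[m], resp[m])
        if np.isnan(dprime[k]):
            warnings.warn(
                f"participant {pid}, ear_set {ear_set}, bin {k}: "
                "a condition is absent; SDT metrics missing", stacklevel=3
            )
        msr[k] = float(np.nanmean(rts[m])) if np.isfinite(rts[m]).any() else np.nan
    return BinnedMetrics(pid, ear_set, grid, dprime, bias, msr, n)


def binned_metrics_frame(
    metrics: dict[str, dict[str, BinnedMetrics]]
) -> pd.DataFrame:
    """Tidy long-format view (participant, ear_set, bin_center_s, metrics, n)."""
    rows = []
    for pid, by_ear in metrics.items():
        for ear_set, bm in by_ear.items():
            for k, c in enumerate(bm.grid.centers_s):
                rows.append(
                    dict(participant=pid, ear_set=ear_set, bin_center_s=c,
                         dprime=bm.dprime[k], bias=bm.bias[k],
                         mean_sqrt_rt=bm.mean_sqrt_rt[k], n=bm.n_per_bin[k])
                )
    return pd.DataFrame(rows)
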