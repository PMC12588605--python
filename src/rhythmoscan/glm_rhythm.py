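"""Vector-strength GLM scans for rhythmicity ("Binned" and "Trials" approaches).

The behavioural outcome (binned d'/bias/sqrt-RT, or single-trial correctness /
sqrt-RT) is modelled per participant as a linear combination of an offset, a
linear delay trend, a slow half-cycle u/v regressor at 0.5 Hz, and sine/cosine
regressors at one probe frequency. The rhythmic effect size is the vector
strength, (beta_sin^2 + beta_cos^2)/2: phase-free and quadratic in the
modulation amplitude. Significance per frequency comes from a permutation null
(delay <-> outcome assignment shuffled within participant, model refitted), with
the group statistic being the unweighted participant mean of vector strengths
and an add-one percentile p-value.

The permutation refits use hand-vectorised engines (a fixed 2-row projector for
the Gaussian family, a batched ridge-stabilised IRLS for the binomial family);
both are validated against statsmodels fits in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "UV_FREQ_HZ",
    "frequency_grid",
    "build_design",
    "RhythmDesign",
    "RhythmFit",
    "fit_rhythm_model",
    "NullDistribution",
    "permutation_null",
    "RhythmScanResult",
    "rhythm_scan",
    "RhythmScan",
]

UV_FREQ_HZ = 0.5
WINDOW_MID_S = 0.6
COLUMNS = ("intercept", "linear", "uv", "sin", "cos")


def frequency_grid(approach: str) -> np.ndarray:
    """Probe-frequency grid per approach.

    binned: 1.2-4.0 Hz step 0.1 plus 4.2-8.0 Hz step 0.2 (49 frequencies);
    trials: the binned grid extended by 8.8-12.0 Hz step 0.8 (54 frequencies).
    """
    low = np.round(np.arange(12, 41) * 0.1, 10)
    mid = np.round(np.arange(21, 41) * 0.2, 10)
    if approach == "binned":
        return np.concatenate([low, mid])
    if approach == "trials":
        high = np.round(np.arange(11, 16) * 0.8, 10)
        return np.concatenate([low, mid, high])
    raise ValueError(f"unknown approach {approach!r}")


@dataclass
class RhythmDesign:
    """Design matrix for one probe frequency."""

    times_s: np.ndarray
    freq_hz: float
    X: np.ndarray = field(repr=False)

    @property
    def columns(self) -> tuple[str, ...]:
        return COLUMNS


def _design_matrix(times: np.ndarray, freq_hz: float) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    w = 2 * np.pi * freq_hz * t
    return np.column_stack([
        np.ones_like(t),
        t,
        np.cos(2 * np.pi * UV_FREQ_HZ * (t - WINDOW_MID_S)),
        np.sin(w),
        np.cos(w),
    ])


def build_design(times_s: np.ndarray, freq_hz: float) -> RhythmDesign:
    """Unstandardised columns: intercept, t, u/v at 0.5 Hz, sin and cos at f.

    The u/v regressor is cos(2*pi*0.5*(t - 0.6)): a half cycle symmetric about
    the midpoint of the 1.2 s target-uncertainty window, capturing a slow
    rise-and-fall of performance that is not rhythmic.
    """
    times_s = np.asarray(times_s, dtype=float)
    return RhythmDesign(times_s, float(freq_hz), _design_matrix(times_s, freq_hz))


@dataclass
class RhythmFit:
    """Fitted rhythm model at one frequency."""

    freq_hz: float
    betas: np.ndarray  # (intercept, linear, uv, sin, cos)
    family: str
    converged: bool

    @property
    def beta_sin(self) -> float:
        return float(self.betas[3])

    @property
    def beta_cos(self) -> float:
        return float(self.betas[4])

    @property
    def vector_strength(self) -> float:
        return (self.beta_sin ** 2 + self.beta_cos ** 2) / 2.0


def fit_rhythm_model(
    outcome: np.ndarray, design: RhythmDesign, family: str = "gaussian"
) -> RhythmFit:
    """Maximum-likelihood fit of the 5-column rhythm model.

    Gaussian identity for continuous outcomes (binned metrics, sqrt-RT);
    binomial logit for single-trial correctness. A binomial fit that fails to
    converge (e.g. separation) falls back to a ridge-stabilised refit and is
    flagged ``converged=False``.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome length does not match design rows")
    if family == "gaussian":
        betas, *_ = np.linalg.lstsq(X, y, rcond=None)
        return RhythmFit(design.freq_hz, betas, family, True)
    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        # diverging linear predictors (fitted probabilities pinned at 0/1)
        # indicate separation even when the deviance stopped changing
        converged = bool(res.converged) and np.abs(X @ res.params).max() < 15.0
        if converged:
            return RhythmFit(design.freq_hz, np.asarray(res.params), family, True)
    except Exception:
        pass
    warnings.warn(
        f"binomial fit at {design.freq_hz} Hz did not converge; "
        "using ridge-stabilised fallback", stacklevel=2
    )
    B, _ = _irls_batch(X, y[:, None], ridge=1e-3)
    return RhythmFit(design.freq_hz, B[:, 0], family, False)


# ---------------------------------------------------------------------------
# batched engines


def _sc_projector(X: np.ndarray) -> np.ndarray:
    """Rows of the least-squares projector giving beta_sin and beta_cos (2, n)."""
    G = X.T @ X
    return np.linalg.solve(G, X.T)[3:5]


def _sc_rows(times: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Stacked sin/cos projector rows for all frequencies at once: (2F, n).

    Equivalent to vertically stacking :func:`_sc_projector` over the grid, but
    built from shared normal-equation blocks (the intercept/trend/uv columns do
    not depend on the probe frequency).
    """
    t = np.asarray(times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    n, F = t.size, freqs.size
    base = np.column_stack([
        np.ones_like(t), t,
        np.cos(2 * np.pi * UV_FREQ_HZ * (t - WINDOW_MID_S)),
    ])  # (n, 3)
    ang = 2 * np.pi * np.outer(t, freqs)
    S, C = np.sin(ang), np.cos(ang)  # (n, F)
    G = np.empty((F, 5, 5))
    G[:, :3, :3] = base.T @ base
    cs, cc = (base.T @ S).T, (base.T @ C).T  # (F, 3)
    G[:, :3, 3] = cs
    G[:, 3, :3] = cs
    G[:, :3, 4] = cc
    G[:, 4, :3] = cc
    G[:, 3, 3] = (S * S).sum(axis=0)
    G[:, 4, 4] = (C * C).sum(axis=0)
    sc = (S * C).sum(axis=0)
    G[:, 3, 4] = sc
    G[:, 4, 3] = sc
    rhs = np.zeros((5, 2))
    rhs[3, 0] = rhs[4, 1] = 1.0
    M = np.linalg.solve(G, np.broadcast_to(rhs, (F, 5, 2)))  # (F, 5, 2)
    Mt = M.transpose(0, 2, 1)  # (F, 2, 5)
    proj = Mt[:, :, :3] @ base.T  # (F, 2, n)
    proj += Mt[:, :, 3, None] * S.T[:, None, :]
    proj += Mt[:, :, 4, None] * C.T[:, None, :]
    return np.ascontiguousarray(proj.reshape(2 * F, n))


def _gaussian_vs(times: np.ndarray, Y: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Vector strength of Gaussian fits for every column of Y at every frequency.

    Y: (n, m) outcome columns (e.g. actual + permutations). Returns (F, m).
    """
    B = (_sc_rows(times, freqs) @ Y).reshape(len(freqs), 2, -1)
    return (B ** 2).sum(axis=1) / 2.0


def _irls_batch(
    X: np.ndarray,
    Y: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Newton/IRLS for logistic fits of many outcome columns at once.

    X: (n, k); Y: (n, m) in {0, 1}. A small ridge on the penalised likelihood
    keeps every refit finite under separation (permutation nulls must never
    abort). Returns (betas (k, m), converged (m,)).
    """
    n, k = X.shape
    m = Y.shape[1]
    ybar = np.clip(Y.mean(axis=0), 1e-9, 1 - 1e-9)
    B = np.zeros((k, m))
    B[0] = np.log(ybar / (1 - ybar))
    XX = np.einsum("ni,nj->ijn", X, X).reshape(k * k, n)
    eye = ridge * np.eye(k)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(X @ B, -30.0, 30.0)
        mu = expit(eta)
        G = X.T @ (Y - mu) - ridge * B  # (k, m)
        W = mu * (1.0 - mu) + 1e-10
        H = (XX @ W).reshape(k, k, m).transpose(2, 0, 1) + eye
        step = np.linalg.solve(H, G.T[:, :, None])[:, :, 0]  # (m, k)
        B += step.T
        converged = np.abs(step).max(axis=1) < tol
        if converged.all():
            break
    return B, converged


def _binomial_vs(times: np.ndarray, Y: np.ndarray, freqs: np.ndarray,
                 ridge: float = 1e-6) -> np.ndarray:
    """Vector strength of batched logistic fits. Y: (n, m); returns (F, m)."""
    out = np.empty((len(freqs), Y.shape[1]))
    for i, f in enumerate(freqs):
        B, conv = _irls_batch(_design_matrix(times, f), Y, ridge=ridge)
        if not conv.all():
            warnings.warn(
                f"{int((~conv).sum())} logistic refits at {f} Hz stopped at the "
                "iteration cap (ridge-stabilised values used)", stacklevel=2
            )
        out[i] = (B[3] ** 2 + B[4] ** 2) / 2.0
    return out


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(n, dtype=np.int32), (n_perm, 1)), axis=1)


# ---------------------------------------------------------------------------
# permutation nulls and scans


@dataclass
class NullDistribution:
    """Permutation null of the group-mean vector strength at one frequency."""

    freq_hz: float
    actual_vs: np.ndarray  # (P,)
    perm_vs: np.ndarray = field(repr=False)  # (P, n_perm)
    p: float = None
    group_actual: float = None
    group_perm: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.group_perm is None:
            self.group_perm = self.perm_vs.mean(axis=0)
        if self.group_actual is None:
            self.group_actual = float(self.actual_vs.mean())
        if self.p is None:
            n_perm = self.group_perm.shape[0]
            self.p = float(
                (1 + (self.group_perm >= self.group_actual).sum()) / (1 + n_perm)
            )


def _clean(times: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(times)
    return times[ok], y[ok]


def permutation_null(
    data: list[tuple[np.ndarray, np.ndarray]],
    freq_hz: float,
    n_perm: int = 10_000,
    family: str = "gaussian",
    seed: int | None = None,
) -> NullDistribution:
    """Permutation null at one frequency for a cohort.

    ``data`` is one (times, outcome) pair per participant; missing outcomes are
    dropped listwise. Within each participant the outcome is shuffled against
    the delays ``n_perm`` times and the model refitted.
    """
    res = rhythm_scan(data, freqs=np.array([freq_hz]), family=family,
                      n_perm=n_perm, seed=seed, keep_participant_perms=True)
    return NullDistribution(freq_hz, res.actual_vs[:, 0], res.perm_vs[:, 0, :],
                            p=res.p[0])


@dataclass
class RhythmScanResult:
    """Full-grid scan output."""

    approach: str
    family: str
    freqs_hz: np.ndarray
    actual_vs: np.ndarray  # (P, F)
    group_perm: np.ndarray = field(repr=False)  # (F, n_perm)
    p: np.ndarray = None
    perm_vs: np.ndarray | None = field(default=None, repr=False)  # (P, F, n_perm)

    def __post_init__(self) -> None:
        if self.p is None:
            group = self.actual_vs.mean(axis=0)
            n_perm = self.group_perm.shape[1]
            exceed = (self.group_perm >= group[:, None]).sum(axis=1)
            self.p = (1.0 + exceed) / (1.0 + n_perm)

    @property
    def group_vs(self) -> np.ndarray:
        return self.actual_vs.mean(axis=0)

    def to_frame(self, **labels: str) -> pd.DataFrame:
        df = pd.DataFrame({
            "approach": self.approach, "freq_hz": self.freqs_hz,
            "group_vs": self.group_vs, "p": self.p,
        })
        for k, v in labels.items():
            df[k] = v
        return df


def rhythm_scan(
    data: list[tuple[np.ndarray, np.ndarray]],
    freqs: np.ndarray | None = None,
    family: str = "gaussian",
    approach: str = "trials",
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    keep_participant_perms: bool = True,
    share_permutations: bool = False,
) -> RhythmScanResult:
    """Fit + permutation null at every grid frequency for a cohort.

    One permutation stream per participant (spawned from the master seed) is
    drawn once and reused across frequencies, so the scan's per-frequency
    p-values share their shuffles exactly as a single shuffle-then-refit pass
    would. ``share_permutations=True`` uses one index matrix for all
    participants (valid when participants are independent; used by the
    calibration fast path).
    """
    if freqs is None:
        freqs = frequency_grid(approach)
    freqs = np.asarray(freqs, dtype=float)
    cleaned = [_clean(t, y) for t, y in data]
    if any(len(np.unique(t)) < 2 for t, _ in cleaned):
        raise ValueError("each participant needs at least 2 distinct delays")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if share_permutations:
        shared_rng = np.random.default_rng(ss)
        streams = None
    else:
        streams = [np.random.default_rng(s) for s in ss.spawn(len(cleaned))]
    vs_fn = _gaussian_vs if family == "gaussian" else _binomial_vs
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")

    P = len(cleaned)
    actual = np.empty((P, len(freqs)))
    group_perm = np.zeros((len(freqs), n_perm))
    perms_kept = np.empty((P, len(freqs), n_perm)) if keep_participant_perms else None
    shared_idx: np.ndarray | None = None
    for i, (t, y) in enumerate(cleaned):
        if share_permutations:
            if shared_idx is None or shared_idx.shape[1] != len(y):
                shared_idx = _perm_indices(shared_rng, len(y), n_perm)
            idx = shared_idx
        else:
            idx = _perm_indices(streams[i], len(y), n_perm)
        Y = np.empty((len(y), n_perm + 1))
        Y[:, 0] = y
        Y[:, 1:] = y[idx].T
        vs = vs_fn(t, Y, freqs)  # (F, n_perm + 1)
        actual[i] = vs[:, 0]
        group_perm += vs[:, 1:]
        if perms_kept is not None:
            perms_kept[i] = vs[:, 1:]
    group_perm /= P
    return RhythmScanResult(approach, family, freqs, actual, group_perm,
                            perm_vs=perms_kept)


class RhythmScan(BaseEstimator):
    """Permutation vector-strength scan, sklearn-style.

    Parameters mirror :func:`rhythm_scan`; ``freqs=None`` uses the approach's
    standard grid. ``fit`` takes a list of (times, outcome) pairs, one per
    participant.

    Fitted attributes: ``freqs_hz_``, ``actual_vs_`` (P, F), ``group_vs_``,
    ``group_perm_``, ``p_``, ``perm_vs_`` (per-participant null matrices,
    needed by the bootstrap prevalence machinery).
    """

    def __init__(self, approach: str = "trials", family: str = "gaussian",
                 freqs: np.ndarray | None = None, n_perm: int = 10_000,
                 seed: int | None = None, keep_participant_perms: bool = True,
                 share_permutations: bool = False):
        self.approach = approach
        self.family = family
        self.freqs = freqs
        self.n_perm = n_perm
        self.seed = seed
        self.keep_participant_perms = keep_participant_perms
        self.share_permutations = share_permutations

    def fit(self, X: list[tuple[np.ndarray, np.ndarray]], y: None = None) -> "RhythmScan":
        res = rhythm_scan(
            X, freqs=self.freqs, family=self.family, approach=self.approach,
            n_perm=self.n_perm, seed=self.seed,
            keep_participant_perms=self.keep_participant_perms,
            share_permutations=self.share_permutations,
        )
        self.result_ = res
        self.freqs_hz_ = res.freqs_hz
        self.actual_vs_ = res.actual_vs
        self.group_vs_ = res.group_vs
        self.group_perm_ = res.group_perm
        self.perm_vs_ = res.perm_vs
        self.p_ = res.p
        return self
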