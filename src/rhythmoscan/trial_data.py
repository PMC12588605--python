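"""Canonical trial-table data model: strict CSV I/O, outlier filtering, RT transform.

One row per trial of a monaural target-in-noise discrimination task. The target
occurs at a random delay after background-noise onset (the 0.3-1.5 s uncertainty
window); downstream rhythmicity analyses operate on delays re-referenced to the
start of that window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "TrialTableError",
    "read_trial_table",
    "write_trial_table",
    "filter_outliers",
    "transform_rt",
    "reference_delays",
    "REQUIRED_COLUMNS",
    "DELAY_WINDOW_S",
    "RT_BOUNDS_S",
]

#: Column schema of a trial table. Readers are strict: every column must be
#: present under exactly this name; extra columns are carried through untouched.
REQUIRED_COLUMNS = (
    "participant_id",
    "experiment",
    "block",
    "trial_index",
    "ear",
    "condition",
    "delay_s",
    "response",
    "correct",
    "rt_s",
    "stim_param",
    "dual_task",
    "dot_change",
    "dot_response",
)

EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4")
EARS = ("L", "R")
CONDITIONS = ("f1", "f2")
#: Responses assigned to the auditory task; anything else (stray key presses,
#: encoded "none") is removed by :func:`filter_outliers`.
TASK_RESPONSES = ("opt1", "opt2")

#: Target-uncertainty window: delays relative to background-noise onset.
DELAY_WINDOW_S = (0.3, 1.5)
#: Reaction-time outlier bounds (very short / very long responses).
RT_BOUNDS_S = (0.15, 2.5)


class TrialTableError(ValueError):
    """Raised on schema or invariant violations in a trial table."""


@dataclass
class TrialTable:
    """An ordered collection of trials plus provenance metadata.

    The payload is a pandas DataFrame using the :data:`REQUIRED_COLUMNS` schema.
    """

    df: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise TrialTableError(f"missing column {missing[0]}")
        dup = self.df.duplicated(subset=["participant_id", "block", "trial_index"])
        if dup.any():
            raise TrialTableError(
                "duplicate (participant_id, block, trial_index) rows: "
                f"{int(dup.sum())} duplicates"
            )

    def __len__(self) -> int:
        return len(self.df)

    def copy_with(self, df: pd.DataFrame, **meta: Any) -> "TrialTable":
        md = dict(self.metadata)
        md.update(meta)
        return TrialTable(df=df, metadata=md)

    @property
    def participants(self) -> list[str]:
        return list(pd.unique(self.df["participant_id"]))


_DTYPES = {
    "participant_id": str,
    "experiment": str,
    "block": "int64",
    "trial_index": "int64",
    "ear": str,
    "condition": str,
    "delay_s": float,
    "response": str,
    "correct": "boolean",
    "rt_s": float,
    "stim_param": float,
    "dual_task": "boolean",
    "dot_change": "boolean",
    "dot_response": str,
}


def read_trial_table(path: str | Path) -> TrialTable:
    """Read a trial table from a strict comma-separated UTF-8 file.

    Raises :class:`TrialTableError` naming the first missing column; cell-level
    parse failures are reported with their (1-based, header-inclusive) line
    number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing column {missing[0]}")
    out = {}
    for col, dtype in _DTYPES.items():
        raw = df[col]
        if dtype is str:
            out[col] = raw
            continue
        vals = raw.replace("", np.nan)
        try:
            if dtype == "boolean":
                mapped = vals.map(
                    {"True": True, "False": False, "true": True, "false": False,
                     "1": True, "0": False, np.nan: pd.NA}
                )
                bad = mapped.isna() & vals.notna()
                if bad.any():
                    line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                    raise TrialTableError(
                        f"unparseable boolean in column {col!r} at line {line}"
                    )
                out[col] = mapped.astype("boolean")
            else:
                # Series.astype uses correctly-rounded float parsing
                # (pd.to_numeric's fast path is not bit-exact)
                out[col] = vals.astype(float).astype(dtype)
        except (ValueError, TypeError) as exc:
            if isinstance(exc, TrialTableError):
                raise
            bad_line = _first_bad_line(vals)
            raise TrialTableError(
                f"unparseable cell in column {col!r} at line {bad_line}: {exc}"
            ) from exc
    parsed = pd.DataFrame(out, index=df.index)
    for col in df.columns:  # carry extra columns through, numeric where possible
        if col not in parsed.columns:
            try:
                parsed[col] = df[col].replace("", np.nan).astype(float)
            except (ValueError, TypeError):
                parsed[col] = df[col]
    table = TrialTable(parsed, metadata={"path": str(path)})
    _report_invariants(table)
    return table


def _first_bad_line(vals: pd.Series) -> int:
    for i, v in enumerate(vals):
        if isinstance(v, str):
            try:
                float(v)
            except ValueError:
                return i + 2
    return -1


def _report_invariants(table: TrialTable) -> None:
    """Collect invariant violations and attach them to metadata (non-fatal)."""
    df = table.df
    problems: list[str] = []
    lo, hi = DELAY_WINDOW_S
    bad_delay = ~df["delay_s"].between(lo, hi)
    if bad_delay.any():
        problems.append(f"{int(bad_delay.sum())} trials with delay_s outside "
                        f"[{lo}, {hi}]")
    neg_rt = df["rt_s"].dropna() < 0
    if neg_rt.any():
        problems.append(f"{int(neg_rt.sum())} trials with negative rt_s")
    if problems:
        warnings.warn("; ".join(problems), stacklevel=3)
        table.metadata["invariant_violations"] = problems


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    """Write the table back as comma-separated UTF-8 text ('.' decimal).

    Floats use the shortest representation that round-trips bit-for-bit.
    """
    table.df.to_csv(path, index=False, encoding="utf-8",
                    float_format=lambda v: repr(float(v)))


def filter_outliers(
    table: TrialTable,
    min_rt_s: float = RT_BOUNDS_S[0],
    max_rt_s: float = RT_BOUNDS_S[1],
) -> TrialTable:
    """Remove outlier trials; the single filtering entry point.

    Removes, in this order of attribution: trials whose response is not one of
    the task-assigned keys (including no response), then trials with
    ``rt_s < min_rt_s`` ("too fast") or ``rt_s > max_rt_s`` ("too slow").
    Per-reason removal counts are stored in ``metadata['filter_counts']``.
    Idempotent. An empty result triggers a warning, not an error.
    """
    df = table.df
    assigned = df["response"].isin(TASK_RESPONSES)
    rt = df["rt_s"]
    too_fast = assigned & (rt < min_rt_s)
    too_slow = assigned & (rt > max_rt_s)
    keep = assigned & ~too_fast & ~too_slow & rt.notna()
    counts = {
        "unassigned_response": int((~assigned).sum()),
        "rt_too_fast": int(too_fast.sum()),
        "rt_too_slow": int(too_slow.sum()),
        "rt_missing": int((assigned & rt.isna()).sum()),
        "retained": int(keep.sum()),
    }
    if counts["retained"] == 0:
        warnings.warn("filter_outliers retained no trials", stacklevel=2)
    return table.copy_with(df.loc[keep].copy(), filter_counts=counts)


def transform_rt(table: TrialTable) -> TrialTable:
    """Add ``rt_sqrt = sqrt(rt_s)``; the raw reaction time is kept.

    The square-root transform symmetrises the right-skewed RT distribution so
    Gaussian-family models of the transformed values are reasonable.
    """
    rt = table.df["rt_s"]
    if (rt.dropna() < 0).any():
        raise TrialTableError("negative rt_s; cannot take square root")
    df = table.df.copy()
    df["rt_sqrt"] = np.sqrt(rt)
    return table.copy_with(df)


def reference_delays(
    table: TrialTable, window_start_s: float = DELAY_WINDOW_S[0]
) -> TrialTable:
    """Add ``delay_ref_s = delay_s - window_start_s`` in [0, 1.2].

    Re-references target delays from background-noise onset to the start of the
    target-uncertainty window, the time axis all rhythmicity analyses use.
    """
    window_len = DELAY_WINDOW_S[1] - DELAY_WINDOW_S[0]
    d = table.df["delay_s"]
    bad = ~d.between(window_start_s, window_start_s + window_len)
    if bad.any():
        rows = list(table.df.index[bad][:20])
        raise TrialTableError(
            f"{int(bad.sum())} trials with delay_s outside "
            f"[{window_start_s}, {window_start_s + window_len}]; rows {rows}"
        )
    df = table.df.copy()
    df["delay_ref_s"] = d - window_start_s
    return table.copy_with(df)
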