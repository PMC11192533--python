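"""Delimited-text table I/O.

All tables are UTF-8 CSV with a header row; durations are serialized in
milliseconds with at most 3 decimal places, proportions unitless. Tap
tables are accepted in two dialects: *long* (one row per tap interval,
with a ``tap_index`` column) or *packed* (one row per trial with a
semicolon-joined ``itis`` list); both parse to the same in-memory form.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import SessionPlan, TrialSpec

__all__ = [
    "TableFormatError",
    "write_plan",
    "read_plan",
    "write_trial_table",
    "read_trial_table",
    "write_tap_table",
    "read_tap_table",
]

PLAN_COLUMNS = ["participant_id", "task", "session_type", "block",
                "trial_index", "is_boundary_repeat", "ioi_ms", "dev", "seed"]

DISC_REQUIRED = {"trial_index", "ioi_ms", "dev", "response"}


class TableFormatError(ValueError):
    """A table file violates the documented schema."""


def _round_ms(x):
    return np.round(np.asarray(x, float), 3)


def write_plan(plan: SessionPlan, path, participant_id: str = "P001") -> None:
    """Serialize a session plan to CSV (one row per planned trial)."""
    rows = [
        {
            "participant_id": participant_id,
            "task": t.task,
            "session_type": plan.session_type,
            "block": t.block,
            "trial_index": t.trial_index,
            "is_boundary_repeat": t.is_boundary_repeat,
            "ioi_ms": round(t.ioi_ms, 3),
            "dev": "" if t.dev is None else t.dev,
            "seed": "" if plan.seed is None else plan.seed,
        }
        for t in plan.trials
    ]
    pd.DataFrame(rows, columns=PLAN_COLUMNS).to_csv(path, index=False)


def read_plan(path) -> SessionPlan:
    """Read a session plan CSV back into a :class:`SessionPlan`."""
    df = pd.read_csv(path)
    missing = set(PLAN_COLUMNS) - {"seed"} - set(df.columns)
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    trials = [
        TrialSpec(
            int(r.trial_index), int(r.block), float(r.ioi_ms),
            None if pd.isna(r.dev) else float(r.dev),
            bool(r.is_boundary_repeat), str(r.task),
        )
        for r in df.itertuples()
    ]
    seed = None
    if "seed" in df.columns and df["seed"].notna().any():
        seed = int(df["seed"].dropna().iloc[0])
    return SessionPlan(str(df["session_type"].iloc[0]), trials, seed=seed)


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a discrimination trial table (CSV)."""
    out = df.copy()
    for col in ("ioi_ms", "delta_ioi_ms", "abs_delta"):
        if col in out.columns:
            out[col] = _round_ms(out[col])
    out.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read a discrimination trial table, validating required columns."""
    df = pd.read_csv(path)
    missing = DISC_REQUIRED - set(df.columns)
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    bad = df[~df["response"].isin(["shorter", "longer"])]
    if len(bad):
        lines = (bad.index + 2).tolist()[:5]
        raise TableFormatError(
            f"{path}: invalid response value(s) at line(s) {lines}"
        )
    if "accuracy" not in df.columns:
        df["accuracy"] = ((df["dev"] > 0) == (df["response"] == "longer")).astype(int)
    if "bias" not in df.columns:
        df["bias"] = np.where(df["accuracy"] == 1, 0,
                              np.where(df["dev"] > 0, -1, 1))
    return df


def write_tap_table(df: pd.DataFrame, path, dialect: str = "packed") -> None:
    """Write a tap table; ``dialect`` is ``"packed"`` or ``"long"``."""
    if dialect == "packed":
        out = df.drop(columns=["itis"]).copy()
        out["itis"] = [
            ";".join(f"{v:.3f}" for v in np.asarray(itis, float))
            for itis in df["itis"]
        ]
        out.to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        for r in df.itertuples():
            for k, iti in enumerate(np.asarray(r.itis, float)):
                rows.append({"trial_index": r.trial_index,
                             "ioi_ms": round(float(r.ioi_ms), 3)
                             if pd.notna(r.ioi_ms) else "",
                             "tap_index": k + 1, "iti_ms": round(iti, 3)})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_tap_table(path) -> pd.DataFrame:
    """Read a tap table in either dialect into trial rows with ITI arrays."""
    df = pd.read_csv(path)
    if "itis" in df.columns:  # packed
        df = df.copy()
        df["itis"] = [
            np.array([float(v) for v in str(s).split(";") if v != ""])
            for s in df["itis"]
        ]
        return df
    if {"trial_index", "tap_index", "iti_ms"} <= set(df.columns):  # long
        rows = []
        for trial, sub in df.groupby("trial_index", sort=True):
            sub = sub.sort_values("tap_index")
            ioi = sub["ioi_ms"].iloc[0] if "ioi_ms" in sub.columns else np.nan
            rows.append({"trial_index": trial, "ioi_ms": ioi,
                         "itis": sub["iti_ms"].to_numpy(float)})
        return pd.DataFrame(rows)
    raise TableFormatError(
        f"{path}: not a recognized tap table (need 'itis' or "
        f"'trial_index/tap_index/iti_ms' columns)"
    )
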