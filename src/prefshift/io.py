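"""Canonical file formats.

The interchange format for behavioural data is a flat CSV trial table
(RFC 4180, UTF-8, '.' decimal), one row per trial, with the exact header::

    participant_id,age,gender,phase,trial_index,role,R0,RD,D_days,choice,
    other_choice,feedback,k_o_true

Missing values are empty fields.  A leading ``#`` comment line records the
generating seed for simulated tables.  Fit results are serialized one row
per participant x model.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import ParticipantDataset, Trial
from .inference import FitResult
from .models import OptionPair

__all__ = [
    "TRIAL_COLUMNS",
    "TrialTableError",
    "write_trial_table",
    "read_trial_table",
    "write_fits",
    "read_fits",
]

TRIAL_COLUMNS = [
    "participant_id", "age", "gender", "phase", "trial_index", "role",
    "R0", "RD", "D_days", "choice", "other_choice", "feedback", "k_o_true",
]


class TrialTableError(ValueError):
    """Schema violation in a trial table, with offending rows listed."""


def _dataset_rows(ds: ParticipantDataset) -> list[dict]:
    k_o = (ds.truth or {}).get("k_o")
    rows = []
    for t in ds.trials:
        rows.append(
            {
                "participant_id": ds.participant_id,
                "age": ds.age,
                "gender": ds.gender,
                "phase": t.phase,
                "trial_index": t.index,
                "role": t.role,
                "R0": t.pair.R0,
                "RD": t.pair.RD,
                "D_days": t.pair.D,
                "choice": t.choice,
                "other_choice": t.other_choice,
                "feedback": t.feedback,
                "k_o_true": k_o,
            }
        )
    return rows


def write_trial_table(
    datasets: Sequence[ParticipantDataset], path, seed: Optional[int] = None
) -> None:
    """Write datasets to the canonical CSV trial table."""
    rows = [r for ds in datasets for r in _dataset_rows(ds)]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as f:
        f.write(f"# prefshift trial table v1 seed={seed}\n")
        df.to_csv(f, index=False)


def read_trial_table(path) -> list[ParticipantDataset]:
    """Read and validate a canonical trial table, grouped by participant.

    Raises :class:`TrialTableError` naming offending columns/rows on any
    schema violation.
    """
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if missing or extra:
        raise TrialTableError(
            f"bad header: missing columns {missing}, unexpected columns {extra}"
        )
    errors: list[str] = []

    def bad(i: int, msg: str) -> None:
        errors.append(f"row {i + 3}: {msg}")  # +3: comment line, header, 1-based

    datasets: dict[str, ParticipantDataset] = {}
    for i, row in df.iterrows():
        pid = row["participant_id"]
        if pd.isna(pid):
            bad(i, "missing participant_id")
            continue
        phase = row["phase"]
        role = row["role"]
        choice = row["choice"]
        if phase not in (1, 2, 3):
            bad(i, f"phase must be 1/2/3, got {phase!r}")
            continue
        if role not in ("self", "other"):
            bad(i, f"role must be self/other, got {role!r}")
            continue
        if choice not in (0, 1):
            bad(i, f"choice must be 0/1, got {choice!r}")
            continue
        if phase == 1 and role != "self":
            bad(i, "phase-1 rows must have role=self")
            continue
        if phase == 1 and not pd.isna(row["feedback"]):
            bad(i, "phase-1 rows must not carry feedback")
            continue
        if phase == 2 and role != "other":
            bad(i, "phase-2 rows must have role=other")
            continue
        if role == "other" and (
            pd.isna(row["feedback"]) or pd.isna(row["other_choice"])
        ):
            bad(i, "other-role rows need feedback and other_choice")
            continue
        try:
            pair = OptionPair(
                R0=float(row["R0"]), RD=float(row["RD"]), D=float(row["D_days"])
            )
        except (ValueError, TypeError) as e:
            bad(i, f"bad option pair: {e}")
            continue
        if pid not in datasets:
            datasets[pid] = ParticipantDataset(
                participant_id=pid,
                age=None if pd.isna(row["age"]) else float(row["age"]),
                gender=None if pd.isna(row["gender"]) else str(row["gender"]),
                truth=(
                    None
                    if pd.isna(row["k_o_true"])
                    else {"k_o": float(row["k_o_true"])}
                ),
            )
        datasets[pid].trials.append(
            Trial(
                phase=int(phase),
                index=int(row["trial_index"]),
                role=str(role),
                pair=pair,
                choice=int(choice),
                other_choice=(
                    None if pd.isna(row["other_choice"]) else int(row["other_choice"])
                ),
                feedback=None if pd.isna(row["feedback"]) else str(row["feedback"]),
            )
        )
    if errors:
        shown = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise TrialTableError(f"trial table schema violations:\n{shown}{more}")
    out = list(datasets.values())
    for ds in out:
        ds.trials.sort(key=lambda t: t.index)
        ds.validate()
    return out


# ---------------------------------------------------------------------------
# Fit serialization
# ---------------------------------------------------------------------------

def write_fits(fits: Sequence[FitResult], path, seed: Optional[int] = None) -> None:
    """One CSV row per participant x model, natural-scale parameters."""
    rows = []
    for f in fits:
        row = {
            "participant_id": f.participant_id,
            "model": f.model,
            "loglik": f.loglik,
            "n_trials": f.n_trials,
            "n_params": f.n_params,
            "bic": f.bic,
            "converged": f.converged,
            "boundary": f.boundary,
            "method": f.method,
        }
        for k, v in f.params.items():
            row[f"param_{k}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as f_:
        f_.write(f"# prefshift fits v1 seed={seed}\n")
        df.to_csv(f_, index=False)


def read_fits(path) -> pd.DataFrame:
    """Fit table as a DataFrame (parameter columns prefixed ``param_``)."""
    return pd.read_csv(path, comment="#", dtype={"participant_id": str})
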