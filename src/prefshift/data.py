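"""In-memory containers for task data.

A participant's run through the delegated interpersonal discounting task is a
flat sequence of trials across three phases:

* phase 1 — 60 self-choices (30 standard + 30 adaptively selected pairs);
* phase 2 — choices made *on behalf of* a partner ("Other"), with veridical
  feedback revealing the Other's actual choice, until a learning criterion or
  a trial cap is reached;
* phase 3 — interleaved mini-blocks of self-choices and other-choices.

Choices are coded 1 = delayed option, 0 = immediate option, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

from .models import OptionPair

__all__ = ["Trial", "ParticipantDataset"]

ROLE_SELF = "self"
ROLE_OTHER = "other"


@dataclass
class Trial:
    """One row of the canonical trial table.

    ``choice`` is always the participant's response (their own choice on
    self-trials, their guess about the Other on other-trials).
    ``other_choice`` is the Other's actual choice, revealed through feedback;
    it is ``None`` on self-trials.
    """

    phase: int
    index: int
    role: str
    pair: OptionPair
    choice: int
    other_choice: Optional[int] = None
    feedback: Optional[str] = None  # "correct" | "incorrect" | None

    def __post_init__(self) -> None:
        if self.phase not in (1, 2, 3):
            raise ValueError(f"phase must be 1, 2 or 3, got {self.phase}")
        if self.role not in (ROLE_SELF, ROLE_OTHER):
            raise ValueError(f"role must be 'self' or 'other', got {self.role!r}")
        if self.choice not in (0, 1):
            raise ValueError(f"choice must be 0 or 1, got {self.choice}")


@dataclass
class ParticipantDataset:
    """All trials for one participant, plus generating ground truth when synthetic."""

    participant_id: str
    trials: list[Trial] = field(default_factory=list)
    age: Optional[float] = None
    gender: Optional[str] = None
    truth: Optional[dict[str, Any]] = None

    def validate(self) -> None:
        """Check protocol invariants; raise ``ValueError`` on violation."""
        for t in self.trials:
            if t.phase == 1 and (t.role != ROLE_SELF or t.feedback is not None):
                raise ValueError(
                    f"{self.participant_id}: phase-1 trial {t.index} must be a "
                    "self trial without feedback"
                )
            if t.phase == 2 and t.role != ROLE_OTHER:
                raise ValueError(
                    f"{self.participant_id}: phase-2 trial {t.index} must have role=other"
                )
            if t.role == ROLE_OTHER and t.phase == 2 and (
                t.feedback is None or t.other_choice is None
            ):
                raise ValueError(
                    f"{self.participant_id}: phase-2 trial {t.index} lacks feedback"
                )

    # -- convenience views ---------------------------------------------------

    def self_trials(self, phase: Optional[int] = None) -> list[Trial]:
        return [
            t
            for t in self.trials
            if t.role == ROLE_SELF and (phase is None or t.phase == phase)
        ]

    def other_trials(self, phase: Optional[int] = None) -> list[Trial]:
        return [
            t
            for t in self.trials
            if t.role == ROLE_OTHER and (phase is None or t.phase == phase)
        ]

    @property
    def n_trials(self) -> int:
        return len(self.trials)
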