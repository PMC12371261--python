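"""Study design description for the longitudinal fiber-intervention layout.

The trial layout modelled throughout the package: daily stool sampling over
28 days, a habitual-diet run-in (days 0-13), a low-dose fiber phase
(days 14-20) and a high-dose phase (days 21-27), with continuous glucose
monitoring at a 15-minute cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NORMAL = "normal"
LOW = "low"
HIGH = "high"

PHASES = (NORMAL, LOW, HIGH)


def default_phase_of_day() -> dict[int, str]:
    phases = {}
    for d in range(28):
        if d <= 13:
            phases[d] = NORMAL
        elif d <= 20:
            phases[d] = LOW
        else:
            phases[d] = HIGH
    return phases


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of a two-group, 28-day dietary-fiber trial.

    Parameters
    ----------
    groups:
        Labels of the participant groups (default: overweight with and
        without type 2 diabetes).
    participants_per_group:
        Number of participants in each group.
    days:
        Ordered fecal-sampling day indices.
    phase_of_day:
        Map from day index to dietary phase (``normal``/``low``/``high``).
    cgm_cadence_minutes:
        Continuous-glucose-monitoring sampling interval; must divide 1440.
    """

    groups: tuple[str, ...] = ("overweight", "t2d")
    participants_per_group: int = 10
    days: tuple[int, ...] = tuple(range(28))
    phase_of_day: dict[int, str] = field(default_factory=default_phase_of_day)
    cgm_cadence_minutes: int = 15

    def __post_init__(self) -> None:
        if self.participants_per_group <= 0:
            raise ValueError("participants_per_group must be positive")
        if 1440 % self.cgm_cadence_minutes != 0:
            raise ValueError("cgm_cadence_minutes must divide 1440")
        if set(self.days) != set(self.phase_of_day):
            raise ValueError("phase_of_day must cover exactly the design days")
        bad = set(self.phase_of_day.values()) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phases: {sorted(bad)}")

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def readings_per_day(self) -> int:
        return 1440 // self.cgm_cadence_minutes

    def participants(self, group: str) -> list[str]:
        """Participant ids for one group, e.g. ``overweight01``."""
        if group not in self.groups:
            raise ValueError(f"unknown group {group!r}")
        return [f"{group}{i + 1:02d}" for i in range(self.participants_per_group)]

    def all_participants(self) -> list[str]:
        return [p for g in self.groups for p in self.participants(g)]

    def group_of(self, participant: str) -> str:
        for g in self.groups:
            if participant.startswith(g):
                return g
        raise ValueError(f"cannot infer group of {participant!r}")

    def days_in_phase(self, phase: str) -> list[int]:
        return [d for d in self.days if self.phase_of_day[d] == phase]

    @property
    def intervention_days(self) -> list[int]:
        return [d for d in self.days if self.phase_of_day[d] != NORMAL]
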