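"""Health states of the five-state PAH progression model.

The model follows the WHO/NYHA functional classification: four ordered
living classes (FC I mildest to FC IV most severe) plus an absorbing
death state. Within one cycle a patient can only move to an adjacent
functional class, die, or stay put.
"""

from __future__ import annotations

from enum import IntEnum


class FunctionalClass(IntEnum):
    """Ordered model states; DEATH is absorbing and not a functional class."""

    FC1 = 0
    FC2 = 1
    FC3 = 2
    FC4 = 3
    DEATH = 4

    @property
    def is_living(self) -> bool:
        return self is not FunctionalClass.DEATH

    @property
    def key(self) -> str:
        """Lower-case config key ('fc1'..'fc4', 'death')."""
        return self.name.lower()


#: The four living states in severity order.
LIVING_STATES: tuple[FunctionalClass, ...] = (
    FunctionalClass.FC1,
    FunctionalClass.FC2,
    FunctionalClass.FC3,
    FunctionalClass.FC4,
)

#: State labels in matrix order.
STATE_LABELS: tuple[str, ...] = ("FC1", "FC2", "FC3", "FC4", "DEATH")

N_STATES: int = 5
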