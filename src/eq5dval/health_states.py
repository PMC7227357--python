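"""EQ-5D-3L health states: representation, enumeration, dominance, the 18-state
orthogonal design, and the value-set sample-size formula.

The EQ-5D-3L descriptive system scores five dimensions — mobility, self-care,
usual activities, pain/discomfort, anxiety/depression — at three levels each
(1 = no problems, 2 = moderate, 3 = severe), so a state is a 5-digit label such
as ``"31122"`` and the system spans 3**5 = 243 distinct states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterator

from scipy.stats import norm

__all__ = [
    "DIMENSIONS",
    "N_STATES",
    "HealthState",
    "DesignSet",
    "SampleSizeParams",
    "parse_state",
    "enumerate_all_states",
    "dominates",
    "design_states",
    "DESIGN_LABELS",
    "required_sample_size",
]

#: Fixed dimension order used by the 5-digit labels.
DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

#: Total number of EQ-5D-3L states (3 levels on 5 dimensions).
N_STATES = 3 ** 5


class InvalidStateLabel(ValueError):
    """Raised for labels that are not five digits in 1..3."""


@dataclass(frozen=True, order=True)
class HealthState:
    """One EQ-5D-3L profile: five ordinal levels, each 1, 2 or 3.

    Instances are immutable, hashable, and totally ordered by their label
    (lexicographic order), which is the canonical deterministic ordering
    throughout the package.
    """

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for pos, dim in enumerate(DIMENSIONS):
            lev = getattr(self, dim)
            if not isinstance(lev, int) or lev not in (1, 2, 3):
                raise InvalidStateLabel(
                    f"level for {dim} (position {pos + 1}) must be 1, 2 or 3; got {lev!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @property
    def label(self) -> str:
        """The canonical 5-digit text label, e.g. ``"31122"``."""
        return "".join(str(v) for v in self.levels)

    @classmethod
    def from_label(cls, label: str) -> "HealthState":
        return parse_state(label)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


#: The state of full health, the anchor valued exactly 1.
FULL_HEALTH_LABEL = "11111"
#: The worst describable state.
WORST_LABEL = "33333"


def parse_state(label: str) -> HealthState:
    """Parse a 5-digit label into a :class:`HealthState`.

    Raises :class:`InvalidStateLabel` naming the offending position when the
    label has the wrong length, a non-digit, or a digit outside 1..3.
    """
    if not isinstance(label, str) or len(label) != 5:
        raise InvalidStateLabel(f"state label must be exactly 5 characters, got {label!r}")
    levels = []
    for pos, ch in enumerate(label, start=1):
        if ch not in "123":
            raise InvalidStateLabel(
                f"invalid character {ch!r} at position {pos} of state label {label!r}; "
                "each digit must be 1, 2 or 3"
            )
        levels.append(int(ch))
    return HealthState(*levels)


@lru_cache(maxsize=1)
def enumerate_all_states() -> tuple[HealthState, ...]:
    """All 243 states in lexicographic label order (11111 first, 33333 last)."""
    return tuple(HealthState(*lv) for lv in product((1, 2, 3), repeat=5))


def dominates(a: HealthState, b: HealthState) -> bool:
    """True iff ``a`` is at least as good as ``b`` on every dimension and
    strictly better on at least one (lower level = better).

    This is the strict partial order behind logical-consistency checks: a
    tariff that values a dominated state above its dominator contains a
    logical error.
    """
    la, lb = a.levels, b.levels
    return all(x <= y for x, y in zip(la, lb)) and la != lb


# ---------------------------------------------------------------------------
# The 18-state valuation design
# ---------------------------------------------------------------------------

#: The 18 states valued in the study, in protocol order. Produced by an
#: L18(2x3^7) orthogonal array: each level of every dimension occurs exactly
#: six times. 11111 (the anchor) and 33333 are both included.
DESIGN_LABELS = (
    "11111", "31122", "22113", "13212", "12321", "21231",
    "22222", "23311", "11332", "32131", "31213", "13123",
    "12233", "33221", "21323", "23132", "32312", "33333",
)

#: Historical variant with 21113 in place of 22113 (breaks the 6/6/6 balance
#: of the self-care column; kept only as a legacy toggle).
_LEGACY_DESIGN_LABELS = tuple(
    "21113" if lab == "22113" else lab for lab in DESIGN_LABELS
)


@dataclass(frozen=True)
class DesignSet:
    """The ordered 18-state design with its anchor convention.

    The first state is full health (11111), fixed at utility 1 exactly; it is
    kept in the design (and in model fitting) rather than dropped.
    """

    states: tuple[HealthState, ...]
    anchor_value: float = 1.0

    def __post_init__(self) -> None:
        if len(self.states) != 18 or len(set(self.states)) != 18:
            raise ValueError("a DesignSet holds exactly 18 distinct states")
        if self.states[0].label != FULL_HEALTH_LABEL:
            raise ValueError("the first design state must be the 11111 anchor")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def __iter__(self) -> Iterator[HealthState]:
        return iter(self.states)

    def __len__(self) -> int:
        return 18


def design_states(legacy_table1: bool = False) -> DesignSet:
    """The canonical 18-state design fixture.

    ``legacy_table1=True`` swaps state 3 to the 21113 variant that appeared in
    some renderings of the design table; the canonical 22113 is the label that
    keeps every column balanced 6/6/6 and is used everywhere else.
    """
    labels = _LEGACY_DESIGN_LABELS if legacy_table1 else DESIGN_LABELS
    return DesignSet(states=tuple(parse_state(lab) for lab in labels))


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs to the value-set sample-size formula n = z^2 * sigma^2 / delta^2.

    alpha : two-sided significance level (0 < alpha < 1)
    delta : tolerated margin of error on a state's mean utility (> 0)
    sigma : anticipated standard deviation of utilities (> 0)
    """

    alpha: float
    delta: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.delta <= 0.0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def required_sample_size(
    alpha: float = 0.05, delta: float = 0.05, sigma: float = 0.4
) -> int:
    """Smallest n with the half-width of the (1-alpha) CI of a mean <= delta.

    n = ceil(z_{1-alpha/2}^2 * sigma^2 / delta^2). With the defaults
    (alpha=0.05, delta=0.05, sigma=0.4) this is ceil(245.85) = 246. The ceiling
    is used because sample sizes are integer counts and rounding down would
    miss the precision target.
    """
    p = SampleSizeParams(alpha=alpha, delta=delta, sigma=sigma)
    z = norm.ppf(1.0 - p.alpha / 2.0)
    n = (z * p.sigma / p.delta) ** 2
    return math.ceil(n)
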