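"""The abridged age partition used throughout the pipeline.

The standard US abridged grid has 19 intervals: [0,1), [1,5), then 5-year
intervals up to [80,85), and an open-ended 85+ group.  Ages are in years.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["AgeGrid", "DEFAULT_GRID", "AGE_GROUP_LABELS"]


@dataclass(frozen=True)
class AgeGrid:
    """Ordered, contiguous age intervals starting at 0, last one open-ended.

    ``starts`` are the exact ages opening each interval; the final interval
    has no upper bound.
    """

    starts: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=float)
        if s.size < 2:
            raise DomainError("an age grid needs at least two intervals")
        if s[0] != 0.0:
            raise DomainError("age grid must start at exact age 0")
        if not np.all(np.diff(s) > 0):
            raise DomainError("age-grid starts must be strictly increasing")

    @classmethod
    def abridged_us(cls) -> "AgeGrid":
        """[0,1), [1,5), [5,10), ..., [80,85), [85,+inf): 19 intervals."""
        return cls(starts=(0.0, 1.0) + tuple(float(a) for a in range(5, 90, 5)))

    @property
    def n_intervals(self) -> int:
        return len(self.starts)

    @property
    def start_array(self) -> np.ndarray:
        return np.asarray(self.starts, dtype=float)

    @property
    def widths(self) -> np.ndarray:
        """Interval widths in years; the open interval's width is +inf."""
        s = self.start_array
        return np.append(np.diff(s), np.inf)

    @property
    def open_start(self) -> float:
        return self.starts[-1]

    @property
    def labels(self) -> tuple[str, ...]:
        out: list[str] = []
        s = self.start_array
        w = self.widths
        for i in range(self.n_intervals):
            if i == self.n_intervals - 1:
                out.append(f"{s[i]:g}+")
            elif w[i] == 1:
                out.append(f"{s[i]:g}")
            else:
                out.append(f"{s[i]:g}-{s[i] + w[i] - 1:g}")
        return tuple(out)

    def index_of(self, age: float) -> int:
        """Index of the interval opening at exact ``age``.

        Only interval start ages are addressable (no interpolation).
        """
        s = self.start_array
        hit = np.nonzero(s == float(age))[0]
        if hit.size == 0:
            raise DomainError(
                f"age {age} is not an interval start of this grid; "
                f"valid starts are {self.starts}"
            )
        return int(hit[0])


DEFAULT_GRID = AgeGrid.abridged_us()

#: Fixed vocabulary for the ``age_group`` column of counts files.
AGE_GROUP_LABELS: tuple[str, ...] = DEFAULT_GRID.labels
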