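"""Containers for multiregion annual rate panels.

A :class:`ComponentSeries` is one region/cause time series together with
its failure threshold (the rate level, in % of population per year, past
which that component is regarded as failed).  A :class:`Panel` is an
ordered collection of such components — the multidegree-of-freedom (MDOF)
system whose joint reliability the rest of the package analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = ["ComponentSeries", "Panel"]


@dataclass(frozen=True)
class ComponentSeries:
    """One region/cause annual rate series with its failure threshold.

    Parameters
    ----------
    component_id
        Text label, e.g. a country name or ``"country|cause"``.
    times
        Strictly increasing integer years.  Gaps are allowed: the
        estimator uses only the ordering of local maxima, not the spacing.
    values
        Nonnegative rates, in % of population per year.
    threshold
        Positive failure limit ``eta`` in the same units.
    """

    component_id: str
    times: np.ndarray
    values: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "threshold", float(self.threshold))
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValueError(
                f"component {self.component_id!r}: times ({times.size}) and "
                f"values ({values.size}) differ in length"
            )
        if times.size == 0:
            raise ValueError(f"component {self.component_id!r} is empty")
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"component {self.component_id!r}: times must be strictly "
                "increasing with no duplicates"
            )
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError(
                f"component {self.component_id!r}: values must be finite and "
                "nonnegative"
            )
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise ValueError(
                f"component {self.component_id!r}: threshold must be positive"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    def restrict_to_years(self, years: np.ndarray) -> "ComponentSeries":
        """Return a copy keeping only the given years (order preserved)."""
        mask = np.isin(self.times, np.asarray(years, dtype=np.int64))
        if not mask.any():
            raise ValueError(
                f"component {self.component_id!r}: no observations left after "
                "restricting years"
            )
        return replace(self, times=self.times[mask], values=self.values[mask])


@dataclass(frozen=True)
class Panel:
    """Ordered collection of :class:`ComponentSeries` with shared metadata."""

    components: tuple[ComponentSeries, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) == 0:
            raise ValueError("a panel must contain at least one component")
        ids = [c.component_id for c in comps]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate component ids: {dupes}")

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self) -> Iterator[ComponentSeries]:
        return iter(self.components)

    @property
    def component_ids(self) -> tuple[str, ...]:
        return tuple(c.component_id for c in self.components)

    def get(self, component_id: str) -> ComponentSeries:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(component_id)

    @property
    def years(self) -> np.ndarray:
        """Sorted distinct observation years across all components."""
        return np.unique(np.concatenate([c.times for c in self.components]))
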