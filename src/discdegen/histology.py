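"""Histopathology score aggregation and nucleus pulposus cell censuses.

Degeneration is graded on seven categories — NP shape, NP area, NP matrix,
NP cellularity, AF/NP border, AF, and endplate — each an integer within a
configured range (default 0-2, total 0-14; the range ships in config as the
grading-system assumption).  Cell censuses count surviving ("alive") NP
cells in three fields of view (anterior, centre, posterior of the NP at
x200 magnification); the surviving-cell percentage of a treated disc is the
field-summed alive count relative to the matched contrast-agent control
disc.  Cell clone (cluster) prevalence is the fraction of discs in which
clusters were observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SCORE_CATEGORIES",
    "HistologyScore",
    "CellCensus",
    "total_score",
    "survived_percentage",
    "clone_prevalence",
]

SCORE_CATEGORIES = (
    "np_shape",
    "np_area",
    "np_matrix",
    "np_cellularity",
    "af_np_border",
    "af",
    "endplate",
)

CENSUS_FIELDS = ("anterior", "center", "posterior")


@dataclass
class HistologyScore:
    """Seven category grades for one disc; ``score_range`` is inclusive."""

    scores: dict[str, int]
    score_range: tuple[int, int] = (0, 2)

    def __post_init__(self) -> None:
        missing = set(SCORE_CATEGORIES) - set(self.scores)
        if missing:
            raise ValueError(f"missing score categories: {sorted(missing)}")
        lo, hi = self.score_range
        for cat in SCORE_CATEGORIES:
            v = self.scores[cat]
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"score {cat!r} must be an integer, got {v!r}")
            if not lo <= v <= hi:
                raise ValueError(f"score {cat!r}={v} outside range [{lo}, {hi}]")

    @property
    def total(self) -> int:
        return total_score(self)


@dataclass
class CellCensus:
    """Alive (and optionally dead) NP cell counts in three fields of view."""

    alive: dict[str, int]
    dead: dict[str, int] | None = None
    clone_present: bool = False
    magnification: str = "x200"

    def __post_init__(self) -> None:
        if tuple(sorted(self.alive)) != tuple(sorted(CENSUS_FIELDS)):
            raise ValueError(f"census requires exactly the fields {CENSUS_FIELDS}")
        for d in (self.alive, self.dead or {}):
            for f, v in d.items():
                if (not isinstance(v, int)) or isinstance(v, bool) or v < 0:
                    raise ValueError(f"count for field {f!r} must be a nonnegative integer")

    @property
    def total_alive(self) -> int:
        return sum(self.alive.values())


def total_score(s: HistologyScore) -> int:
    """Sum of the seven category grades."""
    return sum(s.scores[c] for c in SCORE_CATEGORIES)


def survived_percentage(treated: CellCensus, control: CellCensus) -> float:
    """Surviving-cell percentage of a treated disc against its control.

    Computed from field-summed counts (not the mean of per-field
    percentages), which is robust to unequal field densities.
    """
    if control.total_alive <= 0:
        raise ValueError("control census has no alive cells")
    return 100.0 * treated.total_alive / control.total_alive


def clone_prevalence(n_positive: int, n_total: int) -> float:
    """Percent of discs with cell clusters, reported to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    return round(100.0 * n_positive / n_total, 1)
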