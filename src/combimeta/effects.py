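"""Log odds ratios from 2x2 outcome tables.

Each primary study contributes a 2x2 table of severe / non-severe COVID-19
outcomes in an exposed group (HIV plus a comorbidity) versus a comparator
group (HIV monoinfection).  The effect measure throughout the package is the
log odds ratio with its Wald (Woolf) standard error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TwoByTwo", "EffectEstimate", "log_odds_ratio", "Z95"]

#: Normal multiplier for 95% Wald intervals, matching the reporting
#: convention of the source studies.
Z95 = 1.96


class DomainError(ValueError):
    """A computation was requested outside its domain of definition."""


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 outcome table.

    Parameters
    ----------
    a : int
        Events (severe outcomes) in the exposed (comorbidity) group.
    b : int
        Non-events in the exposed group.
    c : int
        Events in the comparator (monoinfection) group.
    d : int
        Non-events in the comparator group.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise DomainError(f"cell '{name}' must be an integer, got {value!r}")
            if value < 0:
                raise DomainError(f"cell '{name}' must be non-negative, got {value}")
        if self.a + self.b < 1:
            raise DomainError("exposed arm is empty (a + b must be >= 1)")
        if self.c + self.d < 1:
            raise DomainError("comparator arm is empty (c + d must be >= 1)")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def swapped(self) -> "TwoByTwo":
        """Return the table with the two exposure rows interchanged."""
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error and 95% Wald interval."""

    y: float
    sigma: float
    ci_low: float
    ci_high: float


def log_odds_ratio(table: TwoByTwo, correction: str = "haldane") -> EffectEstimate:
    """Compute the log odds ratio of a 2x2 table.

    ``y = ln(ad / bc)`` with Woolf standard error
    ``sigma = sqrt(1/a + 1/b + 1/c + 1/d)`` and 95% CI ``y +/- 1.96 sigma``.

    Parameters
    ----------
    table : TwoByTwo
    correction : {"haldane", "none"}
        Zero-cell policy.  ``"haldane"`` applies the Haldane-Anscombe
        continuity correction: 0.5 is added to *all four* cells, but only
        when at least one cell is zero.  ``"none"`` requires strictly
        positive cells and raises :class:`DomainError` otherwise.
    """
    if correction not in ("haldane", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    cells = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    if correction == "none":
        for name, value in cells.items():
            if value == 0:
                raise DomainError(
                    f"cell '{name}' is zero; use correction='haldane' or supply "
                    "positive counts"
                )
        a, b, c, d = (float(v) for v in cells.values())
    else:
        shift = 0.5 if table.has_zero_cell else 0.0
        a, b, c, d = (v + shift for v in cells.values())
    y = math.log(a * d) - math.log(b * c)
    sigma = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(y=y, sigma=sigma, ci_low=y - Z95 * sigma, ci_high=y + Z95 * sigma)
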