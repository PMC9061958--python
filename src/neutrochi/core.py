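"""Neutrosophic numbers and indeterminacy intervals.

Neutrosophic statistics attach a *measure of indeterminacy* ``I`` to a
quantity, turning a single number ``x`` into an interval ``[x_L, x_U]``
with the decomposition

    x_N = determinate_part + indeterminate_coefficient * I,
    I in [I_L, I_U].

When the indeterminate coefficient equals the determinate part this is the
multiplicative form ``x_N = (1 + I) * x``, which is the form the
homogeneity test statistic actually uses; the additive decomposition is
kept so that genuinely interval-valued quantities (e.g. probabilities
estimated from distinct lower/upper count tables) fit the same container.

``I = [0, 0]`` recovers classical (fully determinate) statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "IndeterminacyInterval",
    "NeutrosophicValue",
    "make_neutrosophic",
    "evaluate_at",
    "is_classical",
]


@dataclass(frozen=True)
class IndeterminacyInterval:
    """A measure of indeterminacy ``I in [lower, upper]``.

    Both endpoints are dimensionless fractions; ``[0, 0]`` encodes the
    classical (determinate) case.  Endpoints above 1 describe indeterminacy
    exceeding the determinate quantity itself, which is unusual; they are
    rejected unless ``allow_above_one=True``, in which case a warning is
    emitted.
    """

    lower: float
    upper: float
    allow_above_one: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        lo, up = float(self.lower), float(self.upper)
        if not (math.isfinite(lo) and math.isfinite(up)):
            raise ValueError("indeterminacy endpoints must be finite")
        if lo < 0:
            raise ValueError(f"indeterminacy lower endpoint must be >= 0, got {lo}")
        if up < lo:
            raise ValueError(
                f"indeterminacy interval is inverted: lower={lo} > upper={up}"
            )
        if up > 1.0:
            if not self.allow_above_one:
                raise ValueError(
                    f"indeterminacy upper endpoint {up} exceeds 1; pass "
                    "allow_above_one=True if this is intended"
                )
            warnings.warn(
                f"indeterminacy upper endpoint {up} exceeds 1",
                stacklevel=3,
            )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def is_zero(self) -> bool:
        return self.lower == 0.0 and self.upper == 0.0

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @classmethod
    def classical(cls) -> "IndeterminacyInterval":
        return cls(0.0, 0.0)

    def __iter__(self):
        yield self.lower
        yield self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lower:g}, {self.upper:g}]"


@dataclass(frozen=True)
class NeutrosophicValue:
    """A quantity with a determinate part and an indeterminate part.

    The interval endpoints are derived, never stored, so the structural
    invariants ``lower = d + c*I_L`` and ``upper = d + c*I_U`` hold by
    construction.
    """

    determinate_part: float
    indeterminate_coefficient: float
    indeterminacy: IndeterminacyInterval

    @property
    def lower(self) -> float:
        return self.determinate_part + self.indeterminate_coefficient * self.indeterminacy.lower

    @property
    def upper(self) -> float:
        return self.determinate_part + self.indeterminate_coefficient * self.indeterminacy.upper

    @property
    def is_multiplicative(self) -> bool:
        """True when the value has the form ``(1 + I) * x``."""
        return self.indeterminate_coefficient == self.determinate_part

    @classmethod
    def from_interval(cls, lower: float, upper: float) -> "NeutrosophicValue":
        """Embed a plain interval ``[lower, upper]`` as a neutrosophic value.

        The determinate part is the lower endpoint and the indeterminate
        coefficient is the interval width, with indeterminacy spanning
        ``[0, 1]`` (or ``[0, 0]`` for a degenerate interval).
        """
        lower, upper = float(lower), float(upper)
        if upper < lower:
            raise ValueError(f"inverted interval: [{lower}, {upper}]")
        if upper == lower:
            return cls(lower, 0.0, IndeterminacyInterval.classical())
        return cls(lower, upper - lower, IndeterminacyInterval(0.0, 1.0))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lower:.6g}, {self.upper:.6g}]"


def make_neutrosophic(
    determinate: float, indeterminacy: IndeterminacyInterval
) -> NeutrosophicValue:
    """Build the multiplicative neutrosophic form ``(1 + I) * determinate``.

    This is the canonical form for the test statistic and for probabilities
    carrying relative indeterminacy: the indeterminate coefficient equals
    the determinate part, so ``lower = d*(1 + I_L)`` and
    ``upper = d*(1 + I_U)``.

    Parameters
    ----------
    determinate
        The determinate (classical) value; must be nonnegative, as the
        statistic and probabilities it represents are.
    indeterminacy
        The indeterminacy measure ``I in [I_L, I_U]``.

    Raises
    ------
    ValueError
        If ``determinate`` is negative or not finite.
    """
    d = float(determinate)
    if not math.isfinite(d):
        raise ValueError("determinate part must be finite")
    if d < 0:
        raise ValueError(f"determinate part must be >= 0, got {d}")
    return NeutrosophicValue(d, d, indeterminacy)


def evaluate_at(value: NeutrosophicValue, i: float) -> float:
    """Evaluate a neutrosophic value at a specific indeterminacy level.

    Returns ``determinate_part + indeterminate_coefficient * i``; in the
    multiplicative form this is ``determinate_part * (1 + i)``.

    Raises
    ------
    ValueError
        If ``i`` lies outside the value's indeterminacy interval.
    """
    i = float(i)
    ind = value.indeterminacy
    if not (ind.lower <= i <= ind.upper):
        raise ValueError(
            f"indeterminacy level {i} outside the interval [{ind.lower}, {ind.upper}]"
        )
    return value.determinate_part + value.indeterminate_coefficient * i


def is_classical(value: NeutrosophicValue) -> bool:
    """True when the value carries no indeterminacy (``I = [0, 0]``).

    Equivalently the interval is degenerate: ``lower == upper`` equals the
    determinate part and the value reduces to a classical number.
    """
    return value.indeterminacy.is_zero
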