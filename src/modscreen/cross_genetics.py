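"""Balancer-cross designs and Mendelian viability arithmetic.

A modifier screen cross mates balanced driver females (``driver/SM5``) to
males carrying a UAS mis-expression insertion. Adult offspring are scored by
the dominant balancer marker: ``Cy`` flies carry the balancer, ``Cy+`` flies
carry the driver chromosome and are the experimental class. The Mendelian
expectation for the ``Cy+`` fraction depends only on the father's zygosity
and on whether same-balancer homozygotes die:

* homozygous father: two surviving classes, expected ``Cy+`` fraction 1/2;
* heterozygous (balanced) father, balancer homozygotes lethal: three
  surviving classes, expected fraction 1/3;
* heterozygous father with a distinct, viable balancer combination: four
  classes, expected fraction 1/4.

Relative viability ("percent of expected") is the observed ``Cy+`` fraction
divided by that Mendelian expectation. It is deliberately defined on the
fraction of *total* scored adults, not on the ``Cy+/Cy`` odds: only the
fraction-based definition reproduces the parenthetical percentages printed
alongside raw counts in the screen's viability tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Optional

__all__ = [
    "FatherZygosity",
    "Arm",
    "CrossDesign",
    "ProgenyCounts",
    "ViabilityResult",
    "expected_cyplus_fraction",
    "relative_viability",
    "UnscorableCrossError",
]


class FatherZygosity(str, Enum):
    """Zygosity of the mis-expression-allele father in a cross."""

    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"


class Arm(str, Enum):
    """Which mother the cross used: knockdown driver (screen) or driver-only."""

    SCREEN = "screen"
    CONTROL = "control"


class UnscorableCrossError(ValueError):
    """Raised when a cross has no scored adults and viability is undefined."""


@dataclass(frozen=True)
class CrossDesign:
    """Declarative description of a tester x mis-expression cross.

    Parameters
    ----------
    father_zygosity
        Whether the father was homozygous for the insertion or balanced
        heterozygous.
    balancer_homozygote_lethal
        For heterozygous fathers: whether mother and father carry the same
        balancer, so that balancer homozygotes die. Defaults to True, the
        configuration used for the bulk of balanced-father crosses.
    """

    father_zygosity: FatherZygosity
    balancer_homozygote_lethal: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "father_zygosity", FatherZygosity(self.father_zygosity)
        )

    @property
    def expected_cyplus_fraction(self) -> Fraction:
        return expected_cyplus_fraction(self)


@dataclass(frozen=True)
class ProgenyCounts:
    """Observed adult counts for one allele in one cross arm.

    ``cy_count`` is the number of balancer-carrying adults, ``cyplus_count``
    the number of non-balancer (driver-carrying) adults. ``temperature`` is
    carried as metadata only.
    """

    allele_id: str
    arm: Arm
    cy_count: int
    cyplus_count: int
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm", Arm(self.arm))
        if self.cy_count < 0 or self.cyplus_count < 0:
            raise ValueError(
                f"negative progeny count for allele {self.allele_id!r}: "
                f"cy={self.cy_count}, cyplus={self.cyplus_count}"
            )

    @property
    def total(self) -> int:
        return self.cy_count + self.cyplus_count


@dataclass(frozen=True)
class ViabilityResult:
    """Observed Cy+ fraction, its Mendelian expectation, and their ratio."""

    observed_fraction: float
    expected_fraction: float
    relative_viability: float

    @property
    def percent_of_expected(self) -> float:
        """Relative viability on the percent scale used in printed tables."""
        return 100.0 * self.relative_viability


def expected_cyplus_fraction(design: CrossDesign) -> Fraction:
    """Mendelian expected fraction of Cy+ adults for a cross design.

    Returns an exact :class:`fractions.Fraction` (1/2, 1/3 or 1/4); callers
    doing float arithmetic can pass it straight to ``float``.
    """
    if design.father_zygosity is FatherZygosity.HOMOZYGOUS:
        return Fraction(1, 2)
    if design.balancer_homozygote_lethal:
        return Fraction(1, 3)
    return Fraction(1, 4)


def relative_viability(counts: ProgenyCounts, design: CrossDesign) -> ViabilityResult:
    """Relative viability of the Cy+ class against the Mendelian expectation.

    ``observed_fraction = cyplus / (cy + cyplus)`` and
    ``relative_viability = observed_fraction / expected_fraction``, the
    "percent of expected" statistic of screen viability tables (as a ratio,
    not a percentage).

    Raises
    ------
    UnscorableCrossError
        If no adults were scored (``cy + cyplus == 0``).
    """
    total = counts.total
    if total == 0:
        raise UnscorableCrossError(
            f"allele {counts.allele_id!r} ({counts.arm.value} arm): "
            "no scored adults, viability undefined"
        )
    expected = float(expected_cyplus_fraction(design))
    observed = counts.cyplus_count / total
    return ViabilityResult(
        observed_fraction=observed,
        expected_fraction=expected,
        relative_viability=observed / expected,
    )
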