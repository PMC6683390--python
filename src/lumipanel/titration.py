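"""Dilution-series analysis: endpoint titers and IU/mL conversion.

Endpoint semantics only — the titer is the reciprocal of the highest dilution
still at or above the cutoff.  No curve fitting.  A series whose last point is
still positive is *censored*: the true endpoint lies beyond the measured
range, and ratios built on it are lower bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: default potency (IU/mL) of the anti-HPA-1a reference standard
DEFAULT_STANDARD_POTENCY = 100.0


class TitrationError(ValueError):
    """Invalid dilution series or titer arithmetic."""


class NonMonotonicSeriesWarning(UserWarning):
    """MFI increased with dilution somewhere in the series (hook effect)."""


@dataclass(frozen=True)
class DilutionSeries:
    """Ordered (dilution factor, MFI) pairs for one sample on one bead.

    ``dilution_factor`` is the reciprocal dilution (1 = neat, 2 = 1:2, ...).
    """

    sample_id: str
    bead_id: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise TitrationError("empty dilution series")
        factors = [f for f, _ in self.points]
        if any(f < 1 or int(f) != f for f in factors):
            raise TitrationError(f"dilution factors must be positive integers: {factors}")
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise TitrationError(f"dilution factors must be strictly increasing: {factors}")
        if any(m < 0 for _, m in self.points):
            raise TitrationError("negative MFI in dilution series")
        object.__setattr__(
            self, "points", tuple((int(f), float(m)) for f, m in self.points)
        )

    @property
    def factors(self) -> tuple[int, ...]:
        return tuple(f for f, _ in self.points)

    @property
    def mfis(self) -> tuple[float, ...]:
        return tuple(m for _, m in self.points)


@dataclass(frozen=True)
class TiterResult:
    """Endpoint titer, censoring status, and optional IU/mL concentration."""

    titer: int  # reciprocal of the highest positive dilution; 0 = no positive point
    censored: bool  # last measured point still positive -> true endpoint beyond range
    concentration: float | None = None  # potency / titer, when a standard potency is known


def endpoint_titer(
    series: DilutionSeries,
    cutoff: float,
    standard_potency: float | None = None,
) -> TiterResult:
    """Largest dilution factor whose MFI is at or above the cutoff.

    Non-monotone MFI across dilutions triggers a warning but does not change
    the endpoint definition.  With ``standard_potency`` given, the result also
    carries the IU/mL concentration ``potency / titer``.
    """
    if cutoff <= 0:
        raise TitrationError(f"cutoff must be positive, got {cutoff}")
    mfis = series.mfis
    if any(b > a for a, b in zip(mfis, mfis[1:])):
        warnings.warn(
            f"series {series.sample_id}/{series.bead_id}: MFI rises with "
            "dilution (possible hook effect); endpoint rule still applied",
            NonMonotonicSeriesWarning,
            stacklevel=2,
        )
    positive = [f for f, m in series.points if m >= cutoff]
    if not positive:
        return TiterResult(titer=0, censored=False, concentration=None)
    titer = max(positive)
    censored = titer == series.factors[-1]
    concentration = None
    if standard_potency is not None:
        concentration = to_concentration(titer, standard_potency)
    logger.info(
        "titer sample=%s bead=%s titer=%d censored=%s",
        series.sample_id, series.bead_id, titer, censored,
    )
    return TiterResult(titer=titer, censored=censored, concentration=concentration)


def to_concentration(titer: int, standard_potency: float) -> float | None:
    """IU/mL equivalent of an endpoint titer against a standard's potency.

    Returns ``potency / titer`` at full precision (round for display); a zero
    titer has no defined concentration and returns None.
    """
    if titer == 0:
        return None
    if titer < 0:
        raise TitrationError(f"titer must be >= 0, got {titer}")
    if standard_potency <= 0:
        raise TitrationError(f"standard potency must be positive, got {standard_potency}")
    return standard_potency / titer


def format_concentration(value: float) -> str:
    """3-significant-figure display form used in reports."""
    return f"{value:.3g}"


@dataclass(frozen=True)
class SensitivityComparison:
    """Fold difference between two endpoint titers."""

    fold: float
    lower_bound: bool  # true when censoring makes the ratio a lower bound


def compare_sensitivity(a: TiterResult, b: TiterResult) -> SensitivityComparison:
    """Fold sensitivity of ``a`` relative to ``b`` (ratio of titers).

    A censored numerator (or a censored denominator) makes the true ratio at
    least (resp. at most) the reported one; either way the result is marked a
    bound rather than an exact fold.
    """
    if a.titer < 1 or b.titer < 1:
        raise TitrationError(
            f"both titers must be >= 1 to compare (got {a.titer}, {b.titer})"
        )
    return SensitivityComparison(
        fold=a.titer / b.titer,
        lower_bound=a.censored or b.censored,
    )
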