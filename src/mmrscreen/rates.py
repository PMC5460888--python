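"""Slippage-rate estimation from fluctuation-assay counts and related statistics.

The reporter fluctuation assay expands a culture to ``N`` cells and counts
Geneticin-resistant colonies ``G`` arising from frameshift-reverting
slippage events.  The per-division slippage rate ``p`` solves the
transcendental equation

    0.6 * G = N * p * log(N * p)

which is monotone in ``p`` for ``N*p > 1`` and is solved by bracketed
root-finding.  The natural logarithm is the default (the constant and the
functional form come from classical Luria-Delbruck median-style
estimation); base 10 is available as a sensitivity knob.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field
from typing import Sequence

from scipy import optimize, stats

__all__ = [
    "LogBase",
    "FluctuationExperiment",
    "SlippageRateEstimate",
    "MutagenesisExperiment",
    "MutationFrequencyResult",
    "WelchResult",
    "RateError",
    "BelowDetection",
    "estimate_slippage_rate",
    "detection_limit",
    "summarize_fluctuation",
    "fold_change",
    "mutation_frequency",
    "welch_one_tailed",
    "significance_stars",
]

#: Constant multiplying the colony total in the slippage-rate equation.
SLIPPAGE_CONSTANT = 0.6


class RateError(ValueError):
    """Invalid input to a rate computation."""


class BelowDetection(RateError):
    """Raised when a zero colony count puts the rate below the detection limit.

    Carries ``detection_limit``, the estimate at a single colony.
    """

    def __init__(self, detection_limit: float):
        super().__init__(
            f"zero resistant colonies: rate below detection limit "
            f"{detection_limit:.4g}"
        )
        self.detection_limit = detection_limit


class LogBase(str, enum.Enum):
    NATURAL = "ln"
    BASE10 = "log10"

    def __call__(self, x: float) -> float:
        return math.log(x) if self is LogBase.NATURAL else math.log10(x)


@dataclass(frozen=True)
class FluctuationExperiment:
    """Replicate Geneticin-resistant colony totals for one cell line.

    ``replicates`` holds one colony total per replicate culture, each
    independently expanded to ``n_expanded`` cells and fully plated.
    """

    variant_id: str
    replicates: tuple[int, ...]
    n_expanded: int = 10_000_000
    cells_per_plate: int = 100_000
    n_plates: int = 100

    def __init__(
        self,
        variant_id: str,
        replicates: Sequence[int],
        n_expanded: int = 10_000_000,
        cells_per_plate: int = 100_000,
        n_plates: int = 100,
    ) -> None:
        object.__setattr__(self, "variant_id", variant_id)
        # counts are normally integers; fractional totals are accepted for
        # analytic fixtures
        object.__setattr__(
            self,
            "replicates",
            tuple(
                int(r) if float(r).is_integer() else float(r) for r in replicates
            ),
        )
        object.__setattr__(self, "n_expanded", int(n_expanded))
        object.__setattr__(self, "cells_per_plate", int(cells_per_plate))
        object.__setattr__(self, "n_plates", int(n_plates))
        if not self.replicates:
            raise RateError("replicates must be non-empty")
        if any(r < 0 for r in self.replicates):
            raise RateError("colony counts must be non-negative")
        if self.n_expanded < self.cells_per_plate * self.n_plates:
            raise RateError(
                "n_expanded smaller than the number of cells plated "
                f"({self.n_expanded} < {self.cells_per_plate * self.n_plates})"
            )


@dataclass(frozen=True)
class SlippageRateEstimate:
    variant_id: str
    p_per_replicate: tuple[float, ...]  # NaN marks a below-detection replicate
    p_mean: float
    p_sd: float
    below_detection: bool
    detection_limit: float


@dataclass(frozen=True)
class MutagenesisExperiment:
    """Mutagen-exposure arm: dose, cells plated and resistant-colony counts."""

    variant_id: str
    dose_uM: float
    replicates: tuple[int, ...]
    cells_plated: int = 1_500_000

    def __init__(
        self,
        variant_id: str,
        dose_uM: float,
        replicates: Sequence[int],
        cells_plated: int = 1_500_000,
    ) -> None:
        object.__setattr__(self, "variant_id", variant_id)
        object.__setattr__(self, "dose_uM", float(dose_uM))
        object.__setattr__(self, "replicates", tuple(int(r) for r in replicates))
        object.__setattr__(self, "cells_plated", int(cells_plated))
        if not self.replicates:
            raise RateError("replicates must be non-empty")
        if any(r < 0 for r in self.replicates):
            raise RateError("colony counts must be non-negative")
        if self.cells_plated <= 0:
            raise RateError("cells_plated must be positive")


@dataclass(frozen=True)
class MutationFrequencyResult:
    variant_id: str
    dose_uM: float
    freq_per_replicate: tuple[float, ...]
    freq_mean: float


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_freedom: float
    p_one_tailed: float


def _rate_equation(np_product: float, log: LogBase) -> float:
    return np_product * log(np_product)


def estimate_slippage_rate(
    geneticin_total: float,
    n_expanded: int,
    log_base: LogBase = LogBase.NATURAL,
) -> float:
    """Solve ``0.6 * G = N * p * log(N * p)`` for the slippage rate ``p``.

    Returns the unique root with ``N*p > 1``, located by Brent's method on a
    bracket where the left-hand side is strictly increasing, to relative
    tolerance 1e-10.  A zero colony count raises :class:`BelowDetection`
    carrying the single-colony detection limit.
    """
    if n_expanded < 2:
        raise RateError(f"n_expanded must be >= 2, got {n_expanded}")
    if geneticin_total < 0:
        raise RateError("geneticin_total must be non-negative")
    if geneticin_total == 0:
        raise BelowDetection(detection_limit(n_expanded, log_base))

    target = SLIPPAGE_CONSTANT * geneticin_total
    # Solve for x = N*p on (1, hi]; x*log(x) is 0 at x=1 and increasing.
    lo = 1.0 + 1e-12
    hi = 2.0
    while _rate_equation(hi, log_base) < target:
        hi *= 2.0
    x = optimize.brentq(
        lambda x: _rate_equation(x, log_base) - target, lo, hi,
        rtol=1e-12, maxiter=200,
    )
    return x / n_expanded


def detection_limit(
    n_expanded: int, log_base: LogBase = LogBase.NATURAL
) -> float:
    """Rate that a single resistant colony would imply: the assay floor."""
    return estimate_slippage_rate(1, n_expanded, log_base)


def summarize_fluctuation(
    exp: FluctuationExperiment, log_base: LogBase = LogBase.NATURAL
) -> SlippageRateEstimate:
    """Per-replicate slippage rates with mean/sd over the finite estimates.

    Zero-count replicates are recorded as NaN and flagged via
    ``below_detection`` rather than imputed as zero: the estimator is
    undefined at ``G = 0``.
    """
    limit = detection_limit(exp.n_expanded, log_base)
    estimates: list[float] = []
    below = False
    for count in exp.replicates:
        if count == 0:
            estimates.append(math.nan)
            below = True
        else:
            estimates.append(
                estimate_slippage_rate(count, exp.n_expanded, log_base)
            )
    finite = [p for p in estimates if not math.isnan(p)]
    if finite:
        p_mean = statistics.fmean(finite)
        p_sd = statistics.stdev(finite) if len(finite) > 1 else 0.0
    else:
        p_mean = math.nan
        p_sd = math.nan
    return SlippageRateEstimate(
        variant_id=exp.variant_id,
        p_per_replicate=tuple(estimates),
        p_mean=p_mean,
        p_sd=p_sd,
        below_detection=below,
        detection_limit=limit,
    )


def fold_change(p_variant: float, p_reference: float) -> float:
    """Raw rate ratio ``p_variant / p_reference``."""
    if p_reference <= 0:
        raise RateError("reference rate must be positive")
    return p_variant / p_reference


def round_fold_display(fold: float) -> float:
    """Display rounding for fold changes: nearest 10 when >= 100.

    Below 100 the raw value is returned unchanged; raw ratios should always
    be retained alongside the display value.
    """
    if fold >= 100:
        return 10.0 * round(fold / 10.0)
    return fold


def mutation_frequency(exp: MutagenesisExperiment) -> MutationFrequencyResult:
    """Resistant colonies per plated cell, per replicate and averaged."""
    freqs = tuple(r / exp.cells_plated for r in exp.replicates)
    return MutationFrequencyResult(
        variant_id=exp.variant_id,
        dose_uM=exp.dose_uM,
        freq_per_replicate=freqs,
        freq_mean=statistics.fmean(freqs),
    )


def welch_one_tailed(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> WelchResult:
    """One-tailed unpaired t-test with Welch's correction, H1: mean(a) > mean(b).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b); degrees of freedom
    by Welch-Satterthwaite; the one-tailed p-value is the upper tail of the
    t distribution.
    """
    a = [float(x) for x in sample_a]
    b = [float(x) for x in sample_b]
    if len(a) < 2 or len(b) < 2:
        raise RateError("each sample needs at least 2 values")
    if not all(math.isfinite(x) for x in a + b):
        raise RateError("samples must be finite")
    va = statistics.variance(a)
    vb = statistics.variance(b)
    if va == 0 and vb == 0:
        raise RateError("both samples have zero variance; t undefined")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (statistics.fmean(a) - statistics.fmean(b)) / math.sqrt(se2)
    df = se2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = float(stats.t.sf(t, df))
    return WelchResult(t_statistic=t, degrees_freedom=df, p_one_tailed=p)


_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star annotation: p<0.05 '*', <0.01 '**', <0.001 '***', <0.0001 '****'.

    Thresholds are strict: p = 0.05 exactly is 'ns'.
    """
    if not 0.0 <= p <= 1.0:
        raise RateError(f"p-value out of [0, 1]: {p}")
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"
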