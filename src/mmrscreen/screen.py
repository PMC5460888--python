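"""Colony genotype classification and per-variant pathogenicity calling.

The screen introduces a candidate base substitution into heterozygous
mismatch-repair (MMR) reporter cells, selects survivors with 6-thioguanine,
and genotypes the picked colonies.  Each picked colony is resolved into one
of three categories:

* ``loh`` -- the wild-type allele was lost (loss of heterozygosity), an
  alternative route to 6TG resistance that says nothing about the variant;
* ``background`` -- both alleles retained but no planned mutation found;
* ``confirmed_mutant`` -- both alleles retained and the planned mutation
  confirmed by sequencing.

A variant is called MMR-abrogating when the planned mutation is confirmed
in at least two independent colonies (aggregated over antisense and sense
targeting rounds).  Exactly one confirmed colony is reported as
``inconclusive``; zero as ``not_detected``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "AllelePCR",
    "SequenceCall",
    "ColonyCategory",
    "Round",
    "InsightClass",
    "PriorLabel",
    "CallOutcome",
    "VariantRecord",
    "ColonyObservation",
    "ColonyPanel",
    "ColonyFractions",
    "MergedCounts",
    "ScreenCall",
    "ProteinQuant",
    "PerformanceReport",
    "ScreenError",
    "ClassificationError",
    "EvaluationError",
    "classify_colony",
    "colony_fractions",
    "aggregate_rounds",
    "call_variant",
    "relative_protein_level",
    "screen_performance",
]


class ScreenError(ValueError):
    """Base class for screen-analysis errors."""


class ClassificationError(ScreenError):
    """A colony observation cannot be classified (e.g. missing sequencing)."""


class EvaluationError(ScreenError):
    """Performance evaluation is impossible (e.g. an empty truth partition)."""


class AllelePCR(str, enum.Enum):
    BOTH_ALLELES_PRESENT = "both"
    WT_ALLELE_LOST = "wt_lost"


class SequenceCall(str, enum.Enum):
    PLANNED_MUTATION = "mut"
    NO_MUTATION = "wt"
    NOT_TESTED = "nt"


class ColonyCategory(str, enum.Enum):
    LOH = "loh"
    BACKGROUND = "background"
    CONFIRMED_MUTANT = "confirmed_mutant"


class Round(str, enum.Enum):
    ANTISENSE = "antisense"
    SENSE = "sense"


class InsightClass(str, enum.Enum):
    """Five-tier clinical variant classification; NA when unclassified."""

    NOT_PATHOGENIC = "1"
    LIKELY_NOT_PATHOGENIC = "2"
    UNCERTAIN = "3"
    LIKELY_PATHOGENIC = "4"
    PATHOGENIC = "5"
    NA = "NA"


class PriorLabel(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    NON_PATHOGENIC = "non_pathogenic"
    UNCERTAIN = "uncertain"


class CallOutcome(str, enum.Enum):
    MMR_ABROGATING = "mmr_abrogating"
    NOT_DETECTED = "not_detected"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class VariantRecord:
    """One screened variant with annotations and an evaluation truth label."""

    variant_id: str
    human_aa_change: str
    mouse_aa_change: str
    nucleotide_change: str
    insight_class: InsightClass
    prior_label: PriorLabel

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ScreenError("variant_id must be non-empty")


@dataclass(frozen=True)
class ColonyObservation:
    """Allele-PCR plus sequencing result for one picked 6TG-resistant colony.

    LOH colonies are excluded before sequencing, so a lost wild-type allele
    implies ``sequence_call = NOT_TESTED``.
    """

    colony_id: str
    allele_pcr: AllelePCR
    sequence_call: SequenceCall

    def __post_init__(self) -> None:
        if (
            self.allele_pcr is AllelePCR.WT_ALLELE_LOST
            and self.sequence_call is not SequenceCall.NOT_TESTED
        ):
            raise ScreenError(
                f"colony {self.colony_id!r}: LOH colonies are not sequenced; "
                f"got sequence_call={self.sequence_call.value!r}"
            )


@dataclass(frozen=True)
class ColonyPanel:
    """All colonies picked for one variant in one targeting round."""

    variant_id: str
    round: Round
    colonies: tuple[ColonyObservation, ...]

    def __init__(
        self,
        variant_id: str,
        round: Round,
        colonies: Iterable[ColonyObservation],
    ) -> None:
        object.__setattr__(self, "variant_id", variant_id)
        object.__setattr__(self, "round", Round(round))
        object.__setattr__(self, "colonies", tuple(colonies))

    @property
    def n_picked(self) -> int:
        return len(self.colonies)


@dataclass(frozen=True)
class ColonyFractions:
    """Category fractions over the picked colonies of one panel.

    Fractions are exact rationals so that ``f_loh + f_background +
    f_confirmed == 1`` holds without rounding error.
    """

    f_loh: Fraction
    f_background: Fraction
    f_confirmed: Fraction

    def __post_init__(self) -> None:
        total = self.f_loh + self.f_background + self.f_confirmed
        if total != 1:
            raise ScreenError(f"colony fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class MergedCounts:
    """Category counts for one variant merged across targeting rounds."""

    variant_id: str
    n_confirmed: int
    n_loh: int
    n_background: int
    rounds_used: tuple[Round, ...]

    def __post_init__(self) -> None:
        for name in ("n_confirmed", "n_loh", "n_background"):
            if getattr(self, name) < 0:
                raise ScreenError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_confirmed + self.n_loh + self.n_background


@dataclass(frozen=True)
class ScreenCall:
    """Final per-variant call with its supporting colony counts."""

    variant_id: str
    call: CallOutcome
    n_confirmed: int
    n_loh: int
    n_background: int
    rounds_used: tuple[Round, ...]


@dataclass(frozen=True)
class ProteinQuant:
    """Band intensities for one immunoblot lane (arbitrary fluorescence units)."""

    msh6_signal: float
    msh2_signal: float
    loading_signal: float

    def __post_init__(self) -> None:
        if self.msh6_signal < 0 or self.msh2_signal < 0 or self.loading_signal < 0:
            raise ScreenError("band signals must be non-negative")


@dataclass(frozen=True)
class PerformanceReport:
    """Screen sensitivity/specificity with zero-failure lower bounds."""

    n_pathogenic_truth: int
    n_detected: int
    n_nonpathogenic_truth: int
    n_false_positive: int
    sensitivity_point: float
    specificity_point: float
    sensitivity_zero_failure_bound: float
    specificity_zero_failure_bound: float
    excluded_uncertain: tuple[str, ...] = field(default=())


def classify_colony(obs: ColonyObservation) -> ColonyCategory:
    """Resolve one colony into loh / background / confirmed_mutant.

    Raises :class:`ClassificationError` for a colony that retained both
    alleles but was never sequenced: the workflow sequences every retained
    colony, so a missing call is a data error, not a background colony.
    """
    if obs.allele_pcr is AllelePCR.WT_ALLELE_LOST:
        return ColonyCategory.LOH
    if obs.sequence_call is SequenceCall.PLANNED_MUTATION:
        return ColonyCategory.CONFIRMED_MUTANT
    if obs.sequence_call is SequenceCall.NO_MUTATION:
        return ColonyCategory.BACKGROUND
    raise ClassificationError(
        f"colony {obs.colony_id!r} retained both alleles but has no sequencing call"
    )


def _count_panel(panel: ColonyPanel) -> tuple[int, int, int]:
    n_loh = n_bg = n_conf = 0
    for obs in panel.colonies:
        cat = classify_colony(obs)
        if cat is ColonyCategory.LOH:
            n_loh += 1
        elif cat is ColonyCategory.BACKGROUND:
            n_bg += 1
        else:
            n_conf += 1
    return n_loh, n_bg, n_conf


def colony_fractions(panel: ColonyPanel) -> ColonyFractions:
    """Exact category fractions over the picked colonies of one panel."""
    n = panel.n_picked
    if n == 0:
        raise ScreenError(
            f"panel for {panel.variant_id!r} ({panel.round.value}) is empty; "
            "fractions are undefined"
        )
    n_loh, n_bg, n_conf = _count_panel(panel)
    return ColonyFractions(
        f_loh=Fraction(n_loh, n),
        f_background=Fraction(n_bg, n),
        f_confirmed=Fraction(n_conf, n),
    )


def aggregate_rounds(panels: Sequence[ColonyPanel]) -> MergedCounts:
    """Sum colony-category counts for one variant across targeting rounds.

    The sense round is a retry of the antisense round, so a sense panel
    without an antisense panel is rejected.
    """
    if not panels:
        raise ScreenError("aggregate_rounds requires at least one panel")
    variant_ids = {p.variant_id for p in panels}
    if len(variant_ids) != 1:
        raise ScreenError(f"panels mix variant ids: {sorted(variant_ids)}")
    rounds = [p.round for p in panels]
    if len(set(rounds)) != len(rounds):
        raise ScreenError(
            f"duplicate round panel for variant {panels[0].variant_id!r}"
        )
    if Round.SENSE in rounds and Round.ANTISENSE not in rounds:
        raise ScreenError(
            f"variant {panels[0].variant_id!r} has a sense panel without the "
            "antisense round it retries"
        )
    n_loh = n_bg = n_conf = 0
    for panel in panels:
        loh, bg, conf = _count_panel(panel)
        n_loh += loh
        n_bg += bg
        n_conf += conf
    order = {Round.ANTISENSE: 0, Round.SENSE: 1}
    return MergedCounts(
        variant_id=panels[0].variant_id,
        n_confirmed=n_conf,
        n_loh=n_loh,
        n_background=n_bg,
        rounds_used=tuple(sorted(rounds, key=order.__getitem__)),
    )


def call_variant(merged: MergedCounts) -> ScreenCall:
    """Two-independent-colonies rule.

    >= 2 confirmed mutant colonies -> ``mmr_abrogating``; 0 -> ``not_detected``;
    exactly 1 -> ``inconclusive`` (the rule's boundary, surfaced distinctly).
    """
    if merged.n_confirmed >= 2:
        outcome = CallOutcome.MMR_ABROGATING
    elif merged.n_confirmed == 1:
        outcome = CallOutcome.INCONCLUSIVE
    else:
        outcome = CallOutcome.NOT_DETECTED
    return ScreenCall(
        variant_id=merged.variant_id,
        call=outcome,
        n_confirmed=merged.n_confirmed,
        n_loh=merged.n_loh,
        n_background=merged.n_background,
        rounds_used=merged.rounds_used,
    )


def relative_protein_level(
    variant: ProteinQuant, control: ProteinQuant, signal: str = "msh6"
) -> float:
    """Loading-normalized band intensity as percent of the control lane.

    ``100 * (variant signal / variant loading) / (control signal / control
    loading)``.  ``signal`` selects ``"msh6"`` or ``"msh2"``.
    """
    if signal not in ("msh6", "msh2"):
        raise ScreenError(f"unknown signal {signal!r}; expected 'msh6' or 'msh2'")
    if variant.loading_signal <= 0 or control.loading_signal <= 0:
        raise ScreenError("loading signal must be positive in both lanes")
    attr = f"{signal}_signal"
    v = getattr(variant, attr) / variant.loading_signal
    c = getattr(control, attr) / control.loading_signal
    if c == 0:
        raise ScreenError(f"control {signal} signal is zero; ratio undefined")
    return 100.0 * v / c


def zero_failure_bound(n: int) -> float:
    """Lower performance bound 100*(n-1)/n when all n labelled cases succeed."""
    if n <= 0:
        raise EvaluationError("zero-failure bound requires n >= 1")
    return 100.0 * (n - 1) / n


def screen_performance(
    calls: Sequence[ScreenCall], truth: Sequence[VariantRecord]
) -> PerformanceReport:
    """Evaluate calls against prior truth labels.

    Only variants labelled pathogenic or non_pathogenic participate;
    uncertain rows are listed as excluded.  An inconclusive call counts as
    not-detected for sensitivity and as not-called-pathogenic for
    specificity (conservative toward the screen).  With zero failures in a
    partition of size n the reported bound is 100*(n-1)/n; with failures
    the bound field equals the point estimate.
    """
    call_by_id = {c.variant_id: c for c in calls}
    missing = [v.variant_id for v in truth if v.variant_id not in call_by_id]
    if missing:
        raise EvaluationError(f"no screen call for truth variants: {missing}")

    pathogenic = [v for v in truth if v.prior_label is PriorLabel.PATHOGENIC]
    nonpathogenic = [v for v in truth if v.prior_label is PriorLabel.NON_PATHOGENIC]
    excluded = tuple(
        v.variant_id for v in truth if v.prior_label is PriorLabel.UNCERTAIN
    )
    if not pathogenic:
        raise EvaluationError("truth set has no pathogenic variants")
    if not nonpathogenic:
        raise EvaluationError("truth set has no non_pathogenic variants")

    n_path = len(pathogenic)
    n_detected = sum(
        call_by_id[v.variant_id].call is CallOutcome.MMR_ABROGATING
        for v in pathogenic
    )
    n_nonpath = len(nonpathogenic)
    n_fp = sum(
        call_by_id[v.variant_id].call is CallOutcome.MMR_ABROGATING
        for v in nonpathogenic
    )

    sens_point = 100.0 * n_detected / n_path
    spec_point = 100.0 * (n_nonpath - n_fp) / n_nonpath
    sens_bound = zero_failure_bound(n_path) if n_detected == n_path else sens_point
    spec_bound = zero_failure_bound(n_nonpath) if n_fp == 0 else spec_point
    return PerformanceReport(
        n_pathogenic_truth=n_path,
        n_detected=n_detected,
        n_nonpathogenic_truth=n_nonpath,
        n_false_positive=n_fp,
        sensitivity_point=sens_point,
        specificity_point=spec_point,
        sensitivity_zero_failure_bound=sens_bound,
        specificity_zero_failure_bound=spec_bound,
        excluded_uncertain=excluded,
    )


def format_percent(x: float) -> str:
    """One-decimal percent formatting used in all reports."""
    if math.isnan(x):
        return "nan"
    return f"{x:.1f}"
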