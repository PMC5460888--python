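"""Stochastic simulators for the screen, the fluctuation assay and the
mutagenesis assay, plus targeting-oligo design.

Every simulator takes an explicit seed and is bit-reproducible.  The
fluctuation simulator uses an event/clone-size formulation of clonal
expansion (synchronous doubling generations) so that the expected mutant
count has a closed form usable as an independent test oracle:

    E[mutant cells] = p * n_final * log2(n_final / n_start)

A mutation occurs during a cell division with probability ``p`` per
division; the mutated lineage doubles every remaining generation, so an
event in generation g (of G) founds a clone of final size 2**(G - g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .rates import FluctuationExperiment, MutagenesisExperiment
from .screen import (
    AllelePCR,
    ColonyObservation,
    ColonyPanel,
    Round,
    SequenceCall,
)

__all__ = [
    "ScreenSimParams",
    "FluctSimParams",
    "SimulationError",
    "simulate_screen",
    "simulate_fluctuation_assay",
    "simulate_fluctuation_direct",
    "simulate_mnng_assay",
    "design_lmo",
    "default_screen_params",
]


class SimulationError(ValueError):
    """Invalid simulation parameters or an unusable stochastic outcome."""


def _load_defaults() -> dict:
    text = (
        resources.files("mmrscreen").joinpath("data/defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ScreenSimParams:
    """Generative parameters for one screen simulation.

    The survivor rates are calibrated (see ``data/defaults.yaml``) so that
    with targeting efficiency 1e-3 the mean non-LOH fraction among 18
    picked colonies is about 0.40 for an MMR-abrogating variant and about
    0.06 for a neutral one.
    """

    targeting_efficiency: float = 1e-3
    n_cells_selected: int = 1_500_000
    loh_survivor_rate: float = 1.66e-3
    background_survivor_rate: float = 1.06e-4
    n_colonies_picked: int = 18
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "targeting_efficiency",
            "loh_survivor_rate",
            "background_survivor_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {value}")
        if self.n_cells_selected < 0 or self.n_colonies_picked < 0:
            raise SimulationError("counts must be non-negative")


def default_screen_params(rng_seed: int = 0, **overrides) -> ScreenSimParams:
    """Screen parameters from the calibrated config file."""
    cfg = _load_defaults()["screen"]
    cfg.update(overrides)
    return ScreenSimParams(rng_seed=rng_seed, **cfg)


@dataclass(frozen=True)
class FluctSimParams:
    """Parameters for one simulated fluctuation assay.

    ``n_final`` must be ``n_start`` times a power of two (the growth model
    is synchronous doubling).
    """

    p_true: float
    n_start: int = 153
    n_generations: int = 16
    cells_per_plate: int = 100_000
    n_plates: int = 100
    plating_efficiency: float = 1.0
    n_replicates: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.p_true < 0:
            raise SimulationError("p_true must be non-negative")
        if self.n_start < 1 or self.n_generations < 1:
            raise SimulationError("n_start >= 1 and n_generations >= 1 required")
        if not 0.0 <= self.plating_efficiency <= 1.0:
            raise SimulationError("plating_efficiency must be in [0, 1]")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")

    @property
    def n_final(self) -> int:
        return self.n_start * 2**self.n_generations

    @classmethod
    def for_final_size(cls, p_true: float, n_final: int, **kwargs) -> "FluctSimParams":
        """Choose ``n_start``/``n_generations`` so n_start * 2**G == n_final.

        ``n_final`` is reduced to its largest odd divisor for ``n_start``;
        the requested final size must therefore contain a power-of-two
        factor large enough to make a sensible expansion (>= 2**8).
        """
        g = 0
        n_start = int(n_final)
        while n_start % 2 == 0:
            n_start //= 2
            g += 1
        if g < 8:
            raise SimulationError(
                f"n_final={n_final} has only a 2**{g} power-of-two factor; "
                "pick a final size divisible by at least 2**8"
            )
        return cls(p_true=p_true, n_start=n_start, n_generations=g, **kwargs)


def simulate_screen(
    variants: Sequence[tuple[str, bool]],
    params: ScreenSimParams,
) -> tuple[list[ColonyPanel], list[str]]:
    """Simulate one antisense targeting round for each variant.

    ``variants`` pairs each variant id with the latent truth of whether it
    abrogates mismatch repair.  Per variant, independent binomial draws over
    the selected cells give targeted cells (which survive selection iff the
    variant abrogates MMR), LOH survivors and background survivors; the
    picked colonies are a multivariate-hypergeometric draw over the
    survivor categories.  Returns the panels plus warning messages for
    variants with zero survivors (emitted as empty panels).
    """
    rng = np.random.default_rng(params.rng_seed)
    panels: list[ColonyPanel] = []
    warnings: list[str] = []
    for variant_id, abrogates in variants:
        n = params.n_cells_selected
        targeted = rng.binomial(n, params.targeting_efficiency)
        surviving_mutants = targeted if abrogates else 0
        loh = rng.binomial(n, params.loh_survivor_rate)
        background = rng.binomial(n, params.background_survivor_rate)
        survivors = np.array([loh, background, surviving_mutants])
        total = int(survivors.sum())
        if total == 0:
            warnings.append(
                f"variant {variant_id!r}: no 6TG survivors; emitting empty panel"
            )
            panels.append(ColonyPanel(variant_id, Round.ANTISENSE, ()))
            continue
        n_pick = min(params.n_colonies_picked, total)
        picked = rng.multivariate_hypergeometric(survivors, n_pick)
        colonies: list[ColonyObservation] = []
        idx = 0
        for _ in range(int(picked[0])):
            colonies.append(
                ColonyObservation(
                    f"{variant_id}.c{idx}",
                    AllelePCR.WT_ALLELE_LOST,
                    SequenceCall.NOT_TESTED,
                )
            )
            idx += 1
        for _ in range(int(picked[1])):
            colonies.append(
                ColonyObservation(
                    f"{variant_id}.c{idx}",
                    AllelePCR.BOTH_ALLELES_PRESENT,
                    SequenceCall.NO_MUTATION,
                )
            )
            idx += 1
        for _ in range(int(picked[2])):
            colonies.append(
                ColonyObservation(
                    f"{variant_id}.c{idx}",
                    AllelePCR.BOTH_ALLELES_PRESENT,
                    SequenceCall.PLANNED_MUTATION,
                )
            )
            idx += 1
        panels.append(ColonyPanel(variant_id, Round.ANTISENSE, colonies))
    return panels, warnings


def _simulate_mutant_cells(params: FluctSimParams, rng: np.random.Generator) -> int:
    """Mutant cells at the end of one expansion (event/clone-size model)."""
    total_mutants = 0
    cells = params.n_start
    G = params.n_generations
    for g in range(G):
        events = rng.poisson(params.p_true * cells)
        total_mutants += int(events) * 2 ** (G - g)
        cells *= 2
    return total_mutants


def simulate_fluctuation_assay(
    params: FluctSimParams, variant_id: str = "sim"
) -> FluctuationExperiment:
    """Simulate replicate fluctuation cultures and their plated colony counts.

    Each replicate expands ``n_start`` cells through synchronous doubling;
    per generation the number of mutation events is Poisson with mean
    ``p_true`` times the dividing cells, and each event founds a clone that
    doubles until the end of the expansion (the jackpot mechanism).  The
    colony count is a binomial thinning of the mutant cells by the plated
    fraction and plating efficiency.
    """
    rng = np.random.default_rng(params.rng_seed)
    n_final = params.n_final
    cells_plated = min(n_final, params.cells_per_plate * params.n_plates)
    keep = (cells_plated / n_final) * params.plating_efficiency
    cpp = min(params.cells_per_plate, n_final)
    counts: list[int] = []
    for _ in range(params.n_replicates):
        mutants = _simulate_mutant_cells(params, rng)
        if mutants > n_final:
            raise SimulationError(
                f"p_true={params.p_true} saturates the culture "
                f"({mutants} mutants > {n_final} cells)"
            )
        counts.append(int(rng.binomial(mutants, keep)) if mutants else 0)
    return FluctuationExperiment(
        variant_id=variant_id,
        replicates=counts,
        n_expanded=n_final,
        cells_per_plate=cpp,
        n_plates=max(1, cells_plated // cpp),
    )


def simulate_fluctuation_direct(
    params: FluctSimParams, rng: np.random.Generator
) -> int:
    """Per-cell enumeration oracle for the expansion model (small cultures).

    Tracks wild-type and mutant cell counts generation by generation; each
    dividing wild-type cell mutates with probability ``p_true`` and the
    mutated lineage doubles thereafter.  Only usable up to n_final ~ 2**16;
    exists as an independent cross-check of the event/clone-size simulator.
    """
    if params.n_final > 2**16:
        raise SimulationError("direct enumeration capped at n_final <= 2**16")
    wt = params.n_start
    mut = 0
    for _ in range(params.n_generations):
        new_mutants = rng.binomial(wt, params.p_true)
        mut = 2 * (mut + int(new_mutants))
        wt = 2 * (wt - int(new_mutants))
    return mut


def simulate_mnng_assay(
    spontaneous_freq: float,
    induced_freq: float,
    cells_plated: int = 1_500_000,
    n_replicates: int = 2,
    rng_seed: int = 0,
    variant_id: str = "sim",
) -> tuple[MutagenesisExperiment, MutagenesisExperiment]:
    """Poisson colony counts for the untreated and mutagen-treated arms."""
    for name, freq in (
        ("spontaneous_freq", spontaneous_freq),
        ("induced_freq", induced_freq),
    ):
        if not 0.0 <= freq <= 1e-2:
            raise SimulationError(f"{name} must be in [0, 1e-2], got {freq}")
    rng = np.random.default_rng(rng_seed)
    spont = rng.poisson(spontaneous_freq * cells_plated, size=n_replicates)
    induced = rng.poisson(induced_freq * cells_plated, size=n_replicates)
    return (
        MutagenesisExperiment(variant_id, 0.0, [int(x) for x in spont], cells_plated),
        MutagenesisExperiment(variant_id, 4.0, [int(x) for x in induced], cells_plated),
    )


@dataclass(frozen=True)
class LmoDesign:
    sequence: str
    orientation: str
    substitution_position: int  # 1-based reference coordinate of first changed base
    window_start: int  # 1-based, inclusive
    window_end: int  # 1-based, inclusive


def design_lmo(
    reference_cds: str,
    codon_index: int,
    replacement_codon: str,
    oligo_length: int = 35,
    orientation: str = "sense",
) -> LmoDesign:
    """Design a targeting oligo carrying a 1-2 base codon substitution.

    The sense oligo is the mutated reference window with the substitution
    site as close to the oligo centre as the reference boundaries allow
    (``codon_index`` is 1-based); the antisense oligo is its reverse
    complement.  The substitution position is reported in 1-based reference
    coordinates of the first changed base.
    """
    ref = str(reference_cds).upper()
    codon = replacement_codon.upper()
    if orientation not in ("sense", "antisense"):
        raise SimulationError(f"unknown orientation {orientation!r}")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise SimulationError(f"replacement codon must be a 3-mer over ACGT: {codon!r}")
    if oligo_length < 3 or oligo_length > len(ref):
        raise SimulationError(
            f"oligo_length {oligo_length} does not fit the {len(ref)} nt reference"
        )
    start0 = (codon_index - 1) * 3
    if codon_index < 1 or start0 + 3 > len(ref):
        raise SimulationError(f"codon {codon_index} out of range for reference")
    ref_codon = ref[start0 : start0 + 3]
    diffs = [i for i in range(3) if ref_codon[i] != codon[i]]
    if not diffs:
        raise SimulationError(
            f"replacement codon {codon} is identical to the reference codon"
        )
    if len(diffs) > 2:
        raise SimulationError(
            f"replacement {codon} differs from {ref_codon} in 3 bases; max 2"
        )
    mutated = ref[:start0] + codon + ref[start0 + 3 :]
    sub_pos0 = start0 + diffs[0]
    # Centre on the substitution, clamped into the reference.
    left = sub_pos0 - (oligo_length - 1) // 2
    left = max(0, min(left, len(ref) - oligo_length))
    window = mutated[left : left + oligo_length]
    if orientation == "antisense":
        window = str(Seq(window).reverse_complement())
    return LmoDesign(
        sequence=window,
        orientation=orientation,
        substitution_position=sub_pos0 + 1,
        window_start=left + 1,
        window_end=left + oligo_length,
    )
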