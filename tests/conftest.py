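import pytest

from mmrscreen.screen import (
    AllelePCR,
    ColonyObservation,
    ColonyPanel,
    Round,
    SequenceCall,
)


def make_panel(
    variant_id: str,
    n_loh: int,
    n_background: int,
    n_confirmed: int,
    round: Round = Round.ANTISENSE,
) -> ColonyPanel:
    """Build a panel from category counts (the usual test shorthand)."""
    colonies = []
    idx = 0
    for _ in range(n_loh):
        colonies.append(
            ColonyObservation(
                f"{variant_id}.c{idx}", AllelePCR.WT_ALLELE_LOST, SequenceCall.NOT_TESTED
            )
        )
        idx += 1
    for _ in range(n_background):
        colonies.append(
            ColonyObservation(
                f"{variant_id}.c{idx}",
                AllelePCR.BOTH_ALLELES_PRESENT,
                SequenceCall.NO_MUTATION,
            )
        )
        idx += 1
    for _ in range(n_confirmed):
        colonies.append(
            ColonyObservation(
                f"{variant_id}.c{idx}",
                AllelePCR.BOTH_ALLELES_PRESENT,
                SequenceCall.PLANNED_MUTATION,
            )
        )
        idx += 1
    return ColonyPanel(variant_id, round, colonies)


@pytest.fixture
def panel_factory():
    return make_panel
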