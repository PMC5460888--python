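"""Bundled study fixtures: the screened variant table and colony panels.

The tables transcribe the published screen: nine proof-of-principle
variants (five polymorphisms, four pathogenic mutations) and 26 variants of
uncertain significance, with one row per picked 6TG-resistant colony.
Truth labels (``prior_label``) mark the variants whose pathogenicity was
known a priori or established a posteriori; these drive the performance
evaluation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import io
from .screen import ColonyPanel, VariantRecord

__all__ = [
    "fixture_path",
    "load_variants",
    "load_colonies",
    "PROOF_OF_PRINCIPLE",
    "VUS_PANEL",
]

#: The nine proof-of-principle variant ids (5 polymorphisms + 4 pathogenic).
PROOF_OF_PRINCIPLE: tuple[str, ...] = (
    "PP_N1",
    "PP_N2",
    "PP_N3",
    "PP_N4",
    "L1087R",
    "V399E",
    "L450P",
    "G1139S",
    "R1334Q",
)

#: The 26 screened variants of uncertain significance.
VUS_PANEL: tuple[str, ...] = (
    "G686D",
    "L1063R",
    "E1193K",
    "T1219D",
    "T1219I",
    "R128L",
    "R468H",
    "V509A",
    "Y556F",
    "P623A",
    "S666P",
    "E983Q",
    "R1095C",
    "T1255M",
    "R1304K",
    "S285I",
    "G566R",
    "T1142M",
    "R511G",
    "A587P",
    "F706S",
    "A25S",
    "E221D",
    "G670R",
    "R922Q",
    "c.3438+6T>C",
)


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture file."""
    return Path(str(resources.files("mmrscreen").joinpath(f"data/{name}")))


def load_variants() -> list[VariantRecord]:
    return io.read_variants(fixture_path("variants.tsv"))


def load_colonies() -> dict[str, list[ColonyPanel]]:
    return io.read_colonies(fixture_path("colonies.tsv"))
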