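"""Readers and writers for the pipeline's tab-separated tables and JSON reports.

TSV is the canonical dialect: header mandatory, UTF-8, '.' as decimal mark,
rates in scientific notation with 4 significant digits, percents with one
decimal.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections import OrderedDict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .rates import (
    FluctuationExperiment,
    MutagenesisExperiment,
    MutationFrequencyResult,
    SlippageRateEstimate,
)
from .screen import (
    AllelePCR,
    CallOutcome,
    ColonyFractions,
    ColonyObservation,
    ColonyPanel,
    InsightClass,
    PerformanceReport,
    PriorLabel,
    Round,
    ScreenCall,
    SequenceCall,
    VariantRecord,
)

__all__ = [
    "TableError",
    "read_variants",
    "write_variants",
    "read_colonies",
    "write_colonies",
    "read_fluctuation",
    "write_fluctuation",
    "read_mnng",
    "write_mnng",
    "read_calls",
    "write_calls",
    "write_fractions",
    "write_performance",
    "read_performance",
    "write_rates_table",
    "write_mnng_frequencies",
]


class TableError(ValueError):
    """Malformed input table: missing column, unknown enum value, bad row."""


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_enum(cls, raw: str, path, row: int, column: str):
    try:
        return cls(raw)
    except ValueError:
        allowed = [m.value for m in cls]
        raise TableError(
            f"{path}, row {row}: unknown {column} value {raw!r} "
            f"(allowed: {allowed})"
        ) from None


def _parse_int(raw: str, path, row: int, column: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise TableError(
            f"{path}, row {row}: {column} must be an integer, got {raw!r}"
        ) from None


# ---------------------------------------------------------------- variants

_VARIANT_COLUMNS = [
    "variant_id",
    "human_aa_change",
    "mouse_aa_change",
    "nucleotide_change",
    "insight_class",
    "prior_label",
]


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = _read_tsv(path, _VARIANT_COLUMNS)
    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.variant_id in seen:
            raise TableError(f"{path}, row {i}: duplicate variant_id {row.variant_id!r}")
        seen.add(row.variant_id)
        records.append(
            VariantRecord(
                variant_id=row.variant_id,
                human_aa_change=row.human_aa_change,
                mouse_aa_change=row.mouse_aa_change,
                nucleotide_change=row.nucleotide_change,
                insight_class=_parse_enum(InsightClass, row.insight_class, path, i, "insight_class"),
                prior_label=_parse_enum(PriorLabel, row.prior_label, path, i, "prior_label"),
            )
        )
    return records


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "variant_id": r.variant_id,
            "human_aa_change": r.human_aa_change,
            "mouse_aa_change": r.mouse_aa_change,
            "nucleotide_change": r.nucleotide_change,
            "insight_class": r.insight_class.value,
            "prior_label": r.prior_label.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- colonies

_COLONY_COLUMNS = ["variant_id", "round", "colony_id", "allele_pcr", "sequence_call"]


def read_colonies(path: str | Path) -> dict[str, list[ColonyPanel]]:
    """Colony table -> panels grouped per variant, one per (variant, round).

    Rows for the same (variant, round) form one panel in file order; a
    variant appearing again after an intervening variant for the same round
    is a duplicate-panel error.
    """
    df = _read_tsv(path, _COLONY_COLUMNS)
    grouped: "OrderedDict[tuple[str, Round], list[ColonyObservation]]" = OrderedDict()
    last_key: tuple[str, Round] | None = None
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rnd = _parse_enum(Round, row.round, path, i, "round")
        key = (row.variant_id, rnd)
        if key in grouped and key != last_key:
            raise TableError(
                f"{path}, row {i}: duplicate panel for variant "
                f"{row.variant_id!r}, round {rnd.value!r}"
            )
        last_key = key
        obs = ColonyObservation(
            colony_id=row.colony_id,
            allele_pcr=_parse_enum(AllelePCR, row.allele_pcr, path, i, "allele_pcr"),
            sequence_call=_parse_enum(SequenceCall, row.sequence_call, path, i, "sequence_call"),
        )
        grouped.setdefault(key, []).append(obs)
    panels: dict[str, list[ColonyPanel]] = {}
    for (variant_id, rnd), colonies in grouped.items():
        panels.setdefault(variant_id, []).append(
            ColonyPanel(variant_id, rnd, colonies)
        )
    return panels


def write_colonies(
    panels: Sequence[ColonyPanel], path: str | Path
) -> None:
    rows = [
        {
            "variant_id": p.variant_id,
            "round": p.round.value,
            "colony_id": obs.colony_id,
            "allele_pcr": obs.allele_pcr.value,
            "sequence_call": obs.sequence_call.value,
        }
        for p in panels
        for obs in p.colonies
    ]
    pd.DataFrame(rows, columns=_COLONY_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- fluctuation

_FLUCT_COLUMNS = [
    "variant_id",
    "replicate",
    "n_expanded",
    "cells_per_plate",
    "n_plates",
    "geneticin_total",
]


def read_fluctuation(path: str | Path) -> list[FluctuationExperiment]:
    df = _read_tsv(path, _FLUCT_COLUMNS)
    grouped: "OrderedDict[str, dict]" = OrderedDict()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        entry = grouped.setdefault(
            row.variant_id,
            {
                "n_expanded": _parse_int(row.n_expanded, path, i, "n_expanded"),
                "cells_per_plate": _parse_int(row.cells_per_plate, path, i, "cells_per_plate"),
                "n_plates": _parse_int(row.n_plates, path, i, "n_plates"),
                "counts": [],
            },
        )
        try:
            entry["counts"].append(float(row.geneticin_total))
        except ValueError:
            raise TableError(
                f"{path}, row {i}: geneticin_total must be numeric, got "
                f"{row.geneticin_total!r}"
            ) from None
    return [
        FluctuationExperiment(
            variant_id=vid,
            replicates=e["counts"],
            n_expanded=e["n_expanded"],
            cells_per_plate=e["cells_per_plate"],
            n_plates=e["n_plates"],
        )
        for vid, e in grouped.items()
    ]


def write_fluctuation(
    experiments: Sequence[FluctuationExperiment], path: str | Path
) -> None:
    rows = [
        {
            "variant_id": e.variant_id,
            "replicate": j + 1,
            "n_expanded": e.n_expanded,
            "cells_per_plate": e.cells_per_plate,
            "n_plates": e.n_plates,
            "geneticin_total": count,
        }
        for e in experiments
        for j, count in enumerate(e.replicates)
    ]
    pd.DataFrame(rows, columns=_FLUCT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- mutagenesis

_MNNG_COLUMNS = ["variant_id", "dose_uM", "replicate", "cells_plated", "resistant_colonies"]


def read_mnng(path: str | Path) -> list[MutagenesisExperiment]:
    df = _read_tsv(path, _MNNG_COLUMNS)
    grouped: "OrderedDict[tuple[str, float], dict]" = OrderedDict()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            dose = float(row.dose_uM)
        except ValueError:
            raise TableError(f"{path}, row {i}: bad dose_uM {row.dose_uM!r}") from None
        entry = grouped.setdefault(
            (row.variant_id, dose),
            {"cells_plated": _parse_int(row.cells_plated, path, i, "cells_plated"), "counts": []},
        )
        entry["counts"].append(
            _parse_int(row.resistant_colonies, path, i, "resistant_colonies")
        )
    return [
        MutagenesisExperiment(
            variant_id=vid, dose_uM=dose, replicates=e["counts"],
            cells_plated=e["cells_plated"],
        )
        for (vid, dose), e in grouped.items()
    ]


def write_mnng(
    experiments: Sequence[MutagenesisExperiment], path: str | Path
) -> None:
    rows = [
        {
            "variant_id": e.variant_id,
            "dose_uM": _format_dose(e.dose_uM),
            "replicate": j + 1,
            "cells_plated": e.cells_plated,
            "resistant_colonies": count,
        }
        for e in experiments
        for j, count in enumerate(e.replicates)
    ]
    pd.DataFrame(rows, columns=_MNNG_COLUMNS).to_csv(path, sep="\t", index=False)


def _format_dose(dose: float) -> str:
    return str(int(dose)) if dose == int(dose) else repr(dose)


# ---------------------------------------------------------------- calls & reports

_CALL_COLUMNS = [
    "variant_id",
    "call",
    "n_confirmed",
    "n_loh",
    "n_background",
    "rounds_used",
]


def write_calls(calls: Sequence[ScreenCall], path: str | Path) -> None:
    rows = [
        {
            "variant_id": c.variant_id,
            "call": c.call.value,
            "n_confirmed": c.n_confirmed,
            "n_loh": c.n_loh,
            "n_background": c.n_background,
            "rounds_used": ",".join(r.value for r in c.rounds_used),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[ScreenCall]:
    df = _read_tsv(path, _CALL_COLUMNS)
    calls: list[ScreenCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rounds = tuple(
            _parse_enum(Round, r, path, i, "rounds_used")
            for r in row.rounds_used.split(",")
            if r
        )
        calls.append(
            ScreenCall(
                variant_id=row.variant_id,
                call=_parse_enum(CallOutcome, row.call, path, i, "call"),
                n_confirmed=_parse_int(row.n_confirmed, path, i, "n_confirmed"),
                n_loh=_parse_int(row.n_loh, path, i, "n_loh"),
                n_background=_parse_int(row.n_background, path, i, "n_background"),
                rounds_used=rounds,
            )
        )
    return calls


def write_fractions(
    fractions: Sequence[tuple[str, str, ColonyFractions]], path: str | Path
) -> None:
    """Per (variant, round) colony fractions, 4 decimal places."""
    rows = [
        {
            "variant_id": vid,
            "round": rnd,
            "f_loh": f"{float(fr.f_loh):.4f}",
            "f_background": f"{float(fr.f_background):.4f}",
            "f_confirmed": f"{float(fr.f_confirmed):.4f}",
        }
        for vid, rnd, fr in fractions
    ]
    pd.DataFrame(
        rows, columns=["variant_id", "round", "f_loh", "f_background", "f_confirmed"]
    ).to_csv(path, sep="\t", index=False)


def write_performance(report: PerformanceReport, path: str | Path) -> None:
    payload = dataclasses.asdict(report)
    payload["excluded_uncertain"] = list(report.excluded_uncertain)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_performance(path: str | Path) -> PerformanceReport:
    payload = json.loads(Path(path).read_text())
    payload["excluded_uncertain"] = tuple(payload["excluded_uncertain"])
    return PerformanceReport(**payload)


def _sci(x: float) -> str:
    return "nan" if math.isnan(x) else f"{x:.3e}"


def write_rates_table(
    rows: Sequence[dict], path: str | Path
) -> None:
    """Slippage-rate summary table.

    Each row dict carries: estimate (SlippageRateEstimate), fold_raw,
    fold_display, p_value, stars (any of the last four may be None for the
    reference line).
    """
    out = []
    for row in rows:
        est: SlippageRateEstimate = row["estimate"]
        out.append(
            {
                "variant_id": est.variant_id,
                "p_per_replicate": ";".join(_sci(p) for p in est.p_per_replicate),
                "p_mean": _sci(est.p_mean),
                "p_sd": _sci(est.p_sd),
                "below_detection": str(est.below_detection).lower(),
                "detection_limit": _sci(est.detection_limit),
                "fold_raw": "" if row.get("fold_raw") is None else _sci(row["fold_raw"]),
                "fold_display": ""
                if row.get("fold_display") is None
                else f"{row['fold_display']:g}",
                "p_value": "" if row.get("p_value") is None else f"{row['p_value']:.3e}",
                "stars": row.get("stars") or "",
            }
        )
    pd.DataFrame(
        out,
        columns=[
            "variant_id",
            "p_per_replicate",
            "p_mean",
            "p_sd",
            "below_detection",
            "detection_limit",
            "fold_raw",
            "fold_display",
            "p_value",
            "stars",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_mnng_frequencies(
    results: Sequence[MutationFrequencyResult], path: str | Path
) -> None:
    rows = [
        {
            "variant_id": r.variant_id,
            "dose_uM": _format_dose(r.dose_uM),
            "freq_per_replicate": ";".join(_sci(f) for f in r.freq_per_replicate),
            "freq_mean": _sci(r.freq_mean),
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["variant_id", "dose_uM", "freq_per_replicate", "freq_mean"]
    ).to_csv(path, sep="\t", index=False)
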