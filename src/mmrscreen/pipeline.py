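"""Stage orchestration: classify, evaluate, rates, mutagenesis, simulate, report.

Each ``run_*`` function is a thin deterministic wrapper around the analysis
modules: it reads the declared tables, runs the stage, writes the declared
outputs and logs record counts at every boundary so silent data loss is
impossible.  The CLI in :mod:`mmrscreen.cli` calls straight into these.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import io
from .rates import (
    LogBase,
    fold_change,
    mutation_frequency,
    round_fold_display,
    significance_stars,
    summarize_fluctuation,
    welch_one_tailed,
)
from .screen import (
    CallOutcome,
    ScreenCall,
    aggregate_rounds,
    call_variant,
    colony_fractions,
    screen_performance,
)
from .simulate import (
    FluctSimParams,
    default_screen_params,
    simulate_fluctuation_assay,
    simulate_mnng_assay,
    simulate_screen,
)

logger = logging.getLogger("mmrscreen")

__all__ = [
    "PipelineConfig",
    "run_classify",
    "run_evaluate",
    "run_rates",
    "run_mnng",
    "run_simulate",
    "run_report",
]


@dataclass
class PipelineConfig:
    """Paths and knobs shared by the pipeline stages."""

    variants: Path | None = None
    colonies: Path | None = None
    fluctuation: Path | None = None
    mnng: Path | None = None
    calls: Path | None = None
    performance: Path | None = None
    reference_id: str | None = None
    log_base: LogBase = LogBase.NATURAL
    rng_seed: int = 0
    outdir: Path = Path(".")
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("variants", "colonies", "fluctuation", "mnng", "calls",
                    "performance", "outdir"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        if "reference_id" in raw:
            kwargs["reference_id"] = raw["reference_id"]
        if "log_base" in raw:
            kwargs["log_base"] = LogBase(raw["log_base"])
        if "rng_seed" in raw:
            kwargs["rng_seed"] = int(raw["rng_seed"])
        if "simulation" in raw:
            kwargs["simulation"] = dict(raw["simulation"])
        return cls(**kwargs)


def _ensure_outdir(config: PipelineConfig) -> Path:
    config.outdir.mkdir(parents=True, exist_ok=True)
    return config.outdir


def run_classify(config: PipelineConfig) -> list[ScreenCall]:
    """variants + colonies -> calls.tsv and fractions.tsv."""
    if config.variants is None or config.colonies is None:
        raise io.TableError("run_classify needs variants and colonies paths")
    outdir = _ensure_outdir(config)
    variants = io.read_variants(config.variants)
    logger.info("read %d variants from %s", len(variants), config.variants)
    panels_by_variant = io.read_colonies(config.colonies)
    n_colonies = sum(
        p.n_picked for ps in panels_by_variant.values() for p in ps
    )
    logger.info(
        "read %d colonies in %d panels from %s",
        n_colonies,
        sum(len(ps) for ps in panels_by_variant.values()),
        config.colonies,
    )

    calls: list[ScreenCall] = []
    fractions: list[tuple[str, str, object]] = []
    n_empty = 0
    for variant in variants:
        panels = panels_by_variant.get(variant.variant_id, [])
        if not panels:
            n_empty += 1
            logger.warning(
                "variant %s has no colony panel; calling not_detected",
                variant.variant_id,
            )
            calls.append(
                ScreenCall(variant.variant_id, CallOutcome.NOT_DETECTED, 0, 0, 0, ())
            )
            continue
        merged = aggregate_rounds(panels)
        calls.append(call_variant(merged))
        for panel in panels:
            if panel.n_picked:
                fractions.append(
                    (variant.variant_id, panel.round.value, colony_fractions(panel))
                )

    by_call = {o: sum(c.call is o for c in calls) for o in CallOutcome}
    logger.info(
        "calls: %d mmr_abrogating, %d not_detected, %d inconclusive "
        "(%d variants without panels)",
        by_call[CallOutcome.MMR_ABROGATING],
        by_call[CallOutcome.NOT_DETECTED],
        by_call[CallOutcome.INCONCLUSIVE],
        n_empty,
    )
    io.write_calls(calls, outdir / "calls.tsv")
    io.write_fractions(fractions, outdir / "fractions.tsv")
    return calls


def run_evaluate(config: PipelineConfig):
    """calls + truth labels -> performance.json."""
    if config.variants is None:
        raise io.TableError("run_evaluate needs the variants (truth) path")
    calls_path = config.calls or config.outdir / "calls.tsv"
    outdir = _ensure_outdir(config)
    truth = io.read_variants(config.variants)
    calls = io.read_calls(calls_path)
    logger.info("evaluating %d calls against %d truth rows", len(calls), len(truth))
    report = screen_performance(calls, truth)
    logger.info(
        "sensitivity %d/%d (bound %.1f%%), specificity FP=%d/%d (bound %.1f%%), "
        "%d uncertain rows excluded",
        report.n_detected,
        report.n_pathogenic_truth,
        report.sensitivity_zero_failure_bound,
        report.n_false_positive,
        report.n_nonpathogenic_truth,
        report.specificity_zero_failure_bound,
        len(report.excluded_uncertain),
    )
    io.write_performance(report, outdir / "performance.json")
    return report


def run_rates(config: PipelineConfig) -> list[dict]:
    """fluctuation.tsv -> rates.tsv with folds and Welch stars vs reference."""
    if config.fluctuation is None:
        raise io.TableError("run_rates needs the fluctuation path")
    outdir = _ensure_outdir(config)
    experiments = io.read_fluctuation(config.fluctuation)
    logger.info(
        "read %d fluctuation experiments (%d replicates) from %s",
        len(experiments),
        sum(len(e.replicates) for e in experiments),
        config.fluctuation,
    )
    estimates = {
        e.variant_id: summarize_fluctuation(e, config.log_base) for e in experiments
    }
    reference = None
    if config.reference_id is not None:
        if config.reference_id not in estimates:
            raise io.TableError(
                f"reference id {config.reference_id!r} not present in "
                f"{config.fluctuation}"
            )
        reference = estimates[config.reference_id]

    rows: list[dict] = []
    for exp in experiments:
        est = estimates[exp.variant_id]
        row: dict = {"estimate": est}
        if reference is not None and exp.variant_id != config.reference_id:
            fold = fold_change(est.p_mean, reference.p_mean)
            row["fold_raw"] = fold
            row["fold_display"] = round_fold_display(fold)
            ref_reps = [p for p in reference.p_per_replicate if p == p]
            var_reps = [p for p in est.p_per_replicate if p == p]
            if len(ref_reps) >= 2 and len(var_reps) >= 2:
                welch = welch_one_tailed(var_reps, ref_reps)
                row["p_value"] = welch.p_one_tailed
                row["stars"] = significance_stars(welch.p_one_tailed)
        rows.append(row)
    io.write_rates_table(rows, outdir / "rates.tsv")
    logger.info("estimated slippage rates for %d cell lines", len(rows))
    return rows


def run_mnng(config: PipelineConfig):
    """mnng.tsv -> mnng_freq.tsv (frequency per plated cell, both arms)."""
    if config.mnng is None:
        raise io.TableError("run_mnng needs the mnng path")
    outdir = _ensure_outdir(config)
    experiments = io.read_mnng(config.mnng)
    logger.info("read %d mutagenesis arms from %s", len(experiments), config.mnng)
    results = [mutation_frequency(e) for e in experiments]
    io.write_mnng_frequencies(results, outdir / "mnng_freq.tsv")
    return results


def run_simulate(config: PipelineConfig) -> Path:
    """Emit a simulated dataset directory: colonies.tsv, fluctuation.tsv,
    mnng.tsv and a truth.json sidecar.

    ``config.simulation`` may carry: ``variants`` (list of {id, abrogates}),
    ``screen`` (ScreenSimParams overrides), ``fluctuation`` (list of
    {id, p_true} plus FluctSimParams overrides under ``params``), ``mnng``
    (list of {id, spontaneous_freq, induced_freq}).
    """
    outdir = _ensure_outdir(config)
    sim = config.simulation
    seed = config.rng_seed

    spec = sim.get("variants") or [
        {"id": "sim_pathogenic", "abrogates": True},
        {"id": "sim_neutral", "abrogates": False},
    ]
    variants = [(v["id"], bool(v["abrogates"])) for v in spec]
    params = default_screen_params(rng_seed=seed, **sim.get("screen", {}))
    panels, warnings = simulate_screen(variants, params)
    for message in warnings:
        logger.warning("%s", message)
    io.write_colonies([p for p in panels if p.n_picked], outdir / "colonies.tsv")

    fluct_spec = sim.get("fluctuation", [])
    if fluct_spec:
        experiments = []
        for j, entry in enumerate(fluct_spec):
            fp = FluctSimParams(
                p_true=float(entry["p_true"]),
                rng_seed=seed + 1000 + j,
                **entry.get("params", {}),
            )
            experiments.append(simulate_fluctuation_assay(fp, entry["id"]))
        io.write_fluctuation(experiments, outdir / "fluctuation.tsv")

    mnng_spec = sim.get("mnng", [])
    if mnng_spec:
        arms = []
        for j, entry in enumerate(mnng_spec):
            spont, induced = simulate_mnng_assay(
                float(entry["spontaneous_freq"]),
                float(entry["induced_freq"]),
                rng_seed=seed + 2000 + j,
                variant_id=entry["id"],
            )
            arms.extend([spont, induced])
        io.write_mnng(arms, outdir / "mnng.tsv")

    truth = {
        "rng_seed": seed,
        "variants": [
            {"id": vid, "abrogates": flag} for vid, flag in variants
        ],
        "empty_panels": [p.variant_id for p in panels if not p.n_picked],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    logger.info("simulated dataset written to %s", outdir)
    return outdir


def _md_table(header: Sequence[str], rows: Sequence[Sequence[str]]) -> list[str]:
    lines = ["| " + " | ".join(header) + " |"]
    lines.append("|" + "|".join(" --- " for _ in header) + "|")
    for row in rows:
        lines.append("| " + " | ".join(str(x) for x in row) + " |")
    return lines


def run_report(config: PipelineConfig) -> Path:
    """Collect stage outputs under ``outdir`` into a Markdown summary."""
    outdir = _ensure_outdir(config)
    lines: list[str] = ["# Screen analysis report", ""]

    calls_path = outdir / "calls.tsv"
    if calls_path.exists():
        calls = io.read_calls(calls_path)
        lines += ["## Variant calls", ""]
        lines += _md_table(
            ["variant", "call", "confirmed", "LOH", "background", "rounds"],
            [
                (
                    c.variant_id,
                    c.call.value,
                    c.n_confirmed,
                    c.n_loh,
                    c.n_background,
                    ",".join(r.value for r in c.rounds_used),
                )
                for c in calls
            ],
        )
        lines.append("")

    rates_path = outdir / "rates.tsv"
    if rates_path.exists():
        import pandas as pd

        df = pd.read_csv(rates_path, sep="\t", dtype=str, keep_default_na=False)
        lines += ["## Slippage rates", ""]
        lines += _md_table(list(df.columns), df.values.tolist())
        lines.append("")

    perf_path = outdir / "performance.json"
    if perf_path.exists():
        report = io.read_performance(perf_path)
        lines += ["## Screen performance", ""]
        lines += _md_table(
            ["metric", "value"],
            [
                ("pathogenic truth variants", report.n_pathogenic_truth),
                ("detected", report.n_detected),
                ("non-pathogenic truth variants", report.n_nonpathogenic_truth),
                ("false positives", report.n_false_positive),
                ("sensitivity point", f"{report.sensitivity_point:.1f}%"),
                ("specificity point", f"{report.specificity_point:.1f}%"),
                (
                    "sensitivity zero-failure bound",
                    f"{report.sensitivity_zero_failure_bound:.1f}%",
                ),
                (
                    "specificity zero-failure bound",
                    f"{report.specificity_zero_failure_bound:.1f}%",
                ),
            ],
        )
        lines.append("")

    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", path)
    return path
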