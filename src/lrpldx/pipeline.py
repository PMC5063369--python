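"""End-to-end orchestration: cutoffs -> NN combos -> rule search -> bootstrap.

A single master seed fans out deterministically to per-module seeds
through ``numpy.random.SeedSequence(master).generate_state(...)`` (taken
mod 2**31), so any module can be rerun in isolation with the seed printed
in the bundle.  Every artifact is a CSV or YAML file stamped with the
master seed and a hash of the full configuration; reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .bootstrap import BootstrapConfig, bootstrap_accuracy_compare
from .cohort import Cohort, Stage, read_cohort, summarize_cohort, write_cohort
from .cutoffs import Criterion, roc_curve, scan_cutoffs
from .metrics import format_percent
from .nn import NNConfig, evaluate_all_combos
from .rules import (
    RuleSpec,
    RuleTemplate,
    SearchResult,
    brute_force_search,
    compare_to_baseline,
)
from .synthetic import GeneratorConfig, generate_cohort, make_stage2_subset

__all__ = ["PipelineConfig", "ReportBundle", "run_stage", "derive_seeds"]


def derive_seeds(master: int, n: int = 6) -> list[int]:
    """Deterministic per-module seeds from one master seed (all < 2**31)."""
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass(frozen=True)
class PipelineConfig:
    stage: Stage = Stage.STAGE_I
    seed: int = 0
    input_csv: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stage2_subset_n: int = 410
    template: Optional[RuleTemplate] = None  # default: AND for I, STAGE2 for II
    fixed_miad_cutoff: Optional[float] = None
    nn: NNConfig = field(default_factory=NNConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    roc_bootstrap_replicates: int = 2000
    outdir: Optional[str] = None

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "stage" in raw:
            kwargs["stage"] = Stage[str(raw["stage"]).upper()]
        for key in (
            "seed",
            "input_csv",
            "stage2_subset_n",
            "fixed_miad_cutoff",
            "roc_bootstrap_replicates",
            "outdir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "template" in raw and raw["template"] is not None:
            kwargs["template"] = RuleTemplate(raw["template"])
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        if "nn" in raw:
            nn_raw = dict(raw["nn"])
            if "input_combo" in nn_raw:
                nn_raw["input_combo"] = tuple(nn_raw["input_combo"])
            kwargs["nn"] = NNConfig(**nn_raw)
        if "bootstrap" in raw:
            kwargs["bootstrap"] = BootstrapConfig(**raw["bootstrap"])
        return PipelineConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (Stage, RuleTemplate)):
            return o.name
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # hash covers the analysis, not where it lands
    blob = json.dumps(d, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ReportBundle:
    config: PipelineConfig
    cohort: Cohort
    summary: dict
    cutoff_table: pd.DataFrame
    roc: dict
    nn_table: pd.DataFrame
    search: SearchResult
    comparison: "pd.DataFrame | None"
    flowchart: dict
    bootstrap: "object"


def _build_cohort(config: PipelineConfig) -> tuple[Cohort, Optional[pd.DataFrame]]:
    seeds = derive_seeds(config.seed)
    if config.input_csv is not None:
        return read_cohort(config.input_csv, stage=config.stage), None
    gen = dataclasses.replace(config.generator, seed=seeds[0], stage=Stage.STAGE_I)
    cohort, sidecar = generate_cohort(gen)
    if config.stage is Stage.STAGE_II:
        cohort = make_stage2_subset(cohort, config.stage2_subset_n, seed=seeds[1])
    return cohort, sidecar


def _flowchart_counts(rule: RuleSpec, cohort: Cohort) -> dict:
    """Branch-by-branch node counts for the decision-flow diagram.

    Counts at every branch sum to the cohort total: each node is assigned
    to the first clause that decides it.
    """
    labels = cohort.labels
    miad = cohort.values("miad")
    maad = cohort.values("maad")
    macd = cohort.values("macd")
    remaining = np.ones(len(cohort), bool)

    def take(mask):
        nonlocal remaining
        sel = remaining & mask
        remaining = remaining & ~mask
        return {
            "n": int(sel.sum()),
            "label_positive": int((sel & labels).sum()),
            "label_negative": int((sel & ~labels).sum()),
        }

    out = {"total": len(cohort), "branches": {}}
    out["branches"]["miad_clause_positive"] = take(miad >= rule.c_miad)
    if rule.template is RuleTemplate.STAGE2_RULE:
        nsuv = cohort.values("nsuv")
        out["branches"]["nsuv_clause_positive"] = take(nsuv >= rule.c_nsuv)
    secondary = (maad >= rule.c_maad) & (macd >= rule.c_macd)
    if rule.template is RuleTemplate.OR_RULE:
        secondary = (maad >= rule.c_maad) | (macd >= rule.c_macd)
    out["branches"]["diameter_clause_positive"] = take(secondary)
    out["branches"]["negative"] = take(np.ones(len(cohort), bool))
    return out


def run_stage(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis for one stage and (optionally) write a bundle."""
    seeds = derive_seeds(config.seed)
    cohort, sidecar = _build_cohort(config)
    summary = summarize_cohort(cohort).as_dict()

    # per-parameter optimal cutoffs (both criteria) and ROC
    cutoff_rows = []
    scans = {}
    roc = {}
    for i, p in enumerate(cohort.stage.parameters):
        for crit in (Criterion.ACCURACY, Criterion.YOUDEN):
            sc = scan_cutoffs(cohort, p, crit)
            if crit is Criterion.ACCURACY:
                scans[p] = sc
            r = sc.best
            cutoff_rows.append(
                {
                    "parameter": p,
                    "criterion": crit.value,
                    "cutoff": r.cutoff,
                    "accuracy": float(r.accuracy),
                    "youden_j": None if r.youden_j is None else float(r.youden_j),
                    "n_correct": r.n_correct,
                    "n_total": r.n_total,
                }
            )
        roc[p] = roc_curve(
            cohort, p, n_boot=config.roc_bootstrap_replicates, seed=seeds[2] + i
        )
    cutoff_table = pd.DataFrame(cutoff_rows)

    # NN combination table (7 or 15 rows)
    nn_cfg = dataclasses.replace(config.nn, seed=seeds[3])
    evals = evaluate_all_combos(cohort, cohort.stage, nn_cfg)
    nn_rows = []
    for ev in evals:
        row = {"parameters": "+".join(p.upper() for p in ev.combo), "code": ev.code}
        c = ev.metrics.counts
        row.update(
            {
                "n_test": ev.n_test,
                "n_correct": c.tp + c.tn,
                "accuracy": float(ev.metrics.accuracy),
                "accuracy_display": format_percent(ev.metrics.accuracy),
            }
        )
        nn_rows.append(row)
    nn_table = pd.DataFrame(nn_rows)

    # combined-rule search
    template = config.template or (
        RuleTemplate.AND_RULE if cohort.stage is Stage.STAGE_I else RuleTemplate.STAGE2_RULE
    )
    search = brute_force_search(
        cohort,
        template,
        c_miad=config.fixed_miad_cutoff,
        audit_limit=0,
    )
    comparison = compare_to_baseline(search)
    flow = _flowchart_counts(search.best_rule, cohort)

    # bootstrap: combined rule vs the MIAD-only baseline
    baseline_rule = RuleSpec(template=template, c_miad=search.baseline.cutoff)
    boot_cfg = dataclasses.replace(config.bootstrap, seed=seeds[4])
    boot = bootstrap_accuracy_compare(cohort, search.best_rule, baseline_rule, boot_cfg)

    bundle = ReportBundle(
        config=config,
        cohort=cohort,
        summary=summary,
        cutoff_table=cutoff_table,
        roc=roc,
        nn_table=nn_table,
        search=search,
        comparison=comparison.ledger,
        flowchart=flow,
        bootstrap=boot,
    )
    if config.outdir is not None:
        _write_bundle(bundle, comparison, sidecar, Path(config.outdir))
    return bundle


def _write_bundle(bundle: ReportBundle, comparison, sidecar, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    stamp = {"seed": cfg.seed, "config_hash": _config_hash(cfg), "stage": cfg.stage.name}

    write_cohort(bundle.cohort, outdir / "cohort.csv")
    if sidecar is not None:
        sidecar.to_csv(outdir / "cohort_truth.csv", index=False)
    (outdir / "summary.yaml").write_text(
        yaml.safe_dump({**stamp, "cohort": bundle.summary}, sort_keys=True)
    )
    bundle.cutoff_table.to_csv(outdir / "cutoffs.csv", index=False)
    for p, r in bundle.roc.items():
        pd.DataFrame({"threshold": r.thresholds, "fpr": r.fpr, "tpr": r.tpr}).to_csv(
            outdir / f"roc_{p}.csv", index=False
        )
    auc = {
        p: {"auc": r.auc, "ci95_low": r.auc_ci95[0], "ci95_high": r.auc_ci95[1]}
        for p, r in bundle.roc.items()
    }
    (outdir / "auc.yaml").write_text(yaml.safe_dump({**stamp, "auc": auc}, sort_keys=True))
    bundle.nn_table.to_csv(outdir / "nn_combos.csv", index=False)

    s = bundle.search
    best = {
        **stamp,
        "rule": s.best_rule.as_dict(),
        "accuracy": float(s.metrics.accuracy),
        "accuracy_display": format_percent(s.metrics.accuracy),
        "baseline_cutoff_mm": s.baseline.cutoff,
        "baseline_accuracy": float(s.baseline.accuracy),
        "corrected_false_negatives": comparison.corrected_fn,
        "introduced_errors": comparison.introduced_errors,
        "net_corrected": comparison.net_corrected,
        "error_reduction_rate": float(comparison.error_reduction_rate),
        "error_reduction_display": format_percent(comparison.error_reduction_rate),
        "n_rules_evaluated": s.n_rules_evaluated,
    }
    (outdir / "best_rule.yaml").write_text(yaml.safe_dump(best, sort_keys=True))
    comparison.ledger.to_csv(outdir / "comparison_ledger.csv", index=False)
    (outdir / "flowchart.yaml").write_text(
        yaml.safe_dump({**stamp, **bundle.flowchart}, sort_keys=True)
    )

    b = bundle.bootstrap
    b.replicate_table().to_csv(outdir / "bootstrap_replicates.csv", index=False)
    (outdir / "bootstrap_summary.yaml").write_text(
        yaml.safe_dump(
            {
                **stamp,
                "summary_mode": b.summary_mode.value,
                "combined_rule": {
                    "summary": b.summary_a,
                    "ci95": [b.ci_a[0], b.ci_a[1]],
                },
                "baseline": {"summary": b.summary_b, "ci95": [b.ci_b[0], b.ci_b[1]]},
                "ci_overlap": bool(b.ci_overlap),
                "overlap_extent": b.overlap_extent,
                "t_statistic": b.t_statistic,
                "p_value": b.p_value,
            },
            sort_keys=True,
        )
    )
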