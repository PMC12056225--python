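"""End-to-end orchestration: read -> benchmark -> evaluate -> select -> classify.

``run_full_pipeline`` executes the whole workflow for every configured
cohort and writes a reproducible report bundle (TSV + JSON, no
timestamps): benchmark size summary, per-benchmark metric tables with a
mean row, selected workflows, classified-variant tables, a stage-count
summary, and per-capita / fold-change rates. ``audit`` re-derives the JSON
summary numbers from the emitted TSVs and reports any mismatch.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .benchmark import (
    BenchmarkSet, benchmark_summary, build_benchmark, filter_rare, merge_benchmarks,
)
from .classify import classify_pdv, classify_pov, extract_vus, stage_counts, write_classified
from .errors import ConfigError, DataError
from .metrics import evaluate_all_tools, fold_change, mean_row, per_capita_rate, performance_table
from .registry import call_matrix, get_registry
from .selection import SelectionPolicy, WorkflowSpec, cross_apply_workflows, select_top_tools
from .simulate import default_config, generate_cohort, write_truth_table
from .variant_model import read_variant_table, write_variant_table

log = logging.getLogger(__name__)

BENCHMARK_SOURCES = ("clinvar", "intervar", "merged")


@dataclass
class CohortInput:
    """One cohort's input: a file (path + dialect) or synthetic."""

    name: str
    path: str | None = None
    dialect: str = "tsv"


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    mode: str = "synthetic"  # synthetic | files
    seed: int = 0
    scale: float = 1.0
    inputs: list[CohortInput] = field(default_factory=list)
    registry_path: str | None = None
    rare_threshold: float = 0.01
    pop_af_max: float = 0.01
    min_agree: int = 0  # 0 = unanimity
    selection_benchmark: str = "intervar"  # benchmark driving tool selection
    conflict_policy: str = "clinvar_wins"
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            if not self.inputs:
                raise ConfigError("files mode requires at least one cohort input")
            for ci in self.inputs:
                if ci.path is None or not Path(ci.path).exists():
                    raise ConfigError(f"input path missing for cohort {ci.name}: {ci.path}")
        if self.registry_path is not None and not Path(self.registry_path).exists():
            raise ConfigError(f"registry file not found: {self.registry_path}")
        if not (0 < self.rare_threshold <= 0.5):
            raise ConfigError("rare_threshold must be in (0, 0.5]")
        if not (0 < self.pop_af_max <= 1):
            raise ConfigError("pop_af_max must be in (0, 1]")
        if self.selection_benchmark not in BENCHMARK_SOURCES:
            raise ConfigError(f"unknown selection benchmark {self.selection_benchmark!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        policy = SelectionPolicy(**data.pop("policy", {}))
        inputs = [CohortInput(**ci) for ci in data.pop("inputs", [])]
        try:
            return cls(policy=policy, inputs=inputs, **data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def canonical(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "scale": self.scale,
            "inputs": [vars(ci) for ci in self.inputs],
            "registry_path": self.registry_path,
            "rare_threshold": self.rare_threshold,
            "pop_af_max": self.pop_af_max,
            "min_agree": self.min_agree,
            "selection_benchmark": self.selection_benchmark,
            "conflict_policy": self.conflict_policy,
            "policy": {
                "fpr_max": self.policy.fpr_max,
                "top_n": self.policy.top_n,
                "rank_by": self.policy.rank_by,
                "collapse_families": self.policy.collapse_families,
                "exclude_scopes": sorted(self.policy.exclude_scopes),
            },
        }


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _metrics_tsv(perfs, path: Path) -> None:
    """Metric table TSV with an appended mean row (undefined skipped)."""
    table = performance_table(perfs)
    means = {"tool": "Mean"}
    for m in ("sensitivity", "specificity", "fpr", "fnr", "mcc"):
        vals = [p.metric(m) for p in perfs]
        usable = [v for v in vals if v is not None]
        means[m] = round(float(pd.Series(usable).mean()), 2) if usable else float("nan")
    table = pd.concat([table, pd.DataFrame([means])], ignore_index=True)
    table.to_csv(path, sep="\t", index=False)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary.

    Any stage failure removes partially written outputs before re-raising
    with the stage name.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for p in out.iterdir():
                if p.is_file():
                    p.unlink()
        raise


def _run(config: PipelineConfig, out: Path) -> dict:
    registry = get_registry(config.registry_path)
    stage = "setup"
    try:
        # ------------------------------------------------------ inputs
        stage = "read"
        cohorts: dict[str, list] = {}
        if config.mode == "synthetic":
            syn = default_config(config.seed, scale=config.scale)
            for cc in syn.cohorts:
                variants, truths = generate_cohort(syn, cc.name, registry)
                cohorts[cc.name] = variants
                write_variant_table(variants, out / f"variants_{cc.name}.tsv", registry)
                write_truth_table(truths, out / f"truth_{cc.name}.tsv")
        else:
            for ci in config.inputs:
                cohorts[ci.name] = read_variant_table(
                    ci.path, dialect=ci.dialect, cohort=ci.name, registry=registry
                )

        summary: dict = {"cohorts": {}, "config_hash": _config_hash(config)}
        benchmarks: dict[str, dict[str, BenchmarkSet]] = {}
        workflows: dict[str, WorkflowSpec] = {}
        vus_sets: dict[str, list] = {}
        call_tables: dict[str, pd.DataFrame] = {}
        classified: dict[str, list] = {}

        for name, variants in cohorts.items():
            entry: dict = {"n_input": len(variants)}
            # -------------------------------------------------- rare filter
            stage = f"rare_filter[{name}]"
            rare = filter_rare(variants, config.rare_threshold)
            entry["n_rare"] = len(rare)
            # -------------------------------------------------- benchmarks
            stage = f"benchmark[{name}]"
            cv = build_benchmark(rare, "clinvar")
            iv = build_benchmark(rare, "intervar")
            merged = merge_benchmarks(cv, iv, config.conflict_policy)
            benchmarks[name] = {"clinvar": cv, "intervar": iv, "merged": merged}
            entry["benchmark"] = {
                s: {"positives": b.n_positive, "negatives": b.n_negative}
                for s, b in benchmarks[name].items()
            }
            # -------------------------------------------------- call matrix
            stage = f"call_matrix[{name}]"
            calls = call_matrix(rare, registry=registry)
            call_tables[name] = calls
            # -------------------------------------------------- metrics
            stage = f"metrics[{name}]"
            perf_by_source = {}
            for source, bench in benchmarks[name].items():
                perfs = evaluate_all_tools(bench, calls)
                perf_by_source[source] = perfs
                _metrics_tsv(perfs, out / f"metrics_{name}_{source}.tsv")
            # -------------------------------------------------- selection
            stage = f"selection[{name}]"
            wf = select_top_tools(
                perf_by_source[config.selection_benchmark],
                registry,
                config.policy,
                cohort=name,
                min_agree=config.min_agree,
            )
            workflows[name] = wf
            wf.to_yaml(out / f"workflow_{name}.yaml")
            entry["workflow"] = {"tools": wf.tools, "min_agree": wf.min_agree}
            # -------------------------------------------------- classification
            stage = f"classify[{name}]"
            vus = extract_vus(rare, merged, config.pop_af_max)
            vus_sets[name] = vus
            cls = classify_pdv(vus, wf, calls)
            cls = classify_pov(cls, vus)
            classified[name] = cls
            write_classified(cls, out / f"classified_{name}.tsv")
            entry["stages"] = stage_counts(cls)
            # -------------------------------------------------- rates
            stage = f"rates[{name}]"
            n_pat = _n_patients(config, name)
            n_pv = merged.n_positive
            n_pov = entry["stages"]["pov"]
            entry["rates"] = {
                "n_patients": n_pat,
                "pv_per_patient": round(per_capita_rate(n_pv, n_pat), 2),
                "pv_pov_per_patient": round(per_capita_rate(n_pv + n_pov, n_pat), 2),
            }
            summary["cohorts"][name] = entry

        # ------------------------------------------------------ cross-cohort
        names = list(cohorts)
        if len(names) == 2:
            stage = "cross_workflows"
            a, b = names
            summary["cross_workflow"] = {}
            for own, other in ((a, b), (b, a)):
                rep = cross_apply_workflows(
                    vus_sets[own], workflows[own], workflows[other], call_tables[own]
                )
                summary["cross_workflow"][own] = {
                    "own_pdv": rep.own_pdv,
                    "other_pdv": rep.other_pdv,
                    "delta": rep.delta,
                    "pct_change": rep.pct_change,
                    "own_unique_pdv": rep.own_unique_pdv,
                    "other_unique_pdv": rep.other_unique_pdv,
                    "unique_delta": rep.unique_delta,
                    "unique_pct_change": rep.unique_pct_change,
                }
            stage = "fold_changes"
            ca, cb = summary["cohorts"][a], summary["cohorts"][b]
            summary["fold_changes"] = {
                f"snv_{a}_over_{b}": _round_fold(ca["n_input"], cb["n_input"]),
                f"rare_{a}_over_{b}": _round_fold(ca["n_rare"], cb["n_rare"]),
                f"pdv_rate_{a}_over_{b}": _round_fold_rate(
                    ca["stages"]["pdv"], ca["n_rare"], cb["stages"]["pdv"], cb["n_rare"]
                ),
                f"pov_rate_{a}_over_{b}": _round_fold_rate(
                    ca["stages"]["pov"], ca["n_rare"], cb["stages"]["pov"], cb["n_rare"]
                ),
            }

        stage = "write_summary"
        _write_json(benchmark_summary(
            [b for per in benchmarks.values() for b in per.values()]
        ), out / "benchmark_summary.json")
        _write_json(summary, out / "summary.json")
        _write_json(
            {
                "package": "vpptbench",
                "version": __version__,
                "config": config.canonical(),
                "config_hash": _config_hash(config),
                "registry_size": len(registry),
            },
            out / "manifest.json",
        )
        return summary
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _n_patients(config: PipelineConfig, cohort: str) -> int:
    if config.mode == "synthetic":
        syn = default_config(config.seed, scale=config.scale)
        return syn.cohort(cohort).n_patients
    return 50  # files mode: override via config in future; study cohorts are 50


def _round_fold(a: int, b: int) -> float | None:
    f = fold_change(a, b)
    return round(f, 2) if f is not None else None


def _round_fold_rate(a: int, ad: int, b: int, bd: int) -> float | None:
    if min(ad, bd) < 1 or b == 0:
        return None
    f = fold_change(a, b, num_denom=ad, den_denom=bd, mode="rate_ratio")
    return round(f, 2) if f is not None else None


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.canonical(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def audit(out_dir: str | Path) -> list[str]:
    """Check that summary.json stage counts match the emitted TSVs.

    Returns a list of discrepancy messages (empty when consistent).
    """
    out = Path(out_dir)
    problems: list[str] = []
    try:
        summary = json.loads((out / "summary.json").read_text())
    except FileNotFoundError:
        return [f"missing summary.json in {out}"]
    for cohort, entry in summary.get("cohorts", {}).items():
        path = out / f"classified_{cohort}.tsv"
        if not path.exists():
            problems.append(f"{cohort}: missing {path.name}")
            continue
        df = pd.read_csv(path, sep="\t")
        n_pov = int((df["stage"] == "pov").sum())
        n_pdv = n_pov + int((df["stage"] == "pdv").sum())
        got = {"vus": len(df), "pdv": n_pdv, "pov": n_pov}
        if got != entry["stages"]:
            problems.append(f"{cohort}: summary stages {entry['stages']} != recount {got}")
        bench = json.loads((out / "benchmark_summary.json").read_text())
        if bench.get(cohort) != entry["benchmark"]:
            problems.append(f"{cohort}: benchmark summary mismatch")
    return problems
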