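"""Ancestry-specific top-tool workflow selection and cross-workflow checks.

A workflow is an ordered list of tools plus a consensus threshold used by
the VUS classifier. Selection from a per-tool performance table proceeds:

1. drop tools with FPR above ``fpr_max`` (default 0.3, strictly above);
2. drop tools whose scope is excluded (default: non-coding-only tools);
3. optionally keep only the best-ranked member of each tool family
   (near-duplicate score variants of one model);
4. rank the remainder by the rank metric (default sensitivity) descending,
   breaking ties by lower FPR, then higher MCC, then name;
5. take the top ``top_n`` (default 10).

Ranking by sensitivity with family collapse reproduces the published
African and European 10-tool sets from the packaged reference metric table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .registry import ToolRegistry, get_registry

log = logging.getLogger(__name__)


class PerformanceRow(Protocol):
    tool: str
    sensitivity: float | None
    fpr: float | None
    mcc: float | None


@dataclass(frozen=True)
class MetricRow:
    """Minimal per-tool metric record (enough to drive selection)."""

    tool: str
    sensitivity: float | None = None
    specificity: float | None = None
    fpr: float | None = None
    fnr: float | None = None
    mcc: float | None = None


@dataclass(frozen=True)
class SelectionPolicy:
    """Knobs of the top-tool selection procedure."""

    fpr_max: float = 0.3
    top_n: int = 10
    rank_by: str = "sensitivity"  # sensitivity | mcc
    collapse_families: bool = True
    exclude_scopes: frozenset[str] = frozenset({"noncoding_only"})
    # tie-break: lower FPR, then higher MCC, then name

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if not (0 < self.fpr_max <= 1):
            raise ConfigError("fpr_max must be in (0, 1]")
        if self.rank_by not in ("sensitivity", "mcc"):
            raise ConfigError(f"rank_by must be sensitivity or mcc, got {self.rank_by!r}")


@dataclass
class WorkflowSpec:
    """An ordered ancestry-specific tool list with its consensus rule."""

    cohort: str
    tools: list[str]
    min_agree: int = 0  # 0 -> unanimity (set in __post_init__)

    def __post_init__(self) -> None:
        if len(set(self.tools)) != len(self.tools):
            raise ConfigError("workflow tools must be unique")
        if self.min_agree == 0:
            self.min_agree = len(self.tools)
        if not (1 <= self.min_agree <= len(self.tools)):
            raise ConfigError(
                f"min_agree must be in [1, {len(self.tools)}], got {self.min_agree}"
            )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"cohort": self.cohort, "tools": list(self.tools), "min_agree": self.min_agree},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(cohort=data["cohort"], tools=list(data["tools"]),
                       min_agree=int(data.get("min_agree", 0)))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: malformed workflow file: {exc}") from exc


def _rank_value(row: PerformanceRow, metric: str) -> float:
    val = getattr(row, metric)
    return float("-inf") if val is None else val


def select_top_tools(
    perfs: Sequence[PerformanceRow],
    registry: ToolRegistry | None = None,
    policy: SelectionPolicy | None = None,
    cohort: str = "",
    min_agree: int = 0,
) -> WorkflowSpec:
    """Select the top-``n`` workflow from a per-tool performance table.

    Deterministic: the result is invariant to the order of ``perfs``. If
    fewer than ``top_n`` tools survive the exclusions, all eligible tools
    are returned with a warning.
    """
    registry = registry or get_registry()
    policy = policy or SelectionPolicy()
    eligible: list[PerformanceRow] = []
    for row in perfs:
        spec = registry.get(row.tool)
        if row.fpr is not None and row.fpr > policy.fpr_max:
            continue
        if spec.scope in policy.exclude_scopes:
            continue
        eligible.append(row)
    if policy.collapse_families:
        best: dict[str, PerformanceRow] = {}
        for row in eligible:
            fam = registry.get(row.tool).family
            cur = best.get(fam)
            if cur is None or _sort_key(row, policy) < _sort_key(cur, policy):
                best[fam] = row
        eligible = list(best.values())
    eligible.sort(key=lambda r: _sort_key(r, policy))
    if len(eligible) < policy.top_n:
        log.warning(
            "only %d tools eligible for top-%d selection", len(eligible), policy.top_n
        )
    chosen = eligible[: policy.top_n]
    return WorkflowSpec(cohort=cohort, tools=[r.tool for r in chosen], min_agree=min_agree)


def _sort_key(row: PerformanceRow, policy: SelectionPolicy):
    return (
        -_rank_value(row, policy.rank_by),
        row.fpr if row.fpr is not None else float("inf"),
        -(row.mcc if row.mcc is not None else float("-inf")),
        row.tool,
    )


@dataclass
class CrossWorkflowReport:
    """PDV counts under a cohort's own vs the alternative workflow."""

    cohort: str
    own_pdv: int
    other_pdv: int
    own_unique_pdv: int    # consensus over the own workflow's non-shared tools
    other_unique_pdv: int  # consensus over the other workflow's non-shared tools

    @property
    def delta(self) -> int:
        return self.other_pdv - self.own_pdv

    @property
    def pct_change(self) -> float | None:
        return percentage_change(self.own_pdv, self.other_pdv)

    @property
    def unique_delta(self) -> int:
        return self.other_unique_pdv - self.own_unique_pdv

    @property
    def unique_pct_change(self) -> float | None:
        return percentage_change(self.own_unique_pdv, self.other_unique_pdv)


def percentage_change(own: int, other: int, decimals: int = 1) -> float | None:
    """(other - own) / own as a percentage, rounded; None when own == 0."""
    if own == 0:
        return None
    return round(100.0 * (other - own) / own, decimals)


def cross_apply_workflows(
    vus,
    own: WorkflowSpec,
    other: WorkflowSpec,
    calls: pd.DataFrame,
) -> CrossWorkflowReport:
    """Compare PDV yield of a cohort's own workflow against the alternative.

    Also re-runs the comparison restricted to each workflow's unique
    (non-shared) tools, with the consensus threshold scaled to the subset:
    unanimity stays unanimity; otherwise ``min(min_agree, subset size)``.
    Identical workflows yield an all-zero-delta report.
    """
    from .classify import classify_pdv  # local import to avoid a cycle

    shared = set(own.tools) & set(other.tools)
    own_unique = [t for t in own.tools if t not in shared]
    other_unique = [t for t in other.tools if t not in shared]

    def n_pdv(workflow: WorkflowSpec) -> int:
        return sum(c.stage.value != "vus" for c in classify_pdv(vus, workflow, calls))

    def subset_wf(parent: WorkflowSpec, tools: list[str]) -> WorkflowSpec | None:
        if not tools:
            return None
        if parent.min_agree == len(parent.tools):
            agree = len(tools)
        else:
            agree = min(parent.min_agree, len(tools))
        return WorkflowSpec(cohort=parent.cohort, tools=tools, min_agree=agree)

    own_n = n_pdv(own)
    other_n = own_n if own.tools == other.tools and own.min_agree == other.min_agree \
        else n_pdv(WorkflowSpec(cohort=own.cohort, tools=list(other.tools),
                                min_agree=other.min_agree))
    wf_ou = subset_wf(own, own_unique)
    wf_tu = subset_wf(other, other_unique)
    own_u = n_pdv(wf_ou) if wf_ou else 0
    other_u = n_pdv(wf_tu) if wf_tu else 0
    return CrossWorkflowReport(
        cohort=own.cohort,
        own_pdv=own_n,
        other_pdv=other_n,
        own_unique_pdv=own_u,
        other_unique_pdv=other_u,
    )


# ---------------------------------------------------------------------------
# packaged reference fixtures

def load_reference_metrics(path: str | Path | None = None) -> dict[str, list[MetricRow]]:
    """Load the packaged per-tool reference metric table.

    Returns ``{"AFR": [MetricRow, ...], "EUR": [...]}`` — the published
    54-tool sensitivity/specificity/FPR/FNR/MCC values on the African and
    European ACMG-AMP-classified benchmark cohorts.
    """
    if path is None:
        ref = resources.files("vpptbench.data") / "reference_tool_metrics.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out: dict[str, list[MetricRow]] = {}
    for cohort in ("AFR", "EUR"):
        rows = []
        for _, r in df.iterrows():
            rows.append(
                MetricRow(
                    tool=str(r["tool"]),
                    sensitivity=float(r[f"sen_{cohort}"]),
                    specificity=float(r[f"spec_{cohort}"]),
                    fpr=float(r[f"fpr_{cohort}"]),
                    fnr=float(r[f"fnr_{cohort}"]),
                    mcc=float(r[f"mcc_{cohort}"]),
                )
            )
        out[cohort] = rows
    return out


def load_reference_counts(path: str | Path | None = None) -> dict:
    """Load the packaged cohort-level count summary (patients, SNVs, sets)."""
    if path is None:
        ref = resources.files("vpptbench.data") / "reference_cohort_counts.yaml"
        with resources.as_file(ref) as p:
            text = p.read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)["cohorts"]
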