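"""VUS -> PDV -> POV classification.

Rare variants that are neither benchmark positives nor negatives, and not
common in the global population reference (gnomAD-style AF <= 1%), are
variants of unknown significance (VUS). A VUS becomes a potentially
deleterious variant (PDV) when either (a) the ancestry-specific workflow's
tools reach consensus (at least ``min_agree`` deleterious calls, no-calls
counting as not-deleterious), or (b) its consequence is stop-gain or
canonical splice-site — the automatic ACMG-AMP-style inclusion route. A
PDV becomes a potentially oncogenic variant (POV) when flagged as
predicted loss-of-function (pLoF) or as oncogenic by a Cancer Genome
Interpreter-style annotation; the two routes are unioned and deduplicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .benchmark import BenchmarkSet
from .errors import ConfigError, DataError
from .registry import DELETERIOUS
from .selection import WorkflowSpec
from .variant_model import AnnotatedVariant, Consequence, VariantKey

log = logging.getLogger(__name__)


class Stage(str, Enum):
    vus = "vus"
    pdv = "pdv"
    pov = "pov"


class PdvReason(str, Enum):
    consensus = "consensus"
    stop_gain = "stop_gain"
    splice = "splice"
    none = "none"


@dataclass
class ClassifiedVariant:
    """One VUS with its classification stage and the reasons it advanced."""

    key: VariantKey
    stage: Stage
    pdv_reason: PdvReason = PdvReason.none
    pov_reason: frozenset[str] = frozenset()  # subset of {"plof", "cgi"}

    def __post_init__(self) -> None:
        if self.stage == Stage.pov and not self.pov_reason:
            raise DataError(f"{self.key}: POV without a reason")
        if self.stage != Stage.pov and self.pov_reason:
            raise DataError(f"{self.key}: pov_reason set on non-POV")
        if self.stage in (Stage.pdv, Stage.pov) and self.pdv_reason == PdvReason.none:
            raise DataError(f"{self.key}: PDV without a reason")


def extract_vus(
    variants: Iterable[AnnotatedVariant],
    benchmark: BenchmarkSet,
    pop_af_max: float = 0.01,
) -> list[AnnotatedVariant]:
    """Drop benchmark PVs/BVs and globally common variants.

    A variant with population AF strictly above ``pop_af_max`` is excluded;
    missing population AF is retained (absence from the reference panel is
    itself evidence of rarity).
    """
    if not (0 < pop_af_max <= 1):
        raise ConfigError(f"pop_af_max must be in (0, 1], got {pop_af_max}")
    known = benchmark.keys
    out = []
    for v in variants:
        if v.key in known:
            continue
        if v.pop_af is not None and v.pop_af > pop_af_max:
            continue
        out.append(v)
    return out


_AUTO_PDV = {Consequence.stop_gain: PdvReason.stop_gain, Consequence.splice: PdvReason.splice}


def classify_pdv(
    vus: Sequence[AnnotatedVariant],
    workflow: WorkflowSpec,
    calls: pd.DataFrame,
) -> list[ClassifiedVariant]:
    """Apply the consensus + stop-gain/splice PDV rules to a VUS set.

    Consensus takes precedence in the recorded reason when both routes
    fire. Raises if a workflow tool is missing from the call table.
    """
    missing = [t for t in workflow.tools if t not in calls.columns]
    if missing:
        raise ConfigError(f"workflow tools absent from call table: {missing}")
    out: list[ClassifiedVariant] = []
    sub = calls[workflow.tools]
    for v in vus:
        if v.key not in sub.index:
            raise DataError(f"VUS key {v.key} absent from call table")
        n_del = int((sub.loc[v.key].to_numpy() == DELETERIOUS).sum())
        consensus = n_del >= workflow.min_agree
        auto = _AUTO_PDV.get(v.consequence)
        if consensus:
            out.append(ClassifiedVariant(v.key, Stage.pdv, PdvReason.consensus))
        elif auto is not None:
            out.append(ClassifiedVariant(v.key, Stage.pdv, auto))
        else:
            out.append(ClassifiedVariant(v.key, Stage.vus))
    n_pdv = sum(c.stage == Stage.pdv for c in out)
    log.info("classify_pdv(%s): %d/%d VUS -> PDV", workflow.cohort, n_pdv, len(out))
    return out


def classify_pov(
    pdvs: Sequence[ClassifiedVariant],
    variants: Mapping[VariantKey, AnnotatedVariant] | Sequence[AnnotatedVariant],
) -> list[ClassifiedVariant]:
    """Promote PDVs carrying a pLoF or oncogenicity flag to POV.

    Returns a new classification list; non-PDV entries pass through
    unchanged. ``pov_reason`` records every contributing flag.
    """
    if not isinstance(variants, Mapping):
        variants = {v.key: v for v in variants}
    out: list[ClassifiedVariant] = []
    for c in pdvs:
        if c.stage != Stage.pdv:
            out.append(c)
            continue
        v = variants.get(c.key)
        if v is None:
            raise DataError(f"PDV key {c.key} missing from annotation lookup")
        reasons = set()
        if v.plof:
            reasons.add("plof")
        if v.cgi_oncogenic:
            reasons.add("cgi")
        if reasons:
            out.append(
                ClassifiedVariant(c.key, Stage.pov, c.pdv_reason, frozenset(reasons))
            )
        else:
            out.append(c)
    n_pov = sum(c.stage == Stage.pov for c in out)
    log.info("classify_pov: %d POV among %d records", n_pov, len(out))
    return out


def stage_counts(classified: Sequence[ClassifiedVariant]) -> dict[str, int]:
    """Nested totals: POV <= PDV <= VUS (each stage includes the next)."""
    n_pov = sum(c.stage == Stage.pov for c in classified)
    n_pdv = n_pov + sum(c.stage == Stage.pdv for c in classified)
    return {"vus": len(classified), "pdv": n_pdv, "pov": n_pov}


def write_classified(classified: Sequence[ClassifiedVariant], path) -> None:
    """TSV: key, stage, pdv_reason, pov_reasons (sorted, comma-joined)."""
    with open(path, "w") as fh:
        fh.write("key\tstage\tpdv_reason\tpov_reasons\n")
        for c in sorted(classified, key=lambda c: c.key):
            fh.write(
                f"{c.key}\t{c.stage.value}\t{c.pdv_reason.value}\t"
                f"{','.join(sorted(c.pov_reason)) or '.'}\n"
            )
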