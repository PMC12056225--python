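"""Benchmark construction from clinical-significance labels.

Positive variants (PVs) are those classified Pathogenic or Likely
pathogenic, benign variants (BVs) those classified Benign or Likely benign,
either by ClinVar or by the InterVar implementation of the ACMG-AMP
criteria. Benchmarks are built per cohort on rare variants (cohort MAF
below 1%) and the two sources can be merged with configurable conflict
handling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .errors import ConfigError, DataError
from .variant_model import AnnotatedVariant, VariantKey

log = logging.getLogger(__name__)

SOURCES = ("clinvar", "intervar")


class ClinicalCall(str, Enum):
    """Coarse clinical classification parsed from a raw label string."""

    positive = "positive"      # Pathogenic / Likely pathogenic
    negative = "negative"      # Benign / Likely benign
    vus = "vus"                # Uncertain significance
    unclassified = "unclassified"  # conflicting, drug response, empty, ...


_POS = {"pathogenic", "likely pathogenic"}
_NEG = {"benign", "likely benign"}
_VUS = {"uncertain significance", "uncertain", "vus"}


def parse_clinical_label(raw: str | None, source: str = "clinvar") -> ClinicalCall:
    """Map a raw ClinVar/InterVar string to a :class:`ClinicalCall`.

    Case-insensitive and underscore/space tolerant. Slash- or
    comma-combined labels (e.g. ``Benign/Likely_benign``) resolve to a
    class only when every component agrees in polarity; anything
    conflicting, uninterpretable or empty is ``unclassified``. Total
    function: never raises.
    """
    if source not in SOURCES:
        raise ConfigError(f"unknown label source {source!r}")
    if raw is None:
        return ClinicalCall.unclassified
    text = re.sub(r"[_\s]+", " ", str(raw)).strip().lower()
    if not text:
        return ClinicalCall.unclassified
    if "conflicting" in text:
        return ClinicalCall.unclassified
    parts = [p.strip() for p in re.split(r"[/,;|]", text) if p.strip()]
    if not parts:
        return ClinicalCall.unclassified
    calls = set()
    for p in parts:
        if p in _POS:
            calls.add(ClinicalCall.positive)
        elif p in _NEG:
            calls.add(ClinicalCall.negative)
        elif p in _VUS:
            calls.add(ClinicalCall.vus)
        else:
            calls.add(ClinicalCall.unclassified)
    if len(calls) == 1:
        return calls.pop()
    return ClinicalCall.unclassified


@dataclass
class BenchmarkSet:
    """Positive (PV) and negative (BV) variant-key sets for one cohort."""

    source: str  # clinvar | intervar | merged
    cohort: str
    positives: set[VariantKey] = field(default_factory=set)
    negatives: set[VariantKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise DataError(
                f"benchmark {self.source}/{self.cohort}: {len(overlap)} keys in both sets"
            )

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        return len(self.negatives)

    @property
    def keys(self) -> set[VariantKey]:
        return self.positives | self.negatives


def filter_rare(
    variants: Iterable[AnnotatedVariant], threshold: float = 0.01
) -> list[AnnotatedVariant]:
    """Keep variants with cohort MAF strictly below ``threshold``.

    A missing cohort MAF is retained (a cohort-private variant is by
    construction rare); the number of such records is logged.
    """
    if not (0 < threshold <= 0.5):
        raise ConfigError(f"rare-variant threshold must be in (0, 0.5], got {threshold}")
    out: list[AnnotatedVariant] = []
    n_missing = 0
    for v in variants:
        if v.cohort_maf is None:
            n_missing += 1
            out.append(v)
        elif v.cohort_maf < threshold:
            out.append(v)
    if n_missing:
        log.info("filter_rare: %d variants retained with missing cohort MAF", n_missing)
    return out


def build_benchmark(
    variants: Sequence[AnnotatedVariant], source: str
) -> BenchmarkSet:
    """Populate PV/BV sets from one label source on rare-filtered variants."""
    if source not in SOURCES:
        raise ConfigError(f"unknown benchmark source {source!r}")
    if not variants:
        log.warning("build_benchmark(%s): empty input, empty benchmark", source)
        return BenchmarkSet(source=source, cohort="", positives=set(), negatives=set())
    cohort = variants[0].cohort
    pos: set[VariantKey] = set()
    neg: set[VariantKey] = set()
    for v in variants:
        raw = v.clinvar_label if source == "clinvar" else v.intervar_label
        call = parse_clinical_label(raw, source)
        if call == ClinicalCall.positive:
            pos.add(v.key)
        elif call == ClinicalCall.negative:
            neg.add(v.key)
    if not pos and not neg:
        log.warning("build_benchmark(%s/%s): no PV or BV labels found", source, cohort)
    log.info("benchmark %s/%s: %d PV, %d BV", source, cohort, len(pos), len(neg))
    return BenchmarkSet(source=source, cohort=cohort, positives=pos, negatives=neg)


def merge_benchmarks(
    a: BenchmarkSet, b: BenchmarkSet, conflict_policy: str = "clinvar_wins"
) -> BenchmarkSet:
    """Union two single-source benchmarks into the merged benchmark.

    Same-polarity duplicates count once. A key positive in one source and
    negative in the other is a cross-source conflict, resolved by
    ``conflict_policy``:

    - ``"clinvar_wins"`` (default): the ClinVar call stands, the InterVar
      call is discarded — ClinVar reflects externally validated functional
      evidence, InterVar is rule-derived.
    - ``"drop"``: conflicted keys are removed from both polarities.
    """
    if a.cohort != b.cohort:
        raise ConfigError(f"cohort mismatch: {a.cohort!r} vs {b.cohort!r}")
    if a.source == b.source:
        raise ConfigError(f"merge requires two distinct sources, got {a.source!r} twice")
    if conflict_policy not in ("clinvar_wins", "drop"):
        raise ConfigError(f"unknown conflict policy {conflict_policy!r}")
    pos = a.positives | b.positives
    neg = a.negatives | b.negatives
    conflicts = pos & neg
    if conflicts:
        log.warning("merge: %d cross-source conflicts (%s)", len(conflicts), conflict_policy)
        if conflict_policy == "drop":
            pos -= conflicts
            neg -= conflicts
        else:
            cv = a if a.source == "clinvar" else b
            for key in conflicts:
                if key in cv.positives:
                    neg.discard(key)
                else:
                    pos.discard(key)
    return BenchmarkSet(source="merged", cohort=a.cohort, positives=pos, negatives=neg)


def benchmark_summary(benchmarks: Iterable[BenchmarkSet]) -> dict:
    """JSON-ready size summary, one entry per (source, cohort)."""
    out: dict = {}
    for b in benchmarks:
        out.setdefault(b.cohort, {})[b.source] = {
            "positives": b.n_positive,
            "negatives": b.n_negative,
        }
    return out
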