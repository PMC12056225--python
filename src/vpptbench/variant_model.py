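"""Domain types and readers/writers for annotated germline SNV tables.

A variant here is a single-nucleotide substitution carrying clinical labels
(ClinVar clinical significance, InterVar ACMG-AMP class), cohort and
population allele frequencies, a consequence class, loss-of-function and
oncogenicity flags, and per-tool numeric scores or categorical predictions
(dbNSFP-style columns). Two input dialects are supported: a tab-separated
multianno-style table and VCF with configurable INFO keys. Coordinates are
1-based and "chr" prefixes are stripped so keys compare across dialects.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import NotAnSnvError, ParseError

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

MISSING = "."


class Consequence(str, Enum):
    """Coarse functional consequence of an SNV, as annotated upstream."""

    missense = "missense"
    stop_gain = "stop_gain"
    splice = "splice"
    synonymous = "synonymous"
    other = "other"
    noncoding = "noncoding"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of an SNV: (chrom, pos, ref, alt), 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # "1:100:A:G" — used in TSV outputs
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def make_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a normalized :class:`VariantKey`.

    Strips any ``chr`` prefix, upper-cases alleles, and rejects anything
    that is not a single-base substitution.

    Raises
    ------
    NotAnSnvError
        If ref/alt are not single, distinct A/C/G/T bases.
    DataError
        If ``pos`` < 1.
    """
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    ref = str(ref).strip().upper()
    alt = str(alt).strip().upper()
    pos = int(pos)
    if pos < 1:
        raise ParseError(f"position must be >= 1, got {pos}")
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        raise NotAnSnvError(f"not an SNV: ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise NotAnSnvError(f"ref and alt identical: {ref!r}")
    return VariantKey(chrom, pos, ref, alt)


def parse_variant_key(text: str) -> VariantKey:
    """Inverse of ``str(key)``: parse ``"1:100:A:G"``."""
    parts = text.split(":")
    if len(parts) != 4:
        raise ParseError(f"malformed variant key {text!r}")
    return make_variant_key(parts[0], int(parts[1]), parts[2], parts[3])


@dataclass
class AnnotatedVariant:
    """One SNV with clinical labels, frequencies and per-tool predictions.

    ``scores`` maps tool name -> numeric score (after transcript reduction a
    single float); ``preds`` maps tool name -> categorical prediction code.
    Missing frequencies/labels are ``None``, never 0 or "".
    """

    key: VariantKey
    cohort: str
    cohort_maf: float | None = None
    pop_af: float | None = None
    clinvar_label: str | None = None
    intervar_label: str | None = None
    consequence: Consequence = Consequence.other
    plof: bool = False
    cgi_oncogenic: bool = False
    scores: dict[str, float] = field(default_factory=dict)
    preds: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSummary:
    """Headline cohort counts: patients, SNVs, rare SNVs."""

    n_patients: int
    n_snvs: int
    n_rare: int

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_snvs, self.n_rare) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_rare > self.n_snvs:
            raise ValueError("n_rare cannot exceed n_snvs")


@dataclass(frozen=True)
class ColumnMap:
    """Column / INFO-key names for the two input dialects.

    Defaults match the TSV written by :func:`write_variant_table`; override
    any field to consume third-party annotation tables.
    """

    chrom: str = "chrom"
    pos: str = "pos"
    ref: str = "ref"
    alt: str = "alt"
    cohort_maf: str = "cohort_maf"
    pop_af: str = "pop_af"
    clinvar: str = "clinvar"
    intervar: str = "intervar"
    consequence: str = "consequence"
    plof: str = "plof"
    cgi_oncogenic: str = "cgi_oncogenic"
    # categorical tool columns are "<tool>_pred"; numeric ones are "<tool>"
    pred_suffix: str = "_pred"


FIXED_COLUMNS = (
    "chrom", "pos", "ref", "alt", "cohort_maf", "pop_af", "clinvar",
    "intervar", "consequence", "plof", "cgi_oncogenic",
)


def _parse_float(text: str | None) -> float | None:
    if text is None:
        return None
    text = text.strip()
    if text in ("", MISSING, "NA", "nan"):
        return None
    return float(text)


def reduce_transcript_scores(raw: str, most_deleterious: str = "max") -> float | None:
    """Collapse a multi-valued per-transcript score field to one number.

    dbNSFP-style fields carry one value per transcript separated by ``;`` or
    ``,``; missing entries appear as ``.``. After direction pre-normalization
    every registry tool is higher-is-more-deleterious, so the conservative
    reduction is the maximum (``most_deleterious="max"``); ``"min"`` is
    available for callers handling un-normalized columns.
    """
    vals: list[float] = []
    for piece in raw.replace(";", ",").split(","):
        v = _parse_float(piece)
        if v is not None and not math.isnan(v):
            vals.append(v)
    if not vals:
        return None
    return max(vals) if most_deleterious == "max" else min(vals)


def _parse_bool(text: str | None) -> bool:
    if text is None:
        return False
    return text.strip().lower() in ("1", "true", "t", "yes", "y")


def _classify_tool_columns(
    header: Sequence[str],
    registry,
    colmap: ColumnMap,
) -> tuple[dict[str, str], dict[str, str], list[str]]:
    """Split non-fixed header columns into score columns, pred columns, unknown."""
    fixed = {getattr(colmap, f) for f in FIXED_COLUMNS}
    score_cols: dict[str, str] = {}
    pred_cols: dict[str, str] = {}
    unknown: list[str] = []
    for col in header:
        if col in fixed:
            continue
        name = col
        is_pred = col.endswith(colmap.pred_suffix)
        if is_pred:
            name = col[: -len(colmap.pred_suffix)]
        spec = registry.find(name) if registry is not None else None
        if spec is None:
            unknown.append(col)
        elif is_pred:
            pred_cols[col] = spec.name
        else:
            score_cols[col] = spec.name
    return score_cols, pred_cols, unknown


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    cohort: str = "cohort",
    registry=None,
    column_map: ColumnMap | None = None,
) -> list[AnnotatedVariant]:
    """Read an annotated SNV table into :class:`AnnotatedVariant` records.

    Non-SNV rows (indels, MNVs) are skipped and counted; duplicate keys keep
    the first occurrence; tool columns absent from the registry are ignored
    with a warning. Multi-valued per-transcript scores are reduced to the
    most-deleterious value.
    """
    if registry is None:
        from .registry import get_registry

        registry = get_registry()
    colmap = column_map or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    if dialect == "tsv":
        variants = _read_tsv(path, cohort, registry, colmap)
    elif dialect == "vcf":
        variants = _read_vcf(path, cohort, registry, colmap)
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    # enforce key uniqueness, first occurrence wins
    seen: dict[VariantKey, int] = {}
    out: list[AnnotatedVariant] = []
    dups = 0
    for v in variants:
        if v.key in seen:
            dups += 1
            continue
        seen[v.key] = 1
        out.append(v)
    if dups:
        log.warning("%s: %d duplicate variant keys dropped (first kept)", path, dups)
    return out


def _read_tsv(path: Path, cohort: str, registry, colmap: ColumnMap) -> list[AnnotatedVariant]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise ParseError(f"{path}: empty file, no header")
        for required in ("chrom", "pos", "ref", "alt"):
            if getattr(colmap, required) not in header:
                raise ParseError(
                    f"{path}: missing required column {getattr(colmap, required)!r}"
                )
        score_cols, pred_cols, unknown = _classify_tool_columns(header, registry, colmap)
        if unknown:
            log.warning("%s: ignoring %d unknown columns: %s", path, len(unknown), unknown)
        out: list[AnnotatedVariant] = []
        skipped = 0
        for lineno, row in enumerate(reader, start=2):
            try:
                key = make_variant_key(
                    row[colmap.chrom], int(row[colmap.pos]), row[colmap.ref], row[colmap.alt]
                )
            except NotAnSnvError:
                skipped += 1
                continue
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            scores: dict[str, float] = {}
            for col, tool in score_cols.items():
                raw = row.get(col)
                if raw is None or raw.strip() in ("", MISSING):
                    continue
                val = reduce_transcript_scores(raw)
                if val is not None:
                    scores[tool] = val
            preds: dict[str, str] = {}
            for col, tool in pred_cols.items():
                raw = row.get(col)
                if raw is None:
                    continue
                raw = raw.strip()
                if raw and raw != MISSING:
                    # multi-transcript prediction strings: keep any deleterious
                    # code if present, else the first code
                    codes = [c for c in raw.replace(";", ",").split(",") if c and c != MISSING]
                    if not codes:
                        continue
                    spec = registry.find(tool)
                    hit = next((c for c in codes if c in spec.deleterious_codes), None)
                    preds[tool] = hit if hit is not None else codes[0]
            cons_raw = (row.get(colmap.consequence) or "other").strip()
            try:
                cons = Consequence(cons_raw) if cons_raw and cons_raw != MISSING else Consequence.other
            except ValueError:
                cons = Consequence.other
            out.append(
                AnnotatedVariant(
                    key=key,
                    cohort=cohort,
                    cohort_maf=_parse_float(row.get(colmap.cohort_maf)),
                    pop_af=_parse_float(row.get(colmap.pop_af)),
                    clinvar_label=_none_if_missing(row.get(colmap.clinvar)),
                    intervar_label=_none_if_missing(row.get(colmap.intervar)),
                    consequence=cons,
                    plof=_parse_bool(row.get(colmap.plof)),
                    cgi_oncogenic=_parse_bool(row.get(colmap.cgi_oncogenic)),
                    scores=scores,
                    preds=preds,
                )
            )
    if skipped:
        log.info("%s: skipped %d non-SNV rows", path, skipped)
    return out


def _none_if_missing(text: str | None) -> str | None:
    if text is None:
        return None
    text = text.strip()
    return None if text in ("", MISSING) else text


def _read_vcf(path: Path, cohort: str, registry, colmap: ColumnMap) -> list[AnnotatedVariant]:
    """VCF dialect: annotations carried as INFO keys named per ``ColumnMap``."""
    from cyvcf2 import VCF

    out: list[AnnotatedVariant] = []
    skipped = 0
    vcf = VCF(str(path))
    info_fields = [f["ID"] for f in vcf.header_iter() if f.type == "INFO"]
    score_cols, pred_cols, unknown = _classify_tool_columns(info_fields, registry, colmap)
    if unknown:
        log.warning("%s: ignoring %d unknown INFO keys", path, len(unknown))
    for rec in vcf:
        alts = rec.ALT or []
        for alt in alts:
            try:
                key = make_variant_key(rec.CHROM, rec.POS, rec.REF, alt)
            except NotAnSnvError:
                skipped += 1
                continue
            info = rec.INFO
            scores: dict[str, float] = {}
            for keyname, tool in score_cols.items():
                raw = info.get(keyname)
                if raw is None:
                    continue
                val = reduce_transcript_scores(str(raw))
                if val is not None:
                    scores[tool] = val
            preds: dict[str, str] = {}
            for keyname, tool in pred_cols.items():
                raw = info.get(keyname)
                if raw is not None and str(raw) != MISSING:
                    preds[tool] = str(raw)
            cons_raw = info.get(colmap.consequence)
            try:
                cons = Consequence(str(cons_raw)) if cons_raw else Consequence.other
            except ValueError:
                cons = Consequence.other
            maf = info.get(colmap.cohort_maf)
            paf = info.get(colmap.pop_af)
            out.append(
                AnnotatedVariant(
                    key=key,
                    cohort=cohort,
                    cohort_maf=float(maf) if maf is not None else None,
                    pop_af=float(paf) if paf is not None else None,
                    clinvar_label=_none_if_missing(info.get(colmap.clinvar)),
                    intervar_label=_none_if_missing(info.get(colmap.intervar)),
                    consequence=cons,
                    plof=bool(info.get(colmap.plof)),
                    cgi_oncogenic=bool(info.get(colmap.cgi_oncogenic)),
                    scores=scores,
                    preds=preds,
                )
            )
    if skipped:
        log.info("%s: skipped %d non-SNV records", path, skipped)
    return out


def write_variant_table(
    variants: Iterable[AnnotatedVariant],
    path: str | Path,
    registry=None,
) -> None:
    """Write the TSV dialect with a fixed, reproducible column order.

    Tool columns appear in registry order; numeric tools as ``<tool>``,
    categorical tools as ``<tool>_pred``. Missing values are ``.``.
    """
    if registry is None:
        from .registry import get_registry

        registry = get_registry()
    colmap = ColumnMap()
    tool_cols: list[tuple[str, str, bool]] = []  # (column, tool, is_pred)
    for spec in registry.tools:
        if spec.mode == "categorical":
            tool_cols.append((spec.name + colmap.pred_suffix, spec.name, True))
        else:
            tool_cols.append((spec.name, spec.name, False))
    header = list(FIXED_COLUMNS) + [c for c, _, _ in tool_cols]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for v in variants:
            row = [
                v.key.chrom,
                v.key.pos,
                v.key.ref,
                v.key.alt,
                _fmt(v.cohort_maf),
                _fmt(v.pop_af),
                v.clinvar_label if v.clinvar_label is not None else MISSING,
                v.intervar_label if v.intervar_label is not None else MISSING,
                v.consequence.value,
                "1" if v.plof else "0",
                "1" if v.cgi_oncogenic else "0",
            ]
            for _, tool, is_pred in tool_cols:
                if is_pred:
                    row.append(v.preds.get(tool, MISSING))
                else:
                    row.append(_fmt(v.scores.get(tool)))
            w.writerow(row)


def _fmt(val: float | None) -> str:
    if val is None:
        return MISSING
    return repr(float(val))
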