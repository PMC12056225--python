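"""Declarative registry of variant pathogenicity prediction tools (VPPTs).

Each tool is either *numeric* — binarized against a published cut-off with
the published inequality, every score column pre-normalized so that higher
means more deleterious — or *categorical* — carrying a dbNSFP-style
prediction code column (e.g. ``D`` deleterious vs ``T`` tolerated).
``family`` groups near-duplicate score variants of one underlying model
(MetaSVM/MetaLR, the Eigen pair, the BayesDel pair, ...) so downstream
workflow selection can keep one representative per family.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .variant_model import AnnotatedVariant

log = logging.getLogger(__name__)

SCOPES = ("coding", "genome_wide", "noncoding_only")
METHODS = ("MSA", "protein", "supervised_ML", "unsupervised_ML", "DL", "meta")

# call codes used in matrices (small ints keep 54 x N tables cheap)
DELETERIOUS = 1
BENIGN = 0
NO_CALL = -1


@dataclass(frozen=True)
class ToolCall:
    """Binarized verdict of one tool on one variant."""

    value: str  # deleterious | benign | no_call

    @staticmethod
    def from_code(code: int) -> "ToolCall":
        return ToolCall({DELETERIOUS: "deleterious", BENIGN: "benign", NO_CALL: "no_call"}[code])


@dataclass(frozen=True)
class ToolSpec:
    """Binarization rule and metadata for one tool."""

    name: str
    mode: str  # numeric | categorical
    cutoff: float | None = None
    direction: str = "ge"  # ge | gt; scores pre-normalized higher = deleterious
    deleterious_codes: frozenset[str] = frozenset()
    benign_code: str = "T"
    scope: str = "coding"
    family: str = ""
    year: int = 0
    method: str = "MSA"
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("numeric", "categorical"):
            raise ConfigError(f"{self.name}: bad mode {self.mode!r}")
        if self.mode == "numeric" and self.cutoff is None:
            raise ConfigError(f"{self.name}: numeric tool requires a cutoff")
        if self.mode == "categorical" and not self.deleterious_codes:
            raise ConfigError(f"{self.name}: categorical tool requires deleterious codes")
        if self.direction not in ("ge", "gt"):
            raise ConfigError(f"{self.name}: bad direction {self.direction!r}")
        if self.scope not in SCOPES:
            raise ConfigError(f"{self.name}: bad scope {self.scope!r}")
        if self.method not in METHODS:
            raise ConfigError(f"{self.name}: bad method {self.method!r}")


def normalize_tool_name(name: str) -> str:
    """Case/punctuation-insensitive canonical form used for lookups."""
    return re.sub(r"[\s_\-\.]+", "", name).lower()


class ToolRegistry:
    """Ordered collection of :class:`ToolSpec` with alias-aware lookup."""

    def __init__(self, tools: Sequence[ToolSpec]):
        self.tools: tuple[ToolSpec, ...] = tuple(tools)
        names = [t.name for t in self.tools]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate tool names in registry")
        self._lookup: dict[str, ToolSpec] = {}
        for t in self.tools:
            for alias in (t.name, *t.aliases):
                key = normalize_tool_name(alias)
                if key in self._lookup and self._lookup[key] is not t:
                    raise ConfigError(f"alias collision on {alias!r}")
                self._lookup[key] = t

    def __len__(self) -> int:
        return len(self.tools)

    def __iter__(self):
        return iter(self.tools)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tools]

    def find(self, name: str) -> ToolSpec | None:
        return self._lookup.get(normalize_tool_name(name))

    def get(self, name: str) -> ToolSpec:
        spec = self.find(name)
        if spec is None:
            raise ConfigError(f"unknown tool {name!r}")
        return spec


def _spec_from_record(rec: dict, index: int) -> ToolSpec:
    try:
        return ToolSpec(
            name=str(rec["name"]),
            mode=str(rec["mode"]),
            cutoff=float(rec["cutoff"]) if "cutoff" in rec else None,
            direction=str(rec.get("direction", "ge")),
            deleterious_codes=frozenset(str(c) for c in rec.get("deleterious_codes", [])),
            benign_code=str(rec.get("benign_code", "T")),
            scope=str(rec.get("scope", "coding")),
            family=str(rec.get("family", rec["name"])),
            year=int(rec.get("year", 0)),
            method=str(rec.get("method", "MSA")),
            aliases=tuple(str(a) for a in rec.get("aliases", [])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"registry record {index}: {exc}") from exc


def load_registry(path: str | Path) -> ToolRegistry:
    """Load a registry from a YAML file (``tools:`` list of records)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "tools" not in data:
        raise ConfigError(f"{path}: registry file must contain a 'tools' list")
    bad: list[str] = []
    specs: list[ToolSpec] = []
    for i, rec in enumerate(data["tools"]):
        try:
            specs.append(_spec_from_record(rec, i))
        except ConfigError as exc:
            bad.append(str(exc))
    if bad:
        raise ConfigError(f"{path}: malformed registry rows:\n" + "\n".join(bad))
    return ToolRegistry(specs)


_default_registry: ToolRegistry | None = None


def get_registry(path: str | Path | None = None) -> ToolRegistry:
    """Return the packaged 54-tool registry (cached) or load from ``path``."""
    global _default_registry
    if path is not None:
        return load_registry(path)
    if _default_registry is None:
        ref = resources.files("vpptbench.data") / "tool_registry.yaml"
        with resources.as_file(ref) as p:
            _default_registry = load_registry(p)
    return _default_registry


def binarize_call(tool: ToolSpec, variant: AnnotatedVariant) -> ToolCall:
    """Binarize one tool on one variant: deleterious / benign / no_call."""
    return ToolCall.from_code(_binarize_code(tool, variant))


def _binarize_code(tool: ToolSpec, variant: AnnotatedVariant) -> int:
    if tool.mode == "categorical":
        pred = variant.preds.get(tool.name)
        if pred is None or pred == "":
            return NO_CALL
        return DELETERIOUS if pred in tool.deleterious_codes else BENIGN
    score = variant.scores.get(tool.name)
    if score is None or np.isnan(score):
        return NO_CALL
    assert tool.cutoff is not None
    if tool.direction == "gt":
        return DELETERIOUS if score > tool.cutoff else BENIGN
    return DELETERIOUS if score >= tool.cutoff else BENIGN


def call_matrix(
    variants: Sequence[AnnotatedVariant],
    tools: Iterable[ToolSpec] | None = None,
    registry: ToolRegistry | None = None,
) -> pd.DataFrame:
    """Binarize every tool on every variant.

    Returns an ``int8`` DataFrame indexed by :class:`VariantKey` with one
    column per tool: 1 deleterious, 0 benign, -1 no-call. Per-tool call
    counts are logged.
    """
    if tools is None:
        tools = (registry or get_registry()).tools
    tools = list(tools)
    index = [v.key for v in variants]
    data = np.full((len(index), len(tools)), NO_CALL, dtype=np.int8)
    for j, tool in enumerate(tools):
        col = data[:, j]
        for i, v in enumerate(variants):
            col[i] = _binarize_code(tool, v)
        n_del = int((col == DELETERIOUS).sum())
        n_ben = int((col == BENIGN).sum())
        log.debug("%s: %d deleterious, %d benign, %d no-call",
                  tool.name, n_del, n_ben, len(index) - n_del - n_ben)
    return pd.DataFrame(data, index=index, columns=[t.name for t in tools])
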