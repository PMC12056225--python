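"""Synthetic paired-cohort generator with known ground truth.

Generates annotated SNV cohorts whose statistical shape mirrors the real
African-vs-European study design: two cohorts differing in variant count,
rare-variant fraction and clinical-label scarcity, with per-tool scores
drawn from class-conditional models so that every tool has a *known*
analytic operating point (:func:`expected_performance`). This is what
makes the whole pipeline testable end-to-end without any controlled-access
data: downstream metric estimates can be checked against closed forms.

Randomness is streamed per (seed, cohort, tool) via independent
``SeedSequence`` substreams, so adding or removing a tool never perturbs
any other column and fixed seeds give byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigError
from .registry import ToolRegistry, ToolSpec, get_registry
from .variant_model import AnnotatedVariant, Consequence, VariantKey

TRUTH_CLASSES = ("pathogenic", "benign", "neutral_vus")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GaussianToolModel:
    """Class-conditional Gaussian score model for a numeric tool."""

    mu_pathogenic: float
    mu_benign: float
    sigma_pathogenic: float = 1.0
    sigma_benign: float = 1.0
    missing_prob: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_pathogenic, self.sigma_benign) <= 0:
            raise ConfigError("sigmas must be positive")
        if not (0 <= self.missing_prob < 1):
            raise ConfigError("missing_prob must be in [0, 1)")


@dataclass(frozen=True)
class CategoricalToolModel:
    """Confusion-probability model for a categorical tool."""

    p_deleterious_pathogenic: float  # P(code in deleterious set | pathogenic)
    p_deleterious_benign: float      # P(code in deleterious set | benign)
    missing_prob: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_deleterious_pathogenic, self.p_deleterious_benign, self.missing_prob):
            if not (0 <= p <= 1):
                raise ConfigError("probabilities must be in [0, 1]")


ToolModel = GaussianToolModel | CategoricalToolModel


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth class of one generated variant."""

    key: VariantKey
    true_class: str  # pathogenic | benign | neutral_vus
    cohort: str


@dataclass(frozen=True)
class CohortConfig:
    """Shape of one synthetic cohort.

    ``frac_pv``/``frac_bv`` are truth-class fractions; the remainder is
    neutral. Truth-pathogenic and truth-benign variants are drawn rare with
    probability ``labelled_rare_prob`` (known clinical variants are
    predominantly rare); neutral variants are rare with probability
    ``rare_fraction``. ``label_probs`` gives, per truth class, the chance
    the class surfaces as a ClinVar / InterVar label — the knob that
    mimics ancestry-dependent label scarcity.
    """

    name: str
    n_patients: int = 50
    n_variants: int = 20000
    rare_fraction: float = 0.25
    frac_pv: float = 0.005
    frac_bv: float = 0.05
    labelled_rare_prob: float = 0.9
    label_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "pathogenic": {"clinvar": 0.5, "intervar": 0.8},
            "benign": {"clinvar": 0.3, "intervar": 0.8},
            "neutral_vus": {"clinvar": 0.0, "intervar": 0.0},
        }
    )
    vus_label_prob: float = 0.3  # neutral variants surfacing as "Uncertain_significance"
    consequence_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.30,
            "stop_gain": 0.01,
            "splice": 0.01,
            "synonymous": 0.28,
            "other": 0.40,
        }
    )
    plof_prob: Mapping[str, float] = field(
        default_factory=lambda: {"pathogenic": 0.10, "benign": 0.001, "neutral_vus": 0.002}
    )
    cgi_prob: Mapping[str, float] = field(
        default_factory=lambda: {"pathogenic": 0.25, "benign": 0.002, "neutral_vus": 0.01}
    )
    missing_maf_prob: float = 0.02
    missing_pop_af_prob: float = 0.10
    common_pop_af_prob: Mapping[str, float] = field(
        default_factory=lambda: {"pathogenic": 0.01, "benign": 0.15, "neutral_vus": 0.03}
    )
    tool_models: Mapping[str, ToolModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigError("n_variants must be >= 1")
        if self.frac_pv + self.frac_bv > 1:
            raise ConfigError("frac_pv + frac_bv must be <= 1")
        for p in (self.rare_fraction, self.frac_pv, self.frac_bv, self.labelled_rare_prob):
            if not (0 <= p <= 1):
                raise ConfigError("fractions must be in [0, 1]")
        total = sum(self.consequence_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"consequence_probs must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticConfig:
    """A seed plus one or more cohort configurations."""

    seed: int
    cohorts: tuple[CohortConfig, ...]

    def cohort(self, name: str) -> CohortConfig:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise ConfigError(f"no cohort named {name!r}")


def _stream(seed: int, cohort: str, label: str) -> np.random.Generator:
    """Independent substream keyed by (seed, cohort, label)."""
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=seed,
            spawn_key=(zlib.crc32(cohort.encode()), zlib.crc32(label.encode())),
        )
    )


def _draw_scores(
    model: ToolModel, spec: ToolSpec, truth: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (values-or-codes, present mask) for one tool column."""
    n = len(truth)
    is_path = truth == 0  # class index 0 = pathogenic
    present = rng.random(n) >= _missing_prob(model)
    if isinstance(model, GaussianToolModel):
        mu = np.where(is_path, model.mu_pathogenic, model.mu_benign)
        sigma = np.where(is_path, model.sigma_pathogenic, model.sigma_benign)
        vals = rng.normal(mu, sigma)
        return vals, present
    p_del = np.where(is_path, model.p_deleterious_pathogenic, model.p_deleterious_benign)
    is_del = rng.random(n) < p_del
    del_code = sorted(spec.deleterious_codes)[0]
    codes = np.where(is_del, del_code, spec.benign_code)
    return codes, present


def _missing_prob(model: ToolModel) -> float:
    return model.missing_prob


def generate_cohort(
    config: SyntheticConfig,
    cohort: str | None = None,
    registry: ToolRegistry | None = None,
) -> tuple[list[AnnotatedVariant], list[TruthRecord]]:
    """Generate one cohort's annotated variants plus their truth records.

    Reproducible: identical config and seed give byte-identical output.
    Variant keys are ``chrom "1"``, positions 1..n, random ref/alt bases.
    """
    registry = registry or get_registry()
    cc = config.cohort(cohort) if cohort is not None else config.cohorts[0]
    n = cc.n_variants
    rng = _stream(config.seed, cc.name, "_skeleton")

    # truth classes: 0 pathogenic, 1 benign, 2 neutral
    truth = rng.choice(
        3, size=n, p=[cc.frac_pv, cc.frac_bv, 1.0 - cc.frac_pv - cc.frac_bv]
    )
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    keys = [
        VariantKey("1", i + 1, str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]))
        for i in range(n)
    ]

    # cohort MAF: labelled classes rare with labelled_rare_prob, neutral with rare_fraction
    rare_p = np.where(truth == 2, cc.rare_fraction, cc.labelled_rare_prob)
    is_rare = rng.random(n) < rare_p
    maf = np.where(is_rare, rng.uniform(0.0, 0.0099, n), rng.uniform(0.011, 0.5, n))
    maf_missing = rng.random(n) < cc.missing_maf_prob

    # population AF: mostly rare; occasionally common per truth class
    common_p = np.array([cc.common_pop_af_prob[TRUTH_CLASSES[t]] for t in truth])
    pop_common = rng.random(n) < common_p
    pop_af = np.where(pop_common, rng.uniform(0.011, 0.2, n), rng.uniform(0.0, 0.009, n))
    pop_missing = rng.random(n) < cc.missing_pop_af_prob

    # surfaced labels
    u = rng.random((n, 3))  # clinvar, intervar, vus-label draws
    clinvar = np.full(n, None, dtype=object)
    intervar = np.full(n, None, dtype=object)
    label_text = {0: ("Pathogenic", "Likely pathogenic"), 1: ("Benign", "Likely benign")}
    for i in range(n):
        cls = TRUTH_CLASSES[truth[i]]
        probs = cc.label_probs[cls]
        if truth[i] in (0, 1):
            texts = label_text[truth[i]]
            if u[i, 0] < probs.get("clinvar", 0.0):
                clinvar[i] = texts[0] if u[i, 2] < 0.5 else texts[1]
            if u[i, 1] < probs.get("intervar", 0.0):
                intervar[i] = texts[0] if u[i, 2] < 0.5 else texts[1]
        else:
            if u[i, 2] < cc.vus_label_prob:
                clinvar[i] = "Uncertain_significance"

    cons_names = list(cc.consequence_probs)
    cons_idx = rng.choice(
        len(cons_names), size=n, p=[cc.consequence_probs[k] for k in cons_names]
    )
    plof_p = np.array([cc.plof_prob[TRUTH_CLASSES[t]] for t in truth])
    cgi_p = np.array([cc.cgi_prob[TRUTH_CLASSES[t]] for t in truth])
    plof = rng.random(n) < plof_p
    cgi = rng.random(n) < cgi_p

    # per-tool columns, each from its own substream
    score_cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pred_cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tool_name in cc.tool_models:
        spec = registry.get(tool_name)
        model = cc.tool_models[tool_name]
        trng = _stream(config.seed, cc.name, spec.name)
        vals, present = _draw_scores(model, spec, truth, trng)
        if isinstance(model, GaussianToolModel):
            score_cols[spec.name] = (vals, present)
        else:
            pred_cols[spec.name] = (vals, present)

    variants: list[AnnotatedVariant] = []
    truths: list[TruthRecord] = []
    for i in range(n):
        scores = {t: float(v[i]) for t, (v, m) in score_cols.items() if m[i]}
        preds = {t: str(v[i]) for t, (v, m) in pred_cols.items() if m[i]}
        variants.append(
            AnnotatedVariant(
                key=keys[i],
                cohort=cc.name,
                cohort_maf=None if maf_missing[i] else round(float(maf[i]), 6),
                pop_af=None if pop_missing[i] else round(float(pop_af[i]), 6),
                clinvar_label=clinvar[i],
                intervar_label=intervar[i],
                consequence=Consequence(cons_names[cons_idx[i]]),
                plof=bool(plof[i]),
                cgi_oncogenic=bool(cgi[i]),
                scores=scores,
                preds=preds,
            )
        )
        truths.append(TruthRecord(key=keys[i], true_class=TRUTH_CLASSES[truth[i]], cohort=cc.name))
    return variants, truths


def generate_cohorts(
    config: SyntheticConfig, registry: ToolRegistry | None = None
) -> dict[str, tuple[list[AnnotatedVariant], list[TruthRecord]]]:
    """Generate every cohort in the config."""
    return {
        cc.name: generate_cohort(config, cc.name, registry) for cc in config.cohorts
    }


def expected_performance(model: ToolModel, tool: ToolSpec) -> tuple[float, float]:
    """Analytic (sensitivity, specificity) of a tool under a score model.

    For a Gaussian model this is the normal tail probability at the cut-off
    (score direction is always higher-is-deleterious); for a categorical
    model it is the programmed confusion probabilities directly.
    """
    if isinstance(model, CategoricalToolModel):
        return model.p_deleterious_pathogenic, 1.0 - model.p_deleterious_benign
    if isinstance(model, GaussianToolModel):
        if tool.cutoff is None:
            raise ConfigError(f"{tool.name}: Gaussian model requires a numeric cutoff")
        c = float(tool.cutoff)
        sen = float(norm.sf(c, loc=model.mu_pathogenic, scale=model.sigma_pathogenic))
        spec = float(norm.cdf(c, loc=model.mu_benign, scale=model.sigma_benign))
        return sen, spec
    raise ConfigError(f"unsupported score model {type(model).__name__}")


def expected_rare_fraction(cc: CohortConfig) -> float:
    """Expected fraction of variants with cohort MAF below 1%."""
    p_neutral = 1.0 - cc.frac_pv - cc.frac_bv
    return (
        (cc.frac_pv + cc.frac_bv) * cc.labelled_rare_prob + p_neutral * cc.rare_fraction
    )


# ---------------------------------------------------------------------------
# default study-shaped configuration

def models_from_reference(
    cohort: str,
    registry: ToolRegistry | None = None,
    missing_prob: float = 0.05,
    clamp: float = 0.01,
) -> dict[str, ToolModel]:
    """Program every registry tool to the reference operating point.

    Numeric tools get unit-variance Gaussians placed so that the normal
    tails at the published cut-off equal the published sensitivity and
    specificity; categorical tools get those probabilities directly.
    Published rates of exactly 0 or 1 are clamped to ``clamp`` /
    ``1 - clamp`` so both class distributions stay proper.
    """
    from .selection import load_reference_metrics

    registry = registry or get_registry()
    ref = load_reference_metrics()[cohort]
    models: dict[str, ToolModel] = {}
    for row in ref:
        spec = registry.get(row.tool)
        sen = min(max(row.sensitivity, clamp), 1 - clamp)
        sp = min(max(row.specificity, clamp), 1 - clamp)
        if spec.mode == "categorical":
            models[spec.name] = CategoricalToolModel(
                p_deleterious_pathogenic=sen,
                p_deleterious_benign=1.0 - sp,
                missing_prob=missing_prob,
            )
        else:
            c = float(spec.cutoff)  # type: ignore[arg-type]
            models[spec.name] = GaussianToolModel(
                mu_pathogenic=c + norm.ppf(sen),
                mu_benign=c - norm.ppf(sp),
                missing_prob=missing_prob,
            )
    return models


def default_config(seed: int, scale: float = 1.0) -> SyntheticConfig:
    """Two cohorts shaped like the study at roughly 1/1000 variant scale.

    The African cohort carries ~1.6x the variants of the European one but a
    lower rare fraction (23.5% vs 31.8%) and scarcer surfaced clinical
    labels; every one of the 54 tools is programmed to its ancestry-specific
    reference operating point. ``scale`` multiplies both cohort sizes.
    """
    afr = CohortConfig(
        name="AFR",
        n_patients=50,
        n_variants=max(1, int(20000 * scale)),
        rare_fraction=0.235,
        frac_pv=0.005,
        frac_bv=0.05,
        label_probs={
            "pathogenic": {"clinvar": 0.25, "intervar": 0.85},
            "benign": {"clinvar": 0.35, "intervar": 0.80},
            "neutral_vus": {},
        },
        tool_models=models_from_reference("AFR"),
    )
    eur = CohortConfig(
        name="EUR",
        n_patients=50,
        n_variants=max(1, int(12400 * scale)),
        rare_fraction=0.318,
        frac_pv=0.010,
        frac_bv=0.12,
        label_probs={
            "pathogenic": {"clinvar": 0.50, "intervar": 0.75},
            "benign": {"clinvar": 0.20, "intervar": 0.90},
            "neutral_vus": {},
        },
        tool_models=models_from_reference("EUR"),
    )
    return SyntheticConfig(seed=seed, cohorts=(afr, eur))


def write_truth_table(truths: Sequence[TruthRecord], path) -> None:
    """Truth TSV: key, cohort, true_class."""
    with open(path, "w") as fh:
        fh.write("key\tcohort\ttrue_class\n")
        for t in truths:
            fh.write(f"{t.key}\t{t.cohort}\t{t.true_class}\n")
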