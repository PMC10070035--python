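"""Seeded generator of biobank-like cohorts with known injected effects.

Emulates the structure of linked electronic-health-record data: coded events
per person per source, repeated timestamped quantitative measures, biallelic
SNP dosages drawn from Hardy-Weinberg proportions at a stated minor-allele
frequency, integer CNV copy numbers, and genotype-phenotype effects injected
at a known effect size so downstream estimators can be checked for recovery.

Everything is deterministic given the spec seed: one global seed is expanded
into per-component substreams via fixed labelled offsets, so individual
stages reproduce when rerun independently.  No linkage disequilibrium,
relatedness or population structure is simulated — the association tests are
single-predictor, so none is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import EventTable, GenotypeMatrix, PhewasError, ValidationError

__all__ = [
    "VariantSpec", "EventTemplate", "MeasureTemplate", "InjectedEffect",
    "CohortSpec", "generate_cohort", "inject_quantitative_effect",
    "generate_null_binary",
]

# fixed labelled substream offsets (never reuse across components)
_SUB_PARTICIPANTS = 11
_SUB_GENOTYPES = 23
_SUB_EVENTS = 37
_SUB_MEASURES = 51
_SUB_EFFECTS = 67
_SUB_NULL = 83

_CENSOR_DATE = date(2020, 1, 1)
_BIRTH_LO = date(1940, 1, 1)
_BIRTH_HI = date(1970, 12, 31)


@dataclass(frozen=True)
class VariantSpec:
    variant_id: str
    maf: float = 0.2
    kind: str = "snp"            # "snp" | "cnv"
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.kind == "snp" and not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf for {self.variant_id!r} must lie in (0, 0.5]")


@dataclass(frozen=True)
class EventTemplate:
    code: str
    vocabulary: str = "ICD10"
    source: str = "hospital"
    rate: float = 0.5            # Poisson mean events per person

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("event rate must be >= 0")


@dataclass(frozen=True)
class MeasureTemplate:
    code: str
    mean: float
    sd: float
    visits: int = 3              # measurements per person
    source: str = "primary_care"
    unit: str = "NA"


@dataclass(frozen=True)
class InjectedEffect:
    """A known genotype->phenotype effect.

    ``target`` names a measure code (quantitative: shifts each measured value
    by beta*dosage) or an event code (binary: per-person probability of
    carrying >=1 event follows a logistic model in dosage).
    """

    variant_id: str
    target: str
    beta: float
    model: str = "additive"      # additive | dominant | recessive
    kind: str = "quantitative"   # quantitative | binary
    baseline_logit: float = -2.0  # binary targets only


@dataclass
class CohortSpec:
    n_participants: int = 1000
    female_fraction: float = 0.5
    variants: Sequence[VariantSpec] = field(default_factory=list)
    cnv_copy_probs: Optional[Sequence[float]] = None  # over copies 0..8
    event_templates: Sequence[EventTemplate] = field(default_factory=list)
    measure_templates: Sequence[MeasureTemplate] = field(default_factory=list)
    injected_effects: Sequence[InjectedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValidationError("female_fraction must lie in [0,1]")
        if self.cnv_copy_probs is not None:
            p = np.asarray(self.cnv_copy_probs, dtype=float)
            if p.ndim != 1 or len(p) > 9 or (p < 0).any():
                raise ValidationError("cnv_copy_probs must be a probability vector over copies 0..8")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError("cnv_copy_probs must sum to 1 within 1e-9")

    @classmethod
    def from_yaml(cls, path: str) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            n_participants=int(raw.get("n_participants", 1000)),
            female_fraction=float(raw.get("female_fraction", 0.5)),
            variants=[VariantSpec(**v) for v in raw.get("variants", [])],
            cnv_copy_probs=raw.get("cnv_copy_probs"),
            event_templates=[EventTemplate(**e) for e in raw.get("event_templates", [])],
            measure_templates=[MeasureTemplate(**m) for m in raw.get("measure_templates", [])],
            injected_effects=[InjectedEffect(**i) for i in raw.get("injected_effects", [])],
            seed=int(raw.get("seed", 0)),
        )


def _rng(seed: int, label: int, extra: int | None = None) -> np.random.Generator:
    key = [seed, label] if extra is None else [seed, label, extra]
    return np.random.default_rng(key)


def _model_dosage(g: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return g
    if model == "dominant":
        return (g >= 1).astype(float)
    if model == "recessive":
        return (g >= 2).astype(float)
    raise ValidationError(f"unknown injected-effect model {model!r}")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, EventTable, GenotypeMatrix]:
    """Generate (participants, events, genotypes) deterministically from the spec seed."""
    n = spec.n_participants
    ids = [f"P{i + 1:06d}" for i in range(n)]

    # participants: sex and birth dates
    rng = _rng(spec.seed, _SUB_PARTICIPANTS)
    sex = np.where(rng.random(n) < spec.female_fraction, "female", "male")
    span = (_BIRTH_HI - _BIRTH_LO).days
    birth_offsets = rng.integers(0, span + 1, size=n)
    birth = pd.to_datetime([_BIRTH_LO + timedelta(days=int(d)) for d in birth_offsets])
    participants = pd.DataFrame({"eid": ids, "sex": sex, "birth_date": birth})

    # genotypes: Hardy-Weinberg hard calls for SNPs, categorical copies for CNVs
    grng = _rng(spec.seed, _SUB_GENOTYPES)
    vrows, dose = [], []
    for v in spec.variants:
        if v.kind == "snp":
            g = grng.binomial(2, v.maf, size=n).astype(float)
        elif v.kind == "cnv":
            probs = spec.cnv_copy_probs
            if probs is None:
                raise ValidationError(f"cnv variant {v.variant_id!r} requires cnv_copy_probs")
            g = grng.choice(len(probs), size=n, p=np.asarray(probs, float)).astype(float)
        else:
            raise ValidationError(f"unknown variant kind {v.kind!r}")
        vrows.append((v.variant_id, v.chrom, v.pos, v.ref, v.alt, v.kind))
        dose.append(g)
    variants = pd.DataFrame(
        vrows, columns=["variant_id", "chrom", "pos", "ref", "alt", "kind"]
    ) if vrows else pd.DataFrame(columns=["variant_id", "chrom", "pos", "ref", "alt", "kind"])
    genotypes = GenotypeMatrix(variants, np.asarray(dose) if dose else np.empty((0, n)), ids)
    dosage_by_id = {v.variant_id: genotypes.dosages[i] for i, v in enumerate(spec.variants)}

    frames: list[pd.DataFrame] = []

    # coded events: Poisson counts per person, dates uniform in [age 30, censor)
    erng = _rng(spec.seed, _SUB_EVENTS)
    binary_effects = {e.target: e for e in spec.injected_effects if e.kind == "binary"}
    for t in spec.event_templates:
        counts = erng.poisson(t.rate, size=n)
        eff = binary_effects.get(t.code)
        if eff is not None:
            g = _model_dosage(dosage_by_id[eff.variant_id], eff.model)
            p_case = 1.0 / (1.0 + np.exp(-(eff.baseline_logit + eff.beta * g)))
            forced = erng.random(n) < p_case
            counts = np.where(forced, np.maximum(counts, 1), 0)
        frames.append(_emit_events(erng, participants, counts, t.code, t.vocabulary,
                                   t.source, values=None, unit="NA"))

    # quantitative measures, with any injected quantitative effects applied
    mrng = _rng(spec.seed, _SUB_MEASURES)
    quant_effects = {e.target: e for e in spec.injected_effects if e.kind == "quantitative"}
    for t in spec.measure_templates:
        counts = np.full(n, t.visits)
        total = int(counts.sum())
        values = mrng.normal(t.mean, t.sd, size=total)
        eff = quant_effects.get(t.code)
        if eff is not None:
            g = _model_dosage(dosage_by_id[eff.variant_id], eff.model)
            values = values + np.repeat(eff.beta * g, counts)
        frames.append(_emit_events(mrng, participants, counts, t.code, "CUSTOM",
                                   t.source, values=values, unit=t.unit))

    if frames:
        events = pd.concat(frames, ignore_index=True)
        events = events.sort_values(["eid", "date", "source", "code"], kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["eid", "source", "vocab", "code", "date", "value", "unit"])
    return participants, EventTable(events), genotypes


def _emit_events(rng: np.random.Generator, participants: pd.DataFrame, counts: np.ndarray,
                 code: str, vocab: str, source: str,
                 values: np.ndarray | None, unit: str) -> pd.DataFrame:
    """Expand per-person counts into dated event rows (uniform between age 30 and censoring)."""
    eids = np.repeat(participants["eid"].to_numpy(), counts)
    births = np.repeat(participants["birth_date"].to_numpy(), counts)
    start = births + np.timedelta64(int(round(30 * 365.25)), "D")
    censor = np.datetime64(_CENSOR_DATE)
    windows = np.maximum((censor - start) / np.timedelta64(1, "D"), 1.0)
    offsets = (rng.random(len(eids)) * windows).astype(int)
    dates = start + offsets.astype("timedelta64[D]")
    return pd.DataFrame({
        "eid": eids,
        "source": source,
        "vocab": vocab,
        "code": code,
        "date": pd.to_datetime(dates),
        "value": values if values is not None else np.nan,
        "unit": unit,
    })


def inject_quantitative_effect(dosages: pd.Series, beta: float, noise_sd: float,
                               seed: int, intercept: float = 0.0,
                               code: str = "SYNTH_TRAIT") -> pd.Series:
    """value_i = intercept + beta * dosage_i + Normal(0, noise_sd), indexed by participant."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = _rng(seed, _SUB_EFFECTS)
    noise = rng.normal(0.0, noise_sd, size=len(dosages)) if noise_sd > 0 else 0.0
    out = intercept + beta * dosages.to_numpy(dtype=float) + noise
    return pd.Series(out, index=dosages.index, name=code)


def generate_null_binary(n: int, case_fraction: float, maf: float, reps: int,
                         seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Replicate (y, dosage) pairs with phenotype independent of genotype.

    Case status is Bernoulli(case_fraction) per person; dosages are
    Hardy-Weinberg hard calls at the stated minor-allele frequency.  Each
    replicate is reproducible from the seed plus its index.
    """
    if not (0.0 < case_fraction < 1.0):
        raise ValidationError("case_fraction must lie in (0,1)")
    if case_fraction * n < 1:
        raise PhewasError("case_fraction * n < 1: expected cases below one")
    out = []
    for rep in range(reps):
        rng = _rng(seed, _SUB_NULL, rep)
        y = (rng.random(n) < case_fraction).astype(float)
        g = rng.binomial(2, maf, size=n).astype(float)
        out.append((y, g))
    return out
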