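"""Model-specific genetic predictors: SNP encodings, CNV codings, risk scores.

Encodings from a dosage vector g in [0, 2]:

* additive:  the dosage itself
* dominant:  1{g >= 1}
* recessive: 1{g == 2}
* genotypic: two indicator columns (1{g == 1}, 1{g == 2}) for a 2-df test

Dominant/recessive/genotypic require hard calls {0,1,2}; imputed fractional
dosages are either rejected or, with the hard-call option, rounded to the
nearest integer when within a threshold (default 0.1) and set to missing
otherwise.  Multiallelic CNV copy numbers are used directly (linear coding)
or mapped through user-specified collapsed categories.  GRS values are
weighted sums of effect-allele-aligned dosages; alignment is by exact string
match on ref/alt with no strand inference — a mismatch is fatal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, GRSDefinition, PhewasError, ValidationError

__all__ = ["EncodedPredictor", "encode", "encode_cnv", "compute_grs", "grs_predictor"]

MODELS = ("additive", "dominant", "recessive", "genotypic")


@dataclass
class EncodedPredictor:
    """One predictor ready for regression: one column, or two for genotypic."""

    predictor_id: str
    model: str
    columns: pd.DataFrame  # index: participant ids; 1 column, 2 for genotypic

    def __post_init__(self) -> None:
        ncol = self.columns.shape[1]
        if self.model == "genotypic" and ncol != 2:
            raise ValidationError("genotypic predictor needs exactly 2 columns")
        if self.model != "genotypic" and ncol != 1:
            raise ValidationError(f"{self.model} predictor needs exactly 1 column")


def _hard_calls(g: np.ndarray, threshold: Optional[float]) -> np.ndarray:
    """Round fractional dosages to hard calls or fail; NaN propagates."""
    out = g.copy()
    obs = ~np.isnan(g)
    fractional = obs & (g != np.round(g))
    if fractional.any():
        if threshold is None:
            raise PhewasError(
                "fractional dosage requires the hard-call threshold option for "
                "dominant/recessive/genotypic models"
            )
        near = np.abs(g - np.round(g)) <= threshold
        out[fractional & near] = np.round(g[fractional & near])
        out[fractional & ~near] = np.nan
    return out


def encode(dosages: pd.Series, model: str, predictor_id: Optional[str] = None,
           hard_call_threshold: Optional[float] = None) -> EncodedPredictor:
    """Encode a SNP dosage vector under a genetic model; missing propagates."""
    if model not in MODELS:
        raise ValidationError(f"unknown genetic model {model!r}")
    pid = predictor_id or str(dosages.name)
    g = dosages.to_numpy(dtype=float)
    obs = ~np.isnan(g)
    if obs.any() and ((g[obs] < 0) | (g[obs] > 2)).any():
        raise ValidationError(f"dosage out of [0,2] for predictor {pid!r}")

    if model == "additive":
        cols = pd.DataFrame({pid: g}, index=dosages.index)
    else:
        h = _hard_calls(g, hard_call_threshold)
        miss = np.isnan(h)
        if model == "dominant":
            col = np.where(miss, np.nan, (h >= 1).astype(float))
            cols = pd.DataFrame({pid: col}, index=dosages.index)
        elif model == "recessive":
            col = np.where(miss, np.nan, (h == 2).astype(float))
            cols = pd.DataFrame({pid: col}, index=dosages.index)
        else:
            het = np.where(miss, np.nan, (h == 1).astype(float))
            hom = np.where(miss, np.nan, (h == 2).astype(float))
            cols = pd.DataFrame({f"{pid}_het": het, f"{pid}_hom": hom}, index=dosages.index)
    return EncodedPredictor(pid, model, cols)


def encode_cnv(copies: pd.Series, scheme: Literal["linear"] | Mapping[int, float] = "linear",
               predictor_id: Optional[str] = None, max_copy: int = 8) -> EncodedPredictor:
    """Encode multiallelic CNV copy numbers.

    ``scheme='linear'`` uses the copy number itself (linear additive model);
    a mapping collapses copies into user-specified category values.  Copies
    absent from the mapping become missing with a warning; non-integer copies
    are fatal.
    """
    pid = predictor_id or str(copies.name)
    c = copies.to_numpy(dtype=float)
    obs = ~np.isnan(c)
    if obs.any() and (c[obs] != np.round(c[obs])).any():
        raise ValidationError(f"non-integer CNV copy number for predictor {pid!r}")
    if obs.any() and ((c[obs] < 0) | (c[obs] > max_copy)).any():
        raise ValidationError(f"CNV copy number outside [0,{max_copy}] for predictor {pid!r}")

    if scheme == "linear":
        out = c
        model = "cnv_linear"
    else:
        mapping = {int(k): float(v) for k, v in scheme.items()}
        out = np.full_like(c, np.nan)
        unmapped = 0
        for i, v in enumerate(c):
            if np.isnan(v):
                continue
            if int(v) in mapping:
                out[i] = mapping[int(v)]
            else:
                unmapped += 1
        if unmapped:
            warnings.warn(f"{unmapped} copy number(s) not in the collapse map; set to missing",
                          stacklevel=2)
        model = "cnv_collapsed"
    return EncodedPredictor(pid, model, pd.DataFrame({pid: out}, index=copies.index))


def compute_grs(definition: GRSDefinition, genotypes: GenotypeMatrix,
                missing_policy: Literal["mean_impute", "complete"] = "mean_impute",
                on_absent_variant: Literal["error", "skip"] = "error",
                ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-participant genetic risk score: sum of weight * aligned dosage.

    Dosages are aligned to the effect allele: used as-is when the effect
    allele is the alt allele, flipped to 2-d when it is the ref allele, and
    fatal otherwise.  Missing dosages make the score missing under policy
    ``complete`` or are replaced by 2 * alt-allele frequency (the cohort mean
    dosage) under ``mean_impute``.  Returns (scores, per-variant report).
    """
    var = genotypes.variants.set_index("variant_id")
    n = len(genotypes.participants)
    score = np.zeros(n)
    missing_any = np.zeros(n, dtype=bool)
    report_rows = []
    used = 0
    for row in definition.entries.itertuples(index=False):
        if row.variant_id not in var.index:
            if on_absent_variant == "error":
                raise PhewasError(f"GRS variant {row.variant_id!r} absent from genotype matrix")
            report_rows.append((row.variant_id, "absent", np.nan))
            continue
        v = var.loc[row.variant_id]
        i = var.index.get_loc(row.variant_id)
        d = genotypes.dosages[i].astype(float)
        if row.effect_allele == v["alt"]:
            aligned = d
        elif row.effect_allele == v["ref"]:
            aligned = 2.0 - d
        else:
            raise PhewasError(
                f"effect allele {row.effect_allele!r} of variant {row.variant_id!r} "
                f"matches neither ref {v['ref']!r} nor alt {v['alt']!r}"
            )
        miss = np.isnan(aligned)
        if miss.any():
            if missing_policy == "mean_impute":
                aligned = np.where(miss, np.nanmean(aligned), aligned)
            else:
                missing_any |= miss
                aligned = np.where(miss, 0.0, aligned)
        score += row.weight * aligned
        used += 1
        report_rows.append((row.variant_id, "used", float(np.nanmean(d) / 2.0)))
    if missing_policy == "complete":
        score = np.where(missing_any, np.nan, score)
    report = pd.DataFrame(report_rows, columns=["variant_id", "status", "alt_frequency"])
    scores = pd.Series(score, index=genotypes.participants, name="GRS")
    return scores, report


def grs_predictor(definition: GRSDefinition, genotypes: GenotypeMatrix,
                  predictor_id: str = "GRS",
                  missing_policy: Literal["mean_impute", "complete"] = "mean_impute",
                  ) -> EncodedPredictor:
    scores, _ = compute_grs(definition, genotypes, missing_policy)
    return EncodedPredictor(predictor_id, "grs",
                            scores.rename(predictor_id).to_frame())
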