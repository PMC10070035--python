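"""Orchestrate the full PheWAS: test grid, minimum-count filters, FDR, plots.

Every (phenotype, predictor, stratum) combination is either fitted or skipped
with a logged reason, and the two sets partition the planned grid.  Binary
phenotypes use Firth-fallback logistic regression (2-df LRT for the genotypic
model); quantitative phenotypes use OLS, optionally after a rank-based
inverse normal transform.  Benjamini-Hochberg FDR is computed across the
whole run by default (one FDR per PheWAS), with a per-stratum option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import (
    build_design,
    firth_fallback,
    fit_linear,
    inverse_normal_transform,
    lrt_genotypic,
)
from .core import AssociationResult, PhenotypeMatrix, PhewasError, ValidationError
from .encoding import EncodedPredictor

__all__ = ["RunConfig", "run_phewas", "apply_fdr", "top_hits", "manhattan_data",
           "render_manhattan"]

_BINARY_MODELS = {"additive", "dominant", "recessive", "genotypic",
                  "grs", "cnv_linear", "cnv_collapsed"}


@dataclass
class RunConfig:
    covariates: Sequence[str] = field(default_factory=list)
    min_cases: int = 50
    min_controls: int = 50
    min_n_quantitative: int = 100
    fdr_level: float = 0.01
    strata: Sequence[str] = ("all",)
    apply_irnt: bool = False
    fdr_per_stratum: bool = False
    sex_covariate: Optional[str] = "sex"   # removed automatically inside sex strata
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValidationError("at least one stratum required")
        if not (0.0 < self.fdr_level < 1.0):
            raise ValidationError("fdr_level must lie in (0,1)")


def run_phewas(pheno: PhenotypeMatrix, predictors: Sequence[EncodedPredictor],
               covars: Optional[pd.DataFrame], config: RunConfig,
               ) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Fit every phenotype x predictor combination in the requested strata.

    Returns (FDR-annotated results, skip log).  Output ordering is
    deterministic: (phenotype_id, predictor_id, model, stratum).
    """
    if covars is not None:
        for c in config.covariates:
            if c not in covars.columns:
                raise PhewasError(f"covariate column {c!r} missing from covariate table")
        covars = covars[list(config.covariates)]
    elif config.covariates:
        raise PhewasError("covariates requested but no covariate table supplied")

    overlap = set(pheno.values.index)
    for pred in predictors:
        overlap &= set(pred.columns.index)
    if not overlap:
        raise PhewasError("phenotype and predictor participant sets do not overlap")

    plan = []
    for m in pheno.meta:
        if m.stratum not in config.strata:
            continue
        for pred in predictors:
            plan.append((m, pred))
    plan.sort(key=lambda t: (t[0].phenotype_id, t[1].predictor_id, t[1].model, t[0].stratum))

    results: list[AssociationResult] = []
    skips = []
    for m, pred in plan:
        y = pheno.values[m.column_id]
        cov = covars
        if cov is not None and config.sex_covariate in (cov.columns if cov is not None else []):
            if m.stratum != "all" or getattr(m, "_sex_restriction", None) is not None:
                cov = cov.drop(columns=[config.sex_covariate])
        design = build_design(y, pred.columns, cov, binary=(m.kind == "binary"))

        if m.kind == "binary":
            if design.n_cases is not None and design.n_cases < config.min_cases:
                skips.append((m.column_id, pred.predictor_id, m.stratum, "min_cases"))
                continue
            if design.n_controls is not None and design.n_controls < config.min_controls:
                skips.append((m.column_id, pred.predictor_id, m.stratum, "min_controls"))
                continue
            if pred.model == "genotypic":
                fit = lrt_genotypic(design)
            else:
                fit = firth_fallback(design)
        else:
            if design.n_used < config.min_n_quantitative:
                skips.append((m.column_id, pred.predictor_id, m.stratum, "min_n"))
                continue
            if config.apply_irnt:
                design = build_design(inverse_normal_transform(y), pred.columns, cov,
                                      binary=False)
            fit = fit_linear(design)

        results.append(AssociationResult(
            phenotype_id=m.column_id,
            predictor_id=pred.predictor_id,
            model=pred.model,
            n=fit.n_used,
            n_cases=fit.n_cases,
            n_controls=fit.n_controls,
            beta=float(fit.beta[0]) if fit.beta.size else float("nan"),
            se=float(fit.se[0]) if fit.se.size else float("nan"),
            p=float(fit.p[0]) if fit.p.size else float("nan"),
            method=fit.method,
            converged=fit.converged,
            stratum=m.stratum,
            category=m.category,
        ))

    skip_log = pd.DataFrame(skips, columns=["phenotype_id", "predictor_id", "stratum", "reason"])
    if config.fdr_per_stratum:
        for stratum in {r.stratum for r in results}:
            apply_fdr([r for r in results if r.stratum == stratum], config.fdr_level)
    else:
        apply_fdr(results, config.fdr_level)
    return results, skip_log


def apply_fdr(results: Sequence[AssociationResult], level: float = 0.01,
              ) -> Sequence[AssociationResult]:
    """Benjamini-Hochberg step-up q-values in place over the converged tests.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; non-converged results
    carry no p-value and are excluded from m.
    """
    tested = [r for r in results if r.converged and np.isfinite(r.p)]
    m = len(tested)
    if m == 0:
        return results
    order = sorted(range(m), key=lambda i: tested[i].p)
    qs = np.empty(m)
    running = math.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * tested[i].p / rank_from_top)
        qs[i] = min(running, 1.0)
    for r, q in zip(tested, qs):
        r.q_value = float(q)
    return results


def top_hits(results: Sequence[AssociationResult], n: int = 5) -> pd.DataFrame:
    """The n smallest-p converged results; ties broken by phenotype_id."""
    conv = [r for r in results if r.converged and np.isfinite(r.p)]
    conv.sort(key=lambda r: (r.p, r.phenotype_id, r.predictor_id, r.model))
    rows = [(r.phenotype_id, r.predictor_id, r.model, r.stratum, r.n, r.n_cases,
             r.n_controls, r.beta, r.se, r.p, r.q_value, r.method) for r in conv[:n]]
    return pd.DataFrame(rows, columns=["phenotype_id", "predictor_id", "model", "stratum",
                                       "n", "n_cases", "n_controls", "beta", "se", "p",
                                       "q_value", "method"])


def manhattan_data(results: Sequence[AssociationResult], level: float = 0.01,
                   ) -> tuple[pd.DataFrame, Optional[float]]:
    """Plot-ready table of (phenotype, category, -log10 p, significant flag).

    The significance line sits at the largest p with q <= level, or None when
    nothing is significant.
    """
    conv = [r for r in results if r.converged and np.isfinite(r.p)]
    rows = []
    for r in conv:
        sig = r.q_value is not None and r.q_value <= level
        rows.append((r.phenotype_id, r.category, -math.log10(r.p), bool(sig)))
    df = pd.DataFrame(rows, columns=["phenotype_id", "category", "neg_log10_p", "significant"])
    sig_p = [r.p for r in conv if r.q_value is not None and r.q_value <= level]
    line = -math.log10(max(sig_p)) if sig_p else None
    return df, line


def render_manhattan(results: Sequence[AssociationResult], path: str,
                     level: float = 0.01) -> None:
    """Render a Manhattan-style plot of -log10 p by phenotype category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df, line = manhattan_data(results, level)
    if df.empty:
        raise PhewasError("no converged results to plot")
    df = df.sort_values(["category", "phenotype_id"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(max(6, len(df) * 0.25), 4))
    for i, (cat, grp) in enumerate(df.groupby("category", sort=True)):
        ax.scatter(grp.index, grp["neg_log10_p"], s=14, label=str(cat))
    if line is not None:
        ax.axhline(line, linestyle="--", linewidth=1, color="red")
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["phenotype_id"], rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
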