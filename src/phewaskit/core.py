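"""Domain types, file readers/writers and validation for every table in the pipeline.

The on-disk dialect is plain TSV throughout.  Missing values are accepted as
empty string or ``NA`` on input and always written back as ``NA``.  Dates are
ISO-8601 calendar dates (time-of-day is ignored).  Sex is coded ``F``/``M``/``NA``
on disk.  Genomic coordinates are carried as 1-based metadata only; no interval
arithmetic ever happens here.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Source",
    "Vocabulary",
    "CodeSet",
    "CodeSetMember",
    "EventTable",
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "AssociationResult",
    "GRSDefinition",
    "PhewasError",
    "ValidationError",
    "read_participants",
    "write_participants",
    "read_events",
    "write_events",
    "validate_event_dates",
    "read_dosages",
    "read_vcf_dosages",
    "write_dosages",
    "read_grs_weights",
    "write_results",
    "read_results",
    "results_to_frame",
    "NA_TOKEN",
]

NA_TOKEN = "NA"

EVENT_COLUMNS = ["eid", "source", "vocab", "code", "date", "value", "unit"]
RESULT_COLUMNS = [
    "phenotype_id", "predictor_id", "model", "n", "n_cases", "n_controls",
    "beta", "se", "p", "method", "converged", "q_value",
]


class PhewasError(Exception):
    """Fatal, named error for malformed input or contract violation."""


class ValidationError(PhewasError):
    pass


class Sex(str, Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class Source(str, Enum):
    hospital = "hospital"
    primary_care = "primary_care"
    self_report = "self_report"
    prescription = "prescription"


class Vocabulary(str, Enum):
    ICD10 = "ICD10"
    ICD9 = "ICD9"
    READ = "READ"
    CUSTOM = "CUSTOM"


_SEX_FROM_DISK = {"F": Sex.female, "M": Sex.male, "NA": Sex.unknown, "": Sex.unknown}
_SEX_TO_DISK = {Sex.female: "F", Sex.male: "M", Sex.unknown: "NA"}


# ---------------------------------------------------------------------------
# code sets

@dataclass(frozen=True)
class CodeSetMember:
    vocabulary: str
    pattern: str
    match_mode: str = "exact"  # "exact" | "prefix"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError("code-set pattern must be non-empty")
        if self.match_mode not in ("exact", "prefix"):
            raise ValidationError(f"unknown match_mode {self.match_mode!r}")

    def matches(self, vocabulary: str, code: str) -> bool:
        if vocabulary != self.vocabulary:
            return False
        if self.match_mode == "exact":
            return code == self.pattern
        return code.startswith(self.pattern)


@dataclass(frozen=True)
class CodeSet:
    """A named collection of (vocabulary, pattern) matchers.

    A code set matches an event iff the vocabularies are equal and the code
    either equals the pattern (``exact``) or starts with it (``prefix``) —
    prefix matching is how related ICD-9/ICD-10 codes are grouped into one
    clinical entity.
    """

    name: str
    members: tuple[CodeSetMember, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"code set {self.name!r} has no members")

    def matches(self, vocabulary: str, code: str) -> bool:
        return any(m.matches(vocabulary, code) for m in self.members)

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        """Vectorised membership mask over an event frame."""
        out = np.zeros(len(events), dtype=bool)
        vocab = events["vocab"].to_numpy()
        code = events["code"].astype(str)
        for m in self.members:
            vmask = vocab == m.vocabulary
            if m.match_mode == "exact":
                out |= vmask & (code == m.pattern).to_numpy()
            else:
                out |= vmask & code.str.startswith(m.pattern).to_numpy()
        return out


# ---------------------------------------------------------------------------
# tables

@dataclass
class EventTable:
    """Long-format coded clinical events.

    ``data`` columns: eid (str), source, vocab, code (str), date
    (datetime64[ns], date-granular), value (float, NaN when the event is not a
    measurement), unit (str or NA).  ``n_rejected``/``rejections`` record rows
    dropped during parsing so validation is total: every malformed row either
    raised a named error or is counted here.
    """

    data: pd.DataFrame
    n_rejected: int = 0
    rejections: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.data)

    def for_participants(self, ids: Iterable[str]) -> "EventTable":
        ids = set(ids)
        return EventTable(self.data[self.data["eid"].isin(ids)].copy(), 0, None)


@dataclass
class GenotypeMatrix:
    """Variants x participants dosage matrix.

    ``variants``: frame with variant_id, chrom, pos, ref, alt, kind
    ("snp" | "cnv").  ``dosages``: float array, one row per variant, NaN for
    missing (never a sentinel number).  SNP dosages live in [0, 2]; CNV rows
    hold integer copy numbers in {0..max_copy}.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    participants: list[str]
    max_copy: int = 8

    def __post_init__(self) -> None:
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants["variant_id"][self.variants["variant_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant_id {dup!r}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.participants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.participants)} participants"
            )
        self._check_bounds()

    def _check_bounds(self) -> None:
        kinds = self.variants["kind"].to_numpy()
        vids = self.variants["variant_id"].to_numpy()
        for i, (vid, kind) in enumerate(zip(vids, kinds)):
            row = self.dosages[i]
            finite = row[~np.isnan(row)]
            if kind == "snp":
                bad = (finite < 0) | (finite > 2)
                if bad.any():
                    j = int(np.flatnonzero(~np.isnan(row) & ((row < 0) | (row > 2)))[0])
                    raise ValidationError(
                        f"SNP dosage out of [0,2] for variant {vid!r}, "
                        f"participant {self.participants[j]!r}: {row[j]}"
                    )
            elif kind == "cnv":
                if np.any(finite != np.round(finite)):
                    j = int(np.flatnonzero(~np.isnan(row) & (row != np.round(row)))[0])
                    raise ValidationError(
                        f"CNV copy number not an integer for variant {vid!r}, "
                        f"participant {self.participants[j]!r}: {row[j]}"
                    )
                bad = (finite < 0) | (finite > self.max_copy)
                if bad.any():
                    j = int(np.flatnonzero(~np.isnan(row) & ((row < 0) | (row > self.max_copy)))[0])
                    raise ValidationError(
                        f"CNV copy number out of [0,{self.max_copy}] for variant {vid!r}, "
                        f"participant {self.participants[j]!r}: {row[j]}"
                    )
            else:
                raise ValidationError(f"unknown variant kind {kind!r} for {vid!r}")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def dosage_series(self, variant_id: str) -> pd.Series:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        i = self.variants.index.get_loc(idx[0])
        return pd.Series(self.dosages[i], index=self.participants, name=variant_id)

    def alt_frequency(self, variant_id: str) -> float:
        d = self.dosage_series(variant_id).to_numpy()
        return float(np.nanmean(d) / 2.0)


@dataclass
class PhenotypeColumn:
    column_id: str
    phenotype_id: str
    kind: str          # "binary" | "quantitative"
    stratum: str = "all"  # "all" | "female_only" | "male_only"
    category: str = "uncategorised"


@dataclass
class PhenotypeMatrix:
    """Participants x phenotypes with per-column metadata.

    ``values``: frame indexed by participant_id; binary columns contain only
    {0.0, 1.0, NaN}, quantitative columns reals or NaN.  ``meta``: one
    PhenotypeColumn per value column, same order; column ids are unique
    including any stratum suffix.
    """

    values: pd.DataFrame
    meta: list[PhenotypeColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.column_id for m in self.meta]
        if list(self.values.columns) != ids:
            raise ValidationError("phenotype matrix metadata does not match value columns")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate phenotype column id")
        for m in self.meta:
            if m.kind == "binary":
                col = self.values[m.column_id]
                ok = col.isna() | col.isin([0.0, 1.0])
                if not ok.all():
                    raise ValidationError(
                        f"binary column {m.column_id!r} contains values outside {{0,1,missing}}"
                    )

    def column_meta(self, column_id: str) -> PhenotypeColumn:
        for m in self.meta:
            if m.column_id == column_id:
                return m
        raise KeyError(column_id)

    def add_column(self, values: pd.Series, meta: PhenotypeColumn) -> None:
        if meta.column_id in self.values.columns:
            raise ValidationError(f"duplicate phenotype_id {meta.column_id!r}")
        self.values[meta.column_id] = values.reindex(self.values.index)
        self.meta.append(meta)

    @classmethod
    def empty(cls, participant_ids: Sequence[str]) -> "PhenotypeMatrix":
        return cls(pd.DataFrame(index=pd.Index(participant_ids, name="eid")), [])

    # -- TSV round trip (our own format; a values file plus a .meta sidecar)
    def write(self, path: str) -> None:
        out = self.values.copy()
        out.insert(0, "eid", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g")
        meta = pd.DataFrame(
            [(m.column_id, m.phenotype_id, m.kind, m.stratum, m.category) for m in self.meta],
            columns=["column_id", "phenotype_id", "kind", "stratum", "category"],
        )
        meta.to_csv(str(path) + ".meta", sep="\t", index=False)

    @classmethod
    def read(cls, path: str) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"eid": str}, na_values=[NA_TOKEN, ""], keep_default_na=False)
        df = df.set_index("eid")
        df.index.name = "eid"
        try:
            meta_df = pd.read_csv(str(path) + ".meta", sep="\t", keep_default_na=False)
            meta = [PhenotypeColumn(*row) for row in meta_df.itertuples(index=False)]
        except FileNotFoundError:
            meta = [PhenotypeColumn(c, c, "quantitative") for c in df.columns]
        return cls(df.astype(float), meta)


@dataclass
class GRSDefinition:
    """Genetic risk score definition: per-variant effect allele and weight."""

    entries: pd.DataFrame  # columns: variant_id, effect_allele, weight

    def __post_init__(self) -> None:
        if self.entries["variant_id"].duplicated().any():
            dup = self.entries["variant_id"][self.entries["variant_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant_id {dup!r} in GRS definition")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AssociationResult:
    phenotype_id: str
    predictor_id: str
    model: str            # additive | dominant | recessive | genotypic | grs | cnv_linear | cnv_collapsed
    n: int
    n_cases: Optional[int]
    n_controls: Optional[int]
    beta: float
    se: float
    p: float
    method: str           # linear | logistic | firth | lrt_2df
    converged: bool
    q_value: Optional[float] = None
    stratum: str = "all"
    category: str = "uncategorised"

    def __post_init__(self) -> None:
        if self.converged:
            if not (0.0 < self.p <= 1.0 or math.isnan(self.p)):
                raise ValidationError(f"p-value {self.p} outside (0,1]")
            if self.n_cases is not None and self.n_controls is not None:
                if self.n_cases + self.n_controls != self.n:
                    raise ValidationError("n_cases + n_controls != n for binary phenotype")


# ---------------------------------------------------------------------------
# participants

def read_participants(path: str) -> pd.DataFrame:
    """Read the participant table (eid, sex, birth_date), sex F/M/NA on disk."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    _require_columns(df, ["eid", "sex", "birth_date"], path)
    if df["eid"].duplicated().any():
        dup = df["eid"][df["eid"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate participant_id {dup!r} in {path}")
    sex = df["sex"].map(lambda s: _SEX_FROM_DISK.get(s, None))
    if sex.isna().any():
        bad = df["sex"][sex.isna()].iloc[0]
        raise ValidationError(f"unknown sex code {bad!r}; expected F, M or NA")
    birth = pd.to_datetime(df["birth_date"], format="%Y-%m-%d", errors="coerce")
    if birth.isna().any():
        bad = df["birth_date"][birth.isna()].iloc[0]
        raise ValidationError(f"unparseable birth_date {bad!r}")
    return pd.DataFrame({"eid": df["eid"], "sex": sex.map(lambda s: s.value), "birth_date": birth})


def write_participants(participants: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame({
        "eid": participants["eid"],
        "sex": participants["sex"].map(lambda s: _SEX_TO_DISK[Sex(s)]),
        "birth_date": participants["birth_date"].dt.strftime("%Y-%m-%d"),
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# events

_VALID_SOURCES = {s.value for s in Source}
_VALID_VOCABS = {v.value for v in Vocabulary}


def read_events(path: str) -> EventTable:
    """Read a long-format clinical event TSV.

    Rows with unparseable dates or unknown source/vocabulary are dropped and
    counted in the rejection report; missing header columns are fatal.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty event file {path}") from None
    _require_columns(raw, EVENT_COLUMNS, path)
    if raw.empty:
        raise ValidationError(f"event file {path} has a header but no rows")

    reasons = pd.Series("", index=raw.index, dtype=object)
    dates = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    reasons[dates.isna()] = "unparseable date"
    bad_source = ~raw["source"].isin(_VALID_SOURCES)
    reasons[bad_source & (reasons == "")] = "unknown source"
    bad_vocab = ~raw["vocab"].isin(_VALID_VOCABS)
    reasons[bad_vocab & (reasons == "")] = "unknown vocabulary"
    empty_code = raw["code"].str.strip() == ""
    reasons[empty_code & (reasons == "")] = "empty code"
    raw_value = raw["value"].mask(raw["value"].isin(["", NA_TOKEN]))
    values = pd.to_numeric(raw_value, errors="coerce")
    bad_value = values.isna() & ~raw["value"].isin(["", NA_TOKEN])
    reasons[bad_value & (reasons == "")] = "non-numeric value"

    keep = reasons == ""
    rejections = pd.DataFrame({"row": raw.index[~keep] + 2, "reason": reasons[~keep]})
    data = pd.DataFrame({
        "eid": raw.loc[keep, "eid"].astype(str),
        "source": raw.loc[keep, "source"],
        "vocab": raw.loc[keep, "vocab"],
        "code": raw.loc[keep, "code"],
        "date": dates[keep],
        "value": values[keep],
        "unit": raw.loc[keep, "unit"].replace({"": NA_TOKEN}),
    }).reset_index(drop=True)
    return EventTable(data, n_rejected=int((~keep).sum()), rejections=rejections.reset_index(drop=True))


def write_events(events: EventTable | pd.DataFrame, path: str) -> None:
    df = events.data if isinstance(events, EventTable) else events
    out = df.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g",
               columns=EVENT_COLUMNS)


def validate_event_dates(events: EventTable, participants: pd.DataFrame) -> EventTable:
    """Drop (with a warning) events dated before the participant's birth."""
    birth = participants.set_index("eid")["birth_date"]
    ev = events.data
    b = ev["eid"].map(birth)
    bad = b.notna() & (ev["date"] < b)
    if bad.any():
        warnings.warn(
            f"dropped {int(bad.sum())} event(s) dated before participant birth",
            stacklevel=2,
        )
    return EventTable(ev[~bad].reset_index(drop=True), events.n_rejected + int(bad.sum()),
                      events.rejections)


# ---------------------------------------------------------------------------
# dosages

def read_dosages(path: str, kind: str = "snp", max_copy: int = 8) -> GenotypeMatrix:
    """Read the canonical TSV dosage dialect.

    First columns: variant_id, chrom, pos, ref, alt; then one column per
    participant.  Bounds are checked per variant kind; any out-of-bounds value
    is fatal and names the variant and participant.
    """
    if kind not in ("snp", "cnv"):
        raise ValidationError(f"unknown variant kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    _require_columns(df, ["variant_id", "chrom", "pos", "ref", "alt"], path)
    participants = [c for c in df.columns if c not in ("variant_id", "chrom", "pos", "ref", "alt")]
    variants = pd.DataFrame({
        "variant_id": df["variant_id"],
        "chrom": df["chrom"],
        "pos": pd.to_numeric(df["pos"]).astype(int),
        "ref": df["ref"],
        "alt": df["alt"],
        "kind": kind,
    })
    raw = df[participants].apply(lambda s: s.mask(s.isin(["", NA_TOKEN])))
    dosages = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    unconvertible = np.isnan(dosages) & raw.notna().to_numpy()
    if unconvertible.any():
        i, j = map(int, np.argwhere(unconvertible)[0])
        raise ValidationError(
            f"non-numeric dosage for variant {variants['variant_id'].iloc[i]!r}, "
            f"participant {participants[j]!r}"
        )
    return GenotypeMatrix(variants, dosages, participants, max_copy=max_copy)


def read_vcf_dosages(path: str, kind: str = "snp", dosage_field: str = "DS") -> GenotypeMatrix:
    """Optional VCF reader using the per-genotype dosage FORMAT field (default DS)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise PhewasError("cyvcf2 is required for VCF input; install phewaskit[vcf]") from exc
    vcf = VCF(path)
    participants = list(vcf.samples)
    rows, dose = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        rows.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0], kind))
        ds = rec.format(dosage_field)
        if ds is None:
            raise ValidationError(f"variant {vid!r} has no {dosage_field} field")
        dose.append(np.asarray(ds, dtype=float).reshape(-1))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "kind"])
    return GenotypeMatrix(variants, np.asarray(dose), participants)


def write_dosages(matrix: GenotypeMatrix, path: str) -> None:
    meta = matrix.variants[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    dose = pd.DataFrame(matrix.dosages, columns=matrix.participants)
    out = pd.concat([meta.reset_index(drop=True), dose], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g")


# ---------------------------------------------------------------------------
# GRS weights

def read_grs_weights(path: str) -> GRSDefinition:
    """Read a TSV of (variant_id, effect_allele, weight); bad weights are fatal."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    _require_columns(df, ["variant_id", "effect_allele", "weight"], path)
    weights = pd.to_numeric(df["weight"], errors="coerce")
    if weights.isna().any():
        line = int(weights.index[weights.isna()][0]) + 2  # header is line 1
        raise ValidationError(f"non-numeric GRS weight at line {line} of {path}")
    return GRSDefinition(pd.DataFrame({
        "variant_id": df["variant_id"],
        "effect_allele": df["effect_allele"],
        "weight": weights.astype(float),
    }))


# ---------------------------------------------------------------------------
# results

def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = [
        (r.phenotype_id, r.predictor_id, r.model, r.n, r.n_cases, r.n_controls,
         r.beta, r.se, r.p, r.method, r.converged, r.q_value)
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Sequence[AssociationResult], path: str) -> None:
    """Write association results as TSV with fixed column order."""
    if not results:
        raise ValidationError("cannot write an empty result list")
    df = results_to_frame(results)
    df["converged"] = df["converged"].map({True: "true", False: "false"})
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_results(path: str) -> list[AssociationResult]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    _require_columns(df, RESULT_COLUMNS, path)

    def _opt_int(s: str) -> Optional[int]:
        return None if s == NA_TOKEN else int(s)

    def _opt_float(s: str) -> Optional[float]:
        return None if s == NA_TOKEN else float(s)

    out = []
    for row in df.itertuples(index=False):
        out.append(AssociationResult(
            phenotype_id=row.phenotype_id, predictor_id=row.predictor_id, model=row.model,
            n=int(row.n), n_cases=_opt_int(row.n_cases), n_controls=_opt_int(row.n_controls),
            beta=float(row.beta) if row.beta != NA_TOKEN else float("nan"),
            se=float(row.se) if row.se != NA_TOKEN else float("nan"),
            p=float(row.p) if row.p != NA_TOKEN else float("nan"),
            method=row.method, converged=row.converged == "true",
            q_value=_opt_float(row.q_value),
        ))
    return out


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r} in {path}")
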