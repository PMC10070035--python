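"""Phenotype engine: turn participants + coded events into a phenotype matrix.

Supports code-group binary phenotypes (phecode-style ICD groupings with
control exclusions), composite case/control definitions combining several
data sources through boolean logic, quantitative traits from repeated
primary-care measurements, longitudinal trajectory slopes, drug-response
deltas, disease-progression phenotypes (age of onset, post-onset event
counts), collapsing of extremely highly correlated traits, and sex strata.

Conventions (all configurable where they are parameters):

* Event counting is by *distinct date*: same-day duplicate codes count once,
  which guards against administrative/billing duplicates.
* Controls for a code group are the non-cases minus the cases of any listed
  exclusion group, mirroring phecode practice.
* Ages use 365.25-day years.
* Participants of unknown sex are missing in both sex strata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import (
    CodeSet,
    CodeSetMember,
    EventTable,
    PhenotypeColumn,
    PhenotypeMatrix,
    PhewasError,
    ValidationError,
)

__all__ = [
    "Predicate", "AnyOf", "AllOf", "NotRule", "Rule",
    "PhenotypeDefinition", "QuantTraitSpec", "CodeGroupMap",
    "map_code_groups", "evaluate_composite", "extract_quantitative",
    "trajectory_slope", "drug_response", "age_of_onset", "event_count",
    "collapse_correlated", "stratify_by_sex", "build_phenotype_matrix",
    "load_definitions", "read_code_group_map",
]

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# boolean phenotype rules

@dataclass(frozen=True)
class Predicate:
    """Leaf predicate: participant has >= min_count distinct-date events
    matching the code set (optionally restricted to one source)."""

    code_set: str
    source: Optional[str] = None
    min_count: int = 1

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")


@dataclass(frozen=True)
class AnyOf:
    children: tuple["Rule", ...]


@dataclass(frozen=True)
class AllOf:
    children: tuple["Rule", ...]


@dataclass(frozen=True)
class NotRule:
    child: "Rule"


Rule = Union[Predicate, AnyOf, AllOf, NotRule]


def parse_rule(raw: Mapping) -> Rule:
    """Parse {any|all|not: ...} dicts with {code_set, source?, min_count?} leaves."""
    if "any" in raw:
        return AnyOf(tuple(parse_rule(c) for c in raw["any"]))
    if "all" in raw:
        return AllOf(tuple(parse_rule(c) for c in raw["all"]))
    if "not" in raw:
        return NotRule(parse_rule(raw["not"]))
    if "code_set" in raw:
        return Predicate(raw["code_set"], raw.get("source"), int(raw.get("min_count", 1)))
    raise ValidationError(f"cannot parse rule node {raw!r}")


def _rule_code_sets(rule: Rule) -> set[str]:
    if isinstance(rule, Predicate):
        return {rule.code_set}
    if isinstance(rule, (AnyOf, AllOf)):
        return set().union(*(_rule_code_sets(c) for c in rule.children)) if rule.children else set()
    return _rule_code_sets(rule.child)


def _positive_predicates(rule: Rule) -> list[Predicate]:
    """Predicates reachable without passing through a NOT (case-qualifying)."""
    if isinstance(rule, Predicate):
        return [rule]
    if isinstance(rule, (AnyOf, AllOf)):
        out: list[Predicate] = []
        for c in rule.children:
            out.extend(_positive_predicates(c))
        return out
    return []  # NOT subtree contributes no qualifying events


@dataclass(frozen=True)
class QuantTraitSpec:
    code_set: str
    aggregation: str = "mean"    # mean | median | first | last | min | max
    min_measurements: int = 1
    plausible_range: Optional[tuple[float, float]] = None
    unit_filter: Optional[str] = None

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean", "median", "first", "last", "min", "max"):
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")
        if self.min_measurements < 1:
            raise ValidationError("min_measurements must be >= 1")
        if self.plausible_range is not None:
            lo, hi = self.plausible_range
            if not lo < hi:
                raise ValidationError("plausible_range low must be < high")


@dataclass(frozen=True)
class TrajectorySpec:
    code_set: str
    min_measurements: int = 3

    def __post_init__(self) -> None:
        if self.min_measurements < 3:
            raise ValidationError("trajectory needs min_measurements >= 3")


@dataclass(frozen=True)
class DrugResponseSpec:
    rx_code_set: str
    measure_code_set: str
    pre_window_days: int = 365
    post_lag_days: int = 30
    post_end_days: int = 365

    def __post_init__(self) -> None:
        if not self.post_lag_days < self.post_end_days:
            raise ValidationError("post window lag must be < end")
        if self.post_lag_days < 1:
            raise ValidationError("post window must start at lag >= 1 day")


@dataclass
class PhenotypeDefinition:
    """Declarative phenotype: binary boolean-rule definitions, quantitative
    trait extraction, or a derived phenotype (trajectory, drug response,
    age of onset, post-onset event count)."""

    phenotype_id: str
    kind: str                                   # "binary" | "quantitative"
    case_rule: Optional[Rule] = None
    control_exclusion_rule: Optional[Rule] = None
    sex_restriction: str = "none"               # none | female_only | male_only
    quantitative_spec: Optional[QuantTraitSpec] = None
    trajectory: Optional[TrajectorySpec] = None
    drug_response: Optional[DrugResponseSpec] = None
    age_of_onset_of: Optional[str] = None       # phenotype_id of a binary definition
    event_count_of: Optional[tuple[str, str]] = None  # (binary phenotype_id, qualifying code set)
    category: str = "uncategorised"

    def __post_init__(self) -> None:
        if self.sex_restriction not in ("none", "female_only", "male_only"):
            raise ValidationError(f"unknown sex_restriction {self.sex_restriction!r}")
        if self.kind == "binary":
            if self.case_rule is None:
                raise ValidationError(f"binary phenotype {self.phenotype_id!r} needs a case_rule")
            if isinstance(self.case_rule, NotRule):
                raise ValidationError("NOT may not appear at the root of a case rule")
        elif self.kind == "quantitative":
            derived = [self.quantitative_spec, self.trajectory, self.drug_response,
                       self.age_of_onset_of, self.event_count_of]
            if sum(x is not None for x in derived) != 1:
                raise ValidationError(
                    f"quantitative phenotype {self.phenotype_id!r} needs exactly one of "
                    "quantitative_spec/trajectory/drug_response/age_of_onset_of/event_count_of"
                )
        else:
            raise ValidationError(f"unknown phenotype kind {self.kind!r}")


@dataclass
class CodeGroupMap:
    """Phecode-style grouping: rows of (vocabulary, pattern, match_mode,
    group_id, group_label) plus per-group exclusion groups whose cases are
    removed from this group's controls."""

    rows: pd.DataFrame            # vocab, pattern, match_mode, group_id, group_label
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.rows["group_id"].str.strip() == "").any():
            raise ValidationError("empty group_id in code-group map")
        dup = self.rows.duplicated(subset=["vocab", "pattern", "group_id"])
        if dup.any():
            r = self.rows[dup].iloc[0]
            raise ValidationError(
                f"duplicate (vocabulary, pattern) ({r['vocab']}, {r['pattern']}) "
                f"within group {r['group_id']!r}"
            )

    @property
    def group_ids(self) -> list[str]:
        seen: list[str] = []
        for g in self.rows["group_id"]:
            if g not in seen:
                seen.append(g)
        return seen

    def code_set(self, group_id: str) -> CodeSet:
        sub = self.rows[self.rows["group_id"] == group_id]
        members = tuple(
            CodeSetMember(r["vocab"], r["pattern"], r["match_mode"])
            for _, r in sub.iterrows()
        )
        return CodeSet(group_id, members)


def read_code_group_map(path: str) -> CodeGroupMap:
    """TSV: vocab, pattern, match_mode, group_id, group_label[, exclusion_groups[, category]]."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    for col in ("vocab", "pattern", "match_mode", "group_id", "group_label"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r} in {path}")
    exclusions: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    for _, r in df.iterrows():
        if "exclusion_groups" in df.columns and r["exclusion_groups"].strip():
            exclusions.setdefault(r["group_id"], [])
            for g in r["exclusion_groups"].split(","):
                g = g.strip()
                if g and g not in exclusions[r["group_id"]]:
                    exclusions[r["group_id"]].append(g)
        if "category" in df.columns and r["category"].strip():
            categories[r["group_id"]] = r["category"].strip()
    rows = df[["vocab", "pattern", "match_mode", "group_id", "group_label"]].copy()
    return CodeGroupMap(rows, exclusions, categories)


# ---------------------------------------------------------------------------
# counting helpers

def _distinct_date_counts(events: pd.DataFrame, code_set: CodeSet,
                          source: Optional[str] = None) -> pd.Series:
    """Per-participant count of distinct event dates matching a code set."""
    mask = code_set.mask(events)
    if source is not None:
        mask &= (events["source"] == source).to_numpy()
    sub = events.loc[mask, ["eid", "date"]]
    if sub.empty:
        return pd.Series(dtype=int)
    return sub.drop_duplicates().groupby("eid").size()


def _measurements(events: pd.DataFrame, code_set: CodeSet,
                  unit_filter: Optional[str] = None,
                  plausible_range: Optional[tuple[float, float]] = None) -> pd.DataFrame:
    """Measurement rows (value present) matching a code set, filtered."""
    mask = code_set.mask(events) & events["value"].notna().to_numpy()
    sub = events.loc[mask, ["eid", "date", "value", "unit"]]
    if unit_filter is not None:
        sub = sub[sub["unit"] == unit_filter]
    if plausible_range is not None:
        lo, hi = plausible_range
        sub = sub[(sub["value"] >= lo) & (sub["value"] <= hi)]
    return sub


# ---------------------------------------------------------------------------
# phenotype operations

def map_code_groups(events: EventTable, code_map: CodeGroupMap, min_count: int,
                    participants: pd.DataFrame) -> PhenotypeMatrix:
    """Code-group (phecode-style) binary phenotypes.

    Case: >= min_count events on distinct dates matching the group.
    Control: not a case and not a case of any listed exclusion group.
    Otherwise missing.
    """
    if code_map.rows.empty:
        raise ValidationError("code-group map is empty")
    ids = pd.Index(participants["eid"], name="eid")
    ev = events.data
    is_case: dict[str, pd.Series] = {}
    for gid in code_map.group_ids:
        counts = _distinct_date_counts(ev, code_map.code_set(gid)).reindex(ids, fill_value=0)
        is_case[gid] = counts >= min_count

    matrix = PhenotypeMatrix.empty(ids)
    for gid in code_map.group_ids:
        col = is_case[gid].astype(float)
        for ex in code_map.exclusions.get(gid, []):
            if ex in is_case:
                col[~is_case[gid] & is_case[ex]] = np.nan
        label = code_map.rows.loc[code_map.rows["group_id"] == gid, "group_label"].iloc[0]
        matrix.add_column(col, PhenotypeColumn(
            gid, gid, "binary", "all", code_map.categories.get(gid, label)))
    return matrix


def _eval_rule(rule: Rule, counts: Mapping[tuple[str, Optional[str], int], pd.Series],
               ids: pd.Index) -> pd.Series:
    if isinstance(rule, Predicate):
        c = counts[(rule.code_set, rule.source, rule.min_count)]
        return c.reindex(ids, fill_value=0) >= rule.min_count
    if isinstance(rule, AnyOf):
        out = pd.Series(False, index=ids)
        for child in rule.children:
            out |= _eval_rule(child, counts, ids)
        return out
    if isinstance(rule, AllOf):
        out = pd.Series(True, index=ids)
        for child in rule.children:
            out &= _eval_rule(child, counts, ids)
        return out
    return ~_eval_rule(rule.child, counts, ids)


def evaluate_composite(definition: PhenotypeDefinition, events: EventTable,
                       participants: pd.DataFrame,
                       code_sets: Mapping[str, CodeSet]) -> pd.Series:
    """Binary composite phenotype over boolean combinations of code-set predicates.

    Case iff the case rule holds; among non-cases, missing iff the exclusion
    rule holds, else control.  A sex restriction sets the opposite sex (and
    unknown sex) to missing.
    """
    if definition.kind != "binary":
        raise ValidationError("evaluate_composite requires a binary definition")
    needed = _rule_code_sets(definition.case_rule)
    if definition.control_exclusion_rule is not None:
        needed |= _rule_code_sets(definition.control_exclusion_rule)
    for name in needed:
        if name not in code_sets:
            raise PhewasError(f"unknown code_set reference {name!r} in {definition.phenotype_id!r}")

    ids = pd.Index(participants["eid"], name="eid")
    counts: dict[tuple[str, Optional[str], int], pd.Series] = {}

    def collect(rule: Rule) -> None:
        if isinstance(rule, Predicate):
            key = (rule.code_set, rule.source, rule.min_count)
            if key not in counts:
                counts[key] = _distinct_date_counts(events.data, code_sets[rule.code_set], rule.source)
        elif isinstance(rule, (AnyOf, AllOf)):
            for c in rule.children:
                collect(c)
        else:
            collect(rule.child)

    collect(definition.case_rule)
    if definition.control_exclusion_rule is not None:
        collect(definition.control_exclusion_rule)

    case = _eval_rule(definition.case_rule, counts, ids)
    col = case.astype(float)
    if definition.control_exclusion_rule is not None:
        excl = _eval_rule(definition.control_exclusion_rule, counts, ids)
        col[~case & excl] = np.nan
    if definition.sex_restriction != "none":
        keep = "female" if definition.sex_restriction == "female_only" else "male"
        sex = participants.set_index("eid")["sex"].reindex(ids)
        col[sex != keep] = np.nan
    col.name = definition.phenotype_id
    return col


def extract_quantitative(events: EventTable, spec: QuantTraitSpec,
                         participants: pd.DataFrame,
                         code_sets: Mapping[str, CodeSet]) -> pd.Series:
    """Aggregate repeated measurements into one value per participant.

    Values outside the plausible range are dropped; participants with fewer
    than min_measurements remaining values are missing.  ``first``/``last``
    order by event date, with same-day ties averaged.
    """
    ids = pd.Index(participants["eid"], name="eid")
    cs = code_sets[spec.code_set] if isinstance(spec.code_set, str) else spec.code_set
    sub = _measurements(events.data, cs, spec.unit_filter, spec.plausible_range)
    out = pd.Series(np.nan, index=ids, dtype=float)
    if sub.empty:
        return out
    for eid, grp in sub.groupby("eid"):
        if eid not in ids or len(grp) < spec.min_measurements:
            continue
        v = grp["value"]
        if spec.aggregation == "mean":
            out[eid] = v.mean()
        elif spec.aggregation == "median":
            out[eid] = v.median()
        elif spec.aggregation == "min":
            out[eid] = v.min()
        elif spec.aggregation == "max":
            out[eid] = v.max()
        else:  # first / last: by date, same-day ties averaged
            day = grp["date"].min() if spec.aggregation == "first" else grp["date"].max()
            out[eid] = grp.loc[grp["date"] == day, "value"].mean()
    return out


def trajectory_slope(events: EventTable, code_set: CodeSet, min_measurements: int,
                     participants: pd.DataFrame) -> pd.Series:
    """Per-participant OLS slope of measurement value against age in years.

    Requires >= min_measurements values (>= 3) on >= 2 distinct dates.
    """
    if min_measurements < 3:
        raise ValidationError("trajectory requires min_measurements >= 3")
    ids = pd.Index(participants["eid"], name="eid")
    birth = participants.set_index("eid")["birth_date"]
    sub = _measurements(events.data, code_set)
    out = pd.Series(np.nan, index=ids, dtype=float)
    for eid, grp in sub.groupby("eid"):
        if eid not in ids or len(grp) < min_measurements or grp["date"].nunique() < 2:
            continue
        age = (grp["date"] - birth[eid]).dt.days / DAYS_PER_YEAR
        x = age.to_numpy(float)
        y = grp["value"].to_numpy(float)
        xc = x - x.mean()
        out[eid] = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    return out


def drug_response(events: EventTable, rx_code_set: CodeSet, measure_code_set: CodeSet,
                  pre_window_days: int, post_window: tuple[int, int],
                  participants: pd.DataFrame) -> pd.Series:
    """Change in a measured value after first prescription.

    Index date = first matching prescription.  delta = mean(measures in
    [index+lag, index+end]) - mean(measures in [index-pre, index)).  The pre
    window is half-open before the index date and the post window starts at
    lag >= 1 day, so a measure on the index date counts in neither.
    """
    lag, end = post_window
    if not lag < end:
        raise ValidationError("post window lag must be < end")
    ids = pd.Index(participants["eid"], name="eid")
    ev = events.data
    rx_mask = rx_code_set.mask(ev)
    rx = ev.loc[rx_mask, ["eid", "date"]].groupby("eid")["date"].min()
    meas = _measurements(ev, measure_code_set)
    out = pd.Series(np.nan, index=ids, dtype=float)
    for eid, index_date in rx.items():
        if eid not in ids:
            continue
        m = meas[meas["eid"] == eid]
        pre = m[(m["date"] >= index_date - pd.Timedelta(days=pre_window_days))
                & (m["date"] < index_date)]
        post = m[(m["date"] >= index_date + pd.Timedelta(days=lag))
                 & (m["date"] <= index_date + pd.Timedelta(days=end))]
        if len(pre) >= 1 and len(post) >= 1:
            out[eid] = float(post["value"].mean() - pre["value"].mean())
    return out


def _onset_dates(binary_col: pd.Series, qualifying: Sequence[tuple[CodeSet, Optional[str]]],
                 events: pd.DataFrame) -> pd.Series:
    """Earliest case-qualifying event date per case participant."""
    mask = np.zeros(len(events), dtype=bool)
    for cs, source in qualifying:
        m = cs.mask(events)
        if source is not None:
            m &= (events["source"] == source).to_numpy()
        mask |= m
    firsts = events.loc[mask, ["eid", "date"]].groupby("eid")["date"].min()
    cases = binary_col[binary_col == 1.0].index
    return firsts.reindex(cases)


def age_of_onset(binary_col: pd.Series, qualifying: Sequence[tuple[CodeSet, Optional[str]]],
                 events: EventTable, participants: pd.DataFrame) -> pd.Series:
    """Age in 365.25-day years at the earliest case-qualifying event; non-cases missing."""
    ids = pd.Index(participants["eid"], name="eid")
    birth = participants.set_index("eid")["birth_date"]
    onset = _onset_dates(binary_col, qualifying, events.data)
    out = pd.Series(np.nan, index=ids, dtype=float)
    undated = 0
    for eid, d in onset.items():
        if pd.isna(d):
            undated += 1
            continue
        out[eid] = (d - birth[eid]).days / DAYS_PER_YEAR
    if undated:
        import warnings
        warnings.warn(f"{undated} case(s) had no dated qualifying event; set to missing",
                      stacklevel=2)
    return out


def event_count(binary_col: pd.Series, qualifying_code_set: CodeSet,
                onset_qualifying: Sequence[tuple[CodeSet, Optional[str]]],
                events: EventTable, participants: pd.DataFrame) -> pd.Series:
    """Per-case count of distinct-date qualifying events on/after onset; non-cases missing."""
    ids = pd.Index(participants["eid"], name="eid")
    onset = _onset_dates(binary_col, onset_qualifying, events.data)
    ev = events.data
    mask = qualifying_code_set.mask(ev)
    sub = ev.loc[mask, ["eid", "date"]].drop_duplicates()
    out = pd.Series(np.nan, index=ids, dtype=float)
    for eid, d in onset.items():
        if pd.isna(d):
            continue
        out[eid] = float((sub.loc[sub["eid"] == eid, "date"] >= d).sum())
    return out


def collapse_correlated(matrix: PhenotypeMatrix, r_threshold: float = 0.9,
                        curated_representatives: Optional[Mapping[str, str]] = None,
                        min_shared: int = 30) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """Collapse extremely highly correlated quantitative traits to one representative.

    Pearson correlation on pairwise-complete observations; pairs sharing fewer
    than ``min_shared`` non-missing values are treated as uncorrelated.  An
    undirected graph with an edge where |r| >= r_threshold is split into
    connected components; each component keeps the curated representative if
    supplied, else the column with the most non-missing values (ties broken
    lexicographically).  Binary columns pass through untouched.
    """
    quant = [m.column_id for m in matrix.meta if m.kind == "quantitative"]
    if len(quant) < 2:
        return matrix, pd.DataFrame(columns=["dropped", "representative"])
    vals = matrix.values[quant]
    notna = vals.notna()
    corr = vals.corr(method="pearson", min_periods=min_shared)

    g = nx.Graph()
    g.add_nodes_from(quant)
    for i, a in enumerate(quant):
        for b in quant[i + 1:]:
            r = corr.loc[a, b]
            if pd.notna(r) and abs(r) >= r_threshold:
                g.add_edge(a, b)

    curated = dict(curated_representatives or {})
    keep: set[str] = set()
    report_rows = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        # curated map: component member -> representative column id
        candidates = [curated[c] for c in comp if c in curated]
        if candidates:
            rep = candidates[0]
            if rep not in comp:
                raise PhewasError(
                    f"curated representative {rep!r} is not in its correlation component {comp}")
        else:
            counts = notna[comp].sum()
            rep = sorted(comp, key=lambda c: (-counts[c], c))[0]
        keep.add(rep)
        for c in comp:
            if c != rep:
                report_rows.append((c, rep))

    kept_cols = [m.column_id for m in matrix.meta
                 if m.kind != "quantitative" or m.column_id in keep]
    reduced = PhenotypeMatrix(
        matrix.values[kept_cols].copy(),
        [m for m in matrix.meta if m.column_id in kept_cols],
    )
    report = pd.DataFrame(report_rows, columns=["dropped", "representative"])
    return reduced, report.sort_values("dropped").reset_index(drop=True)


def stratify_by_sex(matrix: PhenotypeMatrix, participants: pd.DataFrame,
                    columns: Optional[Sequence[str]] = None) -> PhenotypeMatrix:
    """Add female-only / male-only copies of each requested column.

    The stratified copy equals the original with the opposite sex and unknown
    sex set to missing; originals are retained.  Columns that are already
    sex-restricted produce only their permitted stratum.
    """
    sex = participants.set_index("eid")["sex"].reindex(matrix.values.index)
    female = (sex == "female").to_numpy()
    male = (sex == "male").to_numpy()
    out = PhenotypeMatrix(matrix.values.copy(), list(matrix.meta))
    targets = columns if columns is not None else [m.column_id for m in matrix.meta]
    for cid in targets:
        m = out.column_meta(cid)
        if m.stratum != "all":
            continue
        restricted = _sex_restriction_of(out, cid)
        base = matrix.values[cid]
        if restricted in (None, "female_only"):
            f = base.where(female, np.nan)
            out.add_column(f, PhenotypeColumn(f"{cid}_female", m.phenotype_id, m.kind,
                                              "female_only", m.category))
        if restricted in (None, "male_only"):
            mcol = base.where(male, np.nan)
            out.add_column(mcol, PhenotypeColumn(f"{cid}_male", m.phenotype_id, m.kind,
                                                 "male_only", m.category))
    return out


def _sex_restriction_of(matrix: PhenotypeMatrix, cid: str) -> Optional[str]:
    # a definition-level restriction is recorded in metadata by the builder
    m = matrix.column_meta(cid)
    return getattr(m, "_sex_restriction", None)


# ---------------------------------------------------------------------------
# configuration loading

def _load_code_sets(raw: Mapping) -> dict[str, CodeSet]:
    out: dict[str, CodeSet] = {}
    for name, members in (raw or {}).items():
        out[name] = CodeSet(name, tuple(
            CodeSetMember(m["vocab"], m["pattern"], m.get("match", m.get("match_mode", "exact")))
            for m in members
        ))
    return out


def load_definitions(path: str) -> tuple[list[PhenotypeDefinition], dict[str, CodeSet]]:
    """Load phenotype definitions plus their code sets from YAML or JSON."""
    with open(path) as fh:
        raw = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    raw = raw or {}
    code_sets = _load_code_sets(raw.get("code_sets"))
    defs: list[PhenotypeDefinition] = []
    for d in raw.get("phenotypes", []):
        q = d.get("quantitative_spec")
        qspec = None
        if q is not None:
            rng = q.get("plausible_range")
            qspec = QuantTraitSpec(
                code_set=q["code_set"], aggregation=q.get("aggregation", "mean"),
                min_measurements=int(q.get("min_measurements", 1)),
                plausible_range=tuple(rng) if rng else None,
                unit_filter=q.get("unit_filter"),
            )
        t = d.get("trajectory")
        tspec = TrajectorySpec(t["code_set"], int(t.get("min_measurements", 3))) if t else None
        dr = d.get("drug_response")
        drspec = DrugResponseSpec(
            dr["rx_code_set"], dr["measure_code_set"],
            int(dr.get("pre_window_days", 365)),
            int(dr.get("post_lag_days", 30)), int(dr.get("post_end_days", 365)),
        ) if dr else None
        ec = d.get("event_count_of")
        defs.append(PhenotypeDefinition(
            phenotype_id=d["phenotype_id"],
            kind=d["kind"],
            case_rule=parse_rule(d["case_rule"]) if d.get("case_rule") else None,
            control_exclusion_rule=(parse_rule(d["control_exclusion_rule"])
                                    if d.get("control_exclusion_rule") else None),
            sex_restriction=d.get("sex_restriction", "none"),
            quantitative_spec=qspec,
            trajectory=tspec,
            drug_response=drspec,
            age_of_onset_of=d.get("age_of_onset_of"),
            event_count_of=(ec["phenotype_id"], ec["code_set"]) if ec else None,
            category=d.get("category", "uncategorised"),
        ))
    return defs, code_sets


# ---------------------------------------------------------------------------
# orchestrator

@dataclass
class BuildOptions:
    code_group_min_count: int = 1
    collapse: bool = False
    r_threshold: float = 0.9
    curated_representatives: Optional[Mapping[str, str]] = None
    stratify: bool = False
    stratify_columns: Optional[Sequence[str]] = None


def build_phenotype_matrix(definitions: Sequence[PhenotypeDefinition],
                           code_sets: Mapping[str, CodeSet],
                           code_map: Optional[CodeGroupMap],
                           events: EventTable,
                           participants: pd.DataFrame,
                           options: Optional[BuildOptions] = None,
                           ) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """Run the full phenotype-generation pipeline in fixed order.

    Order: code groups, composites, quantitative traits, trajectories,
    drug response, progression (age of onset / event counts), collapsing,
    stratification.  Returns the matrix plus a generation log with
    case/control/missing counts per column.  Duplicate phenotype ids across
    sources are fatal.
    """
    options = options or BuildOptions()
    ids = pd.Index(participants["eid"], name="eid")
    matrix = PhenotypeMatrix.empty(ids)

    if code_map is not None and not code_map.rows.empty:
        cg = map_code_groups(events, code_map, options.code_group_min_count, participants)
        for m in cg.meta:
            matrix.add_column(cg.values[m.column_id], m)

    by_id = {d.phenotype_id: d for d in definitions}
    if len(by_id) != len(definitions):
        raise ValidationError("duplicate phenotype_id among definitions")

    binary_defs = [d for d in definitions if d.kind == "binary"]
    for d in binary_defs:
        col = evaluate_composite(d, events, participants, code_sets)
        pc = PhenotypeColumn(d.phenotype_id, d.phenotype_id, "binary", "all", d.category)
        if d.sex_restriction != "none":
            pc._sex_restriction = d.sex_restriction  # type: ignore[attr-defined]
        matrix.add_column(col, pc)

    for d in definitions:
        if d.quantitative_spec is not None:
            col = extract_quantitative(events, d.quantitative_spec, participants, code_sets)
            matrix.add_column(col, PhenotypeColumn(d.phenotype_id, d.phenotype_id,
                                                   "quantitative", "all", d.category))
    for d in definitions:
        if d.trajectory is not None:
            col = trajectory_slope(events, code_sets[d.trajectory.code_set],
                                   d.trajectory.min_measurements, participants)
            matrix.add_column(col, PhenotypeColumn(d.phenotype_id, d.phenotype_id,
                                                   "quantitative", "all", d.category))
    for d in definitions:
        if d.drug_response is not None:
            s = d.drug_response
            col = drug_response(events, code_sets[s.rx_code_set], code_sets[s.measure_code_set],
                                s.pre_window_days, (s.post_lag_days, s.post_end_days),
                                participants)
            matrix.add_column(col, PhenotypeColumn(d.phenotype_id, d.phenotype_id,
                                                   "quantitative", "all", d.category))

    # progression phenotypes reference an already-built binary column
    for d in definitions:
        if d.age_of_onset_of is not None:
            base = _resolve_binary(d.age_of_onset_of, by_id, code_map)
            qual = _qualifying_of(d.age_of_onset_of, by_id, code_map, code_sets)
            col = age_of_onset(matrix.values[d.age_of_onset_of], qual, events, participants)
            matrix.add_column(col, PhenotypeColumn(d.phenotype_id, d.phenotype_id,
                                                   "quantitative", "all", d.category))
        if d.event_count_of is not None:
            base_id, qual_set = d.event_count_of
            _resolve_binary(base_id, by_id, code_map)
            qual = _qualifying_of(base_id, by_id, code_map, code_sets)
            col = event_count(matrix.values[base_id], code_sets[qual_set], qual,
                              events, participants)
            matrix.add_column(col, PhenotypeColumn(d.phenotype_id, d.phenotype_id,
                                                   "quantitative", "all", d.category))

    collapse_report = pd.DataFrame(columns=["dropped", "representative"])
    if options.collapse:
        matrix, collapse_report = collapse_correlated(
            matrix, options.r_threshold, options.curated_representatives)
    if options.stratify:
        matrix = stratify_by_sex(matrix, participants, options.stratify_columns)

    log_rows = []
    for m in matrix.meta:
        col = matrix.values[m.column_id]
        if m.kind == "binary":
            log_rows.append((m.column_id, m.kind, m.stratum, int((col == 1).sum()),
                             int((col == 0).sum()), int(col.isna().sum())))
        else:
            log_rows.append((m.column_id, m.kind, m.stratum, None, None, int(col.isna().sum())))
    log = pd.DataFrame(log_rows, columns=["column_id", "kind", "stratum",
                                          "n_cases", "n_controls", "n_missing"])
    return matrix, log


def _resolve_binary(pid: str, by_id: Mapping[str, PhenotypeDefinition],
                    code_map: Optional[CodeGroupMap]) -> None:
    if pid in by_id and by_id[pid].kind == "binary":
        return
    if code_map is not None and pid in code_map.group_ids:
        return
    raise PhewasError(f"progression phenotype references unknown binary phenotype {pid!r}")


def _qualifying_of(pid: str, by_id: Mapping[str, PhenotypeDefinition],
                   code_map: Optional[CodeGroupMap],
                   code_sets: Mapping[str, CodeSet]) -> list[tuple[CodeSet, Optional[str]]]:
    """Case-qualifying (code set, source) pairs for a binary phenotype."""
    if pid in by_id and by_id[pid].kind == "binary":
        preds = _positive_predicates(by_id[pid].case_rule)
        return [(code_sets[p.code_set], p.source) for p in preds]
    assert code_map is not None
    return [(code_map.code_set(pid), None)]
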