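"""Material property database with matching rules.

Pharmaceutical powders are described here by an 18-column physical property
vector (densities, porosities, flow descriptors, particle sizes).  Literature
granulation studies rarely characterize their raw materials, so a formulation
material is resolved against a reference database by three rules, tried in
order:

1. *exact* -- same name and specification (grade): the record is used as-is;
2. *name-average* -- same name, any specification: the per-property mean over
   all same-name records;
3. *most-similar* -- nearest database record under an autoscaled Euclidean
   distance on a chosen property subset (particle sizes by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed column order shared by every record and every property matrix.
#: Da/Dc/Dt: bulk/tapped/true density (g/mL); porosity, Ie: powder and
#: interparticle porosity (fractions); IC: Carr index (%); Icd: cohesion
#: index; IH: Hausner ratio; angle: angle of repose (deg); flow_time (s);
#: HR: moisture content (%); H: hygroscopicity (%); pf: fines fraction
#: (% < 50 um); Itheta: homogeneity index; D10/D50/D90 (um); span.
PROPERTY_COLUMNS = (
    "Da", "Dc", "Dt", "porosity", "Ie", "IC", "Icd", "IH", "angle",
    "flow_time", "HR", "H", "pf", "Itheta", "D10", "D50", "D90", "span",
)

#: Columns whose values are percentages and must lie in [0, 100].
_PERCENT_COLUMNS = ("IC", "HR", "H", "pf")

#: Default property subset for rule-3 similarity.
DEFAULT_COMPARE_ON = ("D10", "D50", "D90")

RULE_EXACT = "exact"
RULE_NAME_AVERAGE = "name-average"
RULE_MOST_SIMILAR = "most-similar"


class SchemaError(ValueError):
    """A materials table is missing mandatory columns."""


class DuplicateKeyError(ValueError):
    """Two rows share the same (name, specification) key."""


class MaterialNotFoundError(LookupError):
    """A matching rule found no applicable record."""


class UnresolvedMaterialError(LookupError):
    """All three matching rules failed for a requested material."""


def normalize(text: str | None) -> str:
    """Normalize a name/spec for key comparison.

    Trims whitespace, case-folds and collapses internal runs of whitespace,
    so ``" MCC  PH101 "`` and ``"mcc ph101"`` compare equal.
    """
    if text is None:
        return ""
    return re.sub(r"\s+", " ", str(text).strip()).casefold()


def material_key(name: str, spec: str = "") -> str:
    """Single-string key for a (name, specification) pair."""
    name_n, spec_n = normalize(name), normalize(spec)
    return f"{name_n}::{spec_n}" if spec_n else name_n


@dataclass(frozen=True)
class MaterialRecord:
    """One material: name, grade and its 18-property vector.

    Missing values are stored as NaN; :attr:`mask` marks present entries.
    """

    name: str
    spec: str
    properties: np.ndarray  # shape (18,), NaN where absent

    def __post_init__(self):
        props = np.asarray(self.properties, dtype=float)
        if props.shape != (len(PROPERTY_COLUMNS),):
            raise ValueError(
                f"expected {len(PROPERTY_COLUMNS)} properties, got {props.shape}"
            )
        object.__setattr__(self, "properties", props)

    @property
    def key(self) -> str:
        return material_key(self.name, self.spec)

    @property
    def mask(self) -> np.ndarray:
        """Boolean availability mask (True where the property is present)."""
        return ~np.isnan(self.properties)

    def get(self, prop: str) -> float:
        return float(self.properties[PROPERTY_COLUMNS.index(prop)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.properties, index=list(PROPERTY_COLUMNS),
                         name=self.key)

    def violations(self) -> list[str]:
        """Physical-consistency violations; empty list when the record is valid."""
        out: list[str] = []
        get = dict(zip(PROPERTY_COLUMNS, self.properties))
        da, dc, dt = get["Da"], get["Dc"], get["Dt"]
        for label, d in (("Da", da), ("Dc", dc), ("Dt", dt)):
            if np.isfinite(d) and d <= 0:
                out.append(f"{label} must be > 0 (got {d})")
        if np.isfinite(da) and np.isfinite(dc) and da > dc * (1 + 1e-9):
            out.append(f"Da ({da}) > Dc ({dc})")
        if np.isfinite(dc) and np.isfinite(dt) and dc > dt * (1 + 1e-9):
            out.append(f"Dc ({dc}) > Dt ({dt})")
        d10, d50, d90 = get["D10"], get["D50"], get["D90"]
        if np.isfinite(d10) and np.isfinite(d50) and d10 > d50 * (1 + 1e-9):
            out.append(f"D10 ({d10}) > D50 ({d50})")
        if np.isfinite(d50) and np.isfinite(d90) and d50 > d90 * (1 + 1e-9):
            out.append(f"D50 ({d50}) > D90 ({d90})")
        ih = get["IH"]
        if np.isfinite(ih) and np.isfinite(da) and np.isfinite(dc) and da > 0:
            if abs(ih - dc / da) > 0.05 * (dc / da):
                out.append(f"IH ({ih}) inconsistent with Dc/Da ({dc / da:.4f})")
        for col in _PERCENT_COLUMNS:
            v = get[col]
            if np.isfinite(v) and not (0 <= v <= 100):
                out.append(f"{col} ({v}) outside [0, 100]")
        por = get["porosity"]
        if np.isfinite(por) and not (0 <= por <= 1):
            out.append(f"porosity ({por}) outside [0, 1]")
        return out


@dataclass(frozen=True)
class MatchResult:
    """Outcome of resolving a material request against the database."""

    record: MaterialRecord
    rule: str                       # one of the RULE_* constants
    donors: tuple[str, ...]         # keys of the database records used
    distance: float | None = None   # rule-3 similarity distance

    def __post_init__(self):
        if self.rule not in (RULE_EXACT, RULE_NAME_AVERAGE, RULE_MOST_SIMILAR):
            raise ValueError(f"unknown matching rule {self.rule!r}")


@dataclass
class MaterialDB:
    """Records keyed by normalized (name, specification)."""

    records: dict[str, MaterialRecord] = field(default_factory=dict)
    load_report: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: str) -> bool:
        return key in self.records

    def add(self, record: MaterialRecord) -> None:
        if record.key in self.records:
            raise DuplicateKeyError(
                f"duplicate material key {record.key!r} "
                f"({record.name!r}, {record.spec!r})"
            )
        self.records[record.key] = record

    def same_name(self, name: str) -> list[MaterialRecord]:
        name_n = normalize(name)
        return [r for r in self.records.values() if normalize(r.name) == name_n]

    def property_matrix(self) -> pd.DataFrame:
        """All records as a DataFrame (rows keyed, fixed column order)."""
        keys = sorted(self.records)
        data = np.array([self.records[k].properties for k in keys]) \
            if keys else np.empty((0, len(PROPERTY_COLUMNS)))
        return pd.DataFrame(data, index=keys, columns=list(PROPERTY_COLUMNS))


def load_material_db(path) -> MaterialDB:
    """Load a delimited-text materials table.

    The header must name ``name, spec`` and the 18 property columns.  Rows
    violating record invariants are rejected; the rejection reasons are kept
    in ``db.load_report`` (one line per rejected row).
    """
    # sniff the delimiter, then parse with exact (round-trip) float handling
    with open(path, newline="") as fh:
        first = fh.readline()
    delim = max(",;\t|", key=first.count)
    table = pd.read_csv(path, sep=delim, dtype={"spec": str},
                        float_precision="round_trip")
    missing = [c for c in ("name", *PROPERTY_COLUMNS) if c not in table.columns]
    if missing:
        raise SchemaError(f"materials table missing columns: {missing}")
    if "spec" not in table.columns:
        table["spec"] = ""
    db = MaterialDB()
    for idx, row in table.iterrows():
        spec = row["spec"] if isinstance(row["spec"], str) else ""
        props = pd.to_numeric(row[list(PROPERTY_COLUMNS)], errors="coerce")
        rec = MaterialRecord(str(row["name"]), spec, props.to_numpy(dtype=float))
        problems = rec.violations()
        if problems:
            db.load_report.append(
                f"row {idx} ({rec.name!r}, {rec.spec!r}) rejected: "
                + "; ".join(problems)
            )
            continue
        db.add(rec)
    return db


def write_material_db(db: MaterialDB, path) -> None:
    """Write the database back to delimited text (round-trips exactly)."""
    rows = []
    for key in sorted(db.records):
        r = db.records[key]
        rows.append({"name": r.name, "spec": r.spec,
                     **dict(zip(PROPERTY_COLUMNS, r.properties))})
    pd.DataFrame(rows, columns=["name", "spec", *PROPERTY_COLUMNS]).to_csv(
        path, index=False)


def match_exact(db: MaterialDB, name: str, spec: str = "") -> MatchResult:
    """Rule 1: same name and specification."""
    key = material_key(name, spec)
    rec = db.records.get(key)
    if rec is None:
        raise MaterialNotFoundError(f"no record with key {key!r}")
    return MatchResult(rec, RULE_EXACT, (key,))


def match_name_average(db: MaterialDB, name: str) -> MatchResult:
    """Rule 2: per-property mean over all records sharing the name.

    The mean is taken over present values only (equal weights); a property
    absent from every donor stays absent in the result.
    """
    donors = db.same_name(name)
    if not donors:
        raise MaterialNotFoundError(f"no record named {name!r}")
    if len(donors) == 1:
        return MatchResult(donors[0], RULE_NAME_AVERAGE, (donors[0].key,))
    stacked = np.array([d.properties for d in donors])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    rec = MaterialRecord(name, "<name-average>", mean)
    return MatchResult(rec, RULE_NAME_AVERAGE, tuple(d.key for d in donors))


def match_most_similar(
    db: MaterialDB,
    query_properties: Mapping[str, float] | pd.Series,
    compare_on: Sequence[str] = DEFAULT_COMPARE_ON,
) -> MatchResult:
    """Rule 3: nearest record under autoscaled Euclidean distance.

    Each compared property is scaled by its database-wide standard deviation
    (n-1 denominator, present values only) so the particle sizes with large
    absolute magnitudes do not dominate.  The distance is the root mean
    square over the compared properties present in both query and record;
    ties are broken by lexicographic key.
    """
    if not db.records:
        raise MaterialNotFoundError("database is empty")
    compare_on = tuple(compare_on)
    if not compare_on:
        raise ValueError("compare_on must be non-empty")
    query = pd.Series(dict(query_properties), dtype=float)
    missing = [p for p in compare_on if p not in query or not np.isfinite(query[p])]
    if missing:
        raise ValueError(f"query lacks values for compare_on properties {missing}")

    matrix = db.property_matrix()
    cols = list(compare_on)
    scale = matrix[cols].std(ddof=1).to_numpy()
    scale = np.where(np.isfinite(scale) & (scale > 0), scale, 1.0)
    q = query[cols].to_numpy()

    best: tuple[float, str] | None = None
    for key in sorted(db.records):
        rec = db.records[key]
        r = rec.as_series()[cols].to_numpy()
        shared = np.isfinite(r)
        if not shared.any():
            continue
        diff = (q[shared] - r[shared]) / scale[shared]
        dist = float(np.sqrt(np.mean(diff ** 2)))
        if best is None or (dist, key) < best:
            best = (dist, key)
    if best is None:
        raise MaterialNotFoundError(
            f"no record carries any of the compare_on properties {compare_on}"
        )
    dist, key = best
    return MatchResult(db.records[key], RULE_MOST_SIMILAR, (key,), distance=dist)


def resolve_material(
    db: MaterialDB,
    name: str,
    spec: str = "",
    query_properties: Mapping[str, float] | pd.Series | None = None,
    compare_on: Sequence[str] = DEFAULT_COMPARE_ON,
) -> MatchResult:
    """Resolve a material request by rules 1 -> 2 -> 3 in order.

    Rule 3 needs ``query_properties``; without them an unresolvable request
    raises :class:`UnresolvedMaterialError`.
    """
    try:
        return match_exact(db, name, spec)
    except MaterialNotFoundError:
        pass
    try:
        return match_name_average(db, name)
    except MaterialNotFoundError:
        pass
    if query_properties is not None:
        try:
            return match_most_similar(db, query_properties, compare_on)
        except MaterialNotFoundError:
            pass
    raise UnresolvedMaterialError(
        f"material ({name!r}, {spec!r}) could not be resolved by any rule"
    )
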