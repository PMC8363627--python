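"""End-to-end fusion workflow for granulation data.

Aligns heterogeneous run tables into unified 21-feature records, screens
outliers in latent space, splits by formulation (no leakage), fits the
literature-only model, fuses lab runs into the calibration set, and compares
models on external validation data.  Also computes the median granule size
G50 from sieve-analysis masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .material_db import (MaterialDB, UnresolvedMaterialError, material_key,
                          resolve_material)
from .mixing import Formulation, MixingError, mix_properties
from .process import (
    FEATURE_COLUMNS, G_DEFAULT, LS_LITERATURE_RANGE, AgitationSpec,
    GranulatorGeometry, LiquidAdditionSpec, ProcessSpecError,
    dimensionless_process, build_feature_row,
)

PART_CALIBRATION = "calibration"
PART_INTERNAL = "internal-validation"
PART_EXTERNAL = "external-validation"
PART_OUTLIER = "excluded-outlier"
PART_FAILED = "excluded-failed"

#: Mesh -> aperture (um) map for the default sieve stack.  Mesh standards
#: differ between countries, so this is configuration, not physics.
DEFAULT_MESH_APERTURES = {12: 1700, 20: 850, 60: 250, 80: 180, 120: 125,
                          200: 75}


class AlignmentError(ValueError):
    pass


class SieveError(ValueError):
    pass


@dataclass(frozen=True)
class GranulationRecord:
    """One granulation run: features, outcome, provenance."""

    run_id: str
    formulation_id: str
    features: pd.Series            # 21 entries, FEATURE_COLUMNS order
    g50: float | None              # um; None when the run failed
    source: str                    # literature citation key or "lab"
    failed: bool = False           # slurry / no granules
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        feats = pd.Series(self.features, dtype=float).reindex(
            list(FEATURE_COLUMNS))
        if feats.isna().any():
            raise AlignmentError(
                f"run {self.run_id!r}: incomplete feature row "
                f"({list(feats.index[feats.isna()])})"
            )
        object.__setattr__(self, "features", feats)
        if self.failed and self.g50 is not None:
            raise AlignmentError(f"run {self.run_id!r}: failed runs carry no G50")
        if self.g50 is not None and not self.g50 > 0:
            raise AlignmentError(f"run {self.run_id!r}: G50 must be > 0")


@dataclass
class Dataset:
    """Aligned records plus disjoint partition labels."""

    records: list[GranulationRecord]
    partitions: dict[str, str] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for rec in self.records:
            self.partitions.setdefault(rec.run_id, PART_CALIBRATION)

    def __len__(self) -> int:
        return len(self.records)

    def copy(self) -> "Dataset":
        return Dataset(list(self.records), dict(self.partitions),
                       dict(self.reasons))

    def subset(self, partition: str,
               valid_only: bool = True) -> list[GranulationRecord]:
        out = [r for r in self.records
               if self.partitions[r.run_id] == partition]
        if valid_only:
            out = [r for r in out if not r.failed and r.g50 is not None]
        return out

    def X(self, partition: str | None = None,
          valid_only: bool = True) -> pd.DataFrame:
        recs = (self.subset(partition, valid_only) if partition
                else [r for r in self.records
                      if not (valid_only and (r.failed or r.g50 is None))])
        return pd.DataFrame([r.features for r in recs],
                            index=[r.run_id for r in recs],
                            columns=list(FEATURE_COLUMNS))

    def y(self, partition: str | None = None) -> pd.Series:
        recs = (self.subset(partition, True) if partition
                else [r for r in self.records
                      if not r.failed and r.g50 is not None])
        return pd.Series([r.g50 for r in recs],
                         index=[r.run_id for r in recs], name="G50")

    def formulation_ids(self, partition: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if partition is None or self.partitions[r.run_id] == partition:
                seen.setdefault(r.formulation_id)
        return list(seen)

    # -- delimited-text persistence -----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "run_id": r.run_id, "formulation_id": r.formulation_id,
                "source": r.source, "failed": r.failed,
                "partition": self.partitions[r.run_id],
                "reason": self.reasons.get(r.run_id, ""),
                **r.features.to_dict(),
                "G50_um": np.nan if r.g50 is None else r.g50,
            })
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "Dataset":
        table = pd.read_csv(path, sep=None, engine="python")
        records, parts, reasons = [], {}, {}
        for row in table.itertuples():
            g50 = None if pd.isna(row.G50_um) else float(row.G50_um)
            rec = GranulationRecord(
                run_id=str(row.run_id), formulation_id=str(row.formulation_id),
                features=pd.Series({c: getattr(row, c)
                                    for c in FEATURE_COLUMNS}),
                g50=g50, source=str(row.source), failed=bool(row.failed))
            records.append(rec)
            parts[rec.run_id] = str(row.partition)
            if isinstance(row.reason, str) and row.reason:
                reasons[rec.run_id] = row.reason
        return cls(records, parts, reasons)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _liquid_spec(row, rho_l: float) -> LiquidAdditionSpec:
    def val(name):
        v = getattr(row, name, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    solids = val("solids_g")
    if solids is None:
        raise ProcessSpecError("solids_g is required")
    return LiquidAdditionSpec(
        solids_g=solids, water_ml=val("water_ml"), water_g=val("water_g"),
        rate_ml_min=val("rate_ml_min"), duration_min=val("duration_min"),
        rho_l=rho_l)


def align_literature(
    runs: pd.DataFrame,
    formulations: pd.DataFrame,
    db: MaterialDB,
    g: float = G_DEFAULT,
    density: str = "true",
    rho_l: float = 1.0,
    source_default: str = "unknown",
) -> tuple[Dataset, pd.DataFrame]:
    """Align a heterogeneous run table into unified GranulationRecords.

    Per run: resolve every formulation material through the database matching
    rules, mix properties, reduce the process description to (L/S, Fr,
    S'max), and assemble the 21-feature row.  Runs that cannot be aligned are
    excluded and listed in the returned report with their reason; the report
    also records the matching rule used per material and the radius source
    per run, so every alignment decision is auditable.
    """
    # resolve materials once per unique (name, spec)
    fcols = {"formulation_id", "material_name", "mass_fraction"}
    if not fcols.issubset(formulations.columns):
        raise AlignmentError(
            f"formulations table needs columns {sorted(fcols)}")
    forms = formulations.copy()
    if "material_spec" not in forms.columns:
        forms["material_spec"] = ""
    forms["material_spec"] = forms["material_spec"].fillna("")

    report_rows: list[dict] = []
    resolved: dict[str, pd.Series] = {}
    for name, spec in forms[["material_name", "material_spec"]]\
            .drop_duplicates().itertuples(index=False):
        key = material_key(name, spec)
        if key in resolved:
            continue
        try:
            match = resolve_material(db, name, spec)
        except UnresolvedMaterialError as exc:
            report_rows.append({"kind": "material", "id": key,
                                "status": "unresolved", "detail": str(exc)})
            continue
        resolved[key] = match.record.as_series()
        report_rows.append({"kind": "material", "id": key,
                            "status": match.rule,
                            "detail": ",".join(match.donors)})

    formulation_objs: dict[str, Formulation] = {}
    for fid, grp in forms.groupby("formulation_id", sort=False):
        comps = tuple((material_key(r.material_name, r.material_spec),
                       float(r.mass_fraction)) for r in grp.itertuples())
        try:
            formulation_objs[str(fid)] = Formulation(str(fid), comps)
        except MixingError as exc:
            report_rows.append({"kind": "formulation", "id": str(fid),
                                "status": "invalid", "detail": str(exc)})

    matrix = pd.DataFrame(resolved).T
    if not matrix.empty:
        matrix = matrix[list(resolved[next(iter(resolved))].index)]

    records: list[GranulationRecord] = []
    for row in runs.itertuples():
        run_id = str(row.run_id)
        fid = str(row.formulation_id)
        try:
            formulation = formulation_objs.get(fid)
            if formulation is None:
                raise AlignmentError(f"formulation {fid!r} unavailable")
            mixed = mix_properties([formulation], matrix).iloc[0]
            radius_given = getattr(row, "radius_m", None)
            if radius_given is not None and (
                    isinstance(radius_given, float) and math.isnan(radius_given)):
                radius_given = None
            geom = GranulatorGeometry(float(row.scale_L), radius_given)
            rpm = getattr(row, "impeller_rpm", None)
            tip = getattr(row, "tip_speed_ms", None)
            rpm = None if (isinstance(rpm, float) and math.isnan(rpm)) else rpm
            tip = None if (isinstance(tip, float) and math.isnan(tip)) else tip
            agit = AgitationSpec(
                impeller_rpm=None if rpm is None else float(rpm),
                tip_speed_ms=None if tip is None else float(tip))
            liq = _liquid_spec(row, rho_l)
            dp = dimensionless_process(mixed, geom, agit, liq, g=g,
                                       density=density)
            features = build_feature_row(mixed, dp)
            g50 = getattr(row, "G50_um", np.nan)
            g50 = None if (g50 is None or (isinstance(g50, float)
                                           and math.isnan(g50))) else float(g50)
            failed = bool(getattr(row, "failed", False)) or g50 is None
            rec = GranulationRecord(
                run_id=run_id, formulation_id=fid, features=features,
                g50=None if failed else g50,
                source=str(getattr(row, "source", source_default)),
                failed=failed,
                meta={"radius_source": geom.radius_source,
                      "slurry_predicted": dp.slurry})
            records.append(rec)
            warn = ""
            if not LS_LITERATURE_RANGE[0] <= dp.ls <= LS_LITERATURE_RANGE[1]:
                warn = (f"L/S {dp.ls:.3f} outside literature span "
                        f"{LS_LITERATURE_RANGE}")
            report_rows.append({"kind": "run", "id": run_id,
                                "status": f"aligned ({geom.radius_source})",
                                "detail": warn})
        except (AlignmentError, MixingError, ProcessSpecError,
                UnresolvedMaterialError) as exc:
            report_rows.append({"kind": "run", "id": run_id,
                                "status": "excluded", "detail": str(exc)})
    report = pd.DataFrame(report_rows, columns=["kind", "id", "status",
                                                "detail"])
    return Dataset(records), report


# ---------------------------------------------------------------------------
# Screening / splitting / fitting / fusing
# ---------------------------------------------------------------------------

def screen_outliers(ds: Dataset, n_components: int = 2, alpha: float = 0.05,
                    level: str = "formulation") -> Dataset:
    """Flag records beyond the Hotelling T^2 limit of an initial PLS fit.

    By default exclusion is applied at the formulation level: every record
    of a formulation with at least one flagged run is moved to the
    ``excluded-outlier`` partition (a formulation granulating anomalously is
    suspect as a whole).  ``level="record"`` excludes flagged runs only.
    Excluded records keep their data and the exclusion reason.
    """
    if level not in ("formulation", "record"):
        raise ValueError("level must be 'formulation' or 'record'")
    X, y = ds.X(), ds.y()
    if len(y) < n_components + 2:
        raise ValueError("too few valid records to screen")
    model = chem.fit_pls(X, y, n_components)
    t2, limit = chem.hotelling_t2(model.T, n_components, alpha=alpha)
    flagged_runs = list(X.index[t2 > limit])
    out = ds.copy()
    if level == "record":
        for rid in flagged_runs:
            out.partitions[rid] = PART_OUTLIER
            out.reasons[rid] = f"T2 beyond {1 - alpha:.0%} limit"
        return out
    flagged_forms = {r.formulation_id for r in ds.records
                     if r.run_id in set(flagged_runs)}
    for rec in ds.records:
        if rec.formulation_id in flagged_forms:
            out.partitions[rec.run_id] = PART_OUTLIER
            out.reasons[rec.run_id] = (
                f"formulation {rec.formulation_id!r} contains runs beyond "
                f"the {1 - alpha:.0%} T2 limit")
    return out


def split_by_formulation(ds: Dataset, n_validation_formulations: int = 1,
                         seed: int | None = None,
                         validation_ids: list[str] | None = None) -> Dataset:
    """Assign whole formulations to the internal-validation partition.

    All records of one formulation share a partition, so no composition
    leaks between calibration and validation.  Pass ``validation_ids`` to
    reproduce a specific split.
    """
    eligible = [f for f in ds.formulation_ids()
                if any(ds.partitions[r.run_id] in
                       (PART_CALIBRATION, PART_INTERNAL)
                       for r in ds.records if r.formulation_id == f)]
    if validation_ids is None:
        if n_validation_formulations > len(eligible):
            raise ValueError(
                f"requested {n_validation_formulations} validation "
                f"formulations, only {len(eligible)} available")
        rng = np.random.default_rng(seed)
        validation_ids = list(rng.choice(eligible,
                                         size=n_validation_formulations,
                                         replace=False))
    chosen = set(map(str, validation_ids))
    unknown = chosen - set(eligible)
    if unknown:
        raise ValueError(f"unknown formulation ids: {sorted(unknown)}")
    out = ds.copy()
    for rec in ds.records:
        if out.partitions[rec.run_id] in (PART_CALIBRATION, PART_INTERNAL):
            out.partitions[rec.run_id] = (
                PART_INTERNAL if rec.formulation_id in chosen
                else PART_CALIBRATION)
    return out


def fit_model(ds: Dataset, n_components: int | str = "auto", a_max: int = 6,
              folds: int = 7, seed: int | None = 0,
              deviations: tuple[float, ...] = (100.0, 300.0),
              delta: float = 0.01) -> tuple[chem.PLSModel, dict]:
    """Fit PLS on the calibration partition and evaluate it.

    With ``n_components="auto"`` the depth is chosen by the R^2/Q^2 plateau
    rule.  Metrics: calibration R^2 and cross-validated Q^2; RMSEP and
    accuracies on the internal-validation partition when present.
    """
    X = ds.X(PART_CALIBRATION)
    y = ds.y(PART_CALIBRATION)
    if X.empty:
        raise ValueError("calibration partition is empty")
    ledger = None
    if n_components == "auto":
        a_cap = min(a_max, len(y) - 1, X.shape[1])
        n_components, ledger = chem.select_n_lv(X, y, a_cap, folds=folds,
                                                delta=delta, seed=seed)
    model = chem.fit_pls(X, y, int(n_components))
    cv = chem.q2_cv(X, y, model.n_components, folds=folds, seed=seed)
    fitted = model.predict(X)
    metrics = {
        "A": model.n_components,
        "R2": chem.r2(y, fitted),
        "Q2": cv["q2"],
        "RMSE_calibration": chem.rmsep(y, fitted),
        "ledger": ledger,
    }
    internal = ds.subset(PART_INTERNAL)
    if internal:
        Xi = ds.X(PART_INTERNAL)
        yi = ds.y(PART_INTERNAL)
        pi = model.predict(Xi)
        metrics["RMSEP_internal"] = chem.rmsep(yi, pi)
        for dev in deviations:
            metrics[f"accuracy_internal@{dev:g}"] = chem.accuracy(yi, pi, dev)
    return model, metrics


def fuse(ds: Dataset, lab_records: list[GranulationRecord]) -> Dataset:
    """Append lab records to the calibration partition.

    Valid lab runs augment the calibration set; failed (slurry) runs are
    kept, flagged, and excluded from any fit.
    """
    out = ds.copy()
    existing = {r.run_id for r in out.records}
    for rec in lab_records:
        if rec.run_id in existing:
            raise AlignmentError(f"duplicate run id {rec.run_id!r} in fusion")
        if list(rec.features.index) != list(FEATURE_COLUMNS):
            raise AlignmentError(
                f"run {rec.run_id!r}: feature columns do not match")
        out.records.append(rec)
        if rec.failed or rec.g50 is None:
            out.partitions[rec.run_id] = PART_FAILED
            out.reasons[rec.run_id] = "failed run (slurry); excluded from fit"
        else:
            out.partitions[rec.run_id] = PART_CALIBRATION
    return out


def prediction_report(y_obs, y_pred, ls=None,
                      deviations: tuple[float, ...] = (100.0, 300.0),
                      ls_threshold: float = 0.5) -> dict:
    """Summary statistics of a prediction set.

    RMSEP, mean absolute error, accuracy at each deviation, and -- when L/S
    values are supplied -- the mean absolute error stratified into high and
    low liquid-content runs at ``ls_threshold``.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    err = np.abs(y_pred - y_obs)
    out = {
        "n": int(len(y_obs)),
        "RMSEP": chem.rmsep(y_obs, y_pred),
        "MAE": float(err.mean()),
    }
    for dev in deviations:
        out[f"accuracy@{dev:g}"] = chem.accuracy(y_obs, y_pred, dev)
    if ls is not None:
        ls = np.asarray(ls, dtype=float).ravel()
        high = ls >= ls_threshold
        out["MAE_high_LS"] = float(err[high].mean()) if high.any() else np.nan
        out["MAE_low_LS"] = float(err[~high].mean()) if (~high).any() else np.nan
    return out


def compare_models(m1: chem.PLSModel, m2: chem.PLSModel, external: Dataset,
                   deviations: tuple[float, ...] = (100.0, 300.0),
                   ls_threshold: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Per-record and summary comparison of two models on external data."""
    recs = external.subset(PART_EXTERNAL) or [
        r for r in external.records if not r.failed and r.g50 is not None]
    if not recs:
        raise ValueError("external set is empty")
    X = pd.DataFrame([r.features for r in recs],
                     index=[r.run_id for r in recs])
    y = np.array([r.g50 for r in recs])
    ls = X["LS"].to_numpy()
    p1, p2 = m1.predict(X), m2.predict(X)
    table = pd.DataFrame({
        "LS": ls, "y_obs": y,
        "pred_model1": p1, "pred_model2": p2,
        "abs_err_model1": np.abs(p1 - y), "abs_err_model2": np.abs(p2 - y),
    }, index=X.index)
    summary = {
        "model1": prediction_report(y, p1, ls, deviations, ls_threshold),
        "model2": prediction_report(y, p2, ls, deviations, ls_threshold),
    }
    return table, summary


# ---------------------------------------------------------------------------
# Sieve analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SieveResult:
    """Retained masses on a descending sieve stack plus the pan."""

    apertures_um: tuple[float, ...]    # strictly decreasing
    retained_g: tuple[float, ...]
    pan_g: float

    def __post_init__(self):
        ap = tuple(float(a) for a in self.apertures_um)
        ms = tuple(float(m) for m in self.retained_g)
        if len(ap) != len(ms):
            raise SieveError("apertures and masses must align")
        if any(a2 >= a1 for a1, a2 in zip(ap, ap[1:])):
            raise SieveError("apertures must be strictly decreasing")
        if any(m < 0 for m in ms) or self.pan_g < 0:
            raise SieveError("masses must be >= 0")
        if sum(ms) + self.pan_g <= 0:
            raise SieveError("total mass must be > 0")
        object.__setattr__(self, "apertures_um", ap)
        object.__setattr__(self, "retained_g", ms)


def g50_from_sieves(sr: SieveResult, interpolation: str = "log") -> float:
    """Median granule size from the cumulative undersize distribution.

    The undersize mass fraction at each aperture is interpolated at 0.5;
    interpolation is linear in log10(aperture) by default (sieve series are
    geometric), or linear in size with ``interpolation="linear"``.
    A 50% crossing outside the sieve range raises, reporting the bracketing
    bound.
    """
    if interpolation not in ("log", "linear"):
        raise SieveError("interpolation must be 'log' or 'linear'")
    total = sum(sr.retained_g) + sr.pan_g
    # undersize fraction just below each aperture, ascending order
    apertures = np.array(sr.apertures_um[::-1])
    retained = np.array(sr.retained_g[::-1])
    undersize = (sr.pan_g + np.concatenate(
        ([0.0], np.cumsum(retained)[:-1]))) / total
    exact = np.isclose(undersize, 0.5)
    if exact.any():
        return float(apertures[exact.argmax()])
    if undersize[0] > 0.5:
        raise SieveError(
            f"50% crossing below the finest sieve ({apertures[0]:g} um); "
            "add finer sieves")
    if undersize[-1] < 0.5:
        raise SieveError(
            f"50% crossing above the coarsest sieve ({apertures[-1]:g} um); "
            "add coarser sieves")
    hi = int(np.searchsorted(undersize, 0.5))
    lo = hi - 1
    u0, u1 = undersize[lo], undersize[hi]
    frac = (0.5 - u0) / (u1 - u0)
    if interpolation == "log":
        x0, x1 = np.log10(apertures[lo]), np.log10(apertures[hi])
        return float(10 ** (x0 + frac * (x1 - x0)))
    x0, x1 = apertures[lo], apertures[hi]
    return float(x0 + frac * (x1 - x0))
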