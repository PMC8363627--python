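"""Synthetic materials, formulations and granulation outcomes.

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without any external data:

* **Materials** are driven by two latent factors -- a size/flow factor
  (particle sizes, fines fraction, angle of repose, flow time) and a
  density/porosity factor (bulk/tapped/true density, porosities, Carr and
  Hausner indices) -- matching the two dominant directions real excipient
  property tables show.  Derived quantities are enforced exactly
  (IH = Dc/Da, IC = 100 (Dc-Da)/Dc, porosity = 1 - Da/Dt,
  span = (D90-D10)/D50, Da <= Dc <= Dt, D10 <= D50 <= D90), so every record
  satisfies the database invariants by construction.

* **Granule size** follows a log-linear response: liquid content (L/S and
  pore saturation) grows granules, shear (Froude number) breaks them, a wide
  size distribution (span) hinders even growth; multiplicative noise keeps
  G50 positive.  Pore saturation above a threshold produces a slurry failure
  instead of a granule size.

* **A study** pairs literature-like sources -- each source is one narrow
  designed experiment: a single formulation, a small L/S window around its
  own operating point, its own granulator scale, and a source-specific bias
  on log10 G50 -- with bias-free lab runs spanning the whole design space.
  All tables are materialized in the loader formats and pushed through the
  real alignment pipeline, so generated artifacts exercise every invariant
  downstream code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import Dataset, GranulationRecord, align_literature
from .material_db import MaterialDB, MaterialRecord, PROPERTY_COLUMNS
from .process import G_DEFAULT, radius_from_volume

#: Granulator scales (L) emulating the spread of published studies.
LITERATURE_SCALES = (0.25, 1.0, 2.0, 10.0, 25.0, 65.0, 150.0, 300.0, 600.0)

#: Lab bowl radii by scale (L).
LAB_SCALE_RADII = {1.0: 0.070, 2.0: 0.087}


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic generator.

    ``coefficients`` act on log10(G50/um): intercept, L/S ratio (per g/g),
    pore saturation (per 100%), Froude number (per unit) and span (per
    unit).  ``noise_sd`` and ``source_bias_sd`` are standard deviations on
    the log10 scale; ``slurry_threshold`` is the S'max (%) above which a run
    fails instead of yielding granules.
    """

    n_materials: int = 12
    n_factors: int = 2
    coefficients: dict = field(default_factory=lambda: {
        "intercept": 2.2, "ls": 0.55, "smax": 0.20, "fr": -0.03,
        "span": -0.05})
    noise_sd: float = 0.05
    source_bias_sd: float = 0.1
    slurry_threshold: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.source_bias_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.slurry_threshold > 0:
            raise ValueError("slurry threshold must be > 0")
        if self.n_materials < 2:
            raise ValueError("need at least 2 materials")


def _clip(x, lo, hi):
    return np.clip(x, lo, hi)


def generate_material_db(spec: GeneratorSpec,
                         rng: np.random.Generator | None = None) -> MaterialDB:
    """Draw a property-consistent material database.

    Two latent factors map to the 18 properties with small independent
    measurement noise; consistency relations are imposed exactly.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_materials
    f1 = rng.normal(size=n)                     # size / flow factor
    f2 = rng.normal(size=n)                     # density / porosity factor
    e = lambda s=1.0: rng.normal(scale=s, size=n)  # noqa: E731

    d50 = 10 ** (1.9 + 0.45 * f1 + 0.08 * e())
    r10 = rng.uniform(0.15, 0.5, size=n)
    r90 = rng.uniform(1.8, 3.5, size=n)
    d10 = d50 * r10
    d90 = d50 * r90
    span = (d90 - d10) / d50

    da = _clip(0.45 + 0.12 * f2 + 0.03 * e(), 0.15, 0.95)
    compress = _clip(0.22 - 0.06 * f2 + 0.03 * e(), 0.02, 0.6)
    dc = da * (1.0 + compress)
    pore = _clip(0.68 - 0.06 * f2 + 0.04 * e(), 0.45, 0.85)
    dt = np.maximum(dc * 1.05, da / (1.0 - pore))

    porosity = 1.0 - da / dt
    ih = dc / da
    ic = 100.0 * (dc - da) / dc
    ie = (dc - da) / (dc * da)
    angle = _clip(38.0 - 4.0 * f1 + 1.5 * e(), 20.0, 55.0)
    flow_time = _clip(12.0 - 4.0 * f1 + 1.0 * e(), 0.5, 40.0)
    hr = _clip(3.0 + 0.9 * f2 + 0.5 * e(), 0.1, 10.0)
    hygro = _clip(2.0 + 0.7 * f2 + 0.4 * e(), 0.05, 15.0)
    pf = _clip(100.0 / (1.0 + (d50 / 50.0) ** 2.2) + 2.0 * e(), 0.0, 100.0)
    icd = _clip(8.0 - 2.0 * f1 + 1.0 * e(), 0.0, 30.0)
    itheta = _clip(0.02 - 0.004 * f1 + 0.002 * e(), 0.001, 0.08)

    columns = {
        "Da": da, "Dc": dc, "Dt": dt, "porosity": porosity, "Ie": ie,
        "IC": ic, "Icd": icd, "IH": ih, "angle": angle,
        "flow_time": flow_time, "HR": hr, "H": hygro, "pf": pf,
        "Itheta": itheta, "D10": d10, "D50": d50, "D90": d90, "span": span,
    }
    db = MaterialDB()
    for i in range(n):
        props = np.array([columns[c][i] for c in PROPERTY_COLUMNS])
        rec = MaterialRecord(f"MAT{i + 1:02d}", "STD", props)
        problems = rec.violations()
        if problems:  # pragma: no cover - invariants hold by construction
            raise AssertionError(f"generated record invalid: {problems}")
        db.add(rec)
    return db


def generate_response(feature_row: pd.Series, spec: GeneratorSpec,
                      source_bias: float = 0.0,
                      rng: np.random.Generator | None = None
                      ) -> tuple[float | None, bool]:
    """Granule size (um) or slurry failure for one feature row.

    Returns ``(g50, failed)``; failed runs have ``g50 = None``.
    """
    if float(feature_row["Smax"]) > spec.slurry_threshold:
        return None, True
    rng = rng or np.random.default_rng(spec.seed)
    c = spec.coefficients
    log_g50 = (c["intercept"]
               + c["ls"] * float(feature_row["LS"])
               + c["smax"] * float(feature_row["Smax"]) / 100.0
               + c["fr"] * float(feature_row["Fr"])
               + c["span"] * float(feature_row["span"])
               + source_bias
               + (rng.normal(scale=spec.noise_sd) if spec.noise_sd > 0
                  else 0.0))
    return float(10 ** log_g50), False


def generate_study(
    spec: GeneratorSpec,
    n_sources: int = 10,
    n_per_source: int = 14,
    n_lab: int = 14,
    g: float = G_DEFAULT,
) -> dict:
    """Generate a full two-domain study through the real pipeline.

    Literature sources emulate published articles: each fixes one binary
    formulation, operates one granulator scale (radius derived from volume),
    explores a narrow L/S window around its own center, and carries a
    source-specific bias on log10 G50.  Lab runs have zero bias, span the
    full L/S and impeller bounds on the 1 L / 2 L bowls, and random binary
    formulations.  All run and formulation tables are materialized and
    aligned with :func:`granufuse.fusion.align_literature`, so the returned
    datasets passed every loader invariant.

    Returns a dict with ``literature``/``lab`` Datasets, the ``materials``
    database, the raw ``tables``, and ``truth`` (generating coefficients,
    per-source biases, noise level).
    """
    if min(n_sources, n_per_source, n_lab) < 1:
        raise ValueError("counts must be >= 1")
    root = np.random.SeedSequence(spec.seed)
    rng_mat, rng_lit, rng_lab, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4))
    db = generate_material_db(spec, rng_mat)
    keys = sorted(db.records)
    names = {k: (db.records[k].name, db.records[k].spec) for k in keys}

    form_rows: list[dict] = []
    run_rows: list[dict] = []
    biases: dict[str, float] = {}

    def add_formulation(fid: str, k1: str, k2: str, frac1: float) -> None:
        for key, frac in ((k1, frac1), (k2, 1.0 - frac1)):
            name, spc = names[key]
            form_rows.append({"formulation_id": fid, "material_name": name,
                              "material_spec": spc, "mass_fraction": frac})

    # literature domain: one narrow designed experiment per source
    for s in range(n_sources):
        source = f"src{s + 1:02d}"
        biases[source] = float(rng_lit.normal(scale=spec.source_bias_sd)) \
            if spec.source_bias_sd > 0 else 0.0
        k1, k2 = rng_lit.choice(len(keys), size=2, replace=False)
        frac1 = float(rng_lit.uniform(0.1, 0.9))
        fid = f"F-{source}"
        add_formulation(fid, keys[k1], keys[k2], frac1)
        scale = float(rng_lit.choice(LITERATURE_SCALES))
        ls_center = float(rng_lit.uniform(0.15, 1.2))
        solids = 150.0 * scale
        radius = radius_from_volume(scale)
        for j in range(n_per_source):
            w = float(np.clip(ls_center + rng_lit.uniform(-0.15, 0.15),
                              0.025, 1.8))
            fr_target = float(rng_lit.uniform(0.5, 14.0))
            rpm = 60.0 * np.sqrt(fr_target * g / (2.0 * radius))
            run_rows.append({
                "run_id": f"{source}-r{j + 1:02d}", "formulation_id": fid,
                "scale_L": scale, "radius_m": np.nan,
                "impeller_rpm": rpm, "tip_speed_ms": np.nan,
                "water_ml": np.nan, "water_g": w * solids,
                "rate_ml_min": np.nan, "duration_min": np.nan,
                "solids_g": solids, "G50_um": np.nan,
                "source": source, "failed": False,
            })

    # lab domain: full design-space sampling, measured radii, zero bias
    for j in range(n_lab):
        k1, k2 = rng_lab.choice(len(keys), size=2, replace=False)
        frac1 = float(rng_lab.uniform(0.0, 1.0))
        fid = f"F-lab{j + 1:02d}"
        add_formulation(fid, keys[k1], keys[k2], frac1)
        scale = float(rng_lab.choice(sorted(LAB_SCALE_RADII)))
        w = float(rng_lab.uniform(0.025, 1.8))
        rpm = int(rng_lab.integers(350, 1201))
        solids = 150.0 * scale
        run_rows.append({
            "run_id": f"lab-r{j + 1:02d}", "formulation_id": fid,
            "scale_L": scale, "radius_m": LAB_SCALE_RADII[scale],
            "impeller_rpm": float(rpm), "tip_speed_ms": np.nan,
            "water_ml": w * solids, "water_g": np.nan,
            "rate_ml_min": np.nan, "duration_min": np.nan,
            "solids_g": solids, "G50_um": np.nan,
            "source": "lab", "failed": False,
        })

    runs = pd.DataFrame(run_rows)
    formulations = pd.DataFrame(form_rows)
    aligned, report = align_literature(runs, formulations, db, g=g)
    if len(aligned) != len(runs):  # pragma: no cover
        bad = report[report["status"] == "excluded"]
        raise AssertionError(f"generated runs failed alignment:\n{bad}")

    # outcomes from the aligned (unit-consistent) features
    lit_records, lab_records = [], []
    for rec in aligned.records:
        bias = biases.get(rec.source, 0.0)
        g50, failed = generate_response(rec.features, spec, bias, rng_noise)
        new = _with_outcome(rec, g50, failed)
        (lab_records if rec.source == "lab" else lit_records).append(new)
        runs.loc[runs["run_id"] == rec.run_id,
                 ["G50_um", "failed"]] = [np.nan if g50 is None else g50,
                                          failed]

    return {
        "literature": Dataset(lit_records),
        "lab": Dataset(lab_records),
        "materials": db,
        "tables": {"runs": runs, "formulations": formulations},
        "truth": {"coefficients": dict(spec.coefficients),
                  "source_bias": biases, "noise_sd": spec.noise_sd},
    }


def _with_outcome(rec: GranulationRecord, g50: float | None,
                  failed: bool) -> GranulationRecord:
    """Copy of a record with the generated outcome substituted in."""
    return GranulationRecord(
        run_id=rec.run_id, formulation_id=rec.formulation_id,
        features=rec.features, g50=g50, source=rec.source,
        failed=failed, meta=dict(rec.meta))
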