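"""Ideal mixing rule: mixture properties as mass-fraction linear combinations.

A formulation's property vector is the matrix product of its mass-fraction
row with the constituent materials' property matrix.  The linear rule is
applied uniformly to all 18 properties (including true density and the
derived flow indices); this keeps mixture estimation a single, reproducible
matrix product even where a property would classically mix non-linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .material_db import PROPERTY_COLUMNS, material_key

#: Tolerance on the mass-fraction sum.
FRACTION_TOL = 1e-6


class MixingError(ValueError):
    """A formulation cannot be mixed (bad fractions or unresolved component)."""


@dataclass(frozen=True)
class Formulation:
    """Mass-fraction composition over named materials.

    ``components`` maps material keys (as used in the property matrix index)
    to dimensionless mass fractions summing to 1.
    """

    id: str
    components: tuple[tuple[str, float], ...]

    def __post_init__(self):
        comps = tuple((str(k), float(w)) for k, w in self.components)
        object.__setattr__(self, "components", comps)
        self.validate()

    def validate(self) -> None:
        if not self.components:
            raise MixingError(f"formulation {self.id!r} has no components")
        fracs = np.array([w for _, w in self.components])
        if (fracs < 0).any():
            raise MixingError(f"formulation {self.id!r} has negative fractions")
        if abs(fracs.sum() - 1.0) > FRACTION_TOL:
            raise MixingError(
                f"formulation {self.id!r} fractions sum to {fracs.sum()!r}, not 1"
            )

    def weights(self, index: Sequence[str]) -> np.ndarray:
        """Weight row aligned to a property-matrix index."""
        pos = {k: i for i, k in enumerate(index)}
        w = np.zeros(len(index))
        for key, frac in self.components:
            if key not in pos:
                raise MixingError(
                    f"formulation {self.id!r}: component {key!r} not in the "
                    "materials matrix"
                )
            w[pos[key]] += frac
        return w


def load_formulations(path) -> list[Formulation]:
    """Read the long-format formulations table.

    Columns: ``formulation_id, material_name, material_spec, mass_fraction``.
    Component keys are built from the normalized (name, spec) pair.
    """
    table = pd.read_csv(path, sep=None, engine="python",
                        dtype={"material_spec": str})
    required = {"formulation_id", "material_name", "mass_fraction"}
    missing = required - set(table.columns)
    if missing:
        raise MixingError(f"formulations table missing columns: {sorted(missing)}")
    if "material_spec" not in table.columns:
        table["material_spec"] = ""
    out = []
    for fid, grp in table.groupby("formulation_id", sort=False):
        comps = tuple(
            (material_key(r.material_name,
                          r.material_spec if isinstance(r.material_spec, str) else ""),
             float(r.mass_fraction))
            for r in grp.itertuples()
        )
        out.append(Formulation(str(fid), comps))
    return out


def mix_properties(
    formulations: Sequence[Formulation], materials: pd.DataFrame
) -> pd.DataFrame:
    """Mixture property matrix: row i, column k = sum_j w_ij * p_jk.

    ``materials`` is a fully resolved property matrix (rows = material keys,
    columns = the 18 properties in canonical order).  Any missing value in a
    material actually used by a formulation is an error: mixing requires
    fully resolved inputs.
    """
    cols = list(materials.columns)
    if cols != list(PROPERTY_COLUMNS):
        raise MixingError(
            f"materials matrix columns must be {list(PROPERTY_COLUMNS)}, got {cols}"
        )
    index = list(materials.index)
    W = np.array([f.weights(index) for f in formulations]) \
        if formulations else np.empty((0, len(index)))
    P = materials.to_numpy(dtype=float)
    used = W.sum(axis=0) > 0
    bad = np.isnan(P[used]).any(axis=1)
    if bad.any():
        names = [k for k, u in zip(index, used) if u]
        offenders = [names[i] for i in np.where(bad)[0]]
        raise MixingError(f"materials with missing properties used in mixing: "
                          f"{offenders}")
    out = W @ P
    return pd.DataFrame(out, index=[f.id for f in formulations],
                        columns=list(PROPERTY_COLUMNS))


def formulation_true_density(
    formulation: Formulation, materials: pd.DataFrame
) -> float:
    """Mixture true density (g/mL) by the ideal mixing rule."""
    dt = materials["Dt"]
    total = 0.0
    for key, frac in formulation.components:
        if key not in dt.index:
            raise MixingError(
                f"formulation {formulation.id!r}: component {key!r} unresolved"
            )
        value = float(dt.loc[key])
        if not np.isfinite(value):
            raise MixingError(
                f"formulation {formulation.id!r}: true density missing for {key!r}"
            )
        total += frac * value
    return total
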