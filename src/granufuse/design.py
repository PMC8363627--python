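"""Monte-Carlo experimental design over binary formulations.

Candidate formulations enumerate two material groups (cellulose-type vs
lactose-type) over a mass-fraction grid; process conditions (L/S ratio,
integer impeller speed, bowl scale) are sampled uniformly within equipment
bounds.  Candidates are assembled into the 21-column feature matrix, can be
projected into a fitted model's latent space to judge coverage of the
calibration domain, and lab runs are drawn as disjoint random subsets.

Randomness is organized as named substreams spawned from one master seed,
so the L/S draw, the impeller draw, the scale allocation and the run
selection are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import PLSModel, hotelling_t2
from .mixing import Formulation, mix_properties
from .process import FEATURE_COLUMNS, G_DEFAULT, SLURRY_THRESHOLD, \
    epsilon_min, froude, smax

#: Substream order under the master seed; appending new names never
#: perturbs existing draws.
_STREAMS = ("ls", "impeller", "scale", "selection")

#: Default bowl radii (m) per scale (L) for the lab granulator.
DEFAULT_SCALE_RADII = {1.0: 0.070, 2.0: 0.087}

LABEL_MODEL = "modeling"
LABEL_VALIDATION = "validation"
LABEL_UNSELECTED = "unselected"


class DesignError(ValueError):
    pass


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


@dataclass
class DesignSpace:
    """Factor bounds for the granulation design.

    ``group_a``/``group_b`` hold material keys present in the property
    matrix used to build candidates.  ``step_pct`` is the mass-fraction grid
    increment for group-A materials (group B takes the complement).
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    step_pct: int = 1
    ls_bounds: tuple[float, float] = (0.025, 1.8)
    rpm_bounds: tuple[int, int] = (350, 1200)
    scale_radii: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_RADII))
    seed: int = 0

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise DesignError("both material groups must be non-empty")
        if self.step_pct <= 0 or 100 % self.step_pct != 0:
            raise DesignError(f"step_pct must divide 100, got {self.step_pct}")
        for lo, hi in (self.ls_bounds, self.rpm_bounds):
            if not lo < hi:
                raise DesignError(f"bounds must be ordered, got ({lo}, {hi})")
        if not self.scale_radii:
            raise DesignError("at least one scale with a radius is required")


@dataclass
class CandidateSet:
    """Aligned candidate blocks: formulations, process draws, features."""

    formulations: list[Formulation]
    process: pd.DataFrame                 # ls, rpm, scale_L, radius_m
    features: pd.DataFrame                # n x 21, FEATURE_COLUMNS
    labels: np.ndarray                    # modeling | validation | unselected
    slurry: np.ndarray                    # predicted S'max > threshold

    def __len__(self) -> int:
        return len(self.formulations)


def enumerate_binary_formulations(space: DesignSpace) -> list[Formulation]:
    """All (A, B) pairs with A-fraction on the 0..100% grid.

    Count = |A| * |B| * (100 / step + 1); fractions always sum to 100%.
    """
    levels = np.arange(0, 100 + space.step_pct, space.step_pct)
    out = []
    for a in space.group_a:
        for b in space.group_b:
            for pct in levels:
                fa = pct / 100.0
                fid = f"{a}={pct}%|{b}={100 - pct}%"
                out.append(Formulation(fid, ((a, fa), (b, 1.0 - fa))))
    return out


def sample_process(space: DesignSpace, n: int) -> pd.DataFrame:
    """Uniform process draws: L/S continuous, rpm integer, scale discrete."""
    if n < 1:
        raise DesignError("n must be >= 1")
    rngs = _substreams(space.seed)
    ls = rngs["ls"].uniform(*space.ls_bounds, size=n)
    rpm = rngs["impeller"].integers(space.rpm_bounds[0],
                                    space.rpm_bounds[1] + 1, size=n)
    scales = np.array(sorted(space.scale_radii))
    scale = rngs["scale"].choice(scales, size=n)
    radius = np.array([space.scale_radii[s] for s in scale])
    return pd.DataFrame({"ls": ls, "rpm": rpm.astype(int),
                         "scale_L": scale, "radius_m": radius})


def build_candidates(
    formulations: Sequence[Formulation],
    process_params: pd.DataFrame,
    materials: pd.DataFrame,
    g: float = G_DEFAULT,
    density: str = "true",
) -> CandidateSet:
    """Assemble the n x 21 candidate feature matrix.

    Mixture properties come from the ideal mixing rule; Fr from the sampled
    impeller speed and the scale's radius; S'max from the sampled L/S and
    the mixture densities.  Candidates with S'max above the slurry threshold
    are flagged, not removed: the design surfaces the over-wetting risk.
    """
    formulations = list(formulations)
    if len(formulations) != len(process_params):
        raise DesignError(
            f"{len(formulations)} formulations vs {len(process_params)} "
            "process draws; the blocks must align row-by-row"
        )
    mixed = mix_properties(formulations, materials)
    proc = process_params.reset_index(drop=True)
    fr = np.array([froude(r.rpm, r.radius_m, g=g)
                   for r in proc.itertuples()])
    eps = np.array([epsilon_min(dc, dt)
                    for dc, dt in zip(mixed["Dc"], mixed["Dt"])])
    rho = mixed["Dt" if density == "true" else "Da"].to_numpy()
    s = np.array([smax(w, p, e)
                  for w, p, e in zip(proc["ls"], rho, eps)])
    features = mixed.reset_index(drop=True).copy()
    features["LS"] = proc["ls"].to_numpy()
    features["Fr"] = fr
    features["Smax"] = s
    features = features[list(FEATURE_COLUMNS)]
    features.index = [f.id for f in formulations]
    labels = np.full(len(formulations), LABEL_UNSELECTED, dtype=object)
    return CandidateSet(formulations, proc, features, labels,
                        slurry=s > SLURRY_THRESHOLD)


def select_experiments(candidates: CandidateSet, n_model: int,
                       n_validation: int, seed: int = 0) -> CandidateSet:
    """Label disjoint uniform-random modeling and validation subsets."""
    n = len(candidates)
    if n_model + n_validation > n:
        raise DesignError(
            f"cannot select {n_model}+{n_validation} from {n} candidates")
    rng = _substreams(seed)["selection"]
    picks = rng.choice(n, size=n_model + n_validation, replace=False)
    labels = np.full(n, LABEL_UNSELECTED, dtype=object)
    labels[picks[:n_model]] = LABEL_MODEL
    labels[picks[n_model:]] = LABEL_VALIDATION
    candidates.labels = labels
    return candidates


def coverage_report(model: PLSModel, candidates: CandidateSet,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Project candidates into the model's score space and flag extremes.

    Rows outside the calibration (1 - alpha) Hotelling T^2 limit are marked
    ``outside``; ``nearest_calibration`` is the Euclidean distance to the
    closest calibration score.
    """
    scores = model.project(candidates.features)
    cal = model.T
    var = cal.var(axis=0, ddof=1)
    t2 = (scores ** 2 / var).sum(axis=1)
    _, limit = hotelling_t2(cal, model.n_components, alpha=alpha)
    d2 = ((scores[:, None, :] - cal[None, :, :]) ** 2).sum(axis=2)
    nearest = np.sqrt(d2.min(axis=1))
    return pd.DataFrame({
        **{f"t{a + 1}": scores[:, a] for a in range(scores.shape[1])},
        "T2": t2,
        "outside": t2 > limit,
        "nearest_calibration": nearest,
        "label": candidates.labels,
        "slurry_risk": candidates.slurry,
    }, index=candidates.features.index)
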