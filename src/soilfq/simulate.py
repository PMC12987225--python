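"""Virtual tillage experiments matching the field-trial design.

The generator emulates a single-factor randomized trial: 3 summer-fallow
tillage treatments (FNT no-till, FST subsoiling, FPT plowing) x 5 depth
layers of 10 cm (0-50 cm) x 3 replicates. Soil physical/chemical variables
are drawn from truncated Gaussians around a treatment x layer effect grid;
wet-sieve aggregate proportions from a Dirichlet distribution (so they sum
to 1 exactly); yield components at treatment level with plot noise only
(yield is sampled per plot, not per layer).

Reproducibility: one integer master seed is combined with a stable CRC-32
hash of each variable name to seed an independent substream per variable,
so adding or removing a variable never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import (
    PARTICLE_DENSITY,
    AggregateFractionSet,
    AocRecord,
    SoilLayerRecord,
    YieldRecord,
    records_to_frame,
)

_TRUNCATION_ATTEMPTS = 1000

#: valid sampling ranges per variable (truncation bounds)
_BOUNDS = {
    "bulk_density": (0.05, PARTICLE_DENSITY - 1e-6),
    "water_content": (0.0, 99.0),
    "soc_content": (0.0, np.inf),
    "aoc": (0.0, np.inf),
    "ear_number": (1e-6, np.inf),
    "ear_grain_number": (1e-6, np.inf),
    "thousand_grain_weight": (1e-6, np.inf),
    "grain_yield": (1e-6, np.inf),
}


@dataclass
class ExperimentDesign:
    """Full parameterization of one virtual experiment.

    ``effect_grid`` maps variable -> treatment -> per-layer mean values;
    ``yield_grid`` maps yield component -> treatment -> plot mean;
    ``aoc_grid`` maps treatment -> per-layer list of four class AOC means;
    ``dirichlet_concentration`` maps treatment -> per-layer four positive
    weights (mean proportion x precision).
    """

    treatments: tuple[str, ...] = ("FNT", "FST", "FPT")
    n_layers: int = 5
    layer_thickness: float = 10.0  # cm
    n_replicates: int = 3
    effect_grid: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    yield_grid: dict[str, dict[str, float]] = field(default_factory=dict)
    aoc_grid: dict[str, list[list[float]]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    dirichlet_concentration: dict[str, list[list[float]]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_layers < 1 or self.n_replicates < 1 or len(self.treatments) < 1:
            raise ValidationError("treatments, n_layers and n_replicates must all be >= 1")
        if self.layer_thickness <= 0:
            raise ValidationError("layer_thickness must be > 0")
        for var, sd in self.noise_sd.items():
            if sd < 0:
                raise ValidationError(f"noise_sd[{var!r}] must be >= 0, got {sd}")
        for var, grid in self.effect_grid.items():
            for t in self.treatments:
                if t not in grid:
                    raise ValidationError(f"effect_grid[{var!r}] missing treatment {t!r}")
                if len(grid[t]) != self.n_layers:
                    raise ValidationError(
                        f"effect_grid[{var!r}][{t!r}] must have {self.n_layers} layer means"
                    )
        for t in self.treatments:
            if t not in self.dirichlet_concentration:
                raise ValidationError(f"dirichlet_concentration missing treatment {t!r}")
            for layer_weights in self.dirichlet_concentration[t]:
                if len(layer_weights) != 4 or any(w <= 0 for w in layer_weights):
                    raise ValidationError(
                        f"dirichlet_concentration[{t!r}] needs four positive weights per layer"
                    )


@dataclass
class SimulatedExperiment:
    soil: list[SoilLayerRecord]
    fractions: list[AggregateFractionSet]
    aoc: list[AocRecord]
    yields: list[YieldRecord]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "soil": records_to_frame(self.soil),
            "fractions": records_to_frame(self.fractions),
            "aoc": records_to_frame(self.aoc),
            "yield": records_to_frame(self.yields),
        }


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent deterministic RNG per (seed, variable name)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled Gaussian restricted to [lo, hi]."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise DomainError(f"mean {mean} outside truncation bounds [{lo}, {hi}]")
        return mean
    for _ in range(_TRUNCATION_ATTEMPTS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise DomainError(
        f"truncated-normal rejection failed after {_TRUNCATION_ATTEMPTS} attempts "
        f"(mean={mean}, sd={sd}, bounds=[{lo}, {hi}])"
    )


def generate_experiment(design: ExperimentDesign,
                        seed: int | None = None) -> SimulatedExperiment:
    """Draw one complete virtual experiment from a design.

    One soil/fraction/AOC record per treatment x layer x replicate and one
    yield record per treatment x replicate; byte-identical output for the
    same seed.
    """
    design.validate()
    seed = design.seed if seed is None else seed
    rngs = {name: _substream(seed, name)
            for name in ("bulk_density", "water_content", "soc_content",
                         "fractions", "aoc", "yield")}

    soil: list[SoilLayerRecord] = []
    fracs: list[AggregateFractionSet] = []
    aocs: list[AocRecord] = []
    for t in design.treatments:
        for layer in range(design.n_layers):
            top = layer * design.layer_thickness
            bottom = top + design.layer_thickness
            for rep in range(1, design.n_replicates + 1):
                vals = {}
                for var in ("bulk_density", "water_content", "soc_content"):
                    mean = design.effect_grid[var][t][layer]
                    sd = design.noise_sd.get(var, 0.0)
                    lo, hi = _BOUNDS[var]
                    vals[var] = _truncated_normal(rngs[var], mean, sd, lo, hi)
                soil.append(SoilLayerRecord(
                    treatment=t, replicate=rep, depth_top=top, depth_bottom=bottom,
                    **vals))
                w = rngs["fractions"].dirichlet(
                    np.asarray(design.dirichlet_concentration[t][layer], dtype=float))
                fracs.append(AggregateFractionSet(
                    treatment=t, replicate=rep, depth_top=top, depth_bottom=bottom,
                    proportions=w))
                if design.aoc_grid:
                    means = design.aoc_grid[t][layer]
                    sd = design.noise_sd.get("aoc", 0.0)
                    lo, hi = _BOUNDS["aoc"]
                    aocs.append(AocRecord(
                        treatment=t, replicate=rep, depth_top=top, depth_bottom=bottom,
                        aoc_by_class=np.array([
                            _truncated_normal(rngs["aoc"], m, sd, lo, hi) for m in means
                        ]),
                    ))

    yields: list[YieldRecord] = []
    if design.yield_grid:
        components = ("ear_number", "ear_grain_number",
                      "thousand_grain_weight", "grain_yield")
        for t in design.treatments:
            for rep in range(1, design.n_replicates + 1):
                kwargs = {}
                for comp in components:
                    mean = design.yield_grid[comp][t]
                    sd = design.noise_sd.get(comp, 0.0)
                    lo, hi = _BOUNDS[comp]
                    kwargs[comp] = _truncated_normal(rngs["yield"], mean, sd, lo, hi)
                yields.append(YieldRecord(treatment=t, replicate=rep, **kwargs))

    return SimulatedExperiment(soil=soil, fractions=fracs, aoc=aocs, yields=yields)


# ---------------------------------------------------------------------------
# the planted-effect reference design
# ---------------------------------------------------------------------------

# Treatment x layer effect means, chosen once from the qualitative pattern of
# the field results: FNT has lower BD at 0-20 cm but a compacted 20-30 cm
# layer, higher SWC below 10 cm, the highest topsoil SOC and the largest
# >2 mm aggregate share in 0-30 cm; FPT has the densest topsoil, more deep
# SOC and more <0.053 mm material; FST is intermediate in structure with the
# highest SWC at 0-10 cm and the highest yield. Yield means are the printed
# treatment means of the trial's yield table.
_BD_GRID = {
    "FNT": [1.15, 1.25, 1.45, 1.38, 1.44],
    "FST": [1.18, 1.28, 1.40, 1.42, 1.45],
    "FPT": [1.28, 1.38, 1.38, 1.45, 1.46],
}
_SWC_GRID = {
    "FNT": [14.0, 16.0, 15.0, 14.5, 14.0],
    "FST": [15.0, 14.0, 13.5, 12.5, 12.0],
    "FPT": [13.0, 13.0, 13.0, 11.5, 11.0],
}
_SOC_GRID = {
    "FNT": [9.5, 8.0, 7.0, 4.5, 4.0],
    "FST": [8.2, 7.2, 6.2, 5.0, 4.4],
    "FPT": [6.8, 6.6, 6.4, 5.6, 5.2],
}
# mean aggregate proportions (>2, 2-0.25, 0.25-0.053, <0.053 mm) per layer
_PROP_GRID = {
    "FNT": [(0.32, 0.36, 0.22, 0.10), (0.30, 0.34, 0.24, 0.12),
            (0.26, 0.32, 0.28, 0.14), (0.20, 0.30, 0.32, 0.18),
            (0.18, 0.30, 0.33, 0.19)],
    "FST": [(0.24, 0.32, 0.29, 0.15), (0.22, 0.31, 0.30, 0.17),
            (0.20, 0.30, 0.32, 0.18), (0.19, 0.29, 0.33, 0.19),
            (0.17, 0.29, 0.34, 0.20)],
    "FPT": [(0.17, 0.28, 0.32, 0.23), (0.16, 0.28, 0.33, 0.23),
            (0.18, 0.29, 0.33, 0.20), (0.19, 0.29, 0.33, 0.19),
            (0.18, 0.29, 0.33, 0.20)],
}
#: Dirichlet precision: higher -> replicate proportions cluster tighter
#: around the mean vector (SD ~ sqrt(p(1-p)/(precision+1)) ~ 0.03 at p=0.25).
_DIRICHLET_PRECISION = 300.0

#: class AOC = layer SOC x these multipliers (macro-aggregates carry more OC)
_AOC_FACTORS = (1.20, 1.15, 0.95, 0.85)

_YIELD_GRID = {
    "ear_number": {"FNT": 558.0, "FST": 608.0, "FPT": 584.0},
    "ear_grain_number": {"FNT": 20.0, "FST": 22.0, "FPT": 20.0},
    "thousand_grain_weight": {"FNT": 25.8, "FST": 26.8, "FPT": 27.5},
    "grain_yield": {"FNT": 2985.0, "FST": 3483.0, "FPT": 3028.0},
}

#: replicate noise, chosen so planted treatment contrasts are >= 2 SD at n=3
_NOISE_SD = {
    "bulk_density": 0.03,   # g cm^-3
    "water_content": 0.5,   # %
    "soc_content": 0.25,    # g kg^-1
    "aoc": 0.30,            # g kg^-1
    "ear_number": 6.0,      # 10^4 ha^-1
    "ear_grain_number": 0.3,
    "thousand_grain_weight": 0.5,  # g
    "grain_yield": 70.0,    # kg ha^-1
}


def default_paper_like_design(seed: int = 0) -> ExperimentDesign:
    """The planted-effect reference design used throughout the test suite.

    Plants FNT as the best composite-score treatment (lower topsoil BD,
    higher SWC/SOC/macro-aggregate share) and FST as the highest-yielding
    one, mirroring the direction of the field results. Every constant is a
    module-level grid documented above.
    """
    design = ExperimentDesign(
        effect_grid={
            "bulk_density": {t: list(v) for t, v in _BD_GRID.items()},
            "water_content": {t: list(v) for t, v in _SWC_GRID.items()},
            "soc_content": {t: list(v) for t, v in _SOC_GRID.items()},
        },
        yield_grid={c: dict(v) for c, v in _YIELD_GRID.items()},
        aoc_grid={
            t: [[soc * f for f in _AOC_FACTORS] for soc in _SOC_GRID[t]]
            for t in _SOC_GRID
        },
        noise_sd=dict(_NOISE_SD),
        dirichlet_concentration={
            t: [[p * _DIRICHLET_PRECISION for p in layer] for layer in layers]
            for t, layers in _PROP_GRID.items()
        },
        seed=seed,
    )
    design.validate()
    return design


def with_seed(design: ExperimentDesign, seed: int) -> ExperimentDesign:
    """Copy of a design with a different master seed."""
    return replace(design, seed=seed)
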