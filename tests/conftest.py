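import numpy as np
import pytest

from soilfq.aggregates import class_mean_diameters
from soilfq.io import AggregateFractionSet, SoilLayerRecord
from soilfq.simulate import default_paper_like_design, generate_experiment


def make_fractions(proportions, treatment="FNT", replicate=1,
                   depth_top=0.0, depth_bottom=10.0):
    return AggregateFractionSet(
        treatment=treatment, replicate=replicate,
        depth_top=depth_top, depth_bottom=depth_bottom,
        proportions=np.asarray(proportions, dtype=float),
    )


def power_law_fractions(d_planted: float):
    """Fraction set whose cumulative mass-size curve is exactly
    (d_i/d_max)^(3-D) with d_max equal to the largest class mean diameter,
    so every log-log point lies on the generating line."""
    d = class_mean_diameters()
    d_max = d[0]
    ratios = (d / d_max) ** (3.0 - d_planted)
    w = np.append(-np.diff(ratios), ratios[-1])
    return make_fractions(w), d_max


def make_profile(bds, socs, treatment="FNT", replicate=1, thickness=10.0):
    return [
        SoilLayerRecord(treatment=treatment, replicate=replicate,
                        depth_top=i * thickness, depth_bottom=(i + 1) * thickness,
                        bulk_density=bd, water_content=10.0, soc_content=soc)
        for i, (bd, soc) in enumerate(zip(bds, socs))
    ]


@pytest.fixture(scope="session")
def paper_like_experiment():
    return generate_experiment(default_paper_like_design(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
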