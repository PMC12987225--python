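"""Soil porosity and yield moisture standardization.

Porosity is derived from bulk density against a reference particle density
(2.65 g cm^-3 for mineral soils): SP = (PD - BD) / PD x 100. Grain yields
are expressed at a standard moisture content of 13% using the dry-mass
basis conversion; users with pre-standardized yields can skip the step.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DomainError
from .io import PARTICLE_DENSITY, SoilLayerRecord


def compute_porosity(bulk_density, particle_density: float = PARTICLE_DENSITY):
    """Total porosity (%) from bulk density (g cm^-3).

    Strictly decreasing in bulk density; 0% at BD = PD, 100% at BD -> 0.
    Accepts scalars or arrays.
    """
    bd = np.asarray(bulk_density, dtype=float)
    if particle_density <= 0:
        raise DomainError(f"particle_density must be > 0, got {particle_density}")
    if np.any(bd <= 0):
        raise DomainError("bulk_density must be > 0")
    if np.any(bd > particle_density):
        raise DomainError(
            f"bulk_density exceeds particle density {particle_density} g cm^-3"
        )
    sp = (particle_density - bd) / particle_density * 100.0
    return float(sp) if np.isscalar(bulk_density) else sp


def standardize_yield(raw_yield, measured_moisture, standard_moisture: float = 0.13):
    """Convert a grain yield (kg ha^-1) to a standard moisture basis.

    yield_std = raw * (1 - measured) / (1 - standard); the identity when
    measured equals the standard. Moistures are fractions in [0, 1).
    """
    y = np.asarray(raw_yield, dtype=float)
    m = np.asarray(measured_moisture, dtype=float)
    if np.any(m < 0) or np.any(m >= 1) or not 0 <= standard_moisture < 1:
        raise DomainError("moisture fractions must lie in [0, 1)")
    if np.any(y < 0):
        raise DomainError("raw_yield must be >= 0")
    out = y * (1.0 - m) / (1.0 - standard_moisture)
    return float(out) if np.isscalar(raw_yield) else out


def add_porosity(records: Sequence[SoilLayerRecord],
                 particle_density: float = PARTICLE_DENSITY) -> list[SoilLayerRecord]:
    """Fill the derived porosity field in place for each soil record."""
    for r in records:
        r.porosity = compute_porosity(r.bulk_density, particle_density)
    return list(records)
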