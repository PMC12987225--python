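"""Soil organic carbon stocks: fixed-depth and equivalent-soil-mass methods.

The fixed-depth stock of one layer is SOC (g kg^-1) x BD (g cm^-3) x
thickness (cm) x 0.1, giving Mg ha^-1. Fixed-depth totals are biased when
treatments differ in bulk density (a denser profile holds more soil within
the same depth), so profile comparisons use the equivalent-soil-mass (ESM)
method: cumulative SOC stock is expressed as a function of cumulative soil
mass and evaluated at common reference masses, by default the lightest
profile's cumulative masses so that no profile needs extrapolation.

Interpolation of cumulative stock vs cumulative mass is monotone piecewise
cubic (PCHIP) by default, which cannot overshoot between knots; a linear
option is available and is used automatically with fewer than 3 knots.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, ExtrapolationError, ValidationError
from .io import AggregateFractionSet, AocRecord, CarbonStockProfile, SoilLayerRecord, check_depth_tiling

#: g cm^-2 -> Mg ha^-1
_MASS_TO_MG_HA = 100.0


def stock_fixed_depth(soc, bulk_density, thickness):
    """Layer SOC stock, Mg ha^-1, from concentration, BD and thickness (cm)."""
    soc = np.asarray(soc, dtype=float)
    bd = np.asarray(bulk_density, dtype=float)
    th = np.asarray(thickness, dtype=float)
    if np.any(soc < 0) or np.any(bd < 0) or np.any(th < 0):
        raise DomainError("soc, bulk_density and thickness must all be >= 0")
    out = soc * bd * th * 0.1
    return float(out) if out.ndim == 0 else out


def _sorted_profile(records: Sequence[SoilLayerRecord]) -> list[SoilLayerRecord]:
    recs = sorted(records, key=lambda r: r.depth_top)
    check_depth_tiling(recs)
    return recs


def profile_cumulative(records: Sequence[SoilLayerRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(cumulative soil mass, cumulative SOC stock) at each layer bottom.

    Mass in Mg ha^-1 (BD x thickness x 100), stock in Mg ha^-1; both start
    implicitly at (0, 0) at the surface.
    """
    recs = _sorted_profile(records)
    masses = np.array([r.bulk_density * r.thickness * _MASS_TO_MG_HA for r in recs])
    stocks = np.array([stock_fixed_depth(r.soc_content, r.bulk_density, r.thickness)
                       for r in recs])
    cum_mass = np.cumsum(masses)
    if np.any(np.diff(np.concatenate([[0.0], cum_mass])) <= 0):
        raise ValidationError("cumulative soil mass must be strictly increasing")
    return cum_mass, np.cumsum(stocks)


def stock_profile_fixed(records: Sequence[SoilLayerRecord]) -> CarbonStockProfile:
    """Fixed-depth stock profile for one treatment x replicate."""
    recs = _sorted_profile(records)
    stocks = np.array([stock_fixed_depth(r.soc_content, r.bulk_density, r.thickness)
                       for r in recs])
    return CarbonStockProfile(
        treatment=recs[0].treatment, replicate=recs[0].replicate,
        layer_stocks=stocks, cumulative_stock_0_50=float(stocks.sum()),
        method="fixed_depth",
    )


def reference_masses_lightest(profiles: Sequence[Sequence[SoilLayerRecord]]) -> np.ndarray:
    """Per-boundary minimum cumulative soil mass across profiles.

    Using the lightest profile as the reference guarantees every profile can
    be evaluated by interpolation, never extrapolation.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    cum_masses = []
    n_layers = None
    for prof in profiles:
        recs = _sorted_profile(prof)
        if n_layers is None:
            n_layers = len(recs)
            depths = [(r.depth_top, r.depth_bottom) for r in recs]
        elif len(recs) != n_layers or [(r.depth_top, r.depth_bottom) for r in recs] != depths:
            raise ValidationError("inconsistent layering across profiles")
        cum_masses.append(profile_cumulative(recs)[0])
    ref = np.min(np.vstack(cum_masses), axis=0)
    if np.any(np.diff(np.concatenate([[0.0], ref])) <= 0):
        raise ValidationError("reference masses must be strictly increasing")
    return ref


def cumulative_stock_at_mass(records: Sequence[SoilLayerRecord], reference_mass,
                             interpolation: str = "pchip"):
    """Cumulative SOC stock (Mg ha^-1) at given cumulative soil mass(es)."""
    cum_mass, cum_stock = profile_cumulative(records)
    ref = np.atleast_1d(np.asarray(reference_mass, dtype=float))
    if np.any(ref < 0):
        raise DomainError("reference masses must be >= 0")
    if np.any(ref > cum_mass[-1] + 1e-9):
        raise ExtrapolationError(
            f"reference mass {ref.max():.6g} Mg ha^-1 exceeds total profile mass "
            f"{cum_mass[-1]:.6g} Mg ha^-1"
        )
    xs = np.concatenate([[0.0], cum_mass])
    ys = np.concatenate([[0.0], cum_stock])
    if interpolation == "linear" or len(xs) < 3:
        out = np.interp(ref, xs, ys)
    elif interpolation == "pchip":
        out = PchipInterpolator(xs, ys)(ref)
    else:
        raise DomainError(f"unknown interpolation {interpolation!r}")
    out = np.clip(out, 0.0, None)
    return float(out[0]) if np.isscalar(reference_mass) or np.ndim(reference_mass) == 0 else out


def stock_equivalent_soil_mass(records: Sequence[SoilLayerRecord],
                               reference_masses,
                               interpolation: str = "pchip") -> CarbonStockProfile:
    """ESM stock profile: stocks between consecutive reference masses.

    The last reference mass defines the profile-total equivalent stock
    (the 0-50 cm-equivalent value when references span the full profile).
    """
    ref = np.asarray(reference_masses, dtype=float)
    if np.any(np.diff(np.concatenate([[0.0], ref])) <= 0):
        raise ValidationError("reference masses must be strictly increasing from 0")
    cum = cumulative_stock_at_mass(records, ref, interpolation=interpolation)
    cum = np.atleast_1d(cum)
    layer_stocks = np.diff(np.concatenate([[0.0], cum]))
    layer_stocks = np.clip(layer_stocks, 0.0, None)
    recs = _sorted_profile(records)
    return CarbonStockProfile(
        treatment=recs[0].treatment, replicate=recs[0].replicate,
        layer_stocks=layer_stocks, cumulative_stock_0_50=float(layer_stocks.sum()),
        method="equivalent_soil_mass",
    )


def recombine_aoc(fractions: AggregateFractionSet, aoc: AocRecord) -> float:
    """Mass-weighted whole-soil OC (g kg^-1) recombined from class AOC values.

    A consistency check linking aggregate-fraction carbon back to bulk SOC:
    the result always lies between the minimum and maximum class AOC.
    """
    w = fractions.proportions
    a = aoc.aoc_by_class
    if len(w) != len(a):
        raise ValidationError("fraction and AOC class counts must match")
    if w.sum() <= 0:
        raise DomainError("all proportions are zero")
    return float(np.dot(w, a) / w.sum())
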