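"""Wet-sieve aggregate-stability indices: MWD, GMD and fractal dimension.

Mean weight diameter (MWD) is the mass-weighted arithmetic mean of class
mean diameters; geometric mean diameter (GMD) the mass-weighted geometric
mean (the log base cancels between numerator and denominator, so natural
logs are used). The fractal dimension D comes from the power-law cumulative
mass-size relation

    w(<= d_i) / w0 = (d_i / d_max) ** (3 - D),

fitted as an ordinary least-squares regression of log10(cumulative mass
ratio) on log10(d_i / d_max), not forced through the origin; D = 3 - slope.
Points with zero cumulative ratio are dropped (log undefined); the
largest-class point, where the ratio is 1 and the log is 0, is kept.

Edge classes have no measured mean diameter, so the conventional midpoints
are used: the open top class (>2 mm) takes (2 + top_cap)/2 where the cap
defaults to 5 mm (samples are pre-broken to < 1 cm so a 5 mm cap is a
realistic ceiling for the largest sieved aggregates); the open bottom class
(<0.053 mm) takes 0.053/2.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sstats

from .errors import DomainError, ValidationError
from .io import CLASS_BOUNDS, AggregateFractionSet, StabilityIndices

DEFAULT_TOP_CAP = 5.0  # mm


def class_mean_diameters(class_bounds=CLASS_BOUNDS, top_cap: float = DEFAULT_TOP_CAP) -> np.ndarray:
    """Mean diameter (mm) of each sieve class in canonical order.

    Interior classes use the arithmetic midpoint of their bounds; the open
    top class uses (lower_bound + top_cap)/2, the open bottom class half its
    upper bound.
    """
    lo0, hi0 = class_bounds[0]
    if lo0 is None or hi0 is not None:
        raise ValidationError(
            "class bounds must be in canonical decreasing order (open top class first)"
        )
    if top_cap <= lo0:
        raise DomainError(
            f"top_cap must exceed the top-class lower bound {lo0} mm, got {top_cap}"
        )
    diams = []
    for lo, hi in class_bounds:
        if lo is not None and hi is not None:
            diams.append((lo + hi) / 2.0)
        elif hi is None:  # open top
            diams.append((lo + top_cap) / 2.0)
        else:  # open bottom
            diams.append(hi / 2.0)
    d = np.array(diams, dtype=float)
    if np.any(np.diff(d) >= 0):
        raise ValidationError("class bounds must be in canonical decreasing order")
    return d


def _diameters(fractions: AggregateFractionSet, top_cap: float) -> np.ndarray:
    if fractions.class_mean_diameters is not None:
        return fractions.class_mean_diameters
    return class_mean_diameters(top_cap=top_cap)


def compute_mwd(fractions: AggregateFractionSet, top_cap: float = DEFAULT_TOP_CAP) -> float:
    """Mean weight diameter, mm: sum_i X_i W_i over the four classes."""
    w = fractions.proportions
    if w.sum() <= 0:
        raise DomainError("all proportions are zero")
    x = _diameters(fractions, top_cap)
    return float(np.dot(x, w))


def compute_gmd(fractions: AggregateFractionSet, top_cap: float = DEFAULT_TOP_CAP) -> float:
    """Geometric mean diameter, mm: exp(sum W_i ln X_i / sum W_i)."""
    w = fractions.proportions
    if w.sum() <= 0:
        raise DomainError("all proportions are zero")
    x = _diameters(fractions, top_cap)
    if np.any(x <= 0):
        raise DomainError("class mean diameters must be > 0")
    return float(np.exp(np.dot(w, np.log(x)) / w.sum()))


def cumulative_mass_ratios(fractions: AggregateFractionSet,
                           top_cap: float = DEFAULT_TOP_CAP) -> tuple[np.ndarray, np.ndarray]:
    """(class mean diameters, cumulative mass ratio w(<= d_i)/w0) per class.

    The ratio at class i accumulates the proportions of class i and all
    smaller classes, so it is 1 at the largest occupied class.
    """
    x = _diameters(fractions, top_cap)
    w = fractions.proportions
    cum = np.cumsum(w[::-1])[::-1]  # from smallest class upward
    return x, cum


def compute_fractal_dimension(fractions: AggregateFractionSet,
                              d_max: float | None = None,
                              top_cap: float = DEFAULT_TOP_CAP,
                              diameters: str = "class_mean") -> tuple[float, float]:
    """Fractal dimension D of the aggregate size distribution and fit r^2.

    Parameters
    ----------
    d_max
        Diameter of the largest aggregate, mm. Defaults to ``top_cap``
        (the per-sample maximum is not measured by wet sieving).
    diameters
        ``"class_mean"`` regresses at class mean diameters (default);
        ``"sieve_opening"`` uses the sieve mesh sizes, where the cumulative
        mass below each opening excludes the retained class.

    Returns
    -------
    (D, r2) with D = 3 - slope of the log-log OLS fit.
    """
    if d_max is None:
        d_max = top_cap
    if d_max <= 0:
        raise DomainError(f"d_max must be > 0, got {d_max}")
    if diameters == "class_mean":
        x, cum = cumulative_mass_ratios(fractions, top_cap)
    elif diameters == "sieve_opening":
        openings = np.array([lo for lo, _ in CLASS_BOUNDS if lo is not None], dtype=float)
        w = fractions.proportions
        # mass strictly below each opening
        cum = np.array([w[i + 1:].sum() for i in range(len(openings))])
        x = openings
    else:
        raise DomainError(f"unknown diameters mode {diameters!r}")
    keep = cum > 0
    x, cum = x[keep], cum[keep]
    if len(x) < 2:
        raise DomainError("insufficient points: need >= 2 classes with positive cumulative mass")
    lx = np.log10(x / d_max)
    ly = np.log10(cum)
    fit = _sstats.linregress(lx, ly)
    return 3.0 - float(fit.slope), float(fit.rvalue) ** 2


def compute_indices(fractions: AggregateFractionSet,
                    d_max: float | None = None,
                    top_cap: float = DEFAULT_TOP_CAP) -> StabilityIndices:
    """All three stability indices for one fraction set."""
    mwd = compute_mwd(fractions, top_cap)
    gmd = compute_gmd(fractions, top_cap)
    d, r2 = compute_fractal_dimension(fractions, d_max=d_max, top_cap=top_cap)
    return StabilityIndices(mwd=mwd, gmd=gmd, fractal_d=d, fit_r2=r2)
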