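"""Z-score standardization and the composite soil-functional-quality score.

Four indicators enter the composite: bulk density BD (physical compactness,
a negative indicator — lower is better), soil water content SWC, mean
weight diameter MWD (aggregate stability) and SOC stock SOCs. Within each
depth layer every indicator is standardized to z = (x - mean)/SD over all
replicate-level observations of all treatments, multiplied by its polarity
(-1 for BD), and the four polarized z-scores are summed with equal weights
into a per-observation total. The treatment with the highest mean total is
ranked best.

Standardization pools replicate values rather than treatment means so that
per-treatment dispersion of the composite is defined; a ``pool="means"``
mode standardizes treatment means instead. Sample (n-1) SD is the default;
population SD is available. Because z-scores are invariant to positive
affine transforms, the composite does not depend on indicator units.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import ZScoreTable

DEFAULT_POLARITY: dict[str, int] = {"BD": -1, "SWC": 1, "MWD": 1, "SOCs": 1}


class ConstantInputWarning(UserWarning):
    """All values identical: z-scores are defined as 0."""


def zscore(values, sd_mode: str = "sample") -> np.ndarray:
    """Standardize a collection to mean 0, SD 1.

    ``sd_mode`` selects the sample (n-1, default) or population (n)
    standard deviation. A constant input yields all zeros and emits
    :class:`ConstantInputWarning`.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError(f"zscore needs >= 2 values, got {x.size}")
    if sd_mode == "sample":
        ddof = 1
    elif sd_mode == "population":
        ddof = 0
    else:
        raise DomainError(f"unknown sd_mode {sd_mode!r}")
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("constant input: z-scores set to 0", ConstantInputWarning,
                      stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def composite_score(observations: pd.DataFrame,
                    polarity: dict[str, int] | None = None,
                    sd_mode: str = "sample",
                    pool: str = "replicates") -> ZScoreTable:
    """Build the composite soil-functional-quality table.

    Parameters
    ----------
    observations
        Tidy frame with columns ``layer``, ``treatment``, ``replicate`` and
        one numeric column per indicator named in ``polarity``.
    polarity
        indicator -> +1/-1; defaults to BD negative, SWC/MWD/SOCs positive.
    pool
        ``"replicates"`` standardizes replicate-level values within each
        layer (default); ``"means"`` standardizes treatment means.
    """
    polarity = dict(DEFAULT_POLARITY if polarity is None else polarity)
    indicators = list(polarity)
    for col in ("layer", "treatment", "replicate"):
        if col not in observations.columns:
            raise ValidationError(f"observations missing column {col!r}")
    for ind in indicators:
        if ind not in observations.columns:
            raise ValidationError(f"observations missing indicator column {ind!r}")
    obs = observations.copy()
    if pool == "means":
        obs = (obs.groupby(["layer", "treatment"], sort=False)[indicators]
                  .mean().reset_index())
        obs["replicate"] = 1
    elif pool != "replicates":
        raise DomainError(f"unknown pool mode {pool!r}")

    for ind in indicators:
        missing = obs[obs[ind].isna()]
        if not missing.empty:
            row = missing.iloc[0]
            raise ValidationError(
                f"missing indicator {ind!r} for layer={row['layer']} "
                f"treatment={row['treatment']}"
            )

    score_rows = []
    for layer, grp in obs.groupby("layer", sort=False):
        for ind in indicators:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConstantInputWarning)
                z = zscore(grp[ind].to_numpy(), sd_mode=sd_mode)
            for (_, row), zval in zip(grp.iterrows(), z):
                score_rows.append({
                    "layer": layer, "treatment": row["treatment"],
                    "replicate": row["replicate"], "indicator": ind,
                    "z": polarity[ind] * zval,
                })
    scores = pd.DataFrame(score_rows)
    totals = (scores.groupby(["layer", "treatment", "replicate"], sort=False)["z"]
                    .sum().reset_index().rename(columns={"z": "total_z"}))
    return ZScoreTable(scores=scores, totals=totals, indicator_polarity=polarity)


class TreatmentRanking(NamedTuple):
    table: pd.DataFrame  # treatment, mean_total, sd_total, rank
    tied: bool


def rank_treatments(table: ZScoreTable) -> TreatmentRanking:
    """Order treatments by overall mean total z, best first.

    The overall score of a replicate is the sum of its per-layer totals;
    treatments are ranked by the replicate mean. Exact ties are broken
    alphabetically and flagged.
    """
    if table.totals.empty:
        raise ValidationError("empty z-score table")
    overall = (table.totals.groupby(["treatment", "replicate"])["total_z"].sum()
                    .groupby("treatment").agg(["mean", "std"])
                    .rename(columns={"mean": "mean_total", "std": "sd_total"})
                    .reset_index())
    overall = overall.sort_values(["mean_total", "treatment"],
                                  ascending=[False, True], kind="mergesort")
    overall["rank"] = np.arange(1, len(overall) + 1)
    tied = bool(overall["mean_total"].duplicated().any())
    return TreatmentRanking(table=overall.reset_index(drop=True), tied=tied)


class QuadraticFit(NamedTuple):
    a: float
    b: float
    c: float
    r2: float
    opens_downward: bool


def quadratic_fit(z_totals, yields) -> QuadraticFit:
    """OLS quadratic y = a z^2 + b z + c relating yield to composite score.

    ``opens_downward`` reports a < 0 (the parabola has an interior optimum,
    i.e. yield peaks at an intermediate soil-quality score).
    """
    z = np.asarray(z_totals, dtype=float)
    y = np.asarray(yields, dtype=float)
    if z.shape != y.shape:
        raise ValidationError("z_totals and yields must have equal length")
    if len(np.unique(z)) < 3:
        raise DomainError("quadratic fit needs >= 3 distinct score values")
    # polynomial.Polynomial.fit returns coefficients in a scaled domain;
    # convert back so a, b, c are in the raw variable
    coeffs = np.polynomial.polynomial.polyfit(z, y, 2)
    c, b, a = (float(v) for v in coeffs)
    pred = a * z**2 + b * z + c
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # curvature below numerical noise (exactly collinear data) counts as flat
    tol = 1e-10 * max(1.0, abs(b), abs(c))
    return QuadraticFit(a=a, b=b, c=c, r2=r2, opens_downward=a < -tol)
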