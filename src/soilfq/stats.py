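"""Inferential layer: one-way ANOVA with Duncan's multiple range test and
compact letter display, percent contrasts, Pearson correlation matrices
with star coding, and random-forest variable importance.

Duncan's new multiple range test compares ordered group means with
span-dependent least significant ranges

    LSR_p = q_{alpha_p}(p, df) * sqrt(MSE / n_h),    alpha_p = 1 - (1 - alpha)^(p-1),

where q is the upper studentized-range quantile at Duncan's protection
level for a span of p means and n_h is the (harmonic mean) group size.
Testing proceeds from the widest range inward; a range contained in a
non-significant wider range is itself declared non-significant, which makes
the non-significant relation a union of contiguous intervals of the ordered
means — each maximal interval receives one letter. No published critical-
value tables are used: quantiles come from numerical inversion of the
studentized-range distribution.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .errors import DomainError, ValidationError


class AnovaResult(NamedTuple):
    F: float
    p: float
    df_between: int
    df_within: int
    mse: float


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from the sums-of-squares decomposition."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise DomainError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in gs):
        raise DomainError("every group needs >= 2 values")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = len(all_vals) - len(gs)
    ms_b = ss_between / df_b
    mse = ss_within / df_w
    if mse == 0:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / mse
        p = float(sstats.f.sf(f, df_b, df_w))
    return AnovaResult(F=float(f), p=p, df_between=df_b, df_within=df_w, mse=float(mse))


def duncan_lsr(span: int, df_within: int, mse: float, n_harmonic: float,
               alpha: float = 0.05) -> float:
    """Least significant range for a span of ``span`` ordered means."""
    if span < 2:
        raise DomainError("span must be >= 2")
    protection = 1.0 - (1.0 - alpha) ** (span - 1)
    q = sstats.studentized_range.isf(protection, span, df_within)
    return float(q * np.sqrt(mse / n_harmonic))


def _significant_ranges(means: np.ndarray, lsrs: dict[int, float]) -> np.ndarray:
    """Boolean matrix sig[i, j] for ordered means (descending), i < j.

    Applies Duncan's containment rule: a range is significant only if its
    difference exceeds the LSR for its span AND every containing range is
    significant.
    """
    k = len(means)
    sig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):  # widest first
        for i in range(0, k - span + 1):
            j = i + span - 1
            exceeds = (means[i] - means[j]) >= lsrs[span]
            contained_ok = True
            if span < k:
                if i > 0 and not sig[i - 1, j]:
                    contained_ok = False
                if j < k - 1 and not sig[i, j + 1]:
                    contained_ok = False
            sig[i, j] = exceeds and contained_ok
    return sig


def _letters_from_ranges(sig: np.ndarray) -> list[str]:
    """Compact letter display from the significance matrix of ordered means."""
    k = sig.shape[0]
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # keep maximal intervals only
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    maximal = sorted(set(maximal))
    letters = [""] * k
    for idx, (lo, hi) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for g in range(lo, hi + 1):
            letters[g] += ch
    return letters


def duncan_mrt(groups: dict[str, Sequence[float]], alpha: float = 0.05,
               mse: float | None = None, df_within: int | None = None) -> pd.DataFrame:
    """Duncan letters for named groups.

    Returns a frame with columns ``group``, ``mean``, ``n``, ``letters``,
    sorted by mean descending; groups sharing a letter are not
    significantly different at level ``alpha``. MSE and its df default to
    the one-way ANOVA of the groups themselves. Unbalanced designs use the
    harmonic mean group size.
    """
    if len(groups) < 2:
        raise DomainError("Duncan's test needs >= 2 groups")
    names = list(groups)
    arrays = {name: np.asarray(groups[name], dtype=float) for name in names}
    if mse is None or df_within is None:
        res = anova_oneway(list(arrays.values()))
        mse = res.mse if mse is None else mse
        df_within = res.df_within if df_within is None else df_within
    ns = np.array([len(arrays[name]) for name in names], dtype=float)
    n_h = len(ns) / np.sum(1.0 / ns)
    order = sorted(names, key=lambda nm: -arrays[nm].mean())
    means = np.array([arrays[nm].mean() for nm in order])
    if mse == 0:
        lsrs = {span: 0.0 for span in range(2, len(order) + 1)}
        sig = np.zeros((len(order), len(order)), dtype=bool)
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                sig[i, j] = means[i] > means[j]
    else:
        lsrs = {span: duncan_lsr(span, df_within, mse, n_h, alpha)
                for span in range(2, len(order) + 1)}
        sig = _significant_ranges(means, lsrs)
    letters = _letters_from_ranges(sig)
    return pd.DataFrame({
        "group": order, "mean": means,
        "n": [len(arrays[nm]) for nm in order], "letters": letters,
    })


def percent_contrast(reference: float, comparison: float) -> float:
    """Percent change of ``comparison`` over ``reference``, half-up to 1 dp."""
    if reference <= 0:
        raise DomainError(f"reference must be > 0, got {reference}")
    pct = 100.0 * (float(comparison) - float(reference)) / float(reference)
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def star_code(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class CorrelationResult(NamedTuple):
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    constant_variables: list[str]


def correlation_matrix(table: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    Variables with zero variance are flagged and their pairs left NaN.
    Requires >= 3 complete observations per pair; the diagonal is r = 1.
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    constant = [c for c in cols if table[c].nunique(dropna=True) <= 1]
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise DomainError(
                    f"need >= 3 complete observations for pair ({cols[i]}, {cols[j]})"
                )
            if cols[i] in constant or cols[j] in constant:
                continue
            res = sstats.pearsonr(pair[cols[i]], pair[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    stars = pd.DataFrame(
        [["" if np.isnan(pv) else star_code(pv) for pv in row] for row in p],
        index=cols, columns=cols,
    )
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        stars=stars, constant_variables=constant,
    )


class ImportanceResult(NamedTuple):
    importances: pd.DataFrame  # feature, importance, rank
    r2_oob: float


def variable_importance(features: pd.DataFrame, response,
                        seed: int = 0, n_estimators: int = 300,
                        n_repeats: int = 10) -> ImportanceResult:
    """Permutation importance of predictors from a random-forest regression.

    The contract is ordinal: only the ranking of predictors is meaningful,
    not the score magnitudes. The out-of-bag R^2 summarizes explained
    variance. Requires >= 10 observations and a non-constant response.
    """
    y = np.asarray(response, dtype=float)
    if len(features) != len(y):
        raise ValidationError("features and response must have equal length")
    if len(y) < 10:
        raise DomainError(f"variable importance needs >= 10 observations, got {len(y)}")
    if np.all(y == y[0]):
        raise DomainError("response is constant")
    rf = RandomForestRegressor(n_estimators=n_estimators, oob_score=True,
                               random_state=seed, n_jobs=1)
    rf.fit(features.to_numpy(), y)
    perm = permutation_importance(rf, features.to_numpy(), y,
                                  n_repeats=n_repeats, random_state=seed, n_jobs=1)
    out = pd.DataFrame({
        "feature": list(features.columns),
        "importance": perm.importances_mean,
    }).sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return ImportanceResult(importances=out, r2_oob=float(rf.oob_score_))
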