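"""End-to-end analysis pipeline: measurements -> indices -> stocks ->
composite score -> inferential statistics, with plain-CSV stage outputs and
one machine-readable JSON summary.

The stage order follows the field workflow: fill porosity, compute
aggregate-stability indices per sample, build SOC stocks (fixed-depth and
equivalent-soil-mass), assemble the four composite indicators (BD, SWC,
MWD, per-layer ESM SOC stock), standardize and rank treatments, then run
the inferential layer (ANOVA + Duncan letters, yield percent contrasts,
correlations, random-forest importance). All stage outputs are plain CSV;
the summary records package versions, the seed and a config hash so a rerun
with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, aggregates, carbon, physical, scoring, stats
from .errors import SoilFQError, ValidationError
from .io import (
    AggregateFractionSet,
    SoilLayerRecord,
    YieldRecord,
    read_config,
    read_soil_table,
    records_to_frame,
    write_results,
)
from .simulate import default_paper_like_design, generate_experiment, with_seed

logger = logging.getLogger("soilfq")


class PipelineError(SoilFQError):
    """A pipeline stage failed; the message names the stage."""


def indices_table(fractions: Sequence[AggregateFractionSet],
                  top_cap: float = aggregates.DEFAULT_TOP_CAP,
                  d_max: float | None = None) -> pd.DataFrame:
    """Stability indices for every fraction set, as a tidy frame."""
    rows = []
    for f in fractions:
        idx = aggregates.compute_indices(f, d_max=d_max, top_cap=top_cap)
        rows.append({
            "treatment": f.treatment, "replicate": f.replicate,
            "depth_top": f.depth_top, "depth_bottom": f.depth_bottom,
            "mwd": idx.mwd, "gmd": idx.gmd,
            "fractal_d": idx.fractal_d, "fit_r2": idx.fit_r2,
        })
    return pd.DataFrame(rows)


def _profiles(soil: Sequence[SoilLayerRecord]) -> dict[tuple[str, int], list[SoilLayerRecord]]:
    out: dict[tuple[str, int], list[SoilLayerRecord]] = {}
    for r in soil:
        out.setdefault((r.treatment, r.replicate), []).append(r)
    return {k: sorted(v, key=lambda r: r.depth_top) for k, v in out.items()}


def stocks_table(soil: Sequence[SoilLayerRecord],
                 interpolation: str = "pchip") -> pd.DataFrame:
    """Fixed-depth and ESM SOC stocks per treatment x replicate x layer.

    ESM stocks are evaluated at the lightest profile's cumulative masses.
    """
    profiles = _profiles(soil)
    ref = carbon.reference_masses_lightest(list(profiles.values()))
    rows = []
    for (t, rep), recs in profiles.items():
        fixed = carbon.stock_profile_fixed(recs)
        esm = carbon.stock_equivalent_soil_mass(recs, ref, interpolation=interpolation)
        for i, r in enumerate(recs):
            rows.append({
                "treatment": t, "replicate": rep,
                "depth_top": r.depth_top, "depth_bottom": r.depth_bottom,
                "stock_fixed": fixed.layer_stocks[i],
                "stock_esm": esm.layer_stocks[i],
                "cumulative_fixed": float(fixed.layer_stocks[: i + 1].sum()),
                "cumulative_esm": float(esm.layer_stocks[: i + 1].sum()),
            })
    return pd.DataFrame(rows)


def composite_observations(soil: Sequence[SoilLayerRecord],
                           fractions: Sequence[AggregateFractionSet],
                           stocks: pd.DataFrame,
                           stock_method: str = "esm",
                           top_cap: float = aggregates.DEFAULT_TOP_CAP) -> pd.DataFrame:
    """Assemble the four composite indicators per (layer, treatment, replicate).

    SOCs is the per-layer stock of the chosen method (``"esm"`` default,
    ``"fixed"`` available).
    """
    mwd = {(f.treatment, f.replicate, f.depth_top): aggregates.compute_mwd(f, top_cap)
           for f in fractions}
    stock_col = {"esm": "stock_esm", "fixed": "stock_fixed"}[stock_method]
    stock = {(r["treatment"], int(r["replicate"]), r["depth_top"]): r[stock_col]
             for _, r in stocks.iterrows()}
    rows = []
    for r in soil:
        key = (r.treatment, r.replicate, r.depth_top)
        if key not in mwd:
            raise ValidationError(
                f"missing indicator 'MWD' for layer={r.depth_top}-{r.depth_bottom} "
                f"treatment={r.treatment}"
            )
        if key not in stock:
            raise ValidationError(
                f"missing indicator 'SOCs' for layer={r.depth_top}-{r.depth_bottom} "
                f"treatment={r.treatment}"
            )
        rows.append({
            "layer": f"{r.depth_top:g}-{r.depth_bottom:g}",
            "treatment": r.treatment, "replicate": r.replicate,
            "BD": r.bulk_density, "SWC": r.water_content,
            "MWD": mwd[key], "SOCs": stock[key],
        })
    return pd.DataFrame(rows)


def yield_contrasts(yields: Sequence[YieldRecord]) -> pd.DataFrame:
    """Pairwise percent contrasts of treatment means per yield component."""
    df = records_to_frame(list(yields))
    comps = ["ear_number", "ear_grain_number", "thousand_grain_weight", "grain_yield"]
    means = df.groupby("treatment")[comps].mean()
    rows = []
    for comp in comps:
        for t_ref in means.index:
            for t_cmp in means.index:
                if t_ref == t_cmp:
                    continue
                rows.append({
                    "component": comp, "reference": t_ref, "comparison": t_cmp,
                    "percent_change": stats.percent_contrast(
                        means.loc[t_ref, comp], means.loc[t_cmp, comp]),
                })
    return pd.DataFrame(rows)


def anova_letters_table(obs: pd.DataFrame, value_cols: Sequence[str],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-layer one-way ANOVA across treatments with Duncan letters."""
    rows = []
    for layer, grp in obs.groupby("layer", sort=False):
        for col in value_cols:
            groups = {t: g[col].to_numpy() for t, g in grp.groupby("treatment")}
            res = stats.anova_oneway(list(groups.values()))
            letters = stats.duncan_mrt(groups, alpha=alpha,
                                       mse=res.mse, df_within=res.df_within)
            for _, lrow in letters.iterrows():
                rows.append({
                    "layer": layer, "variable": col, "treatment": lrow["group"],
                    "mean": lrow["mean"], "letters": lrow["letters"],
                    "F": res.F, "p": res.p,
                })
    return pd.DataFrame(rows)


def _load_inputs(cfg: dict, config_dir: Path, seed: int | None):
    if "simulate" in cfg:
        sim_cfg = cfg["simulate"] or {}
        design = default_paper_like_design()
        use_seed = seed if seed is not None else int(sim_cfg.get("seed", design.seed))
        design = with_seed(design, use_seed)
        if "n_replicates" in sim_cfg:
            design.n_replicates = int(sim_cfg["n_replicates"])
        exp = generate_experiment(design)
        return exp.soil, exp.fractions, exp.aoc, exp.yields, use_seed
    if "inputs" in cfg:
        paths = cfg["inputs"]
        def _p(key):
            return config_dir / paths[key] if not Path(paths[key]).is_absolute() else Path(paths[key])
        soil = read_soil_table(_p("soil"), "soil")
        fractions = read_soil_table(_p("fractions"), "fractions")
        aoc = read_soil_table(_p("aoc"), "aoc") if "aoc" in paths else []
        yields = read_soil_table(_p("yield"), "yield") if "yield" in paths else []
        return soil, fractions, aoc, yields, seed
    raise ValidationError("config must contain a 'simulate' or an 'inputs' section")


def run_pipeline(config_path, outdir, seed: int | None = None) -> dict:
    """Run every stage on the configured dataset; returns the summary dict.

    Writes indices.csv, stocks.csv, zscores.csv, totals.csv, ranking.csv,
    anova_letters.csv, correlations.csv, importance.csv, contrasts.csv (when
    a yield table exists) and summary.json into ``outdir``. On any stage
    failure the partial outputs are removed and a :class:`PipelineError`
    naming the stage is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "config"

    def _write(df, name):
        path = outdir / name
        write_results(df, path)
        written.append(path)

    try:
        cfg = read_config(config_path)
        top_cap = float(cfg.get("top_cap", aggregates.DEFAULT_TOP_CAP))
        interpolation = cfg.get("interpolation", "pchip")

        stage = "load"
        soil, fractions, aoc, yields, used_seed = _load_inputs(
            cfg, Path(config_path).parent, seed)

        stage = "physical"
        physical.add_porosity(soil)
        _write(records_to_frame(soil), "soil.csv")

        stage = "indices"
        idx = indices_table(fractions, top_cap=top_cap)
        _write(idx, "indices.csv")

        stage = "stocks"
        stocks = stocks_table(soil, interpolation=interpolation)
        _write(stocks, "stocks.csv")

        stage = "scoring"
        obs = composite_observations(soil, fractions, stocks, top_cap=top_cap)
        ztab = scoring.composite_score(obs)
        _write(ztab.scores, "zscores.csv")
        _write(ztab.totals, "totals.csv")
        ranking = scoring.rank_treatments(ztab)
        _write(ranking.table, "ranking.csv")

        stage = "stats"
        letters = anova_letters_table(obs, ["BD", "SWC", "MWD", "SOCs"])
        _write(letters, "anova_letters.csv")
        soil_df = records_to_frame(soil)
        corr_vars = obs.merge(
            soil_df.assign(layer=lambda d: d.apply(
                lambda r: f"{r.depth_top:g}-{r.depth_bottom:g}", axis=1))
            [["layer", "treatment", "replicate", "soc_content", "porosity"]],
            on=["layer", "treatment", "replicate"])
        corr = stats.correlation_matrix(
            corr_vars[["BD", "SWC", "MWD", "SOCs", "soc_content", "porosity"]])
        _write(corr.r.round(6).reset_index().rename(columns={"index": "variable"}),
               "correlations.csv")
        imp_seed = used_seed if used_seed is not None else 0
        imp = stats.variable_importance(
            corr_vars[["BD", "SWC", "MWD", "soc_content", "porosity"]],
            corr_vars["SOCs"], seed=imp_seed)
        _write(imp.importances, "importance.csv")

        contrasts_rows = None
        if yields:
            stage = "contrasts"
            contrasts = yield_contrasts(yields)
            _write(contrasts, "contrasts.csv")
            contrasts_rows = contrasts.to_dict(orient="records")

        stage = "summary"
        with open(config_path, "rb") as fh:
            config_hash = hashlib.sha256(fh.read()).hexdigest()
        summary = {
            "soilfq_version": __version__,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "seed": used_seed,
            "config_sha256": config_hash,
            "n_soil_records": len(soil),
            "ranking": [
                {"treatment": r["treatment"], "mean_total": round(r["mean_total"], 10),
                 "rank": int(r["rank"])}
                for _, r in ranking.table.iterrows()
            ],
            "importance_r2_oob": round(imp.r2_oob, 10),
            "contrasts": contrasts_rows,
        }
        path = outdir / "summary.json"
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
        logger.info("pipeline complete: %d outputs in %s", len(written), outdir)
        return summary
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
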