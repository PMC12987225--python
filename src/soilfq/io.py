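"""Domain types and tidy-CSV readers/writers for tillage soil datasets.

The package works on layered soil observations from a replicated tillage
trial: each record is one treatment x replicate x depth-interval
measurement. Tables are plain CSV (UTF-8, "." decimal separator) with
canonical snake_case headers; common header variants are accepted through
an alias map and unknown extra columns are carried through untouched.

Aggregate size classes are fixed in the canonical wet-sieve order
(largest first): >2 mm, 2-0.25 mm, 0.25-0.053 mm, <0.053 mm.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger("soilfq")

#: Reference soil particle density, g cm^-3 (quartz-dominated mineral soils).
PARTICLE_DENSITY = 2.65

#: Wet-sieve diameter classes in canonical order, mm. ``None`` marks an
#: open end (no upper bound for the top class, no lower bound for the bottom).
CLASS_BOUNDS: tuple[tuple[float | None, float | None], ...] = (
    (2.0, None),
    (0.25, 2.0),
    (0.053, 0.25),
    (None, 0.053),
)

CLASS_LABELS = (">2", "2-0.25", "0.25-0.053", "<0.053")

#: Mass-balance tolerance for wet-sieve proportions: sums within this of 1
#: are silently renormalized (sieve recovery loss), larger deviations error.
PROPORTION_SUM_TOL = 1e-3


def setup_logging(verbose: bool = False) -> None:
    """Configure structured logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.WARNING)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SoilLayerRecord:
    """One treatment x replicate x depth observation of soil physical state.

    Depth is encoded as two numeric bounds in cm, 0-based from the surface,
    half-open [top, bottom). Water content is gravimetric percent unless the
    table declares otherwise (the basis is metadata; no conversion is done).
    """

    treatment: str
    replicate: int
    depth_top: float
    depth_bottom: float
    bulk_density: float  # g cm^-3
    water_content: float  # %
    soc_content: float  # g kg^-1
    porosity: float | None = None  # %, derived

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if not self.depth_top < self.depth_bottom:
            raise ValidationError(
                f"depth_top ({self.depth_top}) must be < depth_bottom ({self.depth_bottom})"
            )
        if not 0 < self.bulk_density < PARTICLE_DENSITY:
            raise ValidationError(
                f"bulk_density must lie in (0, {PARTICLE_DENSITY}), got {self.bulk_density}"
            )
        if self.water_content < 0:
            raise ValidationError(f"water_content must be >= 0, got {self.water_content}")
        if self.soc_content < 0:
            raise ValidationError(f"soc_content must be >= 0, got {self.soc_content}")

    @property
    def thickness(self) -> float:
        return self.depth_bottom - self.depth_top


@dataclass
class AggregateFractionSet:
    """Four wet-sieve mass proportions for one soil sample.

    Proportions are stored in canonical class order (largest first) and
    renormalized to sum to 1 when the raw sum deviates by no more than
    ``PROPORTION_SUM_TOL`` (wet sieving never recovers mass exactly).
    """

    treatment: str
    replicate: int
    depth_top: float
    depth_bottom: float
    proportions: np.ndarray
    class_mean_diameters: np.ndarray | None = None  # mm; filled by aggregates module

    def __post_init__(self) -> None:
        w = np.asarray(self.proportions, dtype=float)
        if w.shape != (len(CLASS_BOUNDS),):
            raise ValidationError(
                f"proportions must have {len(CLASS_BOUNDS)} entries, got shape {w.shape}"
            )
        if np.any(w < 0):
            raise ValidationError("proportions must be >= 0")
        total = w.sum()
        if total <= 0:
            raise ValidationError("proportions sum to 0; at least one class must hold mass")
        if abs(total - 1.0) > PROPORTION_SUM_TOL:
            raise ValidationError(
                f"proportions sum to {total:.6g}; outside mass-balance tolerance "
                f"{PROPORTION_SUM_TOL} of 1"
            )
        self.proportions = w / total
        if self.class_mean_diameters is not None:
            d = np.asarray(self.class_mean_diameters, dtype=float)
            if d.shape != w.shape:
                raise ValidationError("class_mean_diameters length must match proportions")
            if np.any(np.diff(d) >= 0):
                raise ValidationError("class_mean_diameters must be strictly decreasing")
            self.class_mean_diameters = d


@dataclass
class StabilityIndices:
    """Aggregate-stability summary: MWD and GMD in mm, fractal dimension D."""

    mwd: float
    gmd: float
    fractal_d: float
    fit_r2: float

    def __post_init__(self) -> None:
        if not self.mwd > 0 or not self.gmd > 0:
            raise ValidationError("mwd and gmd must be > 0")
        if self.gmd > self.mwd + 1e-12:
            raise ValidationError(f"gmd ({self.gmd}) must be <= mwd ({self.mwd})")
        if not self.fractal_d < 3:
            raise ValidationError(f"fractal_d must be < 3, got {self.fractal_d}")


@dataclass
class AocRecord:
    """Organic-carbon concentration within each aggregate size class, g kg^-1."""

    treatment: str
    replicate: int
    depth_top: float
    depth_bottom: float
    aoc_by_class: np.ndarray  # order matches CLASS_BOUNDS

    def __post_init__(self) -> None:
        a = np.asarray(self.aoc_by_class, dtype=float)
        if a.shape != (len(CLASS_BOUNDS),):
            raise ValidationError(
                f"aoc_by_class must have {len(CLASS_BOUNDS)} entries, got shape {a.shape}"
            )
        if np.any(a < 0):
            raise ValidationError("aoc_by_class values must be >= 0")
        self.aoc_by_class = a


@dataclass
class CarbonStockProfile:
    """Per-layer and cumulative SOC stocks (Mg ha^-1) for one profile."""

    treatment: str
    replicate: int
    layer_stocks: np.ndarray
    cumulative_stock_0_50: float
    method: str  # "fixed_depth" | "equivalent_soil_mass"

    def __post_init__(self) -> None:
        s = np.asarray(self.layer_stocks, dtype=float)
        if np.any(s < 0):
            raise ValidationError("layer_stocks must be >= 0")
        if self.method not in ("fixed_depth", "equivalent_soil_mass"):
            raise ValidationError(f"unknown stock method {self.method!r}")
        if abs(s.sum() - self.cumulative_stock_0_50) > 1e-6 * max(1.0, abs(s.sum())):
            raise ValidationError("cumulative_stock_0_50 must equal the sum of layer_stocks")
        self.layer_stocks = s


@dataclass
class YieldRecord:
    """Plot-level wheat yield components; grain yield at 13% moisture."""

    treatment: str
    replicate: int
    ear_number: float  # 10^4 ha^-1
    ear_grain_number: float
    thousand_grain_weight: float  # g
    grain_yield: float  # kg ha^-1

    def __post_init__(self) -> None:
        for name in ("ear_number", "ear_grain_number", "thousand_grain_weight", "grain_yield"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class ZScoreTable:
    """Standardized indicator scores and composite totals.

    ``scores`` holds one row per (layer, treatment, replicate, indicator)
    with the polarity-adjusted z value; ``totals`` one row per
    (layer, treatment, replicate) with the equal-weight sum.
    """

    scores: pd.DataFrame
    totals: pd.DataFrame
    indicator_polarity: dict[str, int] = field(default_factory=dict)

    def treatment_summary(self) -> pd.DataFrame:
        """Mean +/- SD of total z per (layer, treatment), plus overall."""
        per_layer = (
            self.totals.groupby(["layer", "treatment"])["total_z"]
            .agg(["mean", "std"])
            .reset_index()
        )
        overall = (
            self.totals.groupby(["treatment", "replicate"])["total_z"]
            .sum()
            .groupby("treatment")
            .agg(["mean", "std"])
            .reset_index()
        )
        overall.insert(0, "layer", "overall")
        return pd.concat([per_layer, overall], ignore_index=True)


# ---------------------------------------------------------------------------
# table schemas
# ---------------------------------------------------------------------------

_PROP_COLS = [f"prop_{lbl}" for lbl in ("gt2", "2_025", "025_0053", "lt0053")]
_AOC_COLS = [f"aoc_{lbl}" for lbl in ("gt2", "2_025", "025_0053", "lt0053")]

#: canonical column -> accepted aliases (lower-cased comparison)
_ALIASES: dict[str, tuple[str, ...]] = {
    "treatment": ("treat", "tillage"),
    "replicate": ("rep", "block"),
    "depth_top": ("top", "upper_depth"),
    "depth_bottom": ("bottom", "lower_depth"),
    "bulk_density": ("bd",),
    "water_content": ("swc", "soil_water_content"),
    "soc_content": ("soc",),
    "porosity": ("sp", "soil_porosity"),
    "ear_number": ("ears",),
    "ear_grain_number": ("grains_per_ear", "ear_grains"),
    "thousand_grain_weight": ("tgw",),
    "grain_yield": ("yield",),
}

_SCHEMAS: dict[str, dict] = {
    "soil": {
        "required": [
            "treatment", "replicate", "depth_top", "depth_bottom",
            "bulk_density", "water_content", "soc_content",
        ],
        "optional": ["porosity"],
        "type": SoilLayerRecord,
    },
    "fractions": {
        "required": ["treatment", "replicate", "depth_top", "depth_bottom", *_PROP_COLS],
        "optional": [],
        "type": AggregateFractionSet,
    },
    "aoc": {
        "required": ["treatment", "replicate", "depth_top", "depth_bottom", *_AOC_COLS],
        "optional": [],
        "type": AocRecord,
    },
    "yield": {
        "required": [
            "treatment", "replicate", "ear_number", "ear_grain_number",
            "thousand_grain_weight", "grain_yield",
        ],
        "optional": [],
        "type": YieldRecord,
    },
}


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = col.strip().lower()
        for canonical, aliases in _ALIASES.items():
            if key == canonical or key in aliases:
                mapping[col] = canonical
                break
    return df.rename(columns=mapping)


def _numeric(df: pd.DataFrame, cols: Iterable[str],
             allow_missing: tuple[str, ...] = ()) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        if converted.isna().any() and col not in allow_missing:
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"missing value in column {col!r} at row {row}")
        df[col] = converted
    return df


def check_depth_tiling(records: Sequence, top: float = 0.0, bottom: float | None = None) -> None:
    """Require that each treatment x replicate profile tiles depth contiguously.

    Raises :class:`ValidationError` on overlapping or gapped intervals; if
    ``bottom`` is given the profile must end exactly there.
    """
    by_profile: dict[tuple, list] = {}
    for r in records:
        by_profile.setdefault((r.treatment, r.replicate), []).append(r)
    for key, recs in by_profile.items():
        recs = sorted(recs, key=lambda r: r.depth_top)
        cursor = top
        for r in recs:
            if r.depth_top < cursor - 1e-9:
                raise ValidationError(
                    f"overlapping depth intervals for treatment={key[0]} replicate={key[1]} "
                    f"at depth_top={r.depth_top}"
                )
            if r.depth_top > cursor + 1e-9:
                raise ValidationError(
                    f"gap in depth intervals for treatment={key[0]} replicate={key[1]} "
                    f"before depth_top={r.depth_top}"
                )
            cursor = r.depth_bottom
        if bottom is not None and abs(cursor - bottom) > 1e-9:
            raise ValidationError(
                f"profile for treatment={key[0]} replicate={key[1]} ends at {cursor} cm, "
                f"expected {bottom} cm"
            )


def read_soil_table(path, schema: str) -> list:
    """Read a tidy CSV into typed records.

    Parameters
    ----------
    path
        CSV file path.
    schema
        One of ``"soil"``, ``"fractions"``, ``"aoc"``, ``"yield"``.

    Returns
    -------
    list of the schema's record type, one per row, validated.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    spec = _SCHEMAS[schema]
    df = pd.read_csv(path)
    df = _canonicalize_columns(df)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing required column(s) {missing}")
    if df.empty:
        return []
    numeric_cols = [c for c in spec["required"] if c != "treatment"]
    optional_present = tuple(c for c in spec["optional"] if c in df.columns)
    df = _numeric(df.copy(), numeric_cols + list(optional_present),
                  allow_missing=optional_present)
    records = _frame_to_records(df, schema)
    if schema == "soil":
        check_depth_tiling(records)
    logger.debug("read %d %s records from %s", len(records), schema, path)
    return records


def _frame_to_records(df: pd.DataFrame, schema: str) -> list:
    out = []
    for _, row in df.iterrows():
        if schema == "soil":
            out.append(SoilLayerRecord(
                treatment=str(row["treatment"]), replicate=int(row["replicate"]),
                depth_top=float(row["depth_top"]), depth_bottom=float(row["depth_bottom"]),
                bulk_density=float(row["bulk_density"]),
                water_content=float(row["water_content"]),
                soc_content=float(row["soc_content"]),
                porosity=float(row["porosity"]) if "porosity" in row and pd.notna(row.get("porosity")) else None,
            ))
        elif schema == "fractions":
            out.append(AggregateFractionSet(
                treatment=str(row["treatment"]), replicate=int(row["replicate"]),
                depth_top=float(row["depth_top"]), depth_bottom=float(row["depth_bottom"]),
                proportions=np.array([row[c] for c in _PROP_COLS], dtype=float),
            ))
        elif schema == "aoc":
            out.append(AocRecord(
                treatment=str(row["treatment"]), replicate=int(row["replicate"]),
                depth_top=float(row["depth_top"]), depth_bottom=float(row["depth_bottom"]),
                aoc_by_class=np.array([row[c] for c in _AOC_COLS], dtype=float),
            ))
        elif schema == "yield":
            out.append(YieldRecord(
                treatment=str(row["treatment"]), replicate=int(row["replicate"]),
                ear_number=float(row["ear_number"]),
                ear_grain_number=float(row["ear_grain_number"]),
                thousand_grain_weight=float(row["thousand_grain_weight"]),
                grain_yield=float(row["grain_yield"]),
            ))
    return out


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten a homogeneous record collection into a tidy DataFrame."""
    if not records:
        return pd.DataFrame()
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValidationError(f"records must share one type, got {sorted(k.__name__ for k in kinds)}")
    kind = kinds.pop()
    rows = []
    for r in records:
        row = {}
        for f in dc_fields(r):
            v = getattr(r, f.name)
            if f.name == "proportions":
                row.update(dict(zip(_PROP_COLS, v)))
            elif f.name == "aoc_by_class":
                row.update(dict(zip(_AOC_COLS, v)))
            elif f.name == "layer_stocks":
                row.update({f"stock_layer{i + 1}": s for i, s in enumerate(v)})
            elif f.name == "class_mean_diameters":
                continue
            else:
                row[f.name] = v
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["record_type"] = kind.__name__
    return frame


def write_results(records, path) -> None:
    """Write a record collection (or DataFrame) to CSV.

    A round trip through :func:`read_soil_table` reproduces all fields at
    declared precision. An empty collection yields a header-only file when
    the schema is known, else an empty file.
    """
    if isinstance(records, ZScoreTable):
        df = records.scores
    elif isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(list(records))
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    logger.debug("wrote %d rows to %s", len(df), path)


def write_empty(schema: str, path) -> None:
    """Write a header-only CSV for a known schema."""
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    cols = _SCHEMAS[schema]["required"]
    pd.DataFrame(columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged fixture: printed yield-component table
# ---------------------------------------------------------------------------

#: Printed treatment means of the yield-component table
#: (ear number 10^4 ha^-1, grains per ear, thousand-grain weight g,
#: grain yield kg ha^-1 at 13% moisture).
TABLE1_MEANS: dict[str, dict[str, float]] = {
    "FNT": {"ear_number": 558.0, "ear_grain_number": 20.0,
            "thousand_grain_weight": 25.8, "grain_yield": 2985.0},
    "FST": {"ear_number": 608.0, "ear_grain_number": 22.0,
            "thousand_grain_weight": 26.8, "grain_yield": 3483.0},
    "FPT": {"ear_number": 584.0, "ear_grain_number": 20.0,
            "thousand_grain_weight": 27.5, "grain_yield": 3028.0},
}

#: Printed replicate standard deviations matching TABLE1_MEANS.
TABLE1_SDS: dict[str, dict[str, float]] = {
    "FNT": {"ear_number": 7.55, "ear_grain_number": 0.41,
            "thousand_grain_weight": 0.42, "grain_yield": 65.43},
    "FST": {"ear_number": 4.04, "ear_grain_number": 0.22,
            "thousand_grain_weight": 0.37, "grain_yield": 104.54},
    "FPT": {"ear_number": 6.66, "ear_grain_number": 0.35,
            "thousand_grain_weight": 0.81, "grain_yield": 26.00},
}

_TABLE1_FIXTURE = "table1_synthetic_replicates.csv"


def generate_table1_replicates() -> list[YieldRecord]:
    """Reconstruct synthetic replicate triplets from the printed mean +/- SD.

    The published table reports treatment means and SDs (n = 3), not the
    replicates themselves. The triplet (m - s, m, m + s) has sample mean m
    and sample standard deviation exactly s, so these synthetic replicates
    are moment-consistent with the printed summary. Reproduction checks use
    the printed means only.
    """
    records = []
    for treatment, means in TABLE1_MEANS.items():
        sds = TABLE1_SDS[treatment]
        for rep, k in enumerate((-1, 0, 1), start=1):
            records.append(YieldRecord(
                treatment=treatment, replicate=rep,
                **{name: round(means[name] + k * sds[name], 6) for name in means},
            ))
    return records


def load_table1() -> list[YieldRecord]:
    """Load the packaged yield-component fixture (9 synthetic replicates)."""
    with resources.files("soilfq.fixtures").joinpath(_TABLE1_FIXTURE).open() as fh:
        return read_soil_table(fh, schema="yield")


def read_config(path) -> dict:
    """Read a YAML configuration file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a mapping at top level")
    return cfg
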