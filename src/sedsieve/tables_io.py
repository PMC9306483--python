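"""Input tables: reading, validation, normalization, and descriptive QC.

All tables are plain :class:`pandas.DataFrame` objects with canonical column
names (see the ``*_COLUMNS`` constants).  CSV files are UTF-8, comma-separated,
``.`` decimal, with a required header row.

Censoring convention
--------------------
A concentration below the laboratory reporting limit is *censored*: it is
stored as ``c_sed_ug_kg = 0`` with ``censored = True`` and contributes zero to
every summation downstream.  Censored is distinct from *missing*: a
(site, chemical) pair with no row at all was not analyzed.  By default every
registry chemical is assumed to be on the analyte list at every site, so
absent pairs count as non-detections in detection frequencies.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 14 chemical classes used to aggregate results.
CHEM_CLASSES: tuple[str, ...] = (
    "antimicrobial disinfectants",
    "antioxidants",
    "detergent metabolites",
    "dyes and pigments",
    "fire retardants",
    "flavors and fragrances",
    "fuels",
    "herbicides",
    "insecticides",
    "nonprescription drugs",
    "PAHs",
    "plasticizers",
    "solvents",
    "sterols",
)

REGISTRY_COLUMNS = [
    "chemical_id",
    "name",
    "chem_class",
    "koc_L_kg",
    "mw_g_mol",
    "reporting_limit_ug_kg",
    "tef",
    "fcv_ug_gOC",
    "is_pah16",
    "is_esb_pah",
    "is_alkylphenol",
]
MEASUREMENT_COLUMNS = ["site_id", "chemical_id", "c_sed_ug_kg", "censored"]
SITE_COLUMNS = ["site_id", "toc_percent"]  # plus free-form attribute columns
BENCHMARK_COLUMNS = ["chemical_id", "medium", "value", "source", "effect_label"]
ACC_COLUMNS = [
    "chemical_id",
    "endpoint_id",
    "acc_value",
    "acc_unit",
    "gene_symbol",
    "excluded",
    "exclusion_reason",
]
AOP_MAP_COLUMNS = ["endpoint_id", "gene_symbol", "aop_ids", "annotation"]

MEDIA = ("sediment", "porewater")
ACC_UNITS = ("micromolar", "ug_L")

_TRUE_TOKENS = {"true", "t", "yes", "y", "1", "1.0"}
_FALSE_TOKENS = {"false", "f", "no", "n", "0", "0.0", ""}


class SchemaError(ValueError):
    """An input table violates its schema or an invariant."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _as_bool(series: pd.Series, table: str, column: str) -> pd.Series:
    """Coerce a column of bools / 0-1 / yes-no strings to plain bool."""
    if series.dtype == bool:
        return series
    out = []
    for value in series:
        if isinstance(value, (bool, np.bool_)):
            out.append(bool(value))
            continue
        if isinstance(value, (int, float, np.integer, np.floating)) and not pd.isna(value):
            out.append(bool(value))
            continue
        token = "" if pd.isna(value) else str(value).strip().lower()
        if token in _TRUE_TOKENS:
            out.append(True)
        elif token in _FALSE_TOKENS:
            out.append(False)
        else:
            raise SchemaError(f"{table}.{column}: cannot interpret {value!r} as boolean")
    return pd.Series(out, index=series.index, dtype=bool)


def _as_numeric(series: pd.Series, table: str, column: str) -> pd.Series:
    coerced = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & ~series.astype(str).str.strip().eq("") & coerced.isna()
    if bad.any():
        offending = series[bad].iloc[0]
        raise SchemaError(f"{table}.{column}: non-numeric value {offending!r}")
    return coerced.astype(float)


# ---------------------------------------------------------------------------
# chemical registry
# ---------------------------------------------------------------------------

def validate_registry(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a chemical registry and return a normalized copy.

    Invariants enforced: unique ``chemical_id``; recognized ``chem_class``;
    positive ``koc_L_kg`` / ``mw_g_mol`` / ``fcv_ug_gOC`` where present;
    ``tef`` in (0, 1] where present; every 16-PAH member carries class
    ``PAHs``.  Optional constants that are absent stay missing (NaN), never 0.
    """
    df = df.copy()
    _require_columns(df, REGISTRY_COLUMNS, "registry")
    df["chemical_id"] = df["chemical_id"].astype(str)

    duplicated = df["chemical_id"][df["chemical_id"].duplicated()]
    if not duplicated.empty:
        raise SchemaError(f"registry: duplicate chemical_id {duplicated.iloc[0]!r}")

    unknown = df.loc[~df["chem_class"].isin(CHEM_CLASSES)]
    if not unknown.empty:
        row = unknown.iloc[0]
        raise SchemaError(
            f"registry: unknown chem_class {row['chem_class']!r} for "
            f"chemical {row['chemical_id']!r}"
        )

    for column in ("koc_L_kg", "mw_g_mol", "reporting_limit_ug_kg", "tef", "fcv_ug_gOC"):
        df[column] = _as_numeric(df[column], "registry", column)
    for column in ("is_pah16", "is_esb_pah", "is_alkylphenol"):
        df[column] = _as_bool(df[column], "registry", column)

    for column in ("koc_L_kg", "mw_g_mol", "fcv_ug_gOC"):
        bad = df[column].notna() & (df[column] <= 0)
        if bad.any():
            raise SchemaError(
                f"registry.{column}: non-positive value for "
                f"chemical {df.loc[bad, 'chemical_id'].iloc[0]!r}"
            )
    bad_tef = df["tef"].notna() & ((df["tef"] <= 0) | (df["tef"] > 1))
    if bad_tef.any():
        raise SchemaError(
            f"registry.tef: value outside (0, 1] for "
            f"chemical {df.loc[bad_tef, 'chemical_id'].iloc[0]!r}"
        )

    inconsistent = df["is_pah16"] & (df["chem_class"] != "PAHs")
    if inconsistent.any():
        raise SchemaError(
            f"registry: chemical {df.loc[inconsistent, 'chemical_id'].iloc[0]!r} "
            "flagged is_pah16 but chem_class is not 'PAHs'"
        )
    return df.reset_index(drop=True)


def load_registry(path) -> pd.DataFrame:
    """Read and validate ``registry.csv``."""
    return validate_registry(pd.read_csv(path))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def normalize_measurements(raw: pd.DataFrame, registry: pd.DataFrame | None = None) -> pd.DataFrame:
    """Normalize raw measurement rows to the canonical censoring convention.

    ``c_sed_ug_kg`` may be numeric or a ``"<x"`` string as reported by a
    laboratory; ``"<x"`` rows and rows with ``censored = True`` are stored as
    concentration 0 with ``censored = True``.  Detected values pass through
    unchanged.  The operation is idempotent.

    Raises :class:`SchemaError` on negative concentrations, duplicate
    (site, chemical) rows, or (when a registry is given) unregistered
    chemicals.
    """
    df = raw.copy()
    _require_columns(df, ["site_id", "chemical_id", "c_sed_ug_kg"], "measurements")
    df["site_id"] = df["site_id"].astype(str)
    df["chemical_id"] = df["chemical_id"].astype(str)

    values = df["c_sed_ug_kg"]
    below_rl = pd.Series(False, index=df.index)
    if values.dtype == object:
        text = values.astype(str).str.strip()
        below_rl = text.str.startswith("<")
        values = pd.to_numeric(text.str.lstrip("<"), errors="coerce")
    values = _as_numeric(pd.Series(values, index=df.index), "measurements", "c_sed_ug_kg")

    if "censored" in df.columns:
        censored = _as_bool(df["censored"].fillna(False), "measurements", "censored")
    else:
        censored = pd.Series(False, index=df.index)
    censored = censored | below_rl

    if (values.fillna(0) < 0).any():
        bad = df.loc[values < 0].iloc[0]
        raise SchemaError(
            f"measurements: negative concentration for site {bad['site_id']!r}, "
            f"chemical {bad['chemical_id']!r}"
        )

    dup = df.duplicated(subset=["site_id", "chemical_id"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise SchemaError(
            f"measurements: duplicate row for site {bad['site_id']!r}, "
            f"chemical {bad['chemical_id']!r}"
        )

    if registry is not None:
        known = set(registry["chemical_id"])
        unknown = set(df["chemical_id"]) - known
        if unknown:
            raise SchemaError(f"measurements: unregistered chemical_id {sorted(unknown)[0]!r}")

    out = pd.DataFrame(
        {
            "site_id": df["site_id"],
            "chemical_id": df["chemical_id"],
            "c_sed_ug_kg": values.where(~censored, 0.0),
            "censored": censored,
        }
    )
    return out.reset_index(drop=True)


def load_measurements(path, registry: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read ``measurements.csv``, tolerating ``"<x"`` censor markers."""
    return normalize_measurements(pd.read_csv(path), registry)


def detection_frequency(
    measurements: pd.DataFrame,
    n_sites: int,
    chemicals: Iterable[str] | None = None,
) -> pd.Series:
    """Fraction of sites at which each chemical was detected.

    Sites with no row for a chemical count as non-detections (the full
    analyte list is assumed analyzed at every site).  ``chemicals`` widens the
    result to chemicals with zero rows (frequency 0).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    detected = measurements.loc[~measurements["censored"]]
    counts = detected.groupby("chemical_id")["site_id"].nunique()
    if chemicals is not None:
        counts = counts.reindex(list(chemicals), fill_value=0)
    return (counts / float(n_sites)).rename("detection_frequency")


def relative_percent_difference(a: float, b: float) -> float:
    """Duplicate-sample RPD: ``|a - b| / ((a + b) / 2) * 100``.

    Returns NaN with a warning when both duplicates are zero (undefined).
    """
    if a < 0 or b < 0:
        raise ValueError("RPD requires non-negative concentrations")
    if a == 0 and b == 0:
        warnings.warn("RPD undefined for a pair of zero concentrations", stacklevel=2)
        return float("nan")
    return abs(a - b) / ((a + b) / 2.0) * 100.0


def class_concentration_totals(
    measurements: pd.DataFrame, registry: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-site per-class and per-site total concentration sums (µg/kg).

    Censored rows contribute zero (they are stored as zero).  Returns a
    (site × class) wide frame covering every class present in the registry,
    and the per-site totals, which equal the row sums exactly.
    """
    merged = measurements.merge(
        registry[["chemical_id", "chem_class"]], on="chemical_id", how="left"
    )
    if merged["chem_class"].isna().any():
        bad = merged.loc[merged["chem_class"].isna(), "chemical_id"].iloc[0]
        raise SchemaError(f"measurements: unregistered chemical_id {bad!r}")
    classes = [c for c in CHEM_CLASSES if c in set(registry["chem_class"])]
    wide = (
        merged.pivot_table(
            index="site_id",
            columns="chem_class",
            values="c_sed_ug_kg",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=classes, fill_value=0.0)
    )
    wide.columns.name = None
    totals = wide.sum(axis=1).rename("total_ug_kg")
    return wide, totals


# ---------------------------------------------------------------------------
# sites, benchmarks, ACC values, AOP map
# ---------------------------------------------------------------------------

def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    _require_columns(df, SITE_COLUMNS, "sites")
    df["site_id"] = df["site_id"].astype(str)
    if df["site_id"].duplicated().any():
        raise SchemaError("sites: duplicate site_id")
    df["toc_percent"] = _as_numeric(df["toc_percent"], "sites", "toc_percent")
    bad = df["toc_percent"].notna() & (df["toc_percent"] > 100)
    if bad.any():
        raise SchemaError("sites: toc_percent above 100")
    for column in df.columns:
        if column not in ("site_id", "toc_percent"):
            df[column] = _as_numeric(df[column], "sites", column)
    return df.reset_index(drop=True)


def load_sites(path) -> pd.DataFrame:
    return validate_sites(pd.read_csv(path))


def site_attributes(sites: pd.DataFrame) -> list[str]:
    """Names of the watershed-attribute columns in a site table."""
    return [c for c in sites.columns if c not in ("site_id", "toc_percent")]


def validate_benchmarks(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    _require_columns(df, BENCHMARK_COLUMNS, "benchmarks")
    df["chemical_id"] = df["chemical_id"].astype(str)
    if not df["medium"].isin(MEDIA).all():
        bad = df.loc[~df["medium"].isin(MEDIA), "medium"].iloc[0]
        raise SchemaError(f"benchmarks: unknown medium {bad!r}")
    df["value"] = _as_numeric(df["value"], "benchmarks", "value")
    if (df["value"] <= 0).any():
        raise SchemaError("benchmarks: benchmark values must be positive")
    return df.reset_index(drop=True)


def load_benchmarks(path) -> pd.DataFrame:
    return validate_benchmarks(pd.read_csv(path))


def validate_acc(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    _require_columns(df, ACC_COLUMNS, "acc")
    df["chemical_id"] = df["chemical_id"].astype(str)
    df["endpoint_id"] = df["endpoint_id"].astype(str)
    unit = df["acc_unit"].astype(str).str.strip().replace({"µg/L": "ug_L", "ug/L": "ug_L", "uM": "micromolar"})
    if not unit.isin(ACC_UNITS).all():
        bad = unit.loc[~unit.isin(ACC_UNITS)].iloc[0]
        raise SchemaError(f"acc: unknown acc_unit {bad!r}")
    df["acc_unit"] = unit
    df["acc_value"] = _as_numeric(df["acc_value"], "acc", "acc_value")
    if (df["acc_value"] <= 0).any():
        raise SchemaError("acc: acc_value must be positive")
    df["excluded"] = _as_bool(df["excluded"].fillna(False), "acc", "excluded")
    df["gene_symbol"] = df["gene_symbol"].fillna("").astype(str)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("").astype(str)
    if df.duplicated(subset=["chemical_id", "endpoint_id"]).any():
        raise SchemaError("acc: duplicate (chemical_id, endpoint_id) row")
    return df.reset_index(drop=True)


def load_acc(path) -> pd.DataFrame:
    return validate_acc(pd.read_csv(path))


def validate_aop_map(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    _require_columns(df, AOP_MAP_COLUMNS, "aop_map")
    df["endpoint_id"] = df["endpoint_id"].astype(str)
    df["gene_symbol"] = df["gene_symbol"].astype(str)
    if df.duplicated(subset=["endpoint_id", "gene_symbol"]).any():
        raise SchemaError("aop_map: duplicate (endpoint_id, gene_symbol) row")
    df["aop_ids"] = df["aop_ids"].fillna("").astype(str)
    df["annotation"] = df["annotation"].fillna("").astype(str)
    return df.reset_index(drop=True)


def load_aop_map(path) -> pd.DataFrame:
    return validate_aop_map(pd.read_csv(path))
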