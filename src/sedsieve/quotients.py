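"""Toxicity quotients against whole-organism benchmarks.

A toxicity quotient (TQ) is the ratio of a measured (sediment, µg/kg dry wt)
or estimated (porewater, µg/L) concentration to a same-medium benchmark.
For each chemical at each site the TQ against the most sensitive (lowest)
benchmark is the TQ_Max; TQ_Max values are summed within chemical classes
(TQ_Class) and over all chemicals in a sample (TQ_Sample).  Sediment and
porewater screens are fully parallel, distinguished by a ``medium`` tag;
no sum ever mixes media.

Censored chemicals carry TQ 0 (not absent), so summations follow the
zero-substitution convention and exceedance counts never count them.
Chemicals with no benchmark in a medium are absent from that medium's
results (unscreenable), which is different from a TQ of 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tq(conc: float, benchmark: float) -> float:
    """Concentration / benchmark (same units)."""
    if benchmark <= 0:
        raise ValueError("benchmark must be positive")
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return conc / benchmark


def tq_max(conc: float, benchmarks) -> tuple[float, float]:
    """TQ against the most sensitive benchmark: ``(conc / min(b), min(b))``.

    Ties in the minimum are broken by first occurrence, recorded in the
    returned benchmark for provenance.  Raises on an empty benchmark list
    (the chemical is unscreenable, a state the caller must encode as absence,
    never as zero).
    """
    benchmarks = list(benchmarks)
    if not benchmarks:
        raise ValueError("at least one benchmark is required")
    lowest = benchmarks[int(np.argmin(benchmarks))]
    return tq(conc, lowest), lowest


def tq_long(
    concentrations: pd.DataFrame, benchmarks: pd.DataFrame, medium: str
) -> pd.DataFrame:
    """One TQ row per (site, chemical, benchmark) for the given medium.

    ``concentrations`` has columns ``site_id, chemical_id, conc, censored``.
    """
    bench = benchmarks.loc[benchmarks["medium"] == medium]
    merged = concentrations.merge(bench, on="chemical_id", how="inner")
    return pd.DataFrame(
        {
            "site_id": merged["site_id"],
            "chemical_id": merged["chemical_id"],
            "medium": medium,
            "benchmark_value": merged["value"],
            "benchmark_source": merged["source"],
            "tq": merged["conc"] / merged["value"],
        }
    )


def tq_max_table(
    concentrations: pd.DataFrame, benchmarks: pd.DataFrame, medium: str
) -> pd.DataFrame:
    """TQ_Max per (site, chemical) for the given medium.

    Only chemicals with at least one benchmark in the medium appear.  The
    most sensitive benchmark is the minimum value; ties break by file order.
    """
    bench = benchmarks.loc[benchmarks["medium"] == medium]
    if bench.empty:
        return pd.DataFrame(
            columns=["site_id", "chemical_id", "medium", "tq_max", "benchmark_used"]
        )
    # idxmin is stable: first occurrence wins on ties
    lowest = bench.loc[bench.groupby("chemical_id")["value"].idxmin()]
    merged = concentrations.merge(
        lowest[["chemical_id", "value"]], on="chemical_id", how="inner"
    )
    return pd.DataFrame(
        {
            "site_id": merged["site_id"],
            "chemical_id": merged["chemical_id"],
            "medium": medium,
            "tq_max": merged["conc"] / merged["value"],
            "benchmark_used": merged["value"],
        }
    )


def aggregate_tq(
    tqmax: pd.DataFrame,
    registry: pd.DataFrame,
    site_ids=None,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Table-2 style aggregates from a TQ_Max table of one medium.

    Returns ``{"tq_class": site × class frame, "tq_sample": per-site Series}``.
    TQ_Sample equals the sum over classes of TQ_Class exactly.  ``site_ids``
    widens the result to sites with no screenable chemical (sums 0).
    """
    merged = tqmax.merge(
        registry[["chemical_id", "chem_class"]], on="chemical_id", how="left"
    )
    tq_class = merged.pivot_table(
        index="site_id",
        columns="chem_class",
        values="tq_max",
        aggfunc="sum",
        fill_value=0.0,
    )
    tq_class.columns.name = None
    if site_ids is not None:
        tq_class = tq_class.reindex(list(site_ids), fill_value=0.0)
    tq_sample = tq_class.sum(axis=1).rename("tq_sample")
    return {"tq_class": tq_class, "tq_sample": tq_sample}


def count_exceedances(
    tqmax: pd.DataFrame, threshold: float
) -> tuple[pd.Series, pd.Series]:
    """Counts of TQ_Max strictly above ``threshold`` per site and per chemical."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exceed = tqmax.loc[tqmax["tq_max"] > threshold]
    per_site = exceed.groupby("site_id")["chemical_id"].nunique()
    per_chemical = exceed.groupby("chemical_id")["site_id"].nunique()
    return (
        per_site.rename("n_exceedances"),
        per_chemical.rename("n_sites_exceeding"),
    )


def sediment_concentrations(measurements: pd.DataFrame) -> pd.DataFrame:
    """Measurement rows as a generic concentration table for screening."""
    return pd.DataFrame(
        {
            "site_id": measurements["site_id"],
            "chemical_id": measurements["chemical_id"],
            "conc": measurements["c_sed_ug_kg"].astype(float),
            "censored": measurements["censored"].astype(bool),
        }
    )
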