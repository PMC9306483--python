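"""Chemical priority levels, site priority scores, and watershed correlations.

Chemical prioritization
-----------------------
Chemicals are binned by how often and by how much they exceed screening
thresholds across sites, using three metrics in parallel: sediment TQ_Max,
porewater TQ_Max, and EAR_Max.  The top rung (P1) is exceedance of a TQ_Max
of 10 or an EAR_Max of 0.1 at more than 20% of sites.  Chemicals that never
reach a TQ_Max of 0.1 or an EAR_Max of 0.001 anywhere — or were never
detected — are low priority.  Chemicals exceeding that lowest rung at only
1%-20% of sites stay uncategorized, and detected chemicals screenable by no
method are reported as ``no_benchmarks``.  The intermediate rungs P2/P3
follow a geometric ×10 ladder between the defined endpoints (an assumption,
configurable via ``ladder``).

Site prioritization
-------------------
Eight screening methods are each normalized to a priority level 1 (highest
priority) through 4 (no evidence), then averaged into an overall score;
lower scores mean higher priority.  The level criteria:

====================  ============================================  ====  =======  =======  ========
method                criterion                                     4     3        2        1
====================  ============================================  ====  =======  =======  ========
sediment_tq_max       n chemicals with TQ_Max > 1.0                 0     1-9      10-19    >=20
porewater_tq_max      n chemicals with TQ_Max > 1.0                 0     1-9      10-19    >=20
ear_max               n chemicals with EAR_Max > 0.01               0     1-9      10-19    >=20
pah_mixture           TECQ / PECQ / ∑ESBTU exceedance               none  TECQ     one of   both
                                                                          only     PECQ,    PECQ and
                                                                                   ∑ESBTU   ∑ESBTU
alkylphenol_mixture   value of TQ_AP                                0     0.01-    1.0-9.9  >=10
                                                                          0.99
sediment_tq_sample    value of TQ_Sample                            1-9   10-99    100-999  1000-10000
porewater_tq_sample   value of TQ_Sample                            1-9   10-99    100-999  1000-10000
ear_sample            value of EAR_Sample                           <0.1  0.1-     1.0-9.9  >=10
                                                                          0.99
====================  ============================================  ====  =======  =======  ========

Gaps in the printed bins are closed by monotone clamping: TQ_Sample below 1
maps to level 4 and above 10 000 to level 1; a TQ_AP in (0, 0.01) maps to
level 3.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PRIORITY_P1 = "P1"
PRIORITY_P2 = "P2"
PRIORITY_P3 = "P3"
PRIORITY_LOW = "low"
PRIORITY_UNCATEGORIZED = "uncategorized"
PRIORITY_NO_BENCHMARKS = "no_benchmarks"

#: (label, tq_max rung, ear_max rung) from most to least severe; the last
#: rung doubles as the "low" floor (never exceeded anywhere => low priority).
DEFAULT_LADDER: tuple[tuple[str, float, float], ...] = (
    (PRIORITY_P1, 10.0, 0.1),
    (PRIORITY_P2, 1.0, 0.01),
    (PRIORITY_P3, 0.1, 0.001),
)

SITE_METHODS = (
    "sediment_tq_max",
    "porewater_tq_max",
    "ear_max",
    "pah_mixture",
    "alkylphenol_mixture",
    "sediment_tq_sample",
    "porewater_tq_sample",
    "ear_sample",
)

_COUNT_METHODS = {"sediment_tq_max", "porewater_tq_max", "ear_max"}
_TQ_SAMPLE_METHODS = {"sediment_tq_sample", "porewater_tq_sample"}


def chemical_priority(
    tqmax_sediment: pd.DataFrame,
    tqmax_porewater: pd.DataFrame,
    ear_max: pd.DataFrame,
    measurements: pd.DataFrame,
    registry: pd.DataFrame,
    n_sites: int,
    prevalence: float = 0.2,
    ladder: Sequence[tuple[str, float, float]] = DEFAULT_LADDER,
) -> pd.DataFrame:
    """Assign a priority level to every registry chemical.

    ``tqmax_sediment`` / ``tqmax_porewater`` carry columns
    ``site_id, chemical_id, tq_max``; ``ear_max`` carries
    ``site_id, chemical_id, ear_max``.  The prevalence comparison is strict
    (``> prevalence`` fraction of sites).  Returns one row per chemical with
    the level and per-rung exceedance-site counts.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")

    chemicals = list(registry["chemical_id"])
    detected = set(
        measurements.loc[~measurements["censored"], "chemical_id"].unique()
    )
    screenable = (
        set(tqmax_sediment["chemical_id"])
        | set(tqmax_porewater["chemical_id"])
        | set(ear_max["chemical_id"])
    )

    # per (chemical, site) exceedance of each rung under any of the 3 metrics
    def rung_counts(tq_rung: float, ear_rung: float) -> pd.Series:
        frames = []
        for df in (tqmax_sediment, tqmax_porewater):
            hit = df.loc[df["tq_max"] > tq_rung, ["chemical_id", "site_id"]]
            frames.append(hit)
        hit = ear_max.loc[ear_max["ear_max"] > ear_rung, ["chemical_id", "site_id"]]
        frames.append(hit)
        if not frames:
            return pd.Series(dtype=int)
        combined = pd.concat(frames).drop_duplicates()
        return combined.groupby("chemical_id")["site_id"].nunique()

    counts = {
        label: rung_counts(tq_rung, ear_rung) for label, tq_rung, ear_rung in ladder
    }
    floor_label = ladder[-1][0]

    rows = []
    for chem in chemicals:
        n_exceed = {label: int(c.get(chem, 0)) for label, c in counts.items()}
        if chem not in detected:
            level = PRIORITY_LOW
        elif chem not in screenable:
            level = PRIORITY_NO_BENCHMARKS
        else:
            level = None
            for label, _, _ in ladder:
                if n_exceed[label] / n_sites > prevalence:
                    level = label
                    break
            if level is None:
                level = (
                    PRIORITY_UNCATEGORIZED
                    if n_exceed[floor_label] >= 1
                    else PRIORITY_LOW
                )
        row = {"chemical_id": chem, "level": level}
        row.update({f"n_sites_{label}": n_exceed[label] for label in n_exceed})
        rows.append(row)
    return pd.DataFrame(rows)


def site_method_level(method: str, value) -> int:
    """Normalize one screening method's value to a priority level in {1,2,3,4}."""
    if method in _COUNT_METHODS:
        count = int(value)
        if count < 0:
            raise ValueError("count must be non-negative")
        if count == 0:
            return 4
        if count < 10:
            return 3
        if count < 20:
            return 2
        return 1
    if method == "pah_mixture":
        tecq, pecq, esbtu_sum = value
        pec_exceeded = pecq > 1.0
        esb_exceeded = (esbtu_sum is not None) and not pd.isna(esbtu_sum) and esbtu_sum > 1.0
        if pec_exceeded and esb_exceeded:
            return 1
        if pec_exceeded or esb_exceeded:
            return 2
        if tecq > 1.0:
            return 3
        return 4
    if method == "alkylphenol_mixture":
        v = float(value)
        if v < 0:
            raise ValueError("TQ_AP must be non-negative")
        if v == 0:
            return 4
        if v < 1.0:
            return 3
        if v < 10.0:
            return 2
        return 1
    if method in _TQ_SAMPLE_METHODS:
        v = float(value)
        if v < 0:
            raise ValueError("TQ_Sample must be non-negative")
        if v < 10.0:
            return 4
        if v < 100.0:
            return 3
        if v < 1000.0:
            return 2
        return 1
    if method == "ear_sample":
        v = float(value)
        if v < 0:
            raise ValueError("EAR_Sample must be non-negative")
        if v < 0.1:
            return 4
        if v < 1.0:
            return 3
        if v < 10.0:
            return 2
        return 1
    raise ValueError(f"unknown site method {method!r}")


def overall_score(levels: Mapping[str, int | None] | Sequence[int | None]) -> tuple[float, int]:
    """Mean of the available method levels and the number available.

    Missing methods (None/NaN) are skipped; with zero methods available the
    score is undefined and a ValueError is raised.  Lower scores mean higher
    priority.
    """
    if isinstance(levels, Mapping):
        values = list(levels.values())
    else:
        values = list(levels)
    available = [float(v) for v in values if v is not None and not pd.isna(v)]
    if not available:
        raise ValueError("no methods available for overall score")
    return float(np.mean(available)), len(available)


def site_priority_table(method_values: pd.DataFrame) -> pd.DataFrame:
    """Build the per-site priority table from raw method values.

    ``method_values`` is indexed by ``site_id`` with one column per method in
    :data:`SITE_METHODS` holding the method's raw value (the count, the
    ``(tecq, pecq, esbtu)`` tuple, or the sample-level value); NaN marks a
    method unavailable at that site.  Returns one row per site with the eight
    ``level_*`` columns, ``overall_score`` and ``n_methods_available``.
    """
    rows = []
    for site_id, raw in method_values.iterrows():
        levels: dict[str, int | None] = {}
        for method in SITE_METHODS:
            value = raw.get(method)
            missing = value is None or (np.isscalar(value) and pd.isna(value))
            levels[method] = None if missing else site_method_level(method, value)
        score, n_available = overall_score(levels)
        row = {"site_id": site_id}
        row.update({f"level_{m}": levels[m] for m in SITE_METHODS})
        row["overall_score"] = score
        row["n_methods_available"] = n_available
        rows.append(row)
    return pd.DataFrame(rows)


def rank_sites(site_priority: pd.DataFrame, tq_sample_sediment: pd.Series) -> pd.DataFrame:
    """Deterministic site ordering: ascending overall score, ties broken by
    descending sediment TQ_Sample, then lexicographic site id."""
    df = site_priority.copy()
    df["_tq_sample"] = (
        df["site_id"].map(tq_sample_sediment).fillna(0.0).astype(float)
    )
    df = df.sort_values(
        by=["overall_score", "_tq_sample", "site_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_tq_sample")
    df.insert(1, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


def watershed_correlations(
    metrics: pd.DataFrame,
    sites: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman rank correlations between screening metrics and watershed
    attributes.

    ``metrics`` is indexed by ``site_id`` with one column per metric.  Uses
    tie-aware midranks and two-sided p-values; ``significant`` is ``p <
    alpha`` with no multiplicity correction.  Constant vectors give an
    undefined coefficient and are flagged via ``valid = False``.
    """
    from .tables_io import site_attributes

    attr_names = site_attributes(sites)
    attrs = sites.set_index("site_id")[attr_names]
    joined = metrics.join(attrs, how="inner")
    rows = []
    for metric in metrics.columns:
        for attribute in attr_names:
            pair = joined[[metric, attribute]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 paired observations for {metric} vs {attribute}"
                )
            x, y = pair[metric].to_numpy(), pair[attribute].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append(
                    {
                        "metric": metric,
                        "attribute": attribute,
                        "rho": np.nan,
                        "p_value": np.nan,
                        "significant": False,
                        "valid": False,
                    }
                )
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append(
                {
                    "metric": metric,
                    "attribute": attribute,
                    "rho": float(rho),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                    "valid": True,
                }
            )
    return pd.DataFrame(rows)
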