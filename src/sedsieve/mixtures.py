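"""Defined mixture scores: PAH consensus quotients, ESB toxic units, and the
alkylphenol toxic-equivalency quotient.

Three additive, common-mode-of-action mixture screens:

* ∑PAH16 against the consensus threshold effect concentration (TEC,
  1610 µg/kg) and probable effect concentration (PEC, 22 800 µg/kg) for the
  combined concentration of the 16 priority-pollutant PAHs, with the usual
  effect categories (likely / possible / unlikely).
* ∑ESBTU — equilibrium-partitioning sediment benchmark toxic units: the
  TOC-normalized concentration (µg/g OC) of each member PAH divided by its
  chemical-specific final chronic value (FCV, µg/g OC), summed.  Values above
  1.0 flag narcosis potential for sensitive benthic organisms.
* Alkylphenol TEQ — concentrations of detergent-metabolite chemicals weighted
  by toxic equivalency factors relative to nonylphenol (TEQ = Σ C_i × TEF_i),
  screened against the 1400 µg/kg freshwater interim sediment quality
  guideline at the site's TOC:  TQ_AP = TEQ / (1400 × TOC%).

Censored concentrations contribute zero throughout, so all three scores are
biased low by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TEC_PAH16 = 1610.0  # µg/kg dry wt, threshold effect concentration for ∑PAH16
PEC_PAH16 = 22_800.0  # µg/kg dry wt, probable effect concentration for ∑PAH16
ALKYLPHENOL_ISQG = 1400.0  # µg/kg, freshwater interim sediment quality guideline

CATEGORY_UNLIKELY = "unlikely"
CATEGORY_POSSIBLE = "possible"
CATEGORY_LIKELY = "likely"


def sum_pah16(
    measurements: pd.DataFrame, registry: pd.DataFrame, site_ids=None
) -> pd.Series:
    """Per-site combined concentration (µg/kg) of the 16-PAH priority set.

    Not TOC-normalized.  Censored members contribute zero.  A registry whose
    flagged set is not exactly 16 chemicals triggers a warning (user-defined
    subsets are allowed).
    """
    members = registry.loc[registry["is_pah16"], "chemical_id"]
    if len(members) != 16:
        logger.warning("is_pah16 flags %d chemicals (expected 16)", len(members))
    sub = measurements.loc[measurements["chemical_id"].isin(set(members))]
    totals = sub.groupby("site_id")["c_sed_ug_kg"].sum()
    if site_ids is not None:
        totals = totals.reindex(list(site_ids), fill_value=0.0)
    return totals.rename("sum_pah16")


def pah_quotients(
    sum16, tec: float = TEC_PAH16, pec: float = PEC_PAH16
) -> pd.DataFrame:
    """TECQ, PECQ and effect category from per-site ∑PAH16.

    Effects are *likely* when PECQ > 1.0, *unlikely* when TECQ < 1.0 (values
    exactly 1.0 do not trigger the higher category), and *possible* in
    between.  Accepts a scalar or a per-site Series; always returns a frame
    with columns ``sum_pah16, tecq, pecq, category``.
    """
    if tec <= 0 or pec <= 0:
        raise ValueError("tec and pec must be positive")
    values = pd.Series(sum16, dtype=float) if np.isscalar(sum16) else pd.Series(sum16)
    tecq = values / tec
    pecq = values / pec
    category = np.select(
        [pecq > 1.0, tecq > 1.0],
        [CATEGORY_LIKELY, CATEGORY_POSSIBLE],
        default=CATEGORY_UNLIKELY,
    )
    return pd.DataFrame(
        {
            "sum_pah16": values,
            "tecq": tecq,
            "pecq": pecq,
            "category": category,
        },
        index=values.index,
    )


def esbtu(
    measurements: pd.DataFrame,
    sites: pd.DataFrame,
    registry: pd.DataFrame,
) -> pd.DataFrame:
    """Per-site ∑ESBTU over the ESB PAH member set.

    The TOC-normalized concentration is ``c_sed (µg/kg) / (10 × TOC%)`` in
    µg/g OC; each member's toxic unit is that divided by its FCV, and the
    site score is their sum.  Sites with TOC <= 0 are returned with status
    ``no_toc`` and a missing score.  A detected member without an FCV is a
    hard error listing the offending chemicals.
    """
    members = registry.loc[registry["is_esb_pah"]]
    detected = measurements.loc[
        measurements["chemical_id"].isin(set(members["chemical_id"]))
        & ~measurements["censored"]
    ]
    no_fcv = set(members.loc[members["fcv_ug_gOC"].isna(), "chemical_id"])
    offending = sorted(set(detected["chemical_id"]) & no_fcv)
    if offending:
        raise ValueError(f"missing FCV for detected ESB member(s): {offending}")

    merged = measurements.loc[
        measurements["chemical_id"].isin(set(members["chemical_id"]))
    ].merge(members[["chemical_id", "fcv_ug_gOC"]], on="chemical_id")
    merged = merged.merge(sites[["site_id", "toc_percent"]], on="site_id", how="left")

    valid_toc = merged["toc_percent"] > 0
    merged["toxic_unit"] = np.where(
        valid_toc,
        merged["c_sed_ug_kg"] / (10.0 * merged["toc_percent"]) / merged["fcv_ug_gOC"],
        np.nan,
    )
    per_site = merged.groupby("site_id").agg(
        esbtu_sum=("toxic_unit", "sum"), any_valid=("toxic_unit", lambda s: s.notna().any())
    )
    toc = sites.set_index("site_id")["toc_percent"]
    out = pd.DataFrame(index=sites["site_id"])
    out["esbtu_sum"] = per_site["esbtu_sum"].reindex(out.index)
    out["status"] = np.where(toc.reindex(out.index) > 0, "ok", "no_toc")
    out.loc[out["status"] == "no_toc", "esbtu_sum"] = np.nan
    out.loc[(out["status"] == "ok") & out["esbtu_sum"].isna(), "esbtu_sum"] = 0.0
    return out.reset_index()


def alkylphenol_teq(
    measurements: pd.DataFrame, registry: pd.DataFrame, site_ids=None
) -> pd.Series:
    """Per-site alkylphenol TEQ (µg/kg as nonylphenol equivalents).

    TEQ = Σ C_i × TEF_i over the detergent-metabolite member set; censored
    members contribute zero.  A member without a TEF is a hard error.
    """
    members = registry.loc[registry["is_alkylphenol"]]
    missing_tef = members.loc[members["tef"].isna(), "chemical_id"]
    if not missing_tef.empty:
        raise ValueError(
            f"missing TEF for alkylphenol member(s): {sorted(missing_tef)}"
        )
    merged = measurements.merge(
        members[["chemical_id", "tef"]], on="chemical_id", how="inner"
    )
    teq = (merged["c_sed_ug_kg"] * merged["tef"]).groupby(merged["site_id"]).sum()
    if site_ids is not None:
        teq = teq.reindex(list(site_ids), fill_value=0.0)
    return teq.rename("teq")


def alkylphenol_tq(teq, toc_percent):
    """TQ_AP = TEQ / (1400 × TOC%), with TOC in percent (guideline applies at
    1% organic carbon).  Values above 1.0 flag narcosis potential."""
    teq_arr = np.asarray(teq, dtype=float)
    toc_arr = np.asarray(toc_percent, dtype=float)
    if np.any(toc_arr <= 0):
        raise ValueError("toc_percent must be positive")
    if np.any(teq_arr < 0):
        raise ValueError("teq must be non-negative")
    result = teq_arr / (ALKYLPHENOL_ISQG * toc_arr)
    return float(result) if result.ndim == 0 else result
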