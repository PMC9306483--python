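"""Exposure-activity ratio (EAR) screening against high-throughput bioassay data.

An EAR is the ratio of the estimated porewater concentration of a chemical to
an assay endpoint's activity concentration at cutoff (ACC) — the concentration
at which measured in vitro bioactivity first exceeds baseline.  EARs are a
relative bioactivity-potential ranking, not a risk estimate.

Aggregates (per sample):

EAR_Max
    a chemical's maximum EAR over its assay endpoints
EAR_Class / EAR_Sample
    sums of EAR_Max within a chemical class / over all chemicals
EAR_Endpoint
    the additive sum of EARs of all chemicals acting on one assay endpoint,
    the basis of the mixture-of-concern screen

The endpoint-mixture screen retains endpoints whose EAR_Endpoint exceeds a
site threshold (default 0.1) at a minimum number of sites (default 20% of the
study, i.e. max(1, floor(0.2 n))).  Chemicals contributing at least 10% of the
EAR benchmark threshold of 0.01 (i.e. EAR >= 0.001) at a site are members of
the mixture there; chemicals at EAR >= 0.01 at the prevalence count of sites
are flagged as major contributors.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .porewater import porewater_concentrations

logger = logging.getLogger(__name__)

EAR_MAX_THRESHOLD = 0.001
ENDPOINT_SITE_THRESHOLD = 0.1
ENDPOINT_PREVALENCE = 0.2
MEMBER_THRESHOLD = 0.001  # 10% of the 0.01 EAR benchmark threshold
MAJOR_THRESHOLD = 0.01


def required_site_count(prevalence: float, n_sites: int) -> int:
    """Sites needed for the prevalence rule: ``max(1, floor(prevalence * n))``."""
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return max(1, math.floor(prevalence * n_sites))


def acc_to_ug_per_L(acc: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize ACC values to µg/L.

    Micromolar rows are converted with the chemical's molecular weight
    (1 µM of a compound of MW m g/mol is m µg/L); rows already in µg/L pass
    through.  Micromolar rows for chemicals without a molecular weight are
    dropped with a logged warning.  Adds an ``acc_ug_L`` column.
    """
    df = acc.merge(registry[["chemical_id", "mw_g_mol"]], on="chemical_id", how="left")
    micromolar = df["acc_unit"] == "micromolar"
    no_mw = micromolar & df["mw_g_mol"].isna()
    if no_mw.any():
        for chem in df.loc[no_mw, "chemical_id"].unique():
            logger.warning(
                "dropping micromolar ACC rows for %s: no molecular weight", chem
            )
        df = df.loc[~no_mw]
        micromolar = df["acc_unit"] == "micromolar"
    df = df.copy()
    df["acc_ug_L"] = np.where(
        micromolar, df["acc_value"] * df["mw_g_mol"], df["acc_value"]
    )
    return df.drop(columns=["mw_g_mol"]).reset_index(drop=True)


def compute_ear(
    porewater: pd.DataFrame, acc: pd.DataFrame, registry: pd.DataFrame
) -> pd.DataFrame:
    """Long EAR table: one row per (site, chemical, non-excluded endpoint).

    Only chemicals with a usable porewater estimate contribute; censored
    measurements contribute EAR 0.  Excluded ACC rows never contribute.
    """
    usable_acc = acc_to_ug_per_L(acc.loc[~acc["excluded"]], registry)
    conc = porewater_concentrations(porewater)
    merged = conc.merge(
        usable_acc[["chemical_id", "endpoint_id", "acc_ug_L", "gene_symbol"]],
        on="chemical_id",
        how="inner",
    )
    return pd.DataFrame(
        {
            "site_id": merged["site_id"],
            "chemical_id": merged["chemical_id"],
            "endpoint_id": merged["endpoint_id"],
            "ear": merged["conc"] / merged["acc_ug_L"],
        }
    )


def aggregate_ear(
    ear: pd.DataFrame, registry: pd.DataFrame, site_ids=None
) -> dict[str, pd.DataFrame | pd.Series]:
    """EAR_Max / EAR_Class / EAR_Sample / EAR_Endpoint aggregates.

    EAR_Max is a chemical's maximum over its endpoints within a site;
    EAR_Class and EAR_Sample are sums of EAR_Max; EAR_Endpoint sums the
    endpoint-specific EARs of all chemicals sharing that endpoint.
    EAR_Sample equals the sum over classes of EAR_Class exactly.
    """
    ear_max = (
        ear.groupby(["site_id", "chemical_id"], as_index=False)["ear"]
        .max()
        .rename(columns={"ear": "ear_max"})
    )
    merged = ear_max.merge(
        registry[["chemical_id", "chem_class"]], on="chemical_id", how="left"
    )
    ear_class = merged.pivot_table(
        index="site_id",
        columns="chem_class",
        values="ear_max",
        aggfunc="sum",
        fill_value=0.0,
    )
    ear_class.columns.name = None
    if site_ids is not None:
        ear_class = ear_class.reindex(list(site_ids), fill_value=0.0)
    ear_sample = ear_class.sum(axis=1).rename("ear_sample")
    ear_endpoint = (
        ear.groupby(["site_id", "endpoint_id"], as_index=False)["ear"]
        .sum()
        .rename(columns={"ear": "ear_endpoint"})
    )
    return {
        "ear_max": ear_max,
        "ear_class": ear_class,
        "ear_sample": ear_sample,
        "ear_endpoint": ear_endpoint,
    }


def flag_chemicals(
    ear_max: pd.DataFrame, threshold: float = EAR_MAX_THRESHOLD
) -> pd.DataFrame:
    """Chemicals whose EAR_Max strictly exceeds ``threshold`` at >= 1 site.

    Returns per-chemical site counts; an EAR_Max exactly at the threshold is
    not an exceedance.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exceed = ear_max.loc[ear_max["ear_max"] > threshold]
    counts = (
        exceed.groupby("chemical_id")["site_id"]
        .nunique()
        .rename("n_sites_exceeding")
        .reset_index()
    )
    counts["flagged"] = True
    return counts


def priority_endpoints(
    ear: pd.DataFrame,
    ear_endpoint: pd.DataFrame,
    n_sites: int,
    site_threshold: float = ENDPOINT_SITE_THRESHOLD,
    prevalence: float = ENDPOINT_PREVALENCE,
    member_threshold: float = MEMBER_THRESHOLD,
    major_threshold: float = MAJOR_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Identify priority endpoint mixtures and their member chemicals.

    An endpoint is retained iff EAR_Endpoint > ``site_threshold`` (strict) at
    at least ``max(1, floor(prevalence * n_sites))`` sites.  Returns
    ``(summary, membership)``:

    * ``summary`` — one row per retained endpoint: ``endpoint_id``,
      ``n_sites_exceeding``, semicolon-joined ``member_chemicals`` (union over
      sites of chemicals with EAR >= member_threshold) and
      ``major_contributors`` (chemicals with EAR >= major_threshold at at
      least the prevalence count of sites).
    * ``membership`` — long rows (endpoint_id, site_id, chemical_id, ear,
      is_major) for every member at every site.
    """
    needed = required_site_count(prevalence, n_sites)
    counts = (
        ear_endpoint.loc[ear_endpoint["ear_endpoint"] > site_threshold]
        .groupby("endpoint_id")["site_id"]
        .nunique()
    )
    retained = counts[counts >= needed].rename("n_sites_exceeding")

    members = ear.loc[
        ear["endpoint_id"].isin(retained.index) & (ear["ear"] >= member_threshold),
        ["endpoint_id", "site_id", "chemical_id", "ear"],
    ].copy()
    members["is_major_level"] = members["ear"] >= major_threshold

    major_counts = (
        members.loc[members["is_major_level"]]
        .groupby(["endpoint_id", "chemical_id"])["site_id"]
        .nunique()
    )
    major_pairs = set(major_counts[major_counts >= needed].index)
    members["is_major"] = [
        (e, c) in major_pairs
        for e, c in zip(members["endpoint_id"], members["chemical_id"])
    ]
    membership = members.drop(columns=["is_major_level"]).reset_index(drop=True)

    rows = []
    for endpoint_id, n_exceed in retained.sort_index().items():
        sub = membership.loc[membership["endpoint_id"] == endpoint_id]
        member_chems = sorted(sub["chemical_id"].unique())
        major_chems = sorted(sub.loc[sub["is_major"], "chemical_id"].unique())
        rows.append(
            {
                "endpoint_id": endpoint_id,
                "n_sites_exceeding": int(n_exceed),
                "member_chemicals": ";".join(member_chems),
                "major_contributors": ";".join(major_chems),
            }
        )
    summary = pd.DataFrame(
        rows, columns=["endpoint_id", "n_sites_exceeding", "member_chemicals", "major_contributors"]
    )
    return summary, membership


def annotate(report: pd.DataFrame, aop_map: pd.DataFrame) -> pd.DataFrame:
    """Attach gene symbols and AOP identifiers to an endpoint report.

    Left join on ``endpoint_id``: endpoints without a mapping are retained
    with empty annotation, and the row count never changes.  Multiple mapped
    genes/AOPs per endpoint are semicolon-joined.
    """
    per_endpoint = (
        aop_map.groupby("endpoint_id")
        .agg(
            gene_symbol=("gene_symbol", lambda s: ";".join(sorted(set(s)))),
            aop_ids=(
                "aop_ids",
                lambda s: ";".join(
                    sorted({a for joined in s for a in str(joined).split(";") if a})
                ),
            ),
        )
        .reset_index()
    )
    out = report.merge(per_endpoint, on="endpoint_id", how="left")
    out["gene_symbol"] = out["gene_symbol"].fillna("")
    out["aop_ids"] = out["aop_ids"].fillna("")
    return out
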