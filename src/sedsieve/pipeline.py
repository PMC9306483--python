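"""End-to-end screening pipeline: from input tables to priority reports.

``run_screening`` chains the stages in analysis order — porewater estimation,
sediment and porewater toxicity quotients, exposure-activity ratios, the
three defined mixture scores, chemical priority levels, the eight-method site
priority table, and the ranked site list — and returns every intermediate
product in one bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ear_screen, mixtures, prioritize, quotients
from .porewater import porewater_concentrations, porewater_table


@dataclass
class ScreeningConfig:
    """Thresholds of the screening rules; defaults are the standard ones."""

    ear_max_threshold: float = ear_screen.EAR_MAX_THRESHOLD
    endpoint_site_threshold: float = ear_screen.ENDPOINT_SITE_THRESHOLD
    endpoint_prevalence: float = ear_screen.ENDPOINT_PREVALENCE
    member_threshold: float = ear_screen.MEMBER_THRESHOLD
    major_threshold: float = ear_screen.MAJOR_THRESHOLD
    chemical_prevalence: float = 0.2
    tec: float = mixtures.TEC_PAH16
    pec: float = mixtures.PEC_PAH16


@dataclass
class ScreeningResults:
    """All products of one screening run, keyed the way the reports name them."""

    porewater: pd.DataFrame
    tqmax_sediment: pd.DataFrame
    tqmax_porewater: pd.DataFrame
    tq_aggregates_sediment: dict
    tq_aggregates_porewater: dict
    ear: pd.DataFrame
    ear_aggregates: dict
    pah_mixture: pd.DataFrame
    esb: pd.DataFrame
    alkylphenol: pd.DataFrame
    chemical_priority: pd.DataFrame
    site_priority: pd.DataFrame
    ranked_sites: pd.DataFrame
    priority_endpoint_summary: pd.DataFrame
    priority_endpoint_membership: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_screening(
    registry: pd.DataFrame,
    measurements: pd.DataFrame,
    sites: pd.DataFrame,
    benchmarks: pd.DataFrame,
    acc: pd.DataFrame,
    aop_map: pd.DataFrame | None = None,
    config: ScreeningConfig | None = None,
) -> ScreeningResults:
    cfg = config or ScreeningConfig()
    site_ids = list(sites["site_id"])
    n_sites = len(site_ids)

    # porewater estimation and the two parallel quotient screens
    pw = porewater_table(measurements, registry, sites)
    sed_conc = quotients.sediment_concentrations(measurements)
    pw_conc = porewater_concentrations(pw)
    tqmax_sed = quotients.tq_max_table(sed_conc, benchmarks, "sediment")
    tqmax_pw = quotients.tq_max_table(pw_conc, benchmarks, "porewater")
    agg_sed = quotients.aggregate_tq(tqmax_sed, registry, site_ids)
    agg_pw = quotients.aggregate_tq(tqmax_pw, registry, site_ids)

    # exposure-activity ratios
    ear = ear_screen.compute_ear(pw, acc, registry)
    ear_agg = ear_screen.aggregate_ear(ear, registry, site_ids)
    endpoint_summary, endpoint_membership = ear_screen.priority_endpoints(
        ear,
        ear_agg["ear_endpoint"],
        n_sites,
        site_threshold=cfg.endpoint_site_threshold,
        prevalence=cfg.endpoint_prevalence,
        member_threshold=cfg.member_threshold,
        major_threshold=cfg.major_threshold,
    )
    if aop_map is not None and not aop_map.empty:
        endpoint_summary = ear_screen.annotate(endpoint_summary, aop_map)

    # mixture scores
    sum16 = mixtures.sum_pah16(measurements, registry, site_ids)
    pah = mixtures.pah_quotients(sum16, tec=cfg.tec, pec=cfg.pec)
    esb = mixtures.esbtu(measurements, sites, registry).set_index("site_id")
    teq = mixtures.alkylphenol_teq(measurements, registry, site_ids)
    toc = sites.set_index("site_id")["toc_percent"].reindex(site_ids)
    tq_ap = pd.Series(np.nan, index=pd.Index(site_ids, name="site_id"), name="tq_ap")
    valid_toc = toc > 0
    tq_ap[valid_toc] = mixtures.alkylphenol_tq(
        teq[valid_toc].to_numpy(), toc[valid_toc].to_numpy()
    )
    alkylphenol = pd.DataFrame({"teq": teq, "tq_ap": tq_ap})

    # chemical priority levels
    ear_max = ear_agg["ear_max"]
    chem_priority = prioritize.chemical_priority(
        tqmax_sed,
        tqmax_pw,
        ear_max,
        measurements,
        registry,
        n_sites,
        prevalence=cfg.chemical_prevalence,
    )

    # eight-method site priority table
    sed_counts_by_site = (
        tqmax_sed.loc[tqmax_sed["tq_max"] > 1.0]
        .groupby("site_id")["chemical_id"]
        .nunique()
    )
    pw_counts_by_site = (
        tqmax_pw.loc[tqmax_pw["tq_max"] > 1.0]
        .groupby("site_id")["chemical_id"]
        .nunique()
    )
    ear_counts_by_site = (
        ear_max.loc[ear_max["ear_max"] > 0.01]
        .groupby("site_id")["chemical_id"]
        .nunique()
    )

    method_values = pd.DataFrame(index=pd.Index(site_ids, name="site_id"))
    have_sed_bench = not tqmax_sed.empty
    have_pw_bench = not tqmax_pw.empty
    have_ear = not ear.empty
    method_values["sediment_tq_max"] = (
        sed_counts_by_site.reindex(site_ids, fill_value=0)
        if have_sed_bench
        else np.nan
    )
    method_values["porewater_tq_max"] = (
        pw_counts_by_site.reindex(site_ids, fill_value=0) if have_pw_bench else np.nan
    )
    method_values["ear_max"] = (
        ear_counts_by_site.reindex(site_ids, fill_value=0) if have_ear else np.nan
    )
    method_values["pah_mixture"] = [
        (pah.loc[s, "tecq"], pah.loc[s, "pecq"], esb["esbtu_sum"].get(s, np.nan))
        for s in site_ids
    ]
    method_values["alkylphenol_mixture"] = alkylphenol["tq_ap"]
    method_values["sediment_tq_sample"] = (
        agg_sed["tq_sample"].reindex(site_ids) if have_sed_bench else np.nan
    )
    method_values["porewater_tq_sample"] = (
        agg_pw["tq_sample"].reindex(site_ids) if have_pw_bench else np.nan
    )
    method_values["ear_sample"] = (
        ear_agg["ear_sample"].reindex(site_ids) if have_ear else np.nan
    )

    site_priority = prioritize.site_priority_table(method_values)
    ranked = prioritize.rank_sites(site_priority, agg_sed["tq_sample"])

    return ScreeningResults(
        porewater=pw,
        tqmax_sediment=tqmax_sed,
        tqmax_porewater=tqmax_pw,
        tq_aggregates_sediment=agg_sed,
        tq_aggregates_porewater=agg_pw,
        ear=ear,
        ear_aggregates=ear_agg,
        pah_mixture=pah,
        esb=esb.reset_index(),
        alkylphenol=alkylphenol.reset_index(),
        chemical_priority=chem_priority,
        site_priority=site_priority,
        ranked_sites=ranked,
        priority_endpoint_summary=endpoint_summary,
        priority_endpoint_membership=endpoint_membership,
        extras={"method_values": method_values},
    )


def run_study_screening(study, config: ScreeningConfig | None = None) -> ScreeningResults:
    """Convenience wrapper: screen a :class:`~sedsieve.synth.SyntheticStudy`."""
    return run_screening(
        study.registry,
        study.measurements,
        study.sites,
        study.benchmarks,
        study.acc,
        study.aop_map,
        config=config,
    )
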