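"""Equilibrium-partitioning porewater estimation.

The dissolved porewater concentration of a sediment-sorbed chemical is
estimated from its total sediment concentration with a single-phase
organic-carbon partitioning model::

    C_PW = C_SED / (K_OC * f_OC)

where C_PW is in µg/L, C_SED in µg/kg dry weight, K_OC is the chemical's
organic carbon-water partition coefficient (L/kg), and f_OC is the mass
fraction of organic carbon in the sediment sample.  No black-carbon or
salinity corrections are applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: porewater row statuses
STATUS_OK = "ok"
STATUS_NO_KOC = "no_koc"
STATUS_NO_TOC = "no_toc"
STATUS_CENSORED = "censored"


def foc_from_toc(toc_percent: float) -> float:
    """Convert total organic carbon in percent to a mass fraction in (0, 1]."""
    if not 0 < toc_percent <= 100:
        raise ValueError(f"toc_percent must be in (0, 100], got {toc_percent}")
    return toc_percent / 100.0


def estimate_porewater(c_sed, koc, foc):
    """C_SED (µg/kg) / (K_OC (L/kg) × f_OC) → C_PW (µg/L).  Vectorized."""
    c_sed = np.asarray(c_sed, dtype=float)
    koc = np.asarray(koc, dtype=float)
    foc = np.asarray(foc, dtype=float)
    if np.any(c_sed < 0):
        raise ValueError("sediment concentration must be non-negative")
    if np.any(koc <= 0):
        raise ValueError("koc must be positive")
    if np.any((foc <= 0) | (foc > 1)):
        raise ValueError("foc must be in (0, 1]")
    result = c_sed / (koc * foc)
    return float(result) if result.ndim == 0 else result


def porewater_table(
    measurements: pd.DataFrame,
    registry: pd.DataFrame,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Tablewise porewater estimate with per-row status.

    Statuses, in order of precedence:

    ``no_koc``
        the chemical has no partition coefficient; porewater cannot be
        estimated and the chemical is excluded from all porewater metrics
    ``no_toc``
        the site's organic-carbon content is missing or non-positive
    ``censored``
        concentration below the reporting limit; ``c_pw_ug_L`` is 0
    ``ok``
        ``c_pw_ug_L`` holds the equilibrium-partitioning estimate
    """
    df = measurements.merge(
        registry[["chemical_id", "koc_L_kg"]], on="chemical_id", how="left"
    ).merge(sites[["site_id", "toc_percent"]], on="site_id", how="left")

    no_koc = df["koc_L_kg"].isna()
    no_toc = df["toc_percent"].isna() | (df["toc_percent"] <= 0)
    censored = df["censored"].astype(bool)
    status = np.select(
        [no_koc, no_toc, censored],
        [STATUS_NO_KOC, STATUS_NO_TOC, STATUS_CENSORED],
        default=STATUS_OK,
    )

    ok = status == STATUS_OK
    c_pw = np.full(len(df), np.nan)
    c_pw[status == STATUS_CENSORED] = 0.0
    if ok.any():
        c_pw[ok] = estimate_porewater(
            df.loc[ok, "c_sed_ug_kg"].to_numpy(),
            df.loc[ok, "koc_L_kg"].to_numpy(),
            df.loc[ok, "toc_percent"].to_numpy() / 100.0,
        )

    return pd.DataFrame(
        {
            "site_id": df["site_id"],
            "chemical_id": df["chemical_id"],
            "c_pw_ug_L": c_pw,
            "status": status,
        }
    )


def porewater_concentrations(porewater: pd.DataFrame) -> pd.DataFrame:
    """Usable porewater rows (status ok or censored) as a concentration table.

    Returns columns ``site_id, chemical_id, conc, censored`` with censored
    rows carrying concentration 0, ready for quotient screening.
    """
    usable = porewater.loc[
        porewater["status"].isin([STATUS_OK, STATUS_CENSORED])
    ]
    return pd.DataFrame(
        {
            "site_id": usable["site_id"],
            "chemical_id": usable["chemical_id"],
            "conc": usable["c_pw_ug_L"].astype(float),
            "censored": (usable["status"] == STATUS_CENSORED).to_numpy(),
        }
    ).reset_index(drop=True)
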