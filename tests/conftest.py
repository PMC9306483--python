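import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sedsieve as sv

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_REGISTRY_DEFAULTS = {
    "name": None,
    "chem_class": "PAHs",
    "koc_L_kg": 10_000.0,
    "mw_g_mol": 200.0,
    "reporting_limit_ug_kg": 5.0,
    "tef": np.nan,
    "fcv_ug_gOC": np.nan,
    "is_pah16": False,
    "is_esb_pah": False,
    "is_alkylphenol": False,
}


def make_registry(rows):
    """Build a valid registry frame from partial row dicts."""
    full = []
    for row in rows:
        merged = dict(_REGISTRY_DEFAULTS, **row)
        if merged["name"] is None:
            merged["name"] = merged["chemical_id"]
        full.append(merged)
    return sv.tables_io.validate_registry(pd.DataFrame(full))


def make_measurements(rows):
    """rows: (site_id, chemical_id, conc, censored)."""
    return pd.DataFrame(
        rows, columns=["site_id", "chemical_id", "c_sed_ug_kg", "censored"]
    )


def make_benchmarks(rows):
    """rows: (chemical_id, medium, value)."""
    df = pd.DataFrame(rows, columns=["chemical_id", "medium", "value"])
    df["source"] = [f"src{i}" for i in range(len(df))]
    df["effect_label"] = "test"
    return sv.tables_io.validate_benchmarks(df)


@pytest.fixture(scope="session")
def default_study():
    return sv.generate_study(sv.SyntheticStudyConfig(seed=7))


@pytest.fixture(scope="session")
def default_results(default_study):
    return sv.run_study_screening(default_study)
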