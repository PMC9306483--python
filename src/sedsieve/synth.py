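"""Synthetic screening-study generator.

Generates complete, internally consistent studies — registry, measurements,
sites, benchmarks, bioassay ACC values, endpoint/gene/AOP map — together with
the ground truth that produced them, so every pipeline stage is testable
without any external data.

The generator emulates the statistical structure the screening analysis
assumes:

* a per-site contamination intensity drawn lognormally, with a few planted
  "hot" sites at a configurable multiplier;
* per-chemical lognormal sediment concentrations whose medians scale with
  both the site intensity and the chemical's organic-carbon partition
  coefficient, so that strongly sorbing (high-K_OC) chemicals are detected at
  most sites while weakly sorbing ones are mostly left-censored at their
  reporting limits;
* 1-7 benchmarks per screenable chemical spanning up to a configurable
  spread (default one order of magnitude);
* multiple assay endpoints per chemical with ACC values in µM or µg/L, a few
  chemicals fully excluded for data-quality reasons;
* one watershed attribute constructed with a configurable rank correlation
  to the contamination gradient, plus uncorrelated nuisance attributes.

All randomness flows from one master seed; each table draws from its own
deterministic substream, so regenerating one table never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import tables_io
from .tables_io import CHEM_CLASSES, detection_frequency

#: per-class chemical counts of the emulated 87-chemical analyte list
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "antimicrobial disinfectants": 5,
    "antioxidants": 1,
    "detergent metabolites": 8,
    "dyes and pigments": 1,
    "fire retardants": 4,
    "flavors and fragrances": 10,
    "fuels": 4,
    "herbicides": 4,
    "insecticides": 4,
    "nonprescription drugs": 1,
    "PAHs": 36,
    "plasticizers": 4,
    "solvents": 1,
    "sterols": 4,
}

#: nine gene targets used as the endpoint/annotation vocabulary
GENE_VOCABULARY = (
    "ESR1", "AR", "AHR", "PPARG", "NR1I2", "TP53", "THRB", "VDR", "HIF1A",
)


@dataclass
class SyntheticStudyConfig:
    """Configuration of one synthetic study.

    Defaults reproduce the emulated study design: 71 sites, 87 chemicals in
    14 classes, 3 hot sites at 10x the background contamination gradient, and
    a detection model in which chemicals above the median K_OC are detected
    at almost every site while those below are rarely detected.
    """

    n_sites: int = 71
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    #: site contamination intensity ~ intensity_scale × lognormal(median 1, sigma)
    intensity_scale: float = 1.0
    intensity_sigma: float = 0.35
    #: K_OC drawn log-uniformly over 10^a..10^b L/kg
    koc_log10_range: tuple[float, float] = (2.0, 5.2)
    #: chemicals whose K_OC is withheld from the registry (porewater blocked)
    n_missing_koc: int = 4
    #: decades of median concentration per decade of K_OC above/below median
    detection_slope: float = 1.0
    #: within-chemical lognormal concentration noise, ln-units
    concentration_sigma: float = 1.0
    #: reporting limits drawn log-uniformly over this range, µg/kg
    reporting_limit_range: tuple[float, float] = (1.0, 50.0)
    #: fraction of chemicals with sediment / porewater benchmarks
    sediment_benchmark_frac: float = 56 / 87
    porewater_benchmark_frac: float = 56 / 87
    benchmarks_per_chemical: tuple[int, int] = (1, 7)
    benchmark_spread: float = 10.0
    #: fraction of chemicals present in the bioassay table, and how many of
    #: those are fully excluded by data-quality flags
    acc_frac: float = 59 / 87
    n_excluded_acc_chemicals: int = 6
    endpoints_per_chemical: tuple[int, int] = (2, 12)
    n_endpoints_vocab: int = 30
    #: TOC lognormal (median, sigma ln-units), clipped to ``toc_range``, percent
    toc_median: float = 2.0
    toc_sigma: float = 0.5
    toc_range: tuple[float, float] = (0.2, 10.0)
    #: target rank correlation between the lead attribute and contamination
    attr_rho: float = 0.6
    n_hot_sites: int = 3
    hot_multiplier: float = 10.0
    #: duplicate-sample coefficient of variation for the QC table
    duplicate_cv: float = 0.2
    n_duplicate_sites: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not self.class_counts or any(v < 1 for v in self.class_counts.values()):
            raise ValueError("class_counts must be positive")
        unknown = set(self.class_counts) - set(CHEM_CLASSES)
        if unknown:
            raise ValueError(f"unknown chemical class(es): {sorted(unknown)}")
        if self.intensity_sigma <= 0 or self.concentration_sigma <= 0:
            raise ValueError("sigmas must be positive")
        if self.intensity_scale < 0:
            raise ValueError("intensity_scale must be non-negative")
        if self.benchmark_spread < 1:
            raise ValueError("benchmark_spread must be >= 1")
        if not 0 <= self.attr_rho <= 1:
            raise ValueError("attr_rho must be in [0, 1]")
        if self.n_hot_sites < 0 or self.n_hot_sites > self.n_sites:
            raise ValueError("n_hot_sites out of range")
        if self.hot_multiplier <= 0:
            raise ValueError("hot_multiplier must be positive")
        lo, hi = self.benchmarks_per_chemical
        if not 1 <= lo <= hi:
            raise ValueError("benchmarks_per_chemical range invalid")
        lo, hi = self.toc_range
        if not 0 < lo <= hi <= 100:
            raise ValueError("toc_range invalid")
        if not lo <= self.toc_median <= hi or self.toc_sigma <= 0:
            raise ValueError("toc_median/toc_sigma invalid")


@dataclass
class SyntheticStudy:
    """A generated study: the six input tables, QC duplicates, ground truth."""

    registry: pd.DataFrame
    measurements: pd.DataFrame
    sites: pd.DataFrame
    benchmarks: pd.DataFrame
    acc: pd.DataFrame
    aop_map: pd.DataFrame
    duplicates: pd.DataFrame
    ground_truth: dict


def _slug(label: str) -> str:
    return label.replace(" ", "_")


def _log_uniform(rng: np.random.Generator, low: float, high: float, size) -> np.ndarray:
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def generate_study(cfg: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a complete study, deterministic given ``cfg.seed``."""
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    rng_reg, rng_sites, rng_meas, rng_bench, rng_acc, rng_aop, rng_dup = (
        np.random.default_rng(s) for s in streams
    )

    # ---- registry -------------------------------------------------------
    classes = [
        chem_class
        for chem_class in CHEM_CLASSES
        if chem_class in cfg.class_counts
        for _ in range(cfg.class_counts[chem_class])
    ]
    n_chem = len(classes)
    chem_ids = []
    per_class_counter: dict[str, int] = {}
    for chem_class in classes:
        per_class_counter[chem_class] = per_class_counter.get(chem_class, 0) + 1
        chem_ids.append(f"{_slug(chem_class)}_{per_class_counter[chem_class]:02d}")

    log10_koc = rng_reg.uniform(*cfg.koc_log10_range, n_chem)
    koc = 10.0 ** log10_koc
    mw = rng_reg.uniform(94.0, 400.0, n_chem)
    reporting_limit = _log_uniform(rng_reg, *cfg.reporting_limit_range, n_chem)

    is_pah = np.array([c == "PAHs" for c in classes])
    pah_idx = np.flatnonzero(is_pah)
    is_pah16 = np.zeros(n_chem, dtype=bool)
    is_pah16[pah_idx[:16]] = True
    is_esb = np.zeros(n_chem, dtype=bool)
    # the ESB member set excludes one alkylated PAH from the full PAH list
    is_esb[pah_idx[:-1] if len(pah_idx) > 1 else pah_idx] = True

    is_ap = np.array([c == "detergent metabolites" for c in classes])
    tef = np.full(n_chem, np.nan)
    ap_idx = np.flatnonzero(is_ap)
    if ap_idx.size:
        tef[ap_idx] = 0.5
        tef[ap_idx[0]] = 1.0  # the reference compound of the TEQ

    fcv = np.full(n_chem, np.nan)
    fcv[is_esb] = _log_uniform(rng_reg, 5.0, 500.0, int(is_esb.sum()))

    koc_reported = koc.copy()
    if cfg.n_missing_koc:
        missing = rng_reg.choice(n_chem, size=min(cfg.n_missing_koc, n_chem), replace=False)
        koc_reported[missing] = np.nan

    registry = tables_io.validate_registry(
        pd.DataFrame(
            {
                "chemical_id": chem_ids,
                "name": [c.replace("_", " ") for c in chem_ids],
                "chem_class": classes,
                "koc_L_kg": koc_reported,
                "mw_g_mol": mw,
                "reporting_limit_ug_kg": reporting_limit,
                "tef": tef,
                "fcv_ug_gOC": fcv,
                "is_pah16": is_pah16,
                "is_esb_pah": is_esb,
                "is_alkylphenol": is_ap,
            }
        )
    )

    # ---- sites ----------------------------------------------------------
    site_ids = [f"S{i + 1:03d}" for i in range(cfg.n_sites)]
    intensity = cfg.intensity_scale * np.exp(
        rng_sites.normal(0.0, cfg.intensity_sigma, cfg.n_sites)
    )
    hot_sites = sorted(
        rng_sites.choice(cfg.n_sites, size=cfg.n_hot_sites, replace=False).tolist()
    )
    intensity[hot_sites] *= cfg.hot_multiplier
    toc = np.clip(
        cfg.toc_median * np.exp(rng_sites.normal(0.0, cfg.toc_sigma, cfg.n_sites)),
        *cfg.toc_range,
    )

    # Gaussian-copula attribute with rank correlation ~ attr_rho to intensity
    z_int = stats.norm.ppf(
        (stats.rankdata(intensity) - 0.5) / cfg.n_sites
    )
    rho = cfg.attr_rho
    z_attr = rho * z_int + np.sqrt(1 - rho**2) * rng_sites.normal(size=cfg.n_sites)
    population_density = 200.0 * np.exp(z_attr)  # people/km², median 200
    impervious = np.clip(
        15.0 + 12.0 * (0.5 * z_int + np.sqrt(0.75) * rng_sites.normal(size=cfg.n_sites)),
        0.2,
        75.0,
    )
    agriculture = rng_sites.uniform(0.0, 90.0, cfg.n_sites)  # uncorrelated

    sites = tables_io.validate_sites(
        pd.DataFrame(
            {
                "site_id": site_ids,
                "toc_percent": toc,
                "population_density_per_km2": population_density,
                "impervious_pct": impervious,
                "agriculture_pct": agriculture,
            }
        )
    )

    # ---- measurements ---------------------------------------------------
    # median concentration scales with site intensity and with K_OC: a
    # chemical one decade above the median K_OC has a detection_slope-decade
    # higher median concentration relative to its reporting limit
    koc_center = np.mean(cfg.koc_log10_range)
    baseline = reporting_limit * 10.0 ** (
        cfg.detection_slope * (log10_koc - koc_center)
    )
    noise = rng_meas.normal(0.0, cfg.concentration_sigma, (cfg.n_sites, n_chem))
    conc = intensity[:, None] * baseline[None, :] * np.exp(noise)
    censored = conc < reporting_limit[None, :]
    conc = np.where(censored, 0.0, conc)

    measurements = pd.DataFrame(
        {
            "site_id": np.repeat(site_ids, n_chem),
            "chemical_id": np.tile(chem_ids, cfg.n_sites),
            "c_sed_ug_kg": conc.ravel(),
            "censored": censored.ravel(),
        }
    )
    measurements = tables_io.normalize_measurements(measurements, registry)

    # ---- benchmarks -----------------------------------------------------
    foc_typ = cfg.toc_median / 100.0
    baseline_pw = baseline / (koc * foc_typ)
    bench_rows = []
    lo, hi = cfg.benchmarks_per_chemical
    spread_decades = np.log10(cfg.benchmark_spread)
    for medium, frac, anchor in (
        ("sediment", cfg.sediment_benchmark_frac, baseline),
        ("porewater", cfg.porewater_benchmark_frac, baseline_pw),
    ):
        n_with = int(round(frac * n_chem))
        which = rng_bench.choice(n_chem, size=n_with, replace=False)
        for idx in which:
            n_b = int(rng_bench.integers(lo, hi + 1))
            lowest = anchor[idx] * np.exp(rng_bench.normal(np.log(3.0), 1.0))
            offsets = np.concatenate(
                [[0.0], rng_bench.uniform(0.0, spread_decades, n_b - 1)]
            )
            for j, off in enumerate(offsets):
                bench_rows.append(
                    {
                        "chemical_id": chem_ids[idx],
                        "medium": medium,
                        "value": lowest * 10.0**off,
                        "source": f"synthetic-{medium}-{j}",
                        "effect_label": "chronic" if j % 2 else "threshold",
                    }
                )
    benchmarks = tables_io.validate_benchmarks(pd.DataFrame(bench_rows))

    # ---- bioassay ACC values -------------------------------------------
    endpoint_vocab = [
        f"ASSAY_{GENE_VOCABULARY[i % len(GENE_VOCABULARY)]}_{i:02d}"
        for i in range(cfg.n_endpoints_vocab)
    ]
    endpoint_gene = {
        e: GENE_VOCABULARY[i % len(GENE_VOCABULARY)]
        for i, e in enumerate(endpoint_vocab)
    }
    n_acc_chems = int(round(cfg.acc_frac * n_chem))
    acc_chems = rng_acc.choice(n_chem, size=n_acc_chems, replace=False)
    excluded_chems = set(
        rng_acc.choice(
            acc_chems,
            size=min(cfg.n_excluded_acc_chemicals, n_acc_chems),
            replace=False,
        ).tolist()
    )
    acc_rows = []
    e_lo, e_hi = cfg.endpoints_per_chemical
    for idx in acc_chems:
        n_e = int(rng_acc.integers(e_lo, min(e_hi, cfg.n_endpoints_vocab) + 1))
        chosen = rng_acc.choice(cfg.n_endpoints_vocab, size=n_e, replace=False)
        potency = np.exp(rng_acc.normal(np.log(300.0), 2.0))  # per-chemical
        for e_idx in chosen:
            acc_ug_L = baseline_pw[idx] * potency * np.exp(rng_acc.normal(0.0, 1.0))
            in_micromolar = rng_acc.random() < 0.7
            excluded = idx in excluded_chems
            acc_rows.append(
                {
                    "chemical_id": chem_ids[idx],
                    "endpoint_id": endpoint_vocab[e_idx],
                    "acc_value": acc_ug_L / mw[idx] if in_micromolar else acc_ug_L,
                    "acc_unit": "micromolar" if in_micromolar else "ug_L",
                    "gene_symbol": endpoint_gene[endpoint_vocab[e_idx]],
                    "excluded": excluded,
                    "exclusion_reason": "data quality flag" if excluded else "",
                }
            )
    acc = tables_io.validate_acc(pd.DataFrame(acc_rows))

    # ---- AOP map (sparse; some endpoints deliberately unmapped) ---------
    aop_rows = []
    for i, endpoint in enumerate(endpoint_vocab):
        if rng_aop.random() < 0.8:
            n_aop = int(rng_aop.integers(1, 4))
            aops = sorted(
                f"AOP:{int(a)}" for a in rng_aop.choice(200, size=n_aop, replace=False)
            )
            aop_rows.append(
                {
                    "endpoint_id": endpoint,
                    "gene_symbol": endpoint_gene[endpoint],
                    "aop_ids": ";".join(aops),
                    "annotation": f"synthetic annotation {i}",
                }
            )
    aop_map = tables_io.validate_aop_map(pd.DataFrame(aop_rows))

    # ---- QC duplicates --------------------------------------------------
    dup_rows = []
    sigma_dup = np.sqrt(np.log(1 + cfg.duplicate_cv**2))
    for s in range(min(cfg.n_duplicate_sites, cfg.n_sites)):
        detected = (~censored[s]) .nonzero()[0]
        for idx in detected[:10]:
            base = conc[s, idx]
            dup_rows.append(
                {
                    "site_id": site_ids[s],
                    "chemical_id": chem_ids[idx],
                    "c_sed_a_ug_kg": base,
                    "c_sed_b_ug_kg": base * np.exp(rng_dup.normal(0.0, sigma_dup)),
                }
            )
    duplicates = pd.DataFrame(
        dup_rows,
        columns=["site_id", "chemical_id", "c_sed_a_ug_kg", "c_sed_b_ug_kg"],
    )

    ground_truth = {
        "seed": cfg.seed,
        "hot_sites": [site_ids[i] for i in hot_sites],
        "hot_multiplier": cfg.hot_multiplier,
        "site_intensity": dict(zip(site_ids, intensity.tolist())),
        "latent_koc_L_kg": dict(zip(chem_ids, koc.tolist())),
        "n_chemicals": n_chem,
    }
    return SyntheticStudy(
        registry=registry,
        measurements=measurements,
        sites=sites,
        benchmarks=benchmarks,
        acc=acc,
        aop_map=aop_map,
        duplicates=duplicates,
        ground_truth=ground_truth,
    )


def koc_detection_summary(study: SyntheticStudy) -> dict:
    """Median detection frequency of chemicals above vs below the median K_OC.

    Chemicals without a reported K_OC are ignored.  With fewer than two
    chemicals carrying a K_OC the summary degenerates to a single group.
    """
    n_sites = study.sites["site_id"].nunique()
    freq = detection_frequency(
        study.measurements, n_sites, chemicals=study.registry["chemical_id"]
    )
    reg = study.registry.set_index("chemical_id")
    with_koc = reg["koc_L_kg"].dropna()
    if with_koc.empty:
        return {"median_koc_L_kg": float("nan")}
    median_koc = float(with_koc.median())
    above = freq[with_koc[with_koc > median_koc].index]
    below = freq[with_koc[with_koc <= median_koc].index]
    summary = {"median_koc_L_kg": median_koc}
    if len(above):
        summary["above_median_detection"] = float(above.median())
    if len(below):
        summary["below_median_detection"] = float(below.median())
    return summary


# ---------------------------------------------------------------------------
# round-tripping a study through the canonical CSV files
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "registry": "registry.csv",
    "measurements": "measurements.csv",
    "sites": "sites.csv",
    "benchmarks": "benchmarks.csv",
    "acc": "acc.csv",
    "aop_map": "aop_map.csv",
    "duplicates": "duplicates.csv",
}


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the study's tables as canonical CSVs plus ``ground_truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, filename in _TABLE_FILES.items():
        getattr(study, attr).to_csv(outdir / filename, index=False)
    (outdir / "ground_truth.json").write_text(
        json.dumps(study.ground_truth, indent=2, sort_keys=True)
    )


def load_study(directory) -> SyntheticStudy:
    """Read a study back from :func:`write_study` output, re-validating."""
    directory = Path(directory)
    registry = tables_io.load_registry(directory / "registry.csv")
    ground_truth_path = directory / "ground_truth.json"
    return SyntheticStudy(
        registry=registry,
        measurements=tables_io.load_measurements(
            directory / "measurements.csv", registry
        ),
        sites=tables_io.load_sites(directory / "sites.csv"),
        benchmarks=tables_io.load_benchmarks(directory / "benchmarks.csv"),
        acc=tables_io.load_acc(directory / "acc.csv"),
        aop_map=tables_io.load_aop_map(directory / "aop_map.csv"),
        duplicates=(
            pd.read_csv(directory / "duplicates.csv")
            if (directory / "duplicates.csv").exists()
            else pd.DataFrame()
        ),
        ground_truth=(
            json.loads(ground_truth_path.read_text())
            if ground_truth_path.exists()
            else {}
        ),
    )


def config_to_dict(cfg: SyntheticStudyConfig) -> dict:
    return dataclasses.asdict(cfg)
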