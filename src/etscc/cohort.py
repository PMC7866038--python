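"""Synthetic colorectal-liver-metastasis cohorts.

No patient-level data accompany the study design this package implements, so
testing the pipeline end to end requires cohorts that emulate its statistical
structure: serum CEA rising linearly with the largest lesion size, tumor
perfusion (BVF surrogate) falling linearly with size, FOLFOX-style dosing, and
a pathologic Tumor Regression Grade driven by the tumor-site drug
concentration through an ordinal link (higher eTSCC -> lower TRG, i.e. better
response).  Two entry points:

* :func:`generate_cohort` — stochastic cohorts of any size from a
  :class:`CohortConfig`, reproducible under a seed;
* :func:`fixture_cohort` — one deterministic 33-patient cohort whose marginal
  counts and medians reproduce the published cohort table exactly (20 male /
  13 female; primary site 12/12/9; 29 synchronous; 11 with extrahepatic
  disease; TRG counts 2/4/8/13/6; regimens 25/1/7; medians: age 57, lesion
  count 2, largest lesion 3.2 cm, CEA 13.4 ng/mL, 4 cycles).

CT ROI rows are back-computed so that the trapezoidal enhancement-AUC ratio of
the written Hounsfield units returns exactly the BVF each patient was
generated with: the liver enhancement curve is fixed and the tumor curve is
the liver curve scaled by BVF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .pk import PKParameters, Regimen, analytic_cycle, exposure_summary
from .perfusion import DEFAULT_PHASE_TIMES
from .transport import DEFAULT_CEA_REF, TumorBurden, fkill0_surrogate, etscc

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "fixture_cohort",
    "table1_marginals",
    "audit_fixture",
    "COHORT_COLUMNS",
]

#: Fixed healthy-liver enhancement template: baseline 55 HU, arterial +70,
#: portal-venous +60 (trapezoid AUC 3500 HU*s on the default phase times).
LIVER_HU = (55.0, 125.0, 115.0)
TUMOR_BASELINE_HU = 45.0

COHORT_COLUMNS = [
    "patient_id", "age", "gender", "primary_site", "presentation",
    "lesion_count", "extrahepatic", "size_cm", "cea", "bsa", "regimen",
    "bolus_mg_per_m2", "infusion_mg_per_m2", "infusion_hours", "n_cycles",
    "span_hours", "interval_hours", "trg",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the study conditions.

    CEA (ng/mL) is linear in lesion size (cm) with truncation at 1; the BVF
    surrogate is linear-decreasing in size, clamped to (bvf_floor, bvf_cap);
    TRG comes from descending thresholds on log-eTSCC plus Gaussian noise
    (``trg_noise`` -> infinity decouples TRG from eTSCC entirely).
    """

    n: int = 33
    seed: int = 0
    size_range: tuple = (1.0, 10.0)
    cea_slope: float = 4.0
    cea_intercept: float = 0.6
    cea_noise: float = 5.0
    perf_intercept: float = 0.45
    perf_slope: float = 0.035
    perf_noise: float = 0.05
    bvf_floor: float = 0.01
    bvf_cap: float = 0.99
    trg_thresholds: tuple = (-1.3, -2.35, -3.35, -4.8)
    trg_noise: float = 0.9
    regimen_mix: tuple = (25 / 33, 1 / 33, 7 / 33)
    bsa_mean: float = 1.8
    bsa_sd: float = 0.2
    cycle_probs: tuple = (0.08, 0.12, 0.17, 0.20, 0.17, 0.10, 0.08, 0.05, 0.03)
    interval_hours: float = 336.0
    infusion_hours: float = 46.0
    bolus_mg_per_m2: float = 400.0
    infusion_mg_per_m2: float = 2400.0
    lag_range_hours: tuple = (336.0, 1344.0)
    cea_ref: float = DEFAULT_CEA_REF

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.regimen_mix) - 1.0) > 1e-9:
            raise ValueError("regimen_mix proportions must sum to 1")
        if min(self.cea_noise, self.perf_noise, self.trg_noise) < 0:
            raise ValueError("noise SDs must be non-negative")
        if len(self.trg_thresholds) != 4 or np.any(np.diff(self.trg_thresholds) >= 0):
            raise ValueError("trg_thresholds must be 4 strictly decreasing values")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        for key in ("size_range", "trg_thresholds", "regimen_mix",
                    "cycle_probs", "lag_range_hours"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def _sigma_dbar(bsa: float, cfg_or_regimen) -> float:
    """Regimen-average plasma concentration via the analytic PK path."""
    if isinstance(cfg_or_regimen, Regimen):
        reg = cfg_or_regimen
    else:
        cfg = cfg_or_regimen
        reg = Regimen(bsa=bsa, bolus_mg_per_m2=cfg.bolus_mg_per_m2,
                      infusion_mg_per_m2=cfg.infusion_mg_per_m2,
                      infusion_hours=cfg.infusion_hours,
                      interval_hours=cfg.interval_hours,
                      span_hours=cfg.interval_hours)
    prof = analytic_cycle(PKParameters(), reg, grid_step=0.01)
    return exposure_summary([prof], reg).sigma_dbar


def _ct_rows(patient_id: str, bvf: float) -> list[dict]:
    """Long-format CT ROI rows whose enhancement-AUC ratio is exactly bvf."""
    rows = []
    liver_delta = (0.0, LIVER_HU[1] - LIVER_HU[0], LIVER_HU[2] - LIVER_HU[0])
    for site, base, delta in (
        ("liver", LIVER_HU[0], liver_delta),
        ("tumor", TUMOR_BASELINE_HU, tuple(bvf * d for d in liver_delta)),
    ):
        for phase, t, d in zip(("noncontrast", "arterial", "portal"),
                               DEFAULT_PHASE_TIMES, delta):
            rows.append({
                "patient_id": patient_id, "site": site, "phase": phase,
                "time_s": t, "mean_hu": round(base + d, 4), "sd_hu": 8.0,
            })
    return rows


def _trg_from_etscc(log_etscc: np.ndarray, noise: np.ndarray,
                    thresholds: tuple) -> np.ndarray:
    """Ordinal draw: TRG = 1 + number of thresholds the noisy log-eTSCC falls
    below (thresholds descending, so higher eTSCC -> lower TRG)."""
    u = log_etscc + noise
    trg = np.ones(u.size, dtype=int)
    for c in thresholds:
        trg += (u < c).astype(int)
    return trg


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort; returns (cohort table, CT ROI table).

    All randomness flows from one ``numpy`` generator seeded by
    ``seed`` (falling back to ``config.seed``), so identical inputs give
    identical cohorts.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n

    size = rng.uniform(*cfg.size_range, n)
    cea = cfg.cea_intercept + cfg.cea_slope * size + rng.normal(0.0, cfg.cea_noise, n)
    cea = np.clip(cea, 1.0, None)
    bvf_raw = (cfg.perf_intercept - cfg.perf_slope * size
               + rng.normal(0.0, cfg.perf_noise, n))
    bvf = np.clip(bvf_raw, cfg.bvf_floor, cfg.bvf_cap)
    clamp_rate = np.mean(bvf_raw != bvf)
    if clamp_rate > 0.5:
        raise ValueError(
            f"perfusion clamping rate {clamp_rate:.0%} exceeds 50%; "
            "config places most of the BVF mass outside (0, 1)"
        )
    bsa = np.clip(rng.normal(cfg.bsa_mean, cfg.bsa_sd, n), 1.3, 2.4)
    n_cycles = rng.choice(np.arange(1, 10), size=n, p=cfg.cycle_probs)
    lag = rng.uniform(*cfg.lag_range_hours, n)
    span = (n_cycles - 1) * cfg.interval_hours + cfg.infusion_hours + lag
    regimen = rng.choice(["FOLFOX", "FOLFIRI", "combination"], size=n,
                         p=cfg.regimen_mix)

    sigma_dbar = np.array([_sigma_dbar(b, cfg) for b in bsa])
    sigma_t = np.empty(n)
    for i in range(n):
        stb, _ = fkill0_surrogate(sigma_dbar[i], int(n_cycles[i]), float(span[i]),
                                  cfg.infusion_hours,
                                  TumorBurden(cea=float(cea[i]), cea_ref=cfg.cea_ref))
        sigma_t[i] = etscc(stb, float(bvf[i]))

    noise = (rng.normal(0.0, cfg.trg_noise, n) if np.isfinite(cfg.trg_noise)
             else rng.normal(0.0, 1.0, n) * 1e9)
    trg = _trg_from_etscc(np.log(sigma_t), noise, cfg.trg_thresholds)

    age = np.clip(np.round(rng.normal(60.0, 10.0, n)), 35, 90).astype(int)
    gender = rng.choice(["male", "female"], size=n, p=(20 / 33, 13 / 33))
    site = rng.choice(["right_colon", "left_colon", "rectum"], size=n,
                      p=(12 / 33, 12 / 33, 9 / 33))
    presentation = rng.choice(["synchronous", "metachronous"], size=n,
                              p=(29 / 33, 4 / 33))
    extrahepatic = rng.random(n) < 11 / 33
    lesions = rng.choice(np.arange(1, 6), size=n, p=(0.30, 0.30, 0.20, 0.12, 0.08))

    ids = [f"P{i + 1:04d}" for i in range(n)]
    cohort = pd.DataFrame({
        "patient_id": ids, "age": age, "gender": gender, "primary_site": site,
        "presentation": presentation, "lesion_count": lesions,
        "extrahepatic": extrahepatic, "size_cm": np.round(size, 3),
        "cea": np.round(cea, 3), "bsa": np.round(bsa, 3), "regimen": regimen,
        "bolus_mg_per_m2": cfg.bolus_mg_per_m2,
        "infusion_mg_per_m2": cfg.infusion_mg_per_m2,
        "infusion_hours": cfg.infusion_hours, "n_cycles": n_cycles,
        "span_hours": np.round(span, 1), "interval_hours": cfg.interval_hours,
        "trg": trg,
    })[COHORT_COLUMNS]
    ct = pd.DataFrame(
        [row for pid, b in zip(ids, bvf) for row in _ct_rows(pid, float(b))]
    )
    return cohort, ct


# ---------------------------------------------------------------------------
# deterministic fixture
# ---------------------------------------------------------------------------

_FIX_SIZES = (1.0, 1.2, 1.5, 1.7, 1.9, 2.1, 2.3, 2.5, 2.6, 2.7, 2.8, 2.9, 3.0,
              3.0, 3.1, 3.1, 3.2, 3.3, 3.5, 3.7, 4.0, 4.2, 4.5, 4.8, 5.2, 5.6,
              6.0, 6.5, 7.0, 7.6, 8.2, 9.0, 10.0)
_FIX_AGES = (42, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53, 54, 55, 55, 56, 56,
             57, 58, 59, 60, 61, 62, 63, 64, 66, 68, 70, 72, 74, 76, 78, 80, 83)
_FIX_LESIONS = (1,) * 9 + (2,) * 9 + (3,) * 8 + (4,) * 4 + (5,) * 3
_FIX_CYCLES = (1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4, 4, 4,
               5, 5, 5, 5, 5, 6, 6, 6, 7, 7, 8, 8, 9)
_FIX_TRG_COUNTS = {1: 2, 2: 4, 3: 8, 4: 13, 5: 6}


def fixture_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 33-patient cohort reproducing the published marginals.

    Sizes, ages, lesion counts and cycle numbers are fixed sorted sequences
    with the published medians and ranges; CEA is exactly linear in size
    (median 13.4 at the median size 3.2 cm) and the BVF surrogate exactly
    linear-decreasing in size, so the pairwise correlation directions hold
    with no noise.  TRG is assigned by descending eTSCC rank in the published
    grade counts 2/4/8/13/6, i.e. the best-perfused, most-exposed tumors get
    the best grades.  Categorical fields are laid out in a fixed interleaved
    order; a fixed-seed shuffle decouples them from tumor size.
    """
    n = 33
    rng = np.random.default_rng(20160433)  # fixture-internal, never varied
    size = np.array(_FIX_SIZES)
    cea = np.round(0.6 + 4.0 * size, 1)  # median: 0.6 + 4*3.2 = 13.4
    bvf = np.round(0.45 - 0.035 * size, 4)

    age = np.array(_FIX_AGES)[rng.permutation(n)]
    lesions = np.array(_FIX_LESIONS)[rng.permutation(n)]
    n_cycles = np.array(_FIX_CYCLES)[rng.permutation(n)]
    gender = np.array(["male"] * 20 + ["female"] * 13)[rng.permutation(n)]
    site = np.array(["right_colon"] * 12 + ["left_colon"] * 12
                    + ["rectum"] * 9)[rng.permutation(n)]
    presentation = np.array(["synchronous"] * 29
                            + ["metachronous"] * 4)[rng.permutation(n)]
    extrahepatic = np.array([True] * 11 + [False] * 22)[rng.permutation(n)]
    regimen = np.array(["FOLFOX"] * 25 + ["FOLFIRI"] * 1
                       + ["combination"] * 7)[rng.permutation(n)]
    bsa = np.round(1.55 + 0.5 * (np.arange(n)[rng.permutation(n)] / (n - 1)), 3)

    interval, infusion = 336.0, 46.0
    span = (n_cycles - 1) * interval + infusion + 672.0  # surgery 4 weeks post-end

    sigma_t = np.empty(n)
    for i in range(n):
        sd = _sigma_dbar(float(bsa[i]), CohortConfig())
        stb, _ = fkill0_surrogate(sd, int(n_cycles[i]), float(span[i]), infusion,
                                  TumorBurden(cea=float(cea[i])))
        sigma_t[i] = etscc(stb, float(bvf[i]))

    # best response (lowest TRG) to the highest tumor-site concentrations
    order = np.argsort(-sigma_t)
    trg = np.empty(n, dtype=int)
    grades = [g for g, c in sorted(_FIX_TRG_COUNTS.items()) for _ in range(c)]
    trg[order] = grades

    ids = [f"F{i + 1:04d}" for i in range(n)]
    cohort = pd.DataFrame({
        "patient_id": ids, "age": age, "gender": gender, "primary_site": site,
        "presentation": presentation, "lesion_count": lesions,
        "extrahepatic": extrahepatic, "size_cm": size, "cea": cea,
        "bsa": bsa, "regimen": regimen, "bolus_mg_per_m2": 400.0,
        "infusion_mg_per_m2": 2400.0, "infusion_hours": infusion,
        "n_cycles": n_cycles, "span_hours": span, "interval_hours": interval,
        "trg": trg,
    })[COHORT_COLUMNS]
    ct = pd.DataFrame(
        [row for pid, b in zip(ids, bvf) for row in _ct_rows(pid, float(b))]
    )
    return cohort, ct


def table1_marginals() -> dict:
    """Published cohort marginals the fixture must reproduce."""
    return {
        "n": 33,
        "male": 20,
        "female": 13,
        "right_colon": 12,
        "left_colon": 12,
        "rectum": 9,
        "synchronous": 29,
        "extrahepatic": 11,
        "trg_counts": {1: 2, 2: 4, 3: 8, 4: 13, 5: 6},
        "regimen_counts": {"FOLFOX": 25, "FOLFIRI": 1, "combination": 7},
        "median_age": 57,
        "age_range": (42, 83),
        "median_lesions": 2,
        "lesions_range": (1, 5),
        "median_size_cm": 3.2,
        "size_range_cm": (1.0, 10.0),
        "median_cea": 13.4,
        "median_cycles": 4,
        "cycles_range": (1, 9),
    }


def audit_fixture(cohort: pd.DataFrame) -> list[str]:
    """Compare a cohort against every published marginal; returns mismatches
    (empty list when the fixture is faithful)."""
    t = table1_marginals()
    issues = []

    def check(name, got, want):
        if got != want:
            issues.append(f"{name}: got {got!r}, want {want!r}")

    check("n", len(cohort), t["n"])
    g = cohort["gender"].value_counts()
    check("male", int(g.get("male", 0)), t["male"])
    check("female", int(g.get("female", 0)), t["female"])
    s = cohort["primary_site"].value_counts()
    for k in ("right_colon", "left_colon", "rectum"):
        check(k, int(s.get(k, 0)), t[k])
    check("synchronous",
          int((cohort["presentation"] == "synchronous").sum()), t["synchronous"])
    check("extrahepatic", int(cohort["extrahepatic"].sum()), t["extrahepatic"])
    trg_counts = cohort["trg"].value_counts().to_dict()
    for grade, want in t["trg_counts"].items():
        check(f"trg{grade}", int(trg_counts.get(grade, 0)), want)
    reg = cohort["regimen"].value_counts()
    for k, want in t["regimen_counts"].items():
        check(f"regimen_{k}", int(reg.get(k, 0)), want)
    check("median_age", float(cohort["age"].median()), float(t["median_age"]))
    check("age_range", (int(cohort["age"].min()), int(cohort["age"].max())),
          t["age_range"])
    check("median_lesions", float(cohort["lesion_count"].median()),
          float(t["median_lesions"]))
    check("lesions_range",
          (int(cohort["lesion_count"].min()), int(cohort["lesion_count"].max())),
          t["lesions_range"])
    check("median_size_cm", float(cohort["size_cm"].median()), t["median_size_cm"])
    check("size_range_cm",
          (float(cohort["size_cm"].min()), float(cohort["size_cm"].max())),
          t["size_range_cm"])
    check("median_cea", float(cohort["cea"].median()), t["median_cea"])
    check("median_cycles", float(cohort["n_cycles"].median()),
          float(t["median_cycles"]))
    check("cycles_range",
          (int(cohort["n_cycles"].min()), int(cohort["n_cycles"].max())),
          t["cycles_range"])
    return issues
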