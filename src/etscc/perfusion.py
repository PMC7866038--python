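"""Tumor blood volume fraction (BVF) from three-phase CT enhancement.

Colorectal liver metastases are hypovascular relative to liver parenchyma, and
their perfusion can be summarised from routine three-phase contrast CT
(non-contrast, arterial, portal-venous) without any deconvolution: the mean
Hounsfield units of a region of interest, baseline-subtracted and integrated
over the phase times, give an enhancement AUC.  The tumor enhancement AUC
normalised by the same measurement in surrounding healthy liver serves as a
surrogate for the blood volume fraction:

    BVF ~ AUC_tumor / AUC_liver

Phase acquisition times are not part of the ROI record; the default
(0, 35, 70) s is standard three-phase liver CT timing and cancels out of the
ratio whenever tumor and liver share the same times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CTPhaseMeasurement",
    "PerfusionResult",
    "enhancement_curve",
    "bvf_estimate",
    "read_ct_table",
    "DEFAULT_PHASE_TIMES",
]

DEFAULT_PHASE_TIMES = (0.0, 35.0, 70.0)
PHASE_NAMES = ("noncontrast", "arterial", "portal")


@dataclass(frozen=True)
class CTPhaseMeasurement:
    """Mean ROI Hounsfield units for one site across the three CT phases."""

    site: str
    hu_noncontrast: float
    hu_arterial: float
    hu_portal: float
    phase_times: tuple = DEFAULT_PHASE_TIMES
    sd: tuple | None = None

    def __post_init__(self) -> None:
        if self.site not in ("tumor", "liver"):
            raise ValueError("site must be 'tumor' or 'liver'")
        t = self.phase_times
        if len(t) != 3 or t[0] != 0.0 or not (t[0] < t[1] < t[2]):
            raise ValueError("phase_times must be 3 strictly increasing values starting at 0")
        hu = (self.hu_noncontrast, self.hu_arterial, self.hu_portal)
        if not all(np.isfinite(hu)):
            raise ValueError("HU values must be finite")


@dataclass(frozen=True)
class PerfusionResult:
    """Enhancement AUCs (HU*s) and the BVF surrogate; ``clamped`` flags a raw
    tumor/liver ratio outside [0, 1] that was clipped to the model domain."""

    auc_tumor: float
    auc_liver: float
    bvf: float
    clamped: bool = False


def enhancement_curve(m: CTPhaseMeasurement) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted enhancement (time_s, delta_HU) for one site.

    The non-contrast phase anchors the curve at (0, 0).  Negative enhancement
    (ROI darker after contrast) is retained with a warning.
    """
    times = np.asarray(m.phase_times, dtype=float)
    delta = np.array(
        [0.0, m.hu_arterial - m.hu_noncontrast, m.hu_portal - m.hu_noncontrast]
    )
    if np.any(delta < 0):
        warnings.warn(
            f"negative contrast enhancement in {m.site} ROI retained", stacklevel=2
        )
    return times, delta


def bvf_estimate(tumor: CTPhaseMeasurement, liver: CTPhaseMeasurement) -> PerfusionResult:
    """Blood volume fraction surrogate from paired tumor/liver ROI curves.

    Trapezoidal AUC of each enhancement curve; bvf = AUC_tumor / AUC_liver,
    clamped to [0, 1] with the ``clamped`` flag set when the raw ratio falls
    outside the model domain.
    """
    if tuple(tumor.phase_times) != tuple(liver.phase_times):
        raise ValueError("tumor and liver phase_times must match")
    t_t, d_t = enhancement_curve(tumor)
    t_l, d_l = enhancement_curve(liver)
    auc_tumor = float(np.trapezoid(d_t, t_t))
    auc_liver = float(np.trapezoid(d_l, t_l))
    if auc_liver <= 0:
        raise ValueError("liver enhancement AUC must be positive to normalise")
    raw = auc_tumor / auc_liver
    clamped = not (0.0 <= raw <= 1.0)
    return PerfusionResult(auc_tumor, auc_liver, float(np.clip(raw, 0.0, 1.0)), clamped)


def read_ct_table(source) -> dict[str, dict[str, CTPhaseMeasurement]]:
    """Parse a long-format CT ROI table into per-patient measurements.

    Expected columns: patient_id, site ('tumor'/'liver'), phase
    ('noncontrast'/'arterial'/'portal'), time_s, mean_hu and optionally sd_hu.
    Returns {patient_id: {site: CTPhaseMeasurement}}.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"patient_id", "site", "phase", "time_s", "mean_hu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    out: dict[str, dict[str, CTPhaseMeasurement]] = {}
    for (pid, site), grp in df.groupby(["patient_id", "site"], sort=False):
        grp = grp.set_index("phase")
        if set(PHASE_NAMES) - set(grp.index):
            raise ValueError(f"patient {pid} site {site}: missing CT phases")
        hu = {p: float(grp.loc[p, "mean_hu"]) for p in PHASE_NAMES}
        times = tuple(float(grp.loc[p, "time_s"]) for p in PHASE_NAMES)
        sd = None
        if "sd_hu" in grp.columns and grp["sd_hu"].notna().all():
            sd = tuple(float(grp.loc[p, "sd_hu"]) for p in PHASE_NAMES)
        out.setdefault(str(pid), {})[site] = CTPhaseMeasurement(
            site=site,
            hu_noncontrast=hu["noncontrast"],
            hu_arterial=hu["arterial"],
            hu_portal=hu["portal"],
            phase_times=times,
            sd=sd,
        )
    return out
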