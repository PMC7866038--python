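"""Two-compartment plasma pharmacokinetics of 5-fluorouracil.

The systemic model tracks drug concentration in a central (blood) compartment
``sigma_B`` and a peripheral compartment ``sigma_P``.  A chemotherapy cycle is
an intravenous bolus of dose ``D`` (mg per m^2 body surface area), applied as
an initial condition, followed by a constant-rate infusion of dose ``R``
(mg/m^2) spread over ``delta_t`` hours:

    d(sigma_B)/dt = -k12*sigma_B - sigma_B*Cl/V + k21*sigma_P + R*BSA/(delta_t*V)
    d(sigma_P)/dt =  k12*sigma_B - k21*sigma_P

with sigma_B(0) = D*BSA/V (zero when no bolus is given) and sigma_P(0) = 0.
Concentrations are carried in mg/L, which is numerically identical to ug/mL.

Because the system is linear with constant coefficients, a closed-form
bi-exponential solution exists (:func:`analytic_cycle`); the numerical
integrator (:func:`simulate_cycle`) is validated against it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "PKParameters",
    "Regimen",
    "ConcentrationProfile",
    "ExposureSummary",
    "blood_volume",
    "simulate_cycle",
    "analytic_cycle",
    "simulate_regimen",
    "auc_trapezoid",
    "exposure_summary",
]

#: Literature rate constants for 5-FU (1/h) and clearance (L/h).
DEFAULT_K12 = 5.35
DEFAULT_K21 = 5.69
DEFAULT_CLEARANCE = 65.3

#: Minimum BSA (m^2) for which the empirical blood-volume relation is positive.
BSA_MIN = 1.229 / 3.29


def blood_volume(bsa: float) -> float:
    """Patient blood volume in mL from body surface area (m^2).

    Uses the empirical linear relation V = (3.29*BSA - 1.229) * 1000.
    """
    v = (3.29 * bsa - 1.229) * 1000.0
    if v <= 0.0:
        raise ValueError(
            f"BSA={bsa} m^2 yields non-positive blood volume; require BSA > {BSA_MIN:.4f}"
        )
    return v


@dataclass(frozen=True)
class PKParameters:
    """Rate constants of the two-compartment model.

    k12, k21 : 1/h inter-compartment transfer rates (may be zero, e.g. to
        reduce to a one-compartment model); clearance : L/h, strictly positive.
    """

    k12: float = DEFAULT_K12
    k21: float = DEFAULT_K21
    clearance: float = DEFAULT_CLEARANCE

    def __post_init__(self) -> None:
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("transfer rates k12, k21 must be non-negative")
        if self.clearance <= 0:
            raise ValueError("clearance must be strictly positive")


@dataclass(frozen=True)
class Regimen:
    """One patient's dosing schedule.

    bolus_mg_per_m2 : bolus dose D; infusion_mg_per_m2 : infusion dose R;
    infusion_hours : cycle duration delta_t (h); bsa : body surface area (m^2);
    n_cycles : number of cycles N; span_hours : treatment span t, first cycle
    to surgery (h); interval_hours : time between cycle starts (h, FOLFOX
    default 14 days).
    """

    bsa: float
    bolus_mg_per_m2: float = 400.0
    infusion_mg_per_m2: float = 2400.0
    infusion_hours: float = 46.0
    n_cycles: int = 1
    span_hours: float = 46.0
    interval_hours: float = 336.0

    def __post_init__(self) -> None:
        if self.bsa <= BSA_MIN:
            raise ValueError(f"BSA must exceed {BSA_MIN:.4f} m^2")
        if self.bolus_mg_per_m2 < 0 or self.infusion_mg_per_m2 < 0:
            raise ValueError("doses must be non-negative")
        if self.bolus_mg_per_m2 == 0 and self.infusion_mg_per_m2 == 0:
            raise ValueError("bolus and infusion doses cannot both be zero")
        if self.infusion_hours <= 0:
            raise ValueError("infusion duration must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.infusion_hours > self.interval_hours:
            raise ValueError("infusion cannot outlast the cycle interval")
        if self.n_cycles * self.interval_hours > self.span_hours:
            warnings.warn(
                "n_cycles * interval_hours exceeds the treatment span; "
                "check cycle bookkeeping",
                stacklevel=2,
            )

    @property
    def duty_cycle(self) -> float:
        """Dimensionless fraction of the treatment span spent infusing (N*dt/t)."""
        return self.n_cycles * self.infusion_hours / self.span_hours

    @classmethod
    def from_yaml(cls, path, bsa: float, n_cycles: int | None = None,
                  span_hours: float | None = None) -> "Regimen":
        """Load regimen defaults from a YAML file.

        Recognised keys: bolus_mg_per_m2, infusion_mg_per_m2, infusion_hours,
        cycles, span_days, interval_days.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = dict(bsa=bsa)
        if "bolus_mg_per_m2" in cfg:
            kwargs["bolus_mg_per_m2"] = float(cfg["bolus_mg_per_m2"])
        if "infusion_mg_per_m2" in cfg:
            kwargs["infusion_mg_per_m2"] = float(cfg["infusion_mg_per_m2"])
        if "infusion_hours" in cfg:
            kwargs["infusion_hours"] = float(cfg["infusion_hours"])
        if "interval_days" in cfg:
            kwargs["interval_hours"] = 24.0 * float(cfg["interval_days"])
        kwargs["n_cycles"] = int(n_cycles if n_cycles is not None else cfg.get("cycles", 1))
        if span_hours is not None:
            kwargs["span_hours"] = float(span_hours)
        elif "span_days" in cfg:
            kwargs["span_hours"] = 24.0 * float(cfg["span_days"])
        else:
            kwargs["span_hours"] = kwargs["n_cycles"] * kwargs.get("interval_hours", 336.0)
        return cls(**kwargs)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration time courses on a monotone grid (hours, ug/mL)."""

    times: np.ndarray
    sigma_b: np.ndarray
    sigma_p: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        sb = np.asarray(self.sigma_b, dtype=float)
        sp = np.asarray(self.sigma_p, dtype=float)
        if not (t.shape == sb.shape == sp.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("times, sigma_b, sigma_p must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        scale = max(sb.max(initial=0.0), sp.max(initial=0.0), 1.0)
        if sb.min(initial=0.0) < -1e-9 * scale or sp.min(initial=0.0) < -1e-9 * scale:
            raise ValueError("negative concentrations beyond solver tolerance")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sigma_b", np.maximum(sb, 0.0))
        object.__setattr__(self, "sigma_p", np.maximum(sp, 0.0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "sigma_B": self.sigma_b, "sigma_P": self.sigma_p}
        )


@dataclass(frozen=True)
class ExposureSummary:
    """Per-cycle AUCs and cycle-averaged plasma concentrations.

    auc_per_cycle : AUC_i (ug*h/mL); sigma_bar_i : AUC_i/delta_t (ug/mL);
    sigma_dbar : regimen-average concentration sum(AUC_i)/(N*delta_t).
    """

    auc_per_cycle: tuple
    sigma_bar_i: tuple
    sigma_dbar: float


def _system_matrices(params: PKParameters, regimen: Regimen):
    """Return (A, b, x0) of dx/dt = A x + b for the infusion leg; V in litres."""
    v_litre = blood_volume(regimen.bsa) / 1000.0
    a11 = -(params.k12 + params.clearance / v_litre)
    A = np.array([[a11, params.k21], [params.k12, -params.k21]])
    b = np.array(
        [regimen.infusion_mg_per_m2 * regimen.bsa / (regimen.infusion_hours * v_litre), 0.0]
    )
    x0 = np.array([regimen.bolus_mg_per_m2 * regimen.bsa / v_litre, 0.0])
    return A, b, x0


def _make_grid(regimen: Regimen, grid_step: float, t_end: float | None) -> np.ndarray:
    if t_end is None:
        t_end = regimen.interval_hours
    if t_end < regimen.infusion_hours:
        raise ValueError("grid must cover at least the infusion duration")
    n = int(round(t_end / grid_step))
    times = np.linspace(0.0, n * grid_step, n + 1)
    if not np.any(np.isclose(times, regimen.infusion_hours)):
        times = np.sort(np.append(times, regimen.infusion_hours))
    return times


def _linear_solution(A: np.ndarray, b: np.ndarray, x0: np.ndarray,
                     times: np.ndarray) -> np.ndarray:
    """Exact solution of dx/dt = A x + b on `times` (columns are states).

    Uses the eigendecomposition when A has well-separated real eigenvalues and
    falls back to the matrix exponential of the augmented (affine) system for
    degenerate or singular A.
    """
    w, vecs = np.linalg.eig(A)
    sep = np.abs(w[0] - w[1])
    scale = max(np.abs(w).max(), 1e-30)
    nonsingular = np.abs(np.linalg.det(A)) > 1e-12 * scale**2
    if np.all(np.isreal(w)) and sep > 1e-7 * scale and (nonsingular or not b.any()):
        w = w.real
        vecs = vecs.real
        xp = np.linalg.solve(A, -b) if b.any() else np.zeros(2)
        coef = np.linalg.solve(vecs, x0 - xp)
        return vecs @ (coef[:, None] * np.exp(np.outer(w, times))) + xp[:, None]
    # augmented system: d/dt (x, 1) = [[A, b], [0, 0]] (x, 1)
    M = np.zeros((3, 3))
    M[:2, :2] = A
    M[:2, 2] = b
    z0 = np.array([x0[0], x0[1], 1.0])
    out = np.empty((2, times.size))
    for j, t in enumerate(times):
        out[:, j] = (expm(M * t) @ z0)[:2]
    return out


def analytic_cycle(params: PKParameters, regimen: Regimen, grid_step: float = 0.01,
                   t_end: float | None = None) -> ConcentrationProfile:
    """Closed-form concentration profile for one cycle (infusion + washout).

    Exact bi-exponential solution of the constant-coefficient linear system;
    serves as the oracle for :func:`simulate_cycle` and as the fast path in the
    cohort pipeline.
    """
    times = _make_grid(regimen, grid_step, t_end)
    A, b, x0 = _system_matrices(params, regimen)
    dt = regimen.infusion_hours
    on = times <= dt + 1e-12
    x_on = _linear_solution(A, b, x0, times[on])
    x = np.empty((2, times.size))
    x[:, on] = x_on
    if np.any(~on):
        x_dt = _linear_solution(A, b, x0, np.array([dt]))[:, 0]
        x[:, ~on] = _linear_solution(A, np.zeros(2), x_dt, times[~on] - dt)
    return ConcentrationProfile(times, x[0], x[1])


def simulate_cycle(params: PKParameters, regimen: Regimen, grid_step: float = 0.01,
                   t_end: float | None = None, rtol: float = 1e-10,
                   atol: float = 1e-9) -> ConcentrationProfile:
    """Numerically integrate the two-compartment ODEs for one cycle.

    The infusion forcing switches off at ``infusion_hours``, so the two legs
    are integrated separately with a stiff-capable adaptive solver.
    """
    times = _make_grid(regimen, grid_step, t_end)
    A, b, x0 = _system_matrices(params, regimen)
    dt = regimen.infusion_hours
    on = times <= dt + 1e-12

    def rhs_on(t, x):
        return A @ x + b

    def rhs_off(t, x):
        return A @ x

    sol1 = solve_ivp(rhs_on, (0.0, dt), x0, t_eval=times[on], method="LSODA",
                     rtol=rtol, atol=atol)
    if not sol1.success:
        raise RuntimeError(f"integration failure (infusion leg): {sol1.message}")
    x = np.empty((2, times.size))
    x[:, on] = sol1.y
    if np.any(~on):
        sol2 = solve_ivp(rhs_off, (dt, times[-1]), sol1.y[:, -1], t_eval=times[~on],
                         method="LSODA", rtol=rtol, atol=atol)
        if not sol2.success:
            raise RuntimeError(f"integration failure (washout leg): {sol2.message}")
        x[:, ~on] = sol2.y
    scale = max(x[0].max(), 1.0)
    if x.min() < -1e-6 * scale:
        raise RuntimeError("integration produced negative concentrations")
    return ConcentrationProfile(times, x[0], x[1])


def simulate_regimen(params: PKParameters, regimen: Regimen, grid_step: float = 0.01,
                     method: str = "analytic") -> list[ConcentrationProfile]:
    """Per-cycle concentration profiles for the full regimen.

    Each cycle restarts from a drug-free state (washout between 14-day FOLFOX
    cycles is effectively complete), so the N cycles share one profile.
    """
    if method == "analytic":
        prof = analytic_cycle(params, regimen, grid_step)
    elif method == "numeric":
        prof = simulate_cycle(params, regimen, grid_step)
    else:
        raise ValueError(f"unknown method {method!r}")
    return [prof] * regimen.n_cycles


def auc_trapezoid(profile: ConcentrationProfile, window: tuple | None = None) -> float:
    """Trapezoidal AUC (ug*h/mL) of sigma_B over ``window`` (defaults to the
    full grid); window endpoints off the grid are linearly interpolated."""
    t, y = profile.times, profile.sigma_b
    if window is None:
        return float(np.trapezoid(y, t))
    t0, t1 = window
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(f"window [{t0}, {t1}] empty or outside grid [{t[0]}, {t[-1]}]")
    inside = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inside], [t1]))
    yy = np.concatenate(([np.interp(t0, t, y)], y[inside], [np.interp(t1, t, y)]))
    return float(np.trapezoid(yy, tt))


def exposure_summary(profiles: list[ConcentrationProfile], regimen: Regimen) -> ExposureSummary:
    """Cycle-averaged plasma concentrations from per-cycle profiles.

    sigma_bar_i = AUC_i / delta_t for each cycle i, and the regimen-level
    average sigma_dbar = sum_i AUC_i / (N * delta_t), which is identically the
    mean of the sigma_bar_i.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one cycle profile")
    dt = regimen.infusion_hours
    aucs = tuple(auc_trapezoid(p) for p in profiles)
    sigma_bar = tuple(a / dt for a in aucs)
    sigma_dbar = sum(aucs) / (len(aucs) * dt)
    return ExposureSummary(aucs, sigma_bar, sigma_dbar)
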