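"""Single-turnover chlorophyll-a fluorescence induction/relaxation kinetics.

Forward model and nonlinear fitting of flashlet-resolved single-turnover (ST)
fluorescence transients. A train of microsecond excitation flashlets drives
the closed fraction ``C`` of PSII reaction centers from its initial value
toward 1; fluorescence yield rises from Fo to Fm following the
connectivity-corrected yield curve

    F(C) = Fo + (Fm - Fo) * C * (1 - rho) / (1 - rho * C)

where ``rho`` is the probability that an exciton arriving at a closed center
migrates to an open neighbour. During the subsequent relaxation phase the
closed fraction reopens as a double exponential with time constants ``tau1``
(acceptor-side, Qa -> Qb) and ``tau2`` (plastoquinone-pool reoxidation),
probed by sparse flashlets at exponentially increasing dark intervals.

Units: sigma_PSII is in A^2 quanta^-1 and the per-flashlet excitation dose in
quanta A^-2, so sigma * dose is the dimensionless closure probability
increment per flashlet; all times are microseconds, fluorescence is in
arbitrary instrument units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "CANONICAL_WAVELENGTHS",
    "N_INDUCTION_FLASHLETS",
    "DEFAULT_DOSE_PER_FLASHLET",
    "DomainError",
    "ScheduleError",
    "FitInputError",
    "FlashletSchedule",
    "STTrace",
    "STParams",
    "STFitResult",
    "canonical_wavelength",
    "induction_schedule",
    "relaxation_schedule",
    "yield_from_closure",
    "closure_after_induction",
    "simulate_induction",
    "simulate_relaxation",
    "simulate_trace_pair",
    "fit_single_turnover",
    "traces_to_frame",
    "frame_to_traces",
]

# ---------------------------------------------------------------------------
# Instrument constants
# ---------------------------------------------------------------------------

#: Canonical excitation wavelengths (nm). 520 is accepted as an alias of 525.
CANONICAL_WAVELENGTHS: tuple[int, ...] = (420, 442, 458, 505, 525)

#: Induction flashlet count by excitation wavelength.
N_INDUCTION_FLASHLETS: dict[int, int] = {420: 32, 442: 32, 458: 32, 505: 40, 525: 40}

FLASHLET_DURATION_US = 1.3
INDUCTION_GAP_US = 3.4
RELAX_FIRST_GAP_US = 59.0
RELAX_SPAN_US = 300_000.0  # 300 ms relaxation phase
N_RELAXATION_FLASHLETS = 40

#: Excitation dose per flashlet (quanta A^-2). Balances two needs: enough
#: cumulative dose that closure saturates within the 32/40-flashlet train
#: even for quenched cross-sections, and enough flashlets on the sigmoidal
#: rise that sigma_PSII and the connectivity rho stay well identified.
DEFAULT_DOSE_PER_FLASHLET = 2.5e-4


class DomainError(ValueError):
    """Model input outside its physical domain."""


class ScheduleError(ValueError):
    """Flashlet schedule inconsistent with the requested operation."""


class FitInputError(ValueError):
    """Trace unsuitable for fitting (wrong shape, negative fluorescence)."""


def canonical_wavelength(wavelength_nm: int) -> int:
    """Map a wavelength to the canonical set; 520 nm aliases to 525 nm."""
    w = 525 if int(wavelength_nm) == 520 else int(wavelength_nm)
    if w not in CANONICAL_WAVELENGTHS:
        raise DomainError(
            f"wavelength {wavelength_nm} nm not in canonical set {CANONICAL_WAVELENGTHS}"
        )
    return w


# ---------------------------------------------------------------------------
# Schedules and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlashletSchedule:
    """Timing of one flashlet train.

    ``times_us`` are flashlet onset times in microseconds from the start of
    the phase; induction flashlets are evenly spaced (1.3 us flash + 3.4 us
    dark), relaxation gaps grow geometrically from 59 us so that the train
    spans up to 300 ms.
    """

    phase: str  # "induction" | "relaxation"
    times_us: np.ndarray
    dose_per_flashlet: float = DEFAULT_DOSE_PER_FLASHLET
    flashlet_duration_us: float = FLASHLET_DURATION_US

    def __post_init__(self) -> None:
        t = np.asarray(self.times_us, dtype=float)
        object.__setattr__(self, "times_us", t)
        if self.phase not in ("induction", "relaxation"):
            raise ScheduleError(f"unknown phase {self.phase!r}")
        if t.ndim != 1 or len(t) < 1:
            raise ScheduleError("schedule needs at least one flashlet")
        if np.any(np.diff(t) <= 0):
            raise ScheduleError("flashlet times must be strictly increasing")
        gaps = np.diff(t) - self.flashlet_duration_us
        if self.phase == "relaxation":
            if len(gaps) and np.any(np.diff(gaps) <= 0):
                raise ScheduleError("relaxation gaps must be strictly increasing")
            if t[-1] > RELAX_SPAN_US + 1e-6:
                raise ScheduleError("relaxation span exceeds 300 ms")

    def __len__(self) -> int:
        return len(self.times_us)

    @property
    def gap_us(self) -> float:
        """Constant dark interval for induction schedules."""
        if self.phase != "induction":
            raise ScheduleError("gap_us defined for induction schedules only")
        if len(self.times_us) < 2:
            return INDUCTION_GAP_US
        return float(self.times_us[1] - self.times_us[0] - self.flashlet_duration_us)


def induction_schedule(
    n_flashlets: int,
    dose_per_flashlet: float = DEFAULT_DOSE_PER_FLASHLET,
    flashlet_us: float = FLASHLET_DURATION_US,
    gap_us: float = INDUCTION_GAP_US,
) -> FlashletSchedule:
    """Evenly spaced induction train: 1.3 us flashlets, 3.4 us dark gaps."""
    times = np.arange(n_flashlets) * (flashlet_us + gap_us)
    return FlashletSchedule("induction", times, dose_per_flashlet, flashlet_us)


def relaxation_schedule(
    n_flashlets: int = N_RELAXATION_FLASHLETS,
    dose_per_flashlet: float = DEFAULT_DOSE_PER_FLASHLET,
    first_gap_us: float = RELAX_FIRST_GAP_US,
    span_us: float = RELAX_SPAN_US,
    flashlet_us: float = FLASHLET_DURATION_US,
) -> FlashletSchedule:
    """Relaxation train with geometrically increasing dark gaps.

    The growth ratio is solved so the last flashlet lands on ``span_us``
    (default 300 ms); the first gap is 59 us.
    """
    n = int(n_flashlets)
    if n < 2:
        raise ScheduleError("relaxation schedule needs >= 2 flashlets")

    def span_of(r: float) -> float:
        gaps = first_gap_us * r ** np.arange(n)
        return float(np.cumsum(gaps + flashlet_us)[-1] - flashlet_us)

    ratio = brentq(lambda r: span_of(r) - span_us, 1.0 + 1e-9, 2.0)
    gaps = first_gap_us * ratio ** np.arange(n)
    times = np.cumsum(gaps + flashlet_us) - flashlet_us
    return FlashletSchedule("relaxation", times, dose_per_flashlet, flashlet_us)


@dataclass
class STTrace:
    """One flashlet-resolved ST record at a single wavelength.

    Either phase may be absent (``None``); a full acquisition carries both.
    """

    wavelength_nm: int
    induction: Optional[FlashletSchedule] = None
    relaxation: Optional[FlashletSchedule] = None
    f_induction: Optional[np.ndarray] = None
    f_relaxation: Optional[np.ndarray] = None
    sample_id: str = ""
    timepoint_index: int = 0
    repeat_index: int = 0

    def __post_init__(self) -> None:
        self.wavelength_nm = canonical_wavelength(self.wavelength_nm)
        for sched, f, name in (
            (self.induction, self.f_induction, "induction"),
            (self.relaxation, self.f_relaxation, "relaxation"),
        ):
            if (sched is None) != (f is None):
                raise FitInputError(f"{name} schedule and fluorescence must pair")
            if f is not None:
                f = np.asarray(f, dtype=float)
                if len(f) != len(sched):
                    raise FitInputError(f"{name} fluorescence length != flashlet count")
                if not np.all(np.isfinite(f)) or np.any(f <= 0):
                    raise FitInputError(f"{name} fluorescence must be finite and > 0")
                setattr(self, f"f_{name}", f)

    @property
    def n_induction_flashlets(self) -> int:
        return 0 if self.induction is None else len(self.induction)

    @property
    def fluorescence(self) -> np.ndarray:
        parts = [f for f in (self.f_induction, self.f_relaxation) if f is not None]
        return np.concatenate(parts) if parts else np.empty(0)


@dataclass(frozen=True)
class STParams:
    """Biophysical parameters of the ST transient."""

    F0: float
    Fm: float
    sigma_PSII: float  # A^2 quanta^-1
    rho: float
    C0: float = 0.0
    alpha: float = 0.6
    tau1_us: float = 600.0
    tau2_us: float = 12_000.0

    def __post_init__(self) -> None:
        if not (self.Fm > self.F0 > 0):
            raise DomainError("require Fm > F0 > 0")
        if not (0.0 <= self.rho < 1.0):
            raise DomainError("require 0 <= rho < 1")
        if not (0.0 <= self.C0 <= 1.0):
            raise DomainError("require 0 <= C0 <= 1")
        if np.isfinite(self.alpha) and not (0.0 <= self.alpha <= 1.0):
            raise DomainError("require 0 <= alpha <= 1")
        if np.isfinite(self.tau2_us) and not (0 < self.tau1_us < self.tau2_us):
            raise DomainError("require 0 < tau1 < tau2")

    @property
    def phi_PSII(self) -> float:
        return (self.Fm - self.F0) / self.Fm


@dataclass
class STFitResult:
    """Fitted ST parameters with diagnostics."""

    params: STParams
    residual_rms: float
    converged: bool
    message: str = ""

    @property
    def phi_PSII(self) -> float:
        return self.params.phi_PSII

    @property
    def f_prime(self) -> float:
        """Fitted baseline fluorescence at induction start, F(C0)."""
        p = self.params
        return yield_from_closure(p.C0, p.F0, p.Fm, p.rho)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def yield_from_closure(C, F0: float, Fm: float, rho: float):
    """Fluorescence yield at closed fraction ``C`` with connectivity ``rho``.

    F = F0 + (Fm - F0) * C (1 - rho) / (1 - rho C); linear in C at rho = 0,
    sigmoidal (convex) for rho > 0. Monotone increasing, F(0)=F0, F(1)=Fm.
    """
    C = np.asarray(C, dtype=float)
    if not (Fm > F0 > 0):
        raise DomainError("require Fm > F0 > 0")
    if not (0.0 <= rho < 1.0):
        raise DomainError("require 0 <= rho < 1")
    if np.any(C < -1e-12) or np.any(C > 1 + 1e-12):
        raise DomainError("closed fraction C must lie in [0, 1]")
    C = np.clip(C, 0.0, 1.0)
    out = F0 + (Fm - F0) * C * (1.0 - rho) / (1.0 - rho * C)
    return float(out) if out.ndim == 0 else out


def _closure_g(C, rho: float):
    """Integral of (1 - rho C)/(1 - C): the photon-dose coordinate.

    dC/dphi = sigma (1 - C)/(1 - rho C) integrates to
    g(C) = -(1 - rho) ln(1 - C) + rho C = sigma phi, so closure advances by
    exactly sigma * dose in g per flashlet.
    """
    C = np.asarray(C, dtype=float)
    return -(1.0 - rho) * np.log1p(-C) + rho * C


def _solve_closure(targets, rho: float) -> np.ndarray:
    """Invert g(C) = target elementwise (Newton; g is monotone, convex)."""
    t = np.asarray(targets, dtype=float)
    C = np.clip(1.0 - np.exp(-t), 0.0, 1.0 - 1e-15)
    for _ in range(60):
        f = _closure_g(C, rho) - t
        fp = (1.0 - rho * C) / (1.0 - C)
        step = f / fp
        C = np.clip(C - step, 0.0, 1.0 - 1e-15)
        if np.all(np.abs(step) < 1e-13):
            break
    return C


def _induction_closure(
    C0: float,
    sigma: float,
    rho: float,
    n: int,
    dose: float,
    gap_us: float = INDUCTION_GAP_US,
    tau1_us: float = 600.0,
    reopening: bool = False,
) -> tuple[np.ndarray, float]:
    """Closed-fraction states over the induction train.

    Each flashlet delivers its dose continuously, so the closure ODE is
    integrated exactly within the pulse (the per-flashlet update in the
    dose coordinate g). Fluorescence is read out at each flashlet onset
    (the pulse is digitized from its leading edge, before its own dose
    closes centers): the j-th reading sees the state left by the previous
    j-1 flashlets and the first reading sees C0 directly. With
    ``reopening`` enabled the dark gap between flashlets reopens centers at
    rate 1/tau1. Returns (per-flashlet readout states, closed fraction
    after the full train).
    """
    k = sigma * dose
    if not reopening:
        targets = _closure_g(C0, rho) + k * np.arange(n + 1)
        C = _solve_closure(targets, rho)
        return C[:n], float(C[n])
    C = np.empty(n)
    c = float(C0)
    reopen = gap_us / tau1_us
    for j in range(n):
        C[j] = c
        c = float(_solve_closure(_closure_g(c, rho) + k, rho))
        if j < n - 1:
            c = max(c - reopen * c, 0.0)
    return C, c


def simulate_induction(
    params: STParams,
    schedule: FlashletSchedule,
    reopening_enabled: bool = False,
) -> STTrace:
    """Simulate the induction transient under a flashlet train.

    Each flashlet increments the closed fraction by
    ``dose * sigma * (1 - C) / (1 - rho C)`` (clamped to [0, 1]); with
    ``reopening_enabled`` the dark gap additionally reopens centers at rate
    ``1/tau1``. Fluorescence is read out after each flashlet.
    """
    if schedule.phase != "induction":
        raise ScheduleError("simulate_induction requires an induction schedule")
    C, _ = _induction_closure(
        params.C0,
        params.sigma_PSII,
        params.rho,
        len(schedule),
        schedule.dose_per_flashlet,
        schedule.gap_us,
        params.tau1_us,
        reopening_enabled,
    )
    f = yield_from_closure(C, params.F0, params.Fm, params.rho)
    return STTrace(wavelength_nm=505, induction=schedule, f_induction=f)


def closure_after_induction(
    params: STParams,
    schedule: FlashletSchedule,
    reopening_enabled: bool = False,
) -> float:
    """Closed fraction at the end of the induction train."""
    _, c_end = _induction_closure(
        params.C0,
        params.sigma_PSII,
        params.rho,
        len(schedule),
        schedule.dose_per_flashlet,
        schedule.gap_us,
        params.tau1_us,
        reopening_enabled,
    )
    return float(c_end)


def _relaxation_closure(
    t_us: np.ndarray, C_end: float, alpha: float, tau1_us: float, tau2_us: float
) -> np.ndarray:
    fast = alpha * np.exp(-t_us / tau1_us)
    slow = (1.0 - alpha) * (np.exp(-t_us / tau2_us) if np.isfinite(tau2_us) else 0.0)
    return C_end * (fast + slow)


def simulate_relaxation(
    params: STParams, C_end: float, schedule: FlashletSchedule
) -> STTrace:
    """Simulate the relaxation transient after the induction train.

    The closed fraction reopens as C(t) = C_end (alpha e^{-t/tau1} +
    (1-alpha) e^{-t/tau2}); probe-flash re-excitation by the sparse 1.3 us
    flashlets is neglected, so the trace is monotone non-increasing.
    """
    if schedule.phase != "relaxation":
        raise ScheduleError("simulate_relaxation requires a relaxation schedule")
    if not (0.0 < C_end <= 1.0):
        raise DomainError("C_end must lie in (0, 1]; C_end = 0 is degenerate")
    C = _relaxation_closure(
        schedule.times_us, C_end, params.alpha, params.tau1_us, params.tau2_us
    )
    f = yield_from_closure(C, params.F0, params.Fm, params.rho)
    return STTrace(wavelength_nm=505, relaxation=schedule, f_relaxation=f)


def simulate_trace_pair(
    params: STParams,
    wavelength_nm: int = 505,
    noise_rel: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    dose_per_flashlet: float = DEFAULT_DOSE_PER_FLASHLET,
    n_relaxation: int = N_RELAXATION_FLASHLETS,
    reopening_enabled: bool = False,
    sample_id: str = "",
    timepoint_index: int = 0,
    repeat_index: int = 0,
) -> STTrace:
    """Simulate a full induction + relaxation acquisition at one wavelength.

    ``noise_rel`` adds multiplicative Gaussian noise (fractional SD) to every
    flashlet reading; the draw requires ``rng``.
    """
    w = canonical_wavelength(wavelength_nm)
    ind = induction_schedule(N_INDUCTION_FLASHLETS[w], dose_per_flashlet)
    rel = relaxation_schedule(n_relaxation, dose_per_flashlet)
    C_ind, c_last = _induction_closure(
        params.C0, params.sigma_PSII, params.rho, len(ind),
        dose_per_flashlet, ind.gap_us, params.tau1_us, reopening_enabled,
    )
    f_ind = yield_from_closure(C_ind, params.F0, params.Fm, params.rho)
    C_end = max(float(c_last), 1e-9)
    C_rel = _relaxation_closure(
        rel.times_us, C_end, params.alpha, params.tau1_us, params.tau2_us
    )
    f_rel = yield_from_closure(C_rel, params.F0, params.Fm, params.rho)
    if noise_rel > 0:
        if rng is None:
            raise ValueError("noise_rel > 0 requires an rng")
        f_ind = f_ind * (1.0 + noise_rel * rng.standard_normal(len(f_ind)))
        f_rel = f_rel * (1.0 + noise_rel * rng.standard_normal(len(f_rel)))
        f_ind = np.maximum(f_ind, 1e-6)
        f_rel = np.maximum(f_rel, 1e-6)
    return STTrace(
        wavelength_nm=w,
        induction=ind,
        relaxation=rel,
        f_induction=f_ind,
        f_relaxation=f_rel,
        sample_id=sample_id,
        timepoint_index=timepoint_index,
        repeat_index=repeat_index,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_RHO_MAX = 0.8
_TAU1_BOUNDS = (50.0, 10_000.0)  # 50 us .. 10 ms
_TAU2_MAX = 300_000.0  # 300 ms


def _flat(y: np.ndarray, rel_floor: float) -> bool:
    return (y.max() - y.min()) < rel_floor * np.median(y)


def fit_single_turnover(
    trace: STTrace,
    c0_fixed: Optional[float] = None,
    rho_fixed: Optional[float] = None,
    f0_from_dark: Optional[tuple[float, float]] = None,
    noise_floor_rel: float = 0.02,
    reopening_enabled: bool = False,
) -> STFitResult:
    """Two-stage weighted least-squares fit of an ST trace pair.

    Stage 1 fits the induction transient for (F0, Fm, sigma_PSII, rho, C0);
    stage 2 fixes the closed fraction at induction end and fits the
    relaxation for (alpha, tau1, tau2). Residuals are relative (weights
    1/F), matching the multiplicative instrument noise.

    ``c0_fixed=0`` pins the baseline for dark-acclimated acquisitions.
    ``rho_fixed`` pins the connectivity (e.g. to the dark-reference value
    at light-adapted timepoints, or to probe the sigma-rho trade-off).
    ``f0_from_dark=(Fo_dark, Fm_dark)`` ties the light-adapted minimal
    fluorescence to the Oxborough-Baker estimate
    Fo' = Fo / (Fv/Fm + Fo/Fm'), removing F0 from the free parameters;
    without it the minimal fluorescence of a light-adapted induction is
    nearly unidentifiable from the quenched baseline.

    If the fitted slow component is not separated (tau2 < 2 tau1), the
    relaxation is refit as a single exponential and tau2 reported missing.
    """
    if trace.induction is None or trace.relaxation is None:
        raise FitInputError("fit requires both induction and relaxation phases")
    if len(trace.induction) < 16 or len(trace.relaxation) < 16:
        raise FitInputError("fit requires >= 16 flashlets in each phase")
    y_ind = trace.f_induction
    y_rel = trace.f_relaxation
    if np.any(y_ind <= 0) or np.any(y_rel <= 0):
        raise FitInputError("fluorescence must be positive")

    sched = trace.induction
    dose = sched.dose_per_flashlet
    n_ind = len(sched)

    if _flat(np.concatenate([y_ind, y_rel]), noise_floor_rel):
        med = float(np.median(y_ind))
        params = STParams(F0=med, Fm=med * 1.001, sigma_PSII=np.nan, rho=0.0,
                          C0=0.0, alpha=np.nan, tau1_us=np.nan, tau2_us=np.nan)
        return STFitResult(params, residual_rms=float(np.std(y_ind)),
                           converged=False, message="flat trace: no induction signal")

    # --- stage 1: induction -> F0, Fm, sigma, rho, (C0) ---
    fix_c0 = c0_fixed is not None
    fix_rho = rho_fixed is not None
    tie_f0 = f0_from_dark is not None
    if tie_f0:
        fo_d, fm_d = f0_from_dark
        if not (fm_d > fo_d > 0):
            raise DomainError("f0_from_dark requires Fm_dark > Fo_dark > 0")
        fv_over_fm_d = (fm_d - fo_d) / fm_d
    f0_init = float(y_ind[0]) if fix_c0 else 0.92 * float(y_ind[0])
    fm_init = 1.05 * float(y_ind.max())
    fv = max(fm_init - f0_init, 1e-9)
    slope = max((float(y_ind[2]) - float(y_ind[0])) / 2.0, 1e-9)
    sig_init = float(np.clip(slope / fv / dose, 5.0, 4000.0))

    names, x0, lo, hi = [], [], [], []
    if not tie_f0:
        names.append("F0")
        x0.append(f0_init)
        lo.append(0.05 * y_ind[0])
        hi.append(1.2 * y_ind[0])
    names += ["Fm", "sigma"]
    x0 += [fm_init, sig_init]
    lo += [0.7 * y_ind.max(), 1.0]
    hi += [5.0 * y_ind.max(), 8000.0]
    if not fix_rho:
        names.append("rho")
        x0.append(0.3)
        lo.append(0.0)
        hi.append(_RHO_MAX)
    if not fix_c0:
        names.append("C0")
        x0.append(0.05)
        lo.append(0.0)
        hi.append(0.95)

    def unpack(x):
        d = dict(zip(names, x))
        fm = d["Fm"]
        f0 = fo_d / (fv_over_fm_d + fo_d / fm) if tie_f0 else d["F0"]
        rho = rho_fixed if fix_rho else d["rho"]
        c0 = c0_fixed if fix_c0 else d["C0"]
        return float(f0), float(fm), d["sigma"], float(rho), float(c0)

    def resid_ind(x):
        F0, Fm, sigma, rho, c0 = unpack(x)
        C, _ = _induction_closure(c0, sigma, rho, n_ind, dose, sched.gap_us,
                                  600.0, reopening_enabled)
        model = F0 + (Fm - F0) * C * (1.0 - rho) / (1.0 - rho * C)
        return (model - y_ind) / y_ind

    x0 = np.clip(x0, lo, np.asarray(hi) - 1e-12)
    sol1 = least_squares(resid_ind, x0, bounds=(lo, hi), method="trf",
                         xtol=1e-10, ftol=1e-10, gtol=1e-10)
    F0, Fm, sigma, rho, c0 = unpack(sol1.x)
    Fm = max(Fm, F0 * (1 + 1e-9) + 1e-12)

    # --- stage 2: relaxation with C_end fixed -> alpha, tau1, tau2 ---
    C_end = max(
        _induction_closure(c0, sigma, rho, n_ind, dose, sched.gap_us,
                           600.0, reopening_enabled)[1],
        1e-6,
    )
    t_rel = trace.relaxation.times_us

    def resid_rel(x, single=False):
        if single:
            alpha, tau1, tau2 = 1.0, x[0], np.inf
        else:
            alpha, tau1, tau2 = x
        C = _relaxation_closure(t_rel, C_end, alpha, tau1, tau2)
        model = F0 + (Fm - F0) * C * (1.0 - rho) / (1.0 - rho * C)
        return (model - y_rel) / y_rel

    sol2 = least_squares(
        resid_rel, [0.6, 600.0, 12_000.0],
        bounds=([0.0, _TAU1_BOUNDS[0], _TAU1_BOUNDS[0]], [1.0, _TAU1_BOUNDS[1], _TAU2_MAX]),
        method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
    )
    alpha, tau1, tau2 = sol2.x
    if tau2 < tau1:  # exchangeable components: relabel
        alpha, tau1, tau2 = 1.0 - alpha, tau2, tau1
    message = ""
    if tau2 < 2.0 * tau1:
        # components not separated: single-exponential refit, tau2 missing
        sol2s = least_squares(
            lambda x: resid_rel(x, single=True), [max(tau1, _TAU1_BOUNDS[0])],
            bounds=([_TAU1_BOUNDS[0]], [_TAU1_BOUNDS[1]]), method="trf",
            xtol=1e-10, ftol=1e-10,
        )
        alpha, tau1, tau2 = 1.0, float(sol2s.x[0]), np.nan
        message = "tau2 < 2 tau1: single-exponential refit, tau2 missing"

    # convergence: optimizer success and key parameters interior
    at_bound = (
        sigma <= 1.0 * (1 + 1e-6) or sigma >= 8000.0 * (1 - 1e-6)
        or Fm >= 5.0 * y_ind.max() * (1 - 1e-6)
        or (not fix_rho and rho >= _RHO_MAX * (1 - 1e-6))
        or tau1 <= _TAU1_BOUNDS[0] * (1 + 1e-6)
        or tau1 >= _TAU1_BOUNDS[1] * (1 - 1e-6)
        or (np.isfinite(tau2) and tau2 >= _TAU2_MAX * (1 - 1e-6))
    )
    converged = bool(sol1.success and sol2.success and not at_bound)
    if at_bound and not message:
        message = "parameter at bound"

    params = STParams(
        F0=float(F0), Fm=float(Fm), sigma_PSII=float(sigma), rho=float(rho),
        C0=float(c0), alpha=float(np.clip(alpha, 0, 1)),
        tau1_us=float(tau1), tau2_us=float(tau2),
    )
    rms = float(np.sqrt(np.mean(np.concatenate([
        (resid_ind(sol1.x) * y_ind) ** 2,
        (resid_rel([params.alpha, params.tau1_us,
                    params.tau2_us if np.isfinite(params.tau2_us) else _TAU2_MAX])
         * y_rel) ** 2,
    ]))))
    return STFitResult(params=params, residual_rms=rms, converged=converged,
                       message=message)


# ---------------------------------------------------------------------------
# Long-form trace tables
# ---------------------------------------------------------------------------

TRACE_COLUMNS = [
    "sample_id", "wavelength_nm", "timepoint_index", "repeat_index",
    "phase", "time_us", "fluorescence",
]


def traces_to_frame(traces: list[STTrace]) -> pd.DataFrame:
    """Serialize traces to the long-form table (one row per flashlet)."""
    rows = []
    for tr in traces:
        for phase, sched, f in (
            ("induction", tr.induction, tr.f_induction),
            ("relaxation", tr.relaxation, tr.f_relaxation),
        ):
            if sched is None:
                continue
            rows.append(pd.DataFrame({
                "sample_id": tr.sample_id,
                "wavelength_nm": tr.wavelength_nm,
                "timepoint_index": tr.timepoint_index,
                "repeat_index": tr.repeat_index,
                "phase": phase,
                "time_us": sched.times_us,
                "fluorescence": f,
            }))
    if not rows:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRACE_COLUMNS]


def frame_to_traces(
    frame: pd.DataFrame, dose_per_flashlet: float = DEFAULT_DOSE_PER_FLASHLET
) -> list[STTrace]:
    """Reassemble traces from the long-form table."""
    missing = set(TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise FitInputError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    keys = ["sample_id", "wavelength_nm", "timepoint_index", "repeat_index"]
    for (sid, w, tp, rep), grp in frame.groupby(keys, sort=True):
        kw: dict = {}
        for phase in ("induction", "relaxation"):
            sub = grp[grp["phase"] == phase].sort_values("time_us")
            if len(sub):
                kw[phase] = FlashletSchedule(
                    phase, sub["time_us"].to_numpy(), dose_per_flashlet
                )
                kw[f"f_{phase}"] = sub["fluorescence"].to_numpy()
        traces.append(STTrace(
            wavelength_nm=int(w), sample_id=str(sid),
            timepoint_index=int(tp), repeat_index=int(rep), **kw,
        ))
    return traces
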