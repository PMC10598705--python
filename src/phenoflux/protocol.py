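"""Variable actinic light protocol and per-sample metric cube assembly.

The acquisition protocol exposes a dark-acclimated sample to a stepped
actinic light sequence (dark, moderate light, low light, high light, dark
recovery) while single-turnover flashlet acquisitions are repeated at 34
timepoints across 5 excitation wavelengths, 5 sequential repeats each.
Repeats are averaged flashlet-wise and fitted once; the dark-acclimated
first timepoint provides the reference Fm, Fo and sigma_PSII per wavelength
from which the quenching metrics are derived:

    Phi_PSII = (Fm' - F') / Fm'          NPQ = (Fm_dark - Fm') / Fm'
    qP  = (Fm' - F') / (Fm' - Fo')       ABQ = (sigma_dark - sigma') / sigma_dark

with Fo' estimated as Fo / (Fv/Fm + Fo/Fm') when not directly measured.
Eight metrics x 5 wavelengths x 34 timepoints give 1,360 values per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    CANONICAL_WAVELENGTHS,
    FitInputError,
    STFitResult,
    STTrace,
    canonical_wavelength,
    fit_single_turnover,
)

__all__ = [
    "METRICS",
    "ActinicProtocol",
    "ConfigError",
    "MetricRecord",
    "MetricCube",
    "build_protocol",
    "acquire_timepoint",
    "derive_metrics",
    "assemble_metric_cube",
    "cubes_to_tidy",
    "cubes_to_wide",
    "tidy_to_cubes",
]

#: Metric order of the cube (metric-major flattening).
METRICS = ("PhiPSII", "SigmaPSII", "Rho", "NPQ", "ABQ", "qP", "Tau1ST", "Tau2ST")

#: Default actinic segments: (irradiance umol photons m^-2 s^-1, duration s).
DEFAULT_SEGMENTS = ((0.0, 30.0), (300.0, 210.0), (50.0, 90.0), (600.0, 210.0), (0.0, 120.0))
DEFAULT_N_TIMEPOINTS = 34
DEFAULT_N_REPEATS = 5


class ConfigError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class ActinicProtocol:
    """Stepped actinic irradiance schedule with acquisition timepoints."""

    segments: tuple[tuple[float, float], ...] = DEFAULT_SEGMENTS
    timepoint_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_repeats: int = DEFAULT_N_REPEATS

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoint_times_s, dtype=float)
        object.__setattr__(self, "timepoint_times_s", t)
        object.__setattr__(
            self, "segments", tuple((float(e), float(d)) for e, d in self.segments)
        )
        if np.any(np.diff(t) <= 0):
            raise ConfigError("timepoint times must be strictly increasing")
        if t[0] < 0 or t[-1] > self.total_duration_s + 1e-9:
            raise ConfigError("timepoints must lie within the protocol span")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_times_s)

    def irradiance_at(self, time_s: float) -> float:
        """Actinic irradiance (umol photons m^-2 s^-1) at protocol time."""
        edge = 0.0
        for irr, dur in self.segments:
            edge += dur
            if time_s < edge:
                return irr
        return self.segments[-1][0]

    def is_dark(self, timepoint_index: int) -> bool:
        """True if the (1-based) timepoint falls in a dark segment."""
        return self.irradiance_at(float(self.timepoint_times_s[timepoint_index - 1])) == 0.0

    def is_dark_acclimated(self, timepoint_index: int) -> bool:
        """True if the timepoint precedes any actinic light exposure.

        Only here is the initial closed fraction pinned to zero in the fit:
        during dark *recovery* centers may still be partially closed.
        """
        t = float(self.timepoint_times_s[timepoint_index - 1])
        edge = 0.0
        for irr, dur in self.segments:
            if irr > 0:
                return t < edge
            edge += dur
        return True


def build_protocol(config: Optional[Mapping] = None) -> ActinicProtocol:
    """Build the actinic protocol; defaults reproduce the 11-min schedule.

    Default: dark 30 s, 300 umol m^-2 s^-1 for 3.5 min, 50 for 1.5 min,
    600 for 3.5 min, dark recovery 2 min (660 s total) with 34 evenly spaced
    acquisition timepoints (spacing 660/34 ~ 19.4 s, the first at t = 0 in
    the dark). ``config`` may override ``segments``, ``n_timepoints``,
    ``timepoint_times_s`` and ``n_repeats``.
    """
    cfg = dict(config or {})
    segments = tuple(tuple(s) for s in cfg.get("segments", DEFAULT_SEGMENTS))
    total = sum(d for _, d in segments)
    if "timepoint_times_s" in cfg:
        times = np.asarray(cfg["timepoint_times_s"], dtype=float)
    else:
        n = int(cfg.get("n_timepoints", DEFAULT_N_TIMEPOINTS))
        times = np.arange(n) * total / n
    if times[-1] > total or times[0] < 0:
        raise ConfigError("timepoints outside protocol span")
    return ActinicProtocol(
        segments=segments,
        timepoint_times_s=times,
        n_repeats=int(cfg.get("n_repeats", DEFAULT_N_REPEATS)),
    )


# ---------------------------------------------------------------------------
# Acquisition: repeat averaging + fit
# ---------------------------------------------------------------------------


def acquire_timepoint(
    repeats: Sequence[STTrace],
    dark: bool = False,
    n_repeats_expected: int = DEFAULT_N_REPEATS,
    per_repeat: bool = False,
    rho_fixed: Optional[float] = None,
    f0_from_dark: Optional[tuple[float, float]] = None,
):
    """Average repeat traces flashlet-wise and fit the mean trace once.

    Sequential repeats accumulate signal: averaging before the fit maximizes
    SNR. At dark-acclimated timepoints (``dark=True``) the initial closed
    fraction is pinned to zero; at light-adapted timepoints the caller may
    pass ``rho_fixed`` and ``f0_from_dark`` from the dark reference fit (see
    :func:`phenoflux.kinetics.fit_single_turnover`). With ``per_repeat=True``
    each repeat is fitted separately (diagnostics) and a list of results is
    returned.
    """
    repeats = list(repeats)
    if not repeats:
        raise FitInputError("acquire_timepoint needs at least one repeat")
    if len(repeats) != n_repeats_expected:
        warnings.warn(
            f"expected {n_repeats_expected} repeats, got {len(repeats)}; proceeding",
            stacklevel=2,
        )
    w = repeats[0].wavelength_nm
    n_ind = repeats[0].n_induction_flashlets
    for tr in repeats[1:]:
        if tr.wavelength_nm != w or tr.n_induction_flashlets != n_ind:
            raise FitInputError("repeats must share wavelength and schedule")
    c0 = 0.0 if dark else None
    if per_repeat:
        return [
            fit_single_turnover(tr, c0_fixed=c0, rho_fixed=rho_fixed,
                                f0_from_dark=f0_from_dark)
            for tr in repeats
        ]
    mean = STTrace(
        wavelength_nm=w,
        induction=repeats[0].induction,
        relaxation=repeats[0].relaxation,
        f_induction=np.mean([tr.f_induction for tr in repeats], axis=0),
        f_relaxation=np.mean([tr.f_relaxation for tr in repeats], axis=0),
        sample_id=repeats[0].sample_id,
        timepoint_index=repeats[0].timepoint_index,
    )
    return fit_single_turnover(mean, c0_fixed=c0, rho_fixed=rho_fixed,
                               f0_from_dark=f0_from_dark)


# ---------------------------------------------------------------------------
# Metric derivation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricRecord:
    metric: str
    wavelength_nm: int
    timepoint_index: int  # 1-based
    value: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigError(f"unknown metric {self.metric!r}")


def derive_metrics(
    fit_dark: STFitResult, fit_t: STFitResult, wavelength_nm: int, timepoint_index: int
) -> list[MetricRecord]:
    """Derive the 8 metrics at one (wavelength, timepoint) from two fits.

    ``fit_dark`` is the dark-acclimated reference (timepoint 1); ``fit_t``
    the light-adapted fit at the current timepoint. Non-converged fits
    propagate as missing (NaN) values rather than fabricated numbers.
    """
    w = canonical_wavelength(wavelength_nm)
    if not (fit_dark.converged and fit_t.converged):
        vals = dict.fromkeys(METRICS, np.nan)
    else:
        pd_, pt = fit_dark.params, fit_t.params
        fm_p, f_p = pt.Fm, fit_t.f_prime
        fo, fm_d = pd_.F0, pd_.Fm
        fv_over_fm = (fm_d - fo) / fm_d
        fo_p = fo / (fv_over_fm + fo / fm_p)  # Oxborough-Baker estimate
        vals = {
            "PhiPSII": (fm_p - f_p) / fm_p,
            "SigmaPSII": pt.sigma_PSII,
            "Rho": pt.rho,
            "NPQ": (fm_d - fm_p) / fm_p,
            "ABQ": (pd_.sigma_PSII - pt.sigma_PSII) / pd_.sigma_PSII,
            "qP": (fm_p - f_p) / max(fm_p - fo_p, 1e-12),
            "Tau1ST": pt.tau1_us,
            "Tau2ST": pt.tau2_us,
        }
    return [MetricRecord(m, w, timepoint_index, float(vals[m])) for m in METRICS]


# ---------------------------------------------------------------------------
# Metric cube
# ---------------------------------------------------------------------------


@dataclass
class MetricCube:
    """Per-sample metric array [metric(8) x wavelength(5) x timepoint(34)].

    Flattens metric-major, then wavelength ascending, then timepoint, to the
    1,360-value vector of the default protocol. Missing entries are NaN.
    """

    sample_id: str
    values: np.ndarray
    wavelengths: tuple[int, ...] = CANONICAL_WAVELENGTHS
    timepoint_times_s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (len(METRICS), len(self.wavelengths)):
            raise ConfigError("cube shape must be (n_metrics, n_wavelengths, n_timepoints)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)

    @classmethod
    def unflatten(
        cls,
        sample_id: str,
        flat: np.ndarray,
        wavelengths: tuple[int, ...] = CANONICAL_WAVELENGTHS,
        n_timepoints: int = DEFAULT_N_TIMEPOINTS,
        timepoint_times_s: Optional[np.ndarray] = None,
    ) -> "MetricCube":
        shape = (len(METRICS), len(wavelengths), n_timepoints)
        return cls(sample_id, np.asarray(flat, float).reshape(shape),
                   wavelengths, timepoint_times_s)

    def column_names(self) -> list[str]:
        """Deterministic flat column names metric_wavelength_timepoint."""
        return [
            f"{m}_{w}_{t + 1}"
            for m in METRICS
            for w in self.wavelengths
            for t in range(self.n_timepoints)
        ]


def assemble_metric_cube(
    records: Iterable[MetricRecord],
    sample_id: str,
    wavelengths: Sequence[int] = CANONICAL_WAVELENGTHS,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    timepoint_times_s: Optional[np.ndarray] = None,
) -> MetricCube:
    """Assemble per-timepoint metric records into the per-sample cube.

    Missing (metric, wavelength, timepoint) cells are left NaN; a duplicate
    cell is an error.
    """
    wavelengths = tuple(sorted(canonical_wavelength(w) for w in wavelengths))
    m_idx = {m: i for i, m in enumerate(METRICS)}
    w_idx = {w: i for i, w in enumerate(wavelengths)}
    values = np.full((len(METRICS), len(wavelengths), n_timepoints), np.nan)
    seen: set[tuple] = set()
    for rec in records:
        key = (rec.metric, rec.wavelength_nm, rec.timepoint_index)
        if key in seen:
            raise ConfigError(f"duplicate metric record {key}")
        seen.add(key)
        if not 1 <= rec.timepoint_index <= n_timepoints:
            raise ConfigError(f"timepoint index {rec.timepoint_index} out of range")
        values[m_idx[rec.metric], w_idx[rec.wavelength_nm], rec.timepoint_index - 1] = rec.value
    return MetricCube(sample_id, values, wavelengths, timepoint_times_s)


# ---------------------------------------------------------------------------
# Cube tables
# ---------------------------------------------------------------------------


def cubes_to_tidy(cubes: Sequence[MetricCube]) -> pd.DataFrame:
    """Tidy long table: sample_id, metric, wavelength_nm, timepoint_index, time_s, value."""
    frames = []
    for cube in cubes:
        m, w, t = np.meshgrid(
            np.arange(len(METRICS)), np.arange(len(cube.wavelengths)),
            np.arange(cube.n_timepoints), indexing="ij",
        )
        times = (
            cube.timepoint_times_s
            if cube.timepoint_times_s is not None
            else np.full(cube.n_timepoints, np.nan)
        )
        frames.append(pd.DataFrame({
            "sample_id": cube.sample_id,
            "metric": np.asarray(METRICS)[m.ravel()],
            "wavelength_nm": np.asarray(cube.wavelengths)[w.ravel()],
            "timepoint_index": t.ravel() + 1,
            "time_s": np.asarray(times, float)[t.ravel()],
            "value": cube.values.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def cubes_to_wide(cubes: Sequence[MetricCube]) -> pd.DataFrame:
    """Wide table: one row per sample, deterministic metric_wavelength_timepoint columns."""
    cols = cubes[0].column_names()
    data = np.vstack([c.flatten() for c in cubes])
    return pd.DataFrame(data, columns=cols, index=[c.sample_id for c in cubes]).rename_axis(
        "sample_id"
    )


def tidy_to_cubes(frame: pd.DataFrame) -> list[MetricCube]:
    """Rebuild cubes from the tidy long table."""
    cubes = []
    for sid, grp in frame.groupby("sample_id", sort=True):
        wavelengths = tuple(sorted(grp["wavelength_nm"].unique()))
        n_tp = int(grp["timepoint_index"].max())
        recs = [
            MetricRecord(r.metric, int(r.wavelength_nm), int(r.timepoint_index), r.value)
            for r in grp.itertuples()
            if np.isfinite(r.value)
        ]
        times = None
        if grp["time_s"].notna().any():
            tt = grp.drop_duplicates("timepoint_index").sort_values("timepoint_index")
            times = tt["time_s"].to_numpy()
        cubes.append(
            assemble_metric_cube(recs, str(sid), wavelengths, n_tp, times)
        )
    return cubes
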