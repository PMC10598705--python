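"""Synthetic study cohort with known ground truth.

Emulates the study design end to end: 20 coral colonies x 3 replicate
fragments, each colony dominated by one of six Symbiodiniaceae ITS2 types
(C1, C3, C15, C21, C26, D1) and assigned one of four light-response
phenotype archetypes. Every downstream stage (fitting, metric cube,
typing, clustering, statistics, network) can be exercised against this
known truth without any instrument or sequence data.

An archetype is a set of per-wavelength parameter trajectories over the
variable actinic protocol: each quenching state (NPQ, antenna-bed sigma
loss, reaction-center closure, tau shifts) relaxes as a first-order
response toward a segment- and irradiance-dependent asymptote. Flashlet
traces are produced through the single-turnover forward model with
multiplicative instrument noise; colony- and fragment-level lognormal
random effects perturb the archetype parameters.

Cellular traits are linear-Gaussian on the log scale with loadings on
per-colony photophysiology summaries, so that specific trait-metric
Pearson correlations are planted at a configurable magnitude (default
0.75): N:P loads negatively on mean Phi_PSII and positively on mean tau2;
C:P loads positively on NPQ amplitude (and, with a small weight, on qP
depression); granularity loads broadly; neutral lipids are an independent
negative control. ITS2 read counts are drawn multinomially after
multiplying true cell proportions by genus rDNA copy numbers
(Cladocopium 2119 : Durusdinium 362), so copy-number normalization is
required to recover the cell-level composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import (
    CANONICAL_WAVELENGTHS,
    DEFAULT_DOSE_PER_FLASHLET,
    N_INDUCTION_FLASHLETS,
    N_RELAXATION_FLASHLETS,
    STParams,
    STTrace,
    simulate_trace_pair,
    yield_from_closure,
)
from .protocol import (
    METRICS,
    ActinicProtocol,
    ConfigError,
    MetricCube,
    build_protocol,
)

__all__ = [
    "SYMBIONT_GENUS",
    "PhenotypeArchetype",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "plant_trait_correlations",
    "generate_its2_counts",
    "traits_with_ratios",
]

#: Genus of each shipped ITS2 type.
SYMBIONT_GENUS = {
    "C1": "Cladocopium", "C3": "Cladocopium", "C15": "Cladocopium",
    "C21": "Cladocopium", "C26": "Cladocopium", "D1": "Durusdinium",
}

#: rDNA copies per cell by genus (Cladocopium : Durusdinium = 2119 : 362).
DEFAULT_COPY_NUMBERS = {"Cladocopium": 2119.0, "Durusdinium": 362.0}


# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------

#: Relative excitation efficiency by wavelength (blue-absorbing pigments).
_SPECTRAL_SIGMA = {420: 1.15, 442: 1.00, 458: 0.90, 505: 0.60, 525: 0.55}
_SPECTRAL_FM = {420: 1.05, 442: 1.00, 458: 0.95, 505: 0.80, 525: 0.75}


@dataclass(frozen=True)
class PhenotypeArchetype:
    """Light-response archetype: baselines plus first-order response targets.

    Quenching states approach irradiance-dependent asymptotes
    ``amp * E / (E + E_half)`` with onset time constant ``tau_on_s`` under
    light and ``tau_off_s`` in the dark/on down-steps. Archetype 1 carries
    the largest NPQ amplitude and the slowest PQ-pool reoxidation (largest
    tau2); archetype 2 the smallest NPQ amplitude but the deepest, most
    sustained closure (qP depression).
    """

    archetype_id: int
    phi_dark: float
    sigma_dark: float  # A^2 quanta^-1 at 442 nm
    rho: float
    npq_amp: float
    npq_tau_on_s: float
    npq_tau_off_s: float
    abq_amp: float
    qp_depression: float  # asymptotic closed fraction at saturating light
    qp_tau_on_s: float
    qp_tau_off_s: float
    alpha: float
    tau1_us: float
    tau2_us: float
    tau2_light_frac: float  # fractional tau2 increase under saturating light
    e_half: float = 250.0  # irradiance half-saturation (umol m^-2 s^-1)
    fm_dark: float = 3000.0  # instrument units at 442 nm
    spectral_sigma: dict = field(default_factory=lambda: dict(_SPECTRAL_SIGMA))
    spectral_fm: dict = field(default_factory=lambda: dict(_SPECTRAL_FM))


DEFAULT_ARCHETYPES: dict[int, PhenotypeArchetype] = {
    1: PhenotypeArchetype(
        1, phi_dark=0.52, sigma_dark=620.0, rho=0.42,
        npq_amp=1.60, npq_tau_on_s=45.0, npq_tau_off_s=80.0,
        abq_amp=0.30, qp_depression=0.45, qp_tau_on_s=20.0, qp_tau_off_s=35.0,
        alpha=0.60, tau1_us=520.0, tau2_us=30_000.0, tau2_light_frac=0.35,
    ),
    2: PhenotypeArchetype(
        2, phi_dark=0.48, sigma_dark=500.0, rho=0.30,
        npq_amp=0.25, npq_tau_on_s=35.0, npq_tau_off_s=120.0,
        abq_amp=0.08, qp_depression=0.75, qp_tau_on_s=25.0, qp_tau_off_s=90.0,
        alpha=0.55, tau1_us=650.0, tau2_us=8_000.0, tau2_light_frac=0.20,
    ),
    3: PhenotypeArchetype(
        3, phi_dark=0.58, sigma_dark=700.0, rho=0.35,
        npq_amp=0.90, npq_tau_on_s=40.0, npq_tau_off_s=60.0,
        abq_amp=0.45, qp_depression=0.35, qp_tau_on_s=18.0, qp_tau_off_s=30.0,
        alpha=0.62, tau1_us=580.0, tau2_us=15_000.0, tau2_light_frac=0.30,
    ),
    4: PhenotypeArchetype(
        4, phi_dark=0.62, sigma_dark=560.0, rho=0.25,
        npq_amp=0.60, npq_tau_on_s=30.0, npq_tau_off_s=50.0,
        abq_amp=0.15, qp_depression=0.55, qp_tau_on_s=22.0, qp_tau_off_s=40.0,
        alpha=0.68, tau1_us=450.0, tau2_us=4_000.0, tau2_light_frac=0.15,
    ),
}

#: Colony dominant ITS2 type by archetype (cycled over colonies), mirroring
#: the qualitative type/phenotype association of the study design.
DEFAULT_TYPE_BY_ARCHETYPE = {
    1: ["C15", "C15", "C15", "C15", "C15"],
    2: ["D1", "D1", "D1", "C1", "D1"],
    3: ["C3", "D1", "C3", "C3", "D1"],
    4: ["C21", "C26", "C3", "C21", "C26"],
}


@dataclass
class CohortConfig:
    """Study-design and noise configuration of the synthetic cohort."""

    n_colonies: int = 20
    n_fragments: int = 3
    trace_noise_rel: float = 0.01  # multiplicative flashlet noise (fraction)
    colony_cv: float = 0.05  # lognormal CV of colony random effects
    fragment_cv: float = 0.02  # lognormal CV of fragment random effects
    trait_target_r: float = 0.75  # planted trait-summary Pearson magnitude
    trait_fragment_cv: float = 0.05
    n_reads: int = 20_000  # ITS2 sequencing depth per sample
    dominant_cell_fraction: tuple[float, float] = (0.78, 0.95)
    secondary_prob: float = 0.85  # chance a colony hosts a background type
    dose_per_flashlet: float = DEFAULT_DOSE_PER_FLASHLET
    archetypes: dict[int, PhenotypeArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    type_by_archetype: dict[int, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TYPE_BY_ARCHETYPE.items()}
    )
    protocol_config: Optional[dict] = None

    def validate(self) -> None:
        if not 0.0 <= self.trait_target_r < 1.0:
            raise ConfigError("trait_target_r must lie in [0, 1)")
        wl = set(CANONICAL_WAVELENGTHS)
        for a in self.archetypes.values():
            if not wl <= set(a.spectral_sigma) or not wl <= set(a.spectral_fm):
                raise ConfigError(
                    f"archetype {a.archetype_id} missing spectral modifiers for {wl}"
                )


# ---------------------------------------------------------------------------
# First-order trajectory machinery
# ---------------------------------------------------------------------------


def _first_order(
    times_s: np.ndarray,
    protocol: ActinicProtocol,
    target_of_e,
    tau_on_s: float,
    tau_off_s: float,
    x0: float = 0.0,
) -> np.ndarray:
    """Piecewise-exponential relaxation toward per-segment asymptotes."""
    out = np.empty(len(times_s))
    x = x0
    t_seg = 0.0
    i = 0
    for irr, dur in protocol.segments:
        target = target_of_e(irr)
        tau = tau_on_s if target > x else tau_off_s
        t_end = t_seg + dur
        while i < len(times_s) and times_s[i] < t_end - 1e-9:
            dt = times_s[i] - t_seg
            out[i] = target + (x - target) * np.exp(-dt / tau)
            i += 1
        x = target + (x - target) * np.exp(-dur / tau)
        t_seg = t_end
    while i < len(times_s):  # timepoints at the protocol end
        out[i] = x
        i += 1
    return out


def _sat(amp: float, e_half: float):
    return lambda e: amp * e / (e + e_half)


def archetype_trajectories(
    arch: PhenotypeArchetype, protocol: ActinicProtocol, wavelength_nm: int
) -> dict[str, np.ndarray]:
    """True per-timepoint parameter states at one wavelength.

    Returns the quantities the pipeline estimates: Fm', Fo' (Oxborough-Baker
    consistent), sigma', closed fraction C0, rho, alpha, tau1, tau2 and the
    derived metric values.
    """
    t = protocol.timepoint_times_s
    npq = _first_order(t, protocol, _sat(arch.npq_amp, arch.e_half),
                       arch.npq_tau_on_s, arch.npq_tau_off_s)
    abq = _first_order(t, protocol, _sat(arch.abq_amp, arch.e_half),
                       arch.npq_tau_on_s, arch.npq_tau_off_s)
    c0 = _first_order(t, protocol, _sat(arch.qp_depression, arch.e_half),
                      arch.qp_tau_on_s, arch.qp_tau_off_s)
    tau2 = arch.tau2_us * (1.0 + _first_order(
        t, protocol, _sat(arch.tau2_light_frac, arch.e_half), 30.0, 60.0))
    tau1 = arch.tau1_us * (1.0 + 0.3 * _first_order(
        t, protocol, _sat(arch.tau2_light_frac, arch.e_half), 30.0, 60.0))

    fm_dark = arch.fm_dark * arch.spectral_fm[wavelength_nm]
    fo_dark = fm_dark * (1.0 - arch.phi_dark)
    sigma_dark = arch.sigma_dark * arch.spectral_sigma[wavelength_nm]

    fm_p = fm_dark / (1.0 + npq)
    fv_over_fm = arch.phi_dark
    fo_p = fo_dark / (fv_over_fm + fo_dark / fm_p)  # OB-consistent quenched Fo
    sigma_p = sigma_dark * (1.0 - abq)
    f_p = np.array([
        yield_from_closure(c, fo, fm, arch.rho)
        for c, fo, fm in zip(c0, fo_p, fm_p)
    ])
    return {
        "Fm_prime": fm_p, "Fo_prime": fo_p, "F_prime": f_p,
        "sigma_prime": sigma_p, "C0": c0, "rho": np.full_like(t, arch.rho),
        "alpha": np.full_like(t, arch.alpha), "tau1": tau1, "tau2": tau2,
        "NPQ": npq, "ABQ": abq,
        "PhiPSII": (fm_p - f_p) / fm_p,
        "qP": (fm_p - f_p) / (fm_p - fo_p),
        "fm_dark": fm_dark, "fo_dark": fo_dark, "sigma_dark": sigma_dark,
    }


def _true_cube(
    arch: PhenotypeArchetype, protocol: ActinicProtocol, sample_id: str
) -> MetricCube:
    wavelengths = tuple(sorted(CANONICAL_WAVELENGTHS))
    values = np.empty((len(METRICS), len(wavelengths), protocol.n_timepoints))
    for wi, w in enumerate(wavelengths):
        tr = archetype_trajectories(arch, protocol, w)
        per_metric = {
            "PhiPSII": tr["PhiPSII"], "SigmaPSII": tr["sigma_prime"],
            "Rho": tr["rho"], "NPQ": tr["NPQ"], "ABQ": tr["ABQ"],
            "qP": tr["qP"], "Tau1ST": tr["tau1"], "Tau2ST": tr["tau2"],
        }
        for mi, m in enumerate(METRICS):
            values[mi, wi] = per_metric[m]
    return MetricCube(sample_id, values, wavelengths, protocol.timepoint_times_s)


def _perturbed(arch: PhenotypeArchetype, rng: np.random.Generator, cv: float) -> PhenotypeArchetype:
    """Lognormal random effects on the archetype parameters."""
    if cv <= 0:
        return arch
    s = np.sqrt(np.log1p(cv**2))

    def ln() -> float:
        return float(np.exp(rng.normal(-0.5 * s * s, s)))

    return replace(
        arch,
        phi_dark=min(arch.phi_dark * ln(), 0.78),
        sigma_dark=arch.sigma_dark * ln(),
        rho=min(arch.rho * ln(), 0.70),
        npq_amp=arch.npq_amp * ln(),
        abq_amp=min(arch.abq_amp * ln(), 0.8),
        qp_depression=min(arch.qp_depression * ln(), 0.92),
        alpha=min(arch.alpha * ln(), 0.95),
        tau1_us=arch.tau1_us * ln(),
        tau2_us=arch.tau2_us * ln(),
        fm_dark=arch.fm_dark * ln(),
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Generated cohort: truth sidecar, true cubes, traits and ITS2 counts.

    ``truth`` is a per-fragment table (sample_id, colony_id, fragment,
    archetype, dominant_type, secondary_type, dominant_cell_fraction,
    environment); it is written as a sidecar for evaluation and never
    consumed by analysis stages.
    """

    config: CohortConfig
    seed: int
    protocol: ActinicProtocol
    truth: pd.DataFrame
    true_cubes: list[MetricCube]
    latents: pd.DataFrame  # per-colony photophysiology summaries
    traits: pd.DataFrame  # per-fragment cellular traits
    its2_counts: pd.DataFrame  # sample x ITS2 type read counts
    _fragment_archetypes: dict[str, PhenotypeArchetype] = field(repr=False, default=None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.truth["sample_id"])

    def colony_map(self) -> pd.Series:
        return self.truth.set_index("sample_id")["colony_id"]

    def sample_traces(
        self, sample_id: str, noise_rel: Optional[float] = None, n_repeats: Optional[int] = None
    ) -> dict[tuple[int, int], list[STTrace]]:
        """Simulate flashlet traces for one fragment.

        Returns ``{(wavelength_nm, timepoint_index): [repeat traces]}``.
        Deterministic given the cohort seed and sample id (per-sample seed
        streams), independent of generation order.
        """
        noise = self.config.trace_noise_rel if noise_rel is None else noise_rel
        reps = self.protocol.n_repeats if n_repeats is None else n_repeats
        arch = self._fragment_archetypes[sample_id]
        idx = self.sample_ids.index(sample_id)
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(1, idx)))
        out: dict[tuple[int, int], list[STTrace]] = {}
        for w in sorted(CANONICAL_WAVELENGTHS):
            tr = archetype_trajectories(arch, self.protocol, w)
            for ti in range(self.protocol.n_timepoints):
                tau2 = float(tr["tau2"][ti])
                params = STParams(
                    F0=float(tr["Fo_prime"][ti]), Fm=float(tr["Fm_prime"][ti]),
                    sigma_PSII=float(tr["sigma_prime"][ti]), rho=float(tr["rho"][ti]),
                    C0=float(tr["C0"][ti]),
                    alpha=float(tr["alpha"][ti]),
                    tau1_us=float(tr["tau1"][ti]),
                    tau2_us=max(tau2, float(tr["tau1"][ti]) * 1.001 + 1e-6),
                )
                out[(w, ti + 1)] = [
                    simulate_trace_pair(
                        params, w, noise_rel=noise, rng=rng,
                        dose_per_flashlet=self.config.dose_per_flashlet,
                        sample_id=sample_id, timepoint_index=ti + 1, repeat_index=r + 1,
                    )
                    for r in range(reps)
                ]
        return out

    def all_traces(self):
        """Yield (sample_id, traces dict) over the whole cohort."""
        for sid in self.sample_ids:
            yield sid, self.sample_traces(sid)


def generate_cohort(config: Optional[CohortConfig] = None, seed: int = 0) -> Cohort:
    """Generate the full synthetic study (deterministic given ``seed``)."""
    cfg = config or CohortConfig()
    cfg.validate()
    protocol = build_protocol(cfg.protocol_config)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))

    arch_ids = sorted(cfg.archetypes)
    rows = []
    frag_archetypes: dict[str, PhenotypeArchetype] = {}
    true_cubes = []
    colony_latents = []
    per_arch_counter: dict[int, int] = dict.fromkeys(arch_ids, 0)

    for c in range(cfg.n_colonies):
        arch_id = arch_ids[c % len(arch_ids)]
        base = cfg.archetypes[arch_id]
        type_list = cfg.type_by_archetype.get(arch_id, ["C1"])
        dom_type = type_list[per_arch_counter[arch_id] % len(type_list)]
        per_arch_counter[arch_id] += 1
        colony_id = f"colony{c + 1:02d}"
        colony_arch = _perturbed(base, rng, cfg.colony_cv)
        env = "indoor" if c % 2 == 0 else "outdoor"
        p_dom = float(rng.uniform(*cfg.dominant_cell_fraction))
        other_types = [t for t in SYMBIONT_GENUS if t != dom_type]
        sec_type = (
            str(rng.choice(other_types)) if rng.uniform() < cfg.secondary_prob else ""
        )
        if not sec_type:
            p_dom = 1.0

        # colony summaries from the colony-level (pre-fragment) archetype
        cube_c = _true_cube(colony_arch, protocol, colony_id)
        v = cube_c.values
        mi = {m: i for i, m in enumerate(METRICS)}
        colony_latents.append({
            "colony_id": colony_id, "archetype": arch_id,
            "phi_mean": float(np.nanmean(v[mi["PhiPSII"]])),
            "npq_amp": float(np.nanmean(np.nanmax(v[mi["NPQ"]], axis=1))),
            "tau2_mean": float(np.nanmean(v[mi["Tau2ST"]])),
            "qp_depression": float(1.0 - np.nanmean(np.nanmin(v[mi["qP"]], axis=1))),
        })

        for f in range(cfg.n_fragments):
            sid = f"{colony_id}_f{f + 1}"
            frag_arch = _perturbed(colony_arch, rng, cfg.fragment_cv)
            frag_archetypes[sid] = frag_arch
            true_cubes.append(_true_cube(frag_arch, protocol, sid))
            rows.append({
                "sample_id": sid, "colony_id": colony_id, "fragment": f + 1,
                "archetype": arch_id, "dominant_type": dom_type,
                "secondary_type": sec_type, "dominant_cell_fraction": p_dom,
                "environment": env,
            })

    truth = pd.DataFrame(rows)
    latents = pd.DataFrame(colony_latents).set_index("colony_id")
    traits = plant_trait_correlations(
        latents, truth, cfg, np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    )
    its2 = generate_its2_counts(
        truth, cfg, np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    )
    return Cohort(
        config=cfg, seed=seed, protocol=protocol, truth=truth,
        true_cubes=true_cubes, latents=latents, traits=traits, its2_counts=its2,
        _fragment_archetypes=frag_archetypes,
    )


# ---------------------------------------------------------------------------
# Cellular traits with planted correlation structure
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ConfigError("latent summary has zero variance across colonies")
    return (x - x.mean()) / sd


def _planted_two(
    z1: np.ndarray, z2: np.ndarray, r1: float, r2: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized variable with marginal Pearson r1 vs z1 and r2 vs z2.

    Solves the 2x2 system on the empirical correlation of (z1, z2); the
    residual noise variance tops the variable up to unit variance. Requested
    correlations infeasible under the empirical latent correlation raise a
    config error.
    """
    if max(abs(r1), abs(r2)) >= 1.0:
        raise ConfigError("requested |r| must be < 1")
    rho12 = float(np.corrcoef(z1, z2)[0, 1])
    sig = np.array([[1.0, rho12], [rho12, 1.0]])
    c = np.array([r1, r2])
    w = np.linalg.solve(sig, c)
    explained = float(w @ c)
    if explained > 1.0:
        raise ConfigError(
            f"planted correlations (r1={r1}, r2={r2}) infeasible at latent corr {rho12:.2f}"
        )
    x = w[0] * z1 + w[1] * z2
    if explained < 1.0:
        x = x + np.sqrt(1.0 - explained) * rng.standard_normal(len(z1))
    return x


def _planted_loading(
    z_main: np.ndarray, z_extra: np.ndarray, r_main: float, loading_extra: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Marginal r on z_main plus a fixed positive loading on z_extra."""
    if abs(r_main) >= 1.0:
        raise ConfigError("requested |r| must be < 1")
    rho = float(np.corrcoef(z_main, z_extra)[0, 1])
    a = r_main - loading_extra * rho
    var = a * a + loading_extra**2 + 2 * a * loading_extra * rho
    if var > 1.0:
        raise ConfigError("planted loading combination infeasible")
    x = a * z_main + loading_extra * z_extra
    if var < 1.0:
        x = x + np.sqrt(1.0 - var) * rng.standard_normal(len(z_main))
    return x


#: Archetype means of bead-normalized cell size (planted group ordering).
_CELL_SIZE_BY_ARCHETYPE = {1: 1.00, 2: 1.35, 3: 0.90, 4: 1.10}
_CHLA_BY_ARCHETYPE = {1: 1.10, 2: 0.95, 3: 1.25, 4: 1.00}


def plant_trait_correlations(
    latents: pd.DataFrame,
    truth: pd.DataFrame,
    config: Optional[CohortConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Generate per-fragment cellular traits with planted correlations.

    ``latents`` is the per-colony summary table (phi_mean, npq_amp,
    tau2_mean, qp_depression). Trait values are lognormal: the planted
    standardized variable enters the log with a 0.25 SD, keeping all traits
    positive while preserving the Pearson structure to within a small
    monotone-transform attenuation. C, N, P per cell are generated from a
    free P draw and the planted atomic ratios, never the other way around.
    """
    cfg = config or CohortConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    r = cfg.trait_target_r

    z_phi = _standardize(latents["phi_mean"].to_numpy())
    z_npq = _standardize(latents["npq_amp"].to_numpy())
    z_tau2 = _standardize(latents["tau2_mean"].to_numpy())
    z_qp = _standardize(latents["qp_depression"].to_numpy())

    x_np = _planted_two(z_phi, z_tau2, -r, r, rng)  # N:P
    x_cp = _planted_loading(z_npq, z_qp, r, 0.2, rng)  # C:P
    broad = _standardize(z_phi + z_npq + z_tau2 + z_qp)
    x_gran = 0.6 * broad + np.sqrt(1 - 0.36) * rng.standard_normal(len(broad))

    n_col = len(latents)
    arch = latents["archetype"].to_numpy()
    scale = 0.25
    np_atomic = 16.0 * np.exp(scale * x_np)
    cp_atomic = 106.0 * np.exp(scale * x_cp)
    p_pg = 0.5 * np.exp(0.2 * rng.standard_normal(n_col))
    n_pg = np_atomic * (14.0 / 31.0) * p_pg
    c_pg = cp_atomic * (12.0 / 31.0) * p_pg
    granularity = np.exp(scale * x_gran)
    lipids = np.exp(scale * rng.standard_normal(n_col))  # independent control
    size = np.array([_CELL_SIZE_BY_ARCHETYPE[a] for a in arch]) * np.exp(
        0.05 * rng.standard_normal(n_col)
    )
    chla = np.array([_CHLA_BY_ARCHETYPE[a] for a in arch]) * np.exp(
        0.10 * rng.standard_normal(n_col)
    )

    colony_traits = pd.DataFrame({
        "colony_id": latents.index,
        "cell_size": size, "granularity": granularity, "chla": chla,
        "C_per_cell": c_pg, "N_per_cell": n_pg, "P_per_cell": p_pg,
        "neutral_lipids": lipids,
    }).set_index("colony_id")

    rows = []
    s = np.sqrt(np.log1p(cfg.trait_fragment_cv**2))
    trait_cols = list(colony_traits.columns)
    for rec in truth.itertuples():
        base = colony_traits.loc[rec.colony_id]
        noise = np.exp(rng.normal(-0.5 * s * s, s, size=len(trait_cols)))
        rows.append({"sample_id": rec.sample_id, "colony_id": rec.colony_id,
                     **{c: float(base[c] * noise[i]) for i, c in enumerate(trait_cols)}})
    return pd.DataFrame(rows)


def traits_with_ratios(traits: pd.DataFrame) -> pd.DataFrame:
    """Append atomic C:N, C:P and N:P ratios computed from per-cell masses."""
    out = traits.copy()
    c, n, p = out["C_per_cell"] / 12.0, out["N_per_cell"] / 14.0, out["P_per_cell"] / 31.0
    out["C:N"] = c / n
    out["C:P"] = c / p
    out["N:P"] = n / p
    return out


# ---------------------------------------------------------------------------
# ITS2 counts
# ---------------------------------------------------------------------------


def generate_its2_counts(
    truth: pd.DataFrame,
    config: Optional[CohortConfig] = None,
    rng: Optional[np.random.Generator] = None,
    copy_numbers: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Multinomial ITS2 read counts biased by genus rDNA copy number.

    Read probabilities are proportional to (cell proportion x copies per
    cell of the type's genus), so raw read shares over-represent
    Cladocopium (2119 copies) relative to Durusdinium (362) and must be
    copy-number normalized to recover cell-level composition.
    """
    cfg = config or CohortConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    copies = copy_numbers or DEFAULT_COPY_NUMBERS
    types = sorted(SYMBIONT_GENUS)
    rows = []
    for rec in truth.itertuples():
        props = dict.fromkeys(types, 0.0)
        if rec.secondary_type:
            props[rec.dominant_type] = rec.dominant_cell_fraction
            props[rec.secondary_type] = 1.0 - rec.dominant_cell_fraction
        else:
            props[rec.dominant_type] = 1.0
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("cell proportions must sum to 1")
        weights = np.array([props[t] * copies[SYMBIONT_GENUS[t]] for t in types])
        counts = rng.multinomial(cfg.n_reads, weights / weights.sum())
        rows.append({"sample_id": rec.sample_id, **dict(zip(types, counts.tolist()))})
    return pd.DataFrame(rows).set_index("sample_id")
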