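"""End-to-end pipeline: simulate -> fit -> cube -> type -> cluster -> stats -> network.

Binds the stages into one reproducible run. Every output table is a UTF-8
tab-delimited file carrying a schema-version header line; a run directory
also receives the resolved configuration and a manifest of SHA-256 file
hashes, so that rerunning with the same config and seed reproduces the
hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, groupstats, network, symbionts
from .cohort import Cohort, CohortConfig, generate_cohort, traits_with_ratios
from .kinetics import STFitResult, STParams, STTrace, frame_to_traces, traces_to_frame
from .protocol import (
    ActinicProtocol,
    MetricCube,
    acquire_timepoint,
    assemble_metric_cube,
    build_protocol,
    cubes_to_tidy,
    cubes_to_wide,
    derive_metrics,
)

__all__ = [
    "SCHEMA_VERSION",
    "PipelineConfig",
    "write_table",
    "read_table",
    "fit_sample",
    "fit_cohort",
    "fits_to_frame",
    "frame_to_fits",
    "cubes_from_fits",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "phenoflux-table-v1"
_SCHEMA_LINE = f"# schema: {SCHEMA_VERSION}"

FIT_COLUMNS = [
    "sample_id", "wavelength_nm", "timepoint_index", "F0", "Fm", "sigma_PSII",
    "rho", "C0", "alpha", "tau1_us", "tau2_us", "phi_PSII", "residual_rms",
    "converged",
]


class SchemaError(ValueError):
    """Table schema version mismatch."""


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a tab-delimited table with the schema-version header line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_SCHEMA_LINE + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a schema-versioned table, rejecting version mismatches."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("# schema: "):
            raise SchemaError(f"{path}: missing schema header")
        if first != _SCHEMA_LINE:
            raise SchemaError(f"{path}: schema {first[10:]!r} != {SCHEMA_VERSION!r}")
        return pd.read_csv(fh, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    seed: int = 0
    outdir: str = "phenoflux_run"
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    protocol: dict = field(default_factory=dict)  # build_protocol overrides
    n_boot: int = 1000
    k_phenotypes: int = 4
    network_threshold: float = 0.6
    dominance_basis: str = "normalized"
    write_traces: bool = False
    run_stats: bool = True

    def cohort_config(self) -> CohortConfig:
        cfg = CohortConfig(**{
            k: v for k, v in self.cohort.items() if k in
            {f.name for f in dataclasses.fields(CohortConfig)}
        })
        if self.protocol:
            cfg.protocol_config = dict(self.protocol)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Fitting stage
# ---------------------------------------------------------------------------


def fit_sample(
    traces_by_key: dict[tuple[int, int], list[STTrace]],
    protocol: ActinicProtocol,
    sample_id: str,
) -> tuple[MetricCube, list[dict]]:
    """Fit all acquisitions of one sample and derive its metric cube.

    ``traces_by_key`` maps (wavelength_nm, timepoint_index 1-based) to the
    repeat traces. The dark-acclimated fit at timepoint 1 per wavelength is
    the quenching reference; light-adapted timepoints are fit with the
    connectivity pinned to the dark value and the minimal fluorescence tied
    to the Oxborough-Baker estimate, which keeps the light-adapted induction
    identifiable.
    """
    fits: dict[tuple[int, int], STFitResult] = {}
    for (w, tp), repeats in sorted(traces_by_key.items()):
        dark_acclim = protocol.is_dark_acclimated(tp)
        rho_fixed = None
        f0_tie = None
        if not dark_acclim:
            ref = fits.get((w, 1))
            if ref is not None and ref.converged:
                rho_fixed = ref.params.rho
                f0_tie = (ref.params.F0, ref.params.Fm)
        fits[(w, tp)] = acquire_timepoint(
            repeats,
            dark=dark_acclim,
            n_repeats_expected=protocol.n_repeats,
            rho_fixed=rho_fixed,
            f0_from_dark=f0_tie,
        )
    records = []
    rows = []
    for (w, tp), fit in sorted(fits.items()):
        dark = fits.get((w, 1))
        if dark is None:
            raise ValueError(f"sample {sample_id}: no dark reference at wavelength {w}")
        records.extend(derive_metrics(dark, fit, w, tp))
        p = fit.params
        rows.append({
            "sample_id": sample_id, "wavelength_nm": w, "timepoint_index": tp,
            "F0": p.F0, "Fm": p.Fm, "sigma_PSII": p.sigma_PSII, "rho": p.rho,
            "C0": p.C0, "alpha": p.alpha, "tau1_us": p.tau1_us, "tau2_us": p.tau2_us,
            "phi_PSII": fit.phi_PSII, "residual_rms": fit.residual_rms,
            "converged": fit.converged,
        })
    wavelengths = sorted({w for w, _ in fits})
    cube = assemble_metric_cube(
        records, sample_id, wavelengths, protocol.n_timepoints,
        protocol.timepoint_times_s,
    )
    return cube, rows


def fit_cohort(
    cohort: Cohort, progress: bool = False
) -> tuple[list[MetricCube], pd.DataFrame]:
    """Fit every fragment of a synthetic cohort (streamed, one at a time)."""
    cubes, rows = [], []
    for i, sid in enumerate(cohort.sample_ids):
        cube, r = fit_sample(cohort.sample_traces(sid), cohort.protocol, sid)
        cubes.append(cube)
        rows.extend(r)
        if progress:
            logger.info("fitted sample %d/%d (%s)", i + 1, len(cohort.sample_ids), sid)
    return cubes, pd.DataFrame(rows)[FIT_COLUMNS]


def fits_to_frame(rows: pd.DataFrame) -> pd.DataFrame:
    return rows[FIT_COLUMNS]


def frame_to_fits(frame: pd.DataFrame) -> dict[str, dict[tuple[int, int], STFitResult]]:
    """Rebuild per-sample fit results from the fits table."""
    out: dict[str, dict[tuple[int, int], STFitResult]] = {}
    for r in frame.itertuples():
        tau1 = float(r.tau1_us)
        tau2 = float(r.tau2_us)
        if np.isfinite(tau2) and np.isfinite(tau1) and tau2 <= tau1:
            tau2 = tau1 * 1.001
        params = STParams(
            F0=float(r.F0), Fm=max(float(r.Fm), float(r.F0) * (1 + 1e-9)),
            sigma_PSII=float(r.sigma_PSII), rho=float(r.rho), C0=float(r.C0),
            alpha=float(np.clip(r.alpha, 0, 1)) if np.isfinite(r.alpha) else 0.0,
            tau1_us=tau1 if np.isfinite(tau1) else 600.0, tau2_us=tau2,
        ) if np.isfinite(r.F0) and np.isfinite(r.sigma_PSII) else STParams(
            F0=1.0, Fm=1.001, sigma_PSII=np.nan, rho=0.0, tau1_us=1.0, tau2_us=np.nan
        )
        res = STFitResult(params=params, residual_rms=float(r.residual_rms),
                          converged=bool(r.converged))
        out.setdefault(str(r.sample_id), {})[(int(r.wavelength_nm), int(r.timepoint_index))] = res
    return out


def cubes_from_fits(
    frame: pd.DataFrame, protocol: ActinicProtocol
) -> list[MetricCube]:
    """Derive metric cubes from a fits table (dark reference at timepoint 1)."""
    cubes = []
    for sid, fits in sorted(frame_to_fits(frame).items()):
        records = []
        for (w, tp), fit in sorted(fits.items()):
            records.extend(derive_metrics(fits[(w, 1)], fit, w, tp))
        wavelengths = sorted({w for w, _ in fits})
        cubes.append(assemble_metric_cube(
            records, sid, wavelengths, protocol.n_timepoints, protocol.timepoint_times_s
        ))
    return cubes


# ---------------------------------------------------------------------------
# Run directory
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages into a run directory and write the manifest.

    Stage order: simulate -> fit -> cube -> type -> cluster -> stats ->
    network. A stage failure halts the run with a stage-scoped error;
    partial outputs are retained. Rerunning with the same config and seed
    reproduces the manifest hashes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                timings[name] = round(dt, 3)
                if exc_type is not None:
                    logger.error("stage %s: FAILED after %.1fs", name, dt)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.1fs", name, dt)

        return _Stage()

    with stage("simulate"):
        cohort = generate_cohort(config.cohort_config(), seed=config.seed)
        write_table(cohort.truth, outdir / "truth.tsv")
        write_table(cohort.traits, outdir / "traits.tsv")
        write_table(cohort.its2_counts.reset_index(), outdir / "its2_counts.tsv")
        if config.write_traces:
            frames = [traces_to_frame([t for trs in d.values() for t in trs])
                      for _, d in cohort.all_traces()]
            write_table(pd.concat(frames, ignore_index=True), outdir / "traces.tsv")

    with stage("fit"):
        cubes, fit_rows = fit_cohort(cohort, progress=True)
        write_table(fit_rows, outdir / "fits.tsv")

    with stage("cube"):
        tidy = cubes_to_tidy(cubes)
        wide = cubes_to_wide(cubes)
        write_table(tidy, outdir / "cube_tidy.tsv")
        write_table(wide, outdir / "cube_wide.tsv", index=True)

    with stage("type"):
        types = symbionts.dominant_types_table(
            cohort.its2_counts, basis=config.dominance_basis
        )
        write_table(types.reset_index(), outdir / "dominant_types.tsv")

    with stage("cluster"):
        groups = types["dominant_type"]
        usable = groups[groups != symbionts.MIXED]
        screen = clustering.screen_metrics(wide.loc[usable.index], usable)
        write_table(pd.DataFrame([s.__dict__ for s in screen]), outdir / "screen.tsv")
        kept = clustering.kept_metrics(screen)
        z = clustering.zscore_matrix(wide[kept])
        result = clustering.bootstrap_cluster(z, n_boot=config.n_boot, seed=config.seed)
        assignment = clustering.cut_phenotypes(result, k=config.k_phenotypes)
        write_table(assignment.labels.reset_index(), outdir / "phenotypes.tsv")
        write_table(result.support, outdir / "node_support.tsv")
        (outdir / "dendrogram.nwk").write_text(clustering.to_newick(result), encoding="utf-8")
        per_metric, families = clustering.rank_driver_metrics(z, assignment)
        write_table(per_metric, outdir / "driver_metrics.tsv")
        write_table(families, outdir / "driver_families.tsv")

    if config.run_stats:
        with stage("stats"):
            contrasts = groupstats.compare_profiles(tidy, assignment.labels, "phenotype")
            contrasts["pair"] = contrasts["pair"].astype(str)
            write_table(contrasts, outdir / "phenotype_contrasts.tsv")
            traits_r = traits_with_ratios(cohort.traits)
            trait_cols = ["cell_size", "granularity", "chla", "neutral_lipids",
                          "C:N", "C:P", "N:P"]
            comps = groupstats.compare_cellular_traits(
                traits_r, assignment.labels, trait_cols
            )
            rows = [{"trait": c.trait, "test": c.test, "p_omnibus": c.p_omnibus,
                     "letters": json.dumps({str(k): v for k, v in c.letters.items()})}
                    for c in comps]
            write_table(pd.DataFrame(rows), outdir / "trait_stats.tsv")

    with stage("network"):
        traits_r = traits_with_ratios(cohort.traits).set_index("sample_id")
        colony_map = cohort.colony_map()
        trait_cols = ["cell_size", "granularity", "chla", "neutral_lipids",
                      "C:N", "C:P", "N:P"]
        colony_metrics = network.average_replicates(wide, colony_map)
        colony_traits = network.average_replicates(traits_r[trait_cols], colony_map)
        net = network.correlate_traits(
            colony_metrics, colony_traits, threshold=config.network_threshold
        )
        network.export_graph(net, outdir / "network.graphml", "graphml", allow_empty=True)
        network.export_graph(net, outdir / "network_edges.tsv", "edgelist", allow_empty=True)
        write_table(net.summary(), outdir / "network_summary.tsv")

    manifest = {
        "schema": SCHEMA_VERSION,
        "seed": config.seed,
        "timings_s": timings,
        "files": {
            p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
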