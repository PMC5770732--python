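"""Synthetic multi-subject resting-state cohorts with known ground truth.

Generates 4D volumetric runs in which a shared set of smooth spatial
networks is mixed with vector-autoregressive (VAR) time courses and
Gaussian observation noise.  Group differences are planted in two ways
that mirror what the downstream analysis estimates:

* **spatial-map amplitude** differences (the functional-connectivity
  analog) — per-network amplitude multipliers that differ between
  groups, and
* **directed lag-1 coupling** differences (the effective-connectivity
  analog) — group-specific VAR coefficient matrices.

Every run is a deterministic function of the cohort seed, and the
generator returns a :class:`GroundTruth` manifest so that recovery of
the planted structure can be asserted exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .preprocess import BoldRun, fwhm_to_sigma

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "PlacementError",
    "UnstableCouplingError",
    "default_couplings",
    "make_spatial_sources",
    "generate_var_timecourses",
    "generate_cohort",
    "write_cohort",
]


class PlacementError(ValueError):
    """Grid too small to place the requested number of network blobs."""


class UnstableCouplingError(ValueError):
    """VAR coupling matrix has spectral radius >= 1 (non-stationary)."""


def default_couplings(n_networks: int = 6, weakened_edges=None,
                      base_diag: float = 0.3, edge_strength: float = 0.5,
                      weakened_strength: float = 0.2):
    """Default per-group lag-1 coupling matrices.

    Convention: ``C[i, j]`` is the influence of network ``j`` at time
    ``t - 1`` on network ``i`` at time ``t``.  The control group carries
    directed edges at ``edge_strength``; in the patient group the edges
    listed in ``weakened_edges`` are reduced to ``weakened_strength``
    (default gap 0.3).  All edges run from higher to lower network index
    so both matrices are triangular and stationarity holds whenever
    ``base_diag < 1``.

    Returns ``(coupling_patients, coupling_controls)``.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks for directed edges")
    base = np.eye(n_networks) * base_diag
    # controls: directed edges target -> source pattern (i, j) = j drives i
    edges = [(0, 3), (1, 4), (2, 5)] if n_networks >= 6 else [(0, n_networks - 1)]
    if weakened_edges is None:
        weakened_edges = edges[:2] if n_networks >= 6 else edges[:1]
    controls = base.copy()
    for i, j in edges:
        controls[i, j] = edge_strength
    patients = controls.copy()
    for i, j in weakened_edges:
        if j >= n_networks or i >= n_networks:
            raise ValueError(f"weakened edge ({i}, {j}) outside network range")
        patients[i, j] = weakened_strength
    return patients, controls


@dataclass
class CohortConfig:
    """Study conditions for a synthetic two-group cohort.

    Defaults are a scaled-down version of a typical resting-state
    case--control acquisition (larger, acquisition-scale settings —
    20 per group, a 64x64x36 matrix, 240 volumes at TR = 2 s — are a
    configuration choice, not a code change).
    """

    n_per_group: int = 12
    grid: tuple[int, int, int] = (16, 16, 8)
    n_volumes: int = 150
    tr_seconds: float = 2.0
    n_networks: int = 6
    coupling_patients: np.ndarray | None = None
    coupling_controls: np.ndarray | None = None
    #: per-group, per-network amplitude multipliers, shape (2, n_networks);
    #: row 0 = patients, row 1 = controls.
    effect_map: np.ndarray | None = None
    noise_sd: float = 0.5
    smooth_fwhm_mm: float = 6.0
    voxel_size_mm: tuple[float, float, float] = (3.4375, 3.4375, 3.0)
    #: global signal scale applied to the unit-norm source maps; the
    #: default puts blob-core voxels near a signal SD of 1 against the
    #: default observation noise SD of 0.5.
    amplitude: float = 5.0
    #: between-subject SD of the per-network global amplitude jitter.
    amplitude_jitter_sd: float = 0.15
    #: between-subject SD of the per-network *core-region* intensity
    #: multiplier.  Spatial z-maps are scale free, so a purely global
    #: amplitude change cancels; the planted map effect therefore scales
    #: the blob core relative to its periphery, which z-scoring keeps.
    regional_jitter_sd: float = 0.2
    #: fraction of a source's peak defining its core region.
    core_threshold: float = 0.5
    #: planted core-intensity gap, in regional-jitter-SD units, applied
    #: to ``effect_networks`` in the patient group.
    effect_gap_sd: float = 1.0
    effect_networks: tuple[int, ...] = (0, 1, 2)
    innovation_sd: float = 1.0
    #: correlation between patients' severity score and their network-0
    #: amplitude deviation (the planted severity association).
    severity_coupling: float = 0.8
    seed: int = 0

    def resolve(self) -> "CohortConfig":
        """Return a copy with coupling matrices and effect map filled in."""
        cfg = dataclasses.replace(self)
        if cfg.coupling_patients is None or cfg.coupling_controls is None:
            pat, ctl = default_couplings(cfg.n_networks)
            cfg.coupling_patients = pat if cfg.coupling_patients is None else np.asarray(cfg.coupling_patients, float)
            cfg.coupling_controls = ctl if cfg.coupling_controls is None else np.asarray(cfg.coupling_controls, float)
        else:
            cfg.coupling_patients = np.asarray(cfg.coupling_patients, float)
            cfg.coupling_controls = np.asarray(cfg.coupling_controls, float)
        if cfg.effect_map is None:
            # global multipliers default to 1; the planted map difference
            # lives in the core-region multipliers (see regional_jitter_sd)
            cfg.effect_map = np.ones((2, cfg.n_networks))
        else:
            cfg.effect_map = np.asarray(cfg.effect_map, float)
        cfg.effect_networks = tuple(k for k in cfg.effect_networks
                                    if k < cfg.n_networks)
        cfg.grid = tuple(int(g) for g in cfg.grid)
        cfg.voxel_size_mm = tuple(float(v) for v in cfg.voxel_size_mm)
        return cfg

    def validate(self) -> None:
        cfg = self.resolve()
        if cfg.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if cfg.n_volumes <= 10 * cfg.n_networks:
            raise ValueError("n_volumes must exceed 10 x n_networks")
        if cfg.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, mat in (("coupling_patients", cfg.coupling_patients),
                          ("coupling_controls", cfg.coupling_controls)):
            _check_stable(mat, name)
        if cfg.effect_map.shape != (2, cfg.n_networks):
            raise ValueError("effect_map must have shape (2, n_networks)")


@dataclass
class GroundTruth:
    """What was planted: the oracle for every downstream stage."""

    source_maps: np.ndarray          # (n_networks, n_voxels), unit-norm rows
    grid: tuple[int, int, int]
    timecourses: dict[str, np.ndarray]   # subject_id -> (n_networks, t)
    amplitudes: dict[str, np.ndarray]    # subject_id -> per-network amplitude
    #: subject_id -> per-network core-region intensity multiplier
    regional_multipliers: dict[str, np.ndarray]
    #: (n_networks, n_voxels) boolean core-region masks
    core_masks: np.ndarray
    coupling_patients: np.ndarray
    coupling_controls: np.ndarray
    planted_edges: list[tuple[int, int]]      # (target, source) index pairs
    planted_networks: list[int]               # map-intensity-different networks
    severity_coupling: float
    seed: int

    def source_volumes(self) -> np.ndarray:
        """Source maps reshaped to (n_networks, *grid)."""
        return self.source_maps.reshape((-1,) + tuple(self.grid))

    def to_json(self) -> str:
        d = {
            "grid": list(self.grid),
            "source_maps": self.source_maps.tolist(),
            "timecourses": {k: v.tolist() for k, v in self.timecourses.items()},
            "amplitudes": {k: v.tolist() for k, v in self.amplitudes.items()},
            "regional_multipliers": {k: v.tolist() for k, v in
                                     self.regional_multipliers.items()},
            "core_masks": self.core_masks.astype(int).tolist(),
            "coupling_patients": self.coupling_patients.tolist(),
            "coupling_controls": self.coupling_controls.tolist(),
            "planted_edges": [list(e) for e in self.planted_edges],
            "planted_networks": list(self.planted_networks),
            "severity_coupling": self.severity_coupling,
            "seed": self.seed,
        }
        return json.dumps(d)


def _check_stable(coupling: np.ndarray, name: str = "coupling") -> np.ndarray:
    coupling = np.asarray(coupling, dtype=float)
    if coupling.ndim != 2 or coupling.shape[0] != coupling.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    radius = np.max(np.abs(np.linalg.eigvals(coupling)))
    if radius >= 1.0:
        raise UnstableCouplingError(
            f"{name} has spectral radius {radius:.3f} >= 1; the VAR would be non-stationary")
    return coupling


def make_spatial_sources(grid, n_networks, smooth_fwhm_mm=6.0,
                         voxel_size_mm=(3.4375, 3.4375, 3.0), seed=0,
                         radius_voxels=2.0, min_separation_voxels=4):
    """Place ``n_networks`` smooth, nearly non-overlapping blobs on ``grid``.

    Each source starts as a spherical indicator of ``radius_voxels``
    centred on a lattice point (lattice spacing ``min_separation_voxels``,
    guaranteeing low overlap), is optionally smoothed with a Gaussian of
    ``smooth_fwhm_mm``, and is normalised to unit Euclidean norm.

    Returns an array of shape ``(n_networks, n_voxels)``.

    Raises
    ------
    PlacementError
        If the lattice does not offer enough centres for the request.
    """
    from scipy.ndimage import gaussian_filter

    grid = tuple(int(g) for g in grid)
    rng = np.random.default_rng(seed)
    margin = int(np.ceil(radius_voxels))
    centers = []
    for candidate in _lattice(grid, min_separation_voxels, margin):
        centers.append(candidate)
    if len(centers) < n_networks:
        raise PlacementError(
            f"grid {grid} offers only {len(centers)} blob centres at separation "
            f"{min_separation_voxels}; cannot place {n_networks} networks")
    chosen = [centers[i] for i in rng.permutation(len(centers))[:n_networks]]

    ii, jj, kk = np.meshgrid(*[np.arange(g) for g in grid], indexing="ij")
    maps = np.empty((n_networks, int(np.prod(grid))))
    sigma = fwhm_to_sigma(smooth_fwhm_mm, voxel_size_mm)
    for m, c in enumerate(chosen):
        dist2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        blob = (dist2 <= radius_voxels ** 2).astype(float)
        if smooth_fwhm_mm > 0:
            blob = gaussian_filter(blob, sigma=sigma, mode="reflect")
        maps[m] = blob.ravel()
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)

    if n_networks > 1:
        c = np.corrcoef(maps)
        off = np.abs(c[~np.eye(n_networks, dtype=bool)])
        if off.max() >= 0.3:
            raise PlacementError(
                f"placed sources overlap too much (max |r| = {off.max():.2f}); "
                "enlarge the grid or reduce smoothing")
    return maps


def _lattice(grid, spacing, margin):
    axes = []
    for g in grid:
        pts = list(range(margin, g - margin, spacing))
        if not pts:
            pts = [g // 2]
        axes.append(pts)
    for i in axes[0]:
        for j in axes[1]:
            for k in axes[2]:
                yield (i, j, k)


def generate_var_timecourses(coupling, n_volumes, innovation_sd=1.0, seed=0,
                             burn_in=200):
    """Simulate ``x_t = C x_{t-1} + eps_t`` and return (n_series, n_volumes).

    The first ``burn_in`` steps are discarded so the returned sample is
    (approximately) drawn from the stationary distribution.
    """
    coupling = _check_stable(coupling)
    if burn_in < 100:
        raise ValueError("burn_in must be >= 100")
    k = coupling.shape[0]
    rng = np.random.default_rng(seed)
    total = n_volumes + burn_in
    eps = rng.normal(0.0, innovation_sd, size=(k, total))
    x = np.zeros((k, total))
    x[:, 0] = eps[:, 0]
    for t in range(1, total):
        x[:, t] = coupling @ x[:, t - 1] + eps[:, t]
    out = x[:, burn_in:]
    if not np.all(np.isfinite(out)):
        raise RuntimeError("VAR simulation produced non-finite values")
    return out


def generate_cohort(config: CohortConfig):
    """Generate a two-group cohort of :class:`~restconn.preprocess.BoldRun`.

    Each subject's 4D data is ``sum_k amp_ik * tc_k(t) * map_ik + noise``
    where ``map_ik`` is the shared source map with its core region scaled
    by the subject's regional multiplier.  Groups differ only through
    the coupling matrices (directed effect) and the core-region
    multipliers of the planted networks (map-intensity effect).
    Patients' severity scores carry a planted correlation
    (``severity_coupling``) with their network-0 regional modulation;
    controls' scores are near zero.

    Returns ``(runs, truth)`` where ``runs`` is a list of BoldRun
    (patients first) and ``truth`` a :class:`GroundTruth`.
    """
    config.validate()
    cfg = config.resolve()
    root = np.random.SeedSequence(cfg.seed)
    src_seed, tc_seed, subj_seed, cov_seed = root.spawn(4)

    maps = make_spatial_sources(cfg.grid, cfg.n_networks, cfg.smooth_fwhm_mm,
                                cfg.voxel_size_mm,
                                seed=np.random.default_rng(src_seed))
    n_vox = maps.shape[1]
    core_masks = maps >= cfg.core_threshold * maps.max(axis=1, keepdims=True)
    couplings = {"patient": cfg.coupling_patients, "control": cfg.coupling_controls}
    gap = cfg.effect_gap_sd * cfg.regional_jitter_sd

    cov_rng = np.random.default_rng(cov_seed)
    runs: list[BoldRun] = []
    timecourses: dict[str, np.ndarray] = {}
    amplitudes: dict[str, np.ndarray] = {}
    regionals: dict[str, np.ndarray] = {}
    tc_children = tc_seed.spawn(2 * cfg.n_per_group)
    subj_children = subj_seed.spawn(2 * cfg.n_per_group)

    idx = 0
    for g, group in enumerate(("patient", "control")):
        for i in range(cfg.n_per_group):
            sid = f"sub-{group[:3]}{i:02d}"
            srng = np.random.default_rng(subj_children[idx])
            tc = generate_var_timecourses(couplings[group], cfg.n_volumes,
                                          cfg.innovation_sd, seed=tc_children[idx])
            jitter = srng.normal(0.0, cfg.amplitude_jitter_sd, size=cfg.n_networks)
            amp = cfg.amplitude * cfg.effect_map[g] * (1.0 + jitter)
            regional = 1.0 + srng.normal(0.0, cfg.regional_jitter_sd,
                                         size=cfg.n_networks)
            if group == "patient":
                for k in cfg.effect_networks:
                    regional[k] += gap
            subj_maps = maps.copy()
            for k in range(cfg.n_networks):
                subj_maps[k, core_masks[k]] *= regional[k]
            signal = (subj_maps.T * amp) @ tc            # (n_vox, t)
            noise = srng.normal(0.0, cfg.noise_sd, size=(n_vox, cfg.n_volumes))
            data = (signal + noise).reshape(cfg.grid + (cfg.n_volumes,))
            age = float(np.clip(np.round(cov_rng.normal(40.0, 10.0)), 25, 60))
            sex = int(cov_rng.integers(0, 2))
            runs.append(BoldRun(subject_id=sid, group=group, data=data,
                                voxel_size_mm=cfg.voxel_size_mm,
                                tr_seconds=cfg.tr_seconds,
                                mask=np.ones(cfg.grid, dtype=bool),
                                age=age, sex=sex))
            timecourses[sid] = tc
            amplitudes[sid] = amp
            regionals[sid] = regional
            idx += 1

    # severity: planted correlation with network-0 regional modulation
    pat_ids = [r.subject_id for r in runs if r.group == "patient"]
    z = np.array([regionals[s][0] for s in pat_ids])
    z = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    rho = cfg.severity_coupling
    noise = cov_rng.standard_normal(len(pat_ids))
    if z.std() > 0 and len(pat_ids) > 2:
        # orthogonalize so the in-sample correlation equals rho exactly
        noise = noise - noise.mean() - z * (noise @ z) / (z @ z)
    if noise.std() > 0:
        noise = (noise - noise.mean()) / noise.std()
    latent = rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * noise
    for s, v in zip(pat_ids, 19.1 + 5.68 * latent):
        _run_by_id(runs, s).severity = float(v)
    for r in runs:
        if r.group == "control":
            r.severity = float(np.clip(cov_rng.normal(0.65, 0.77), 0, None))

    planted_edges = [(int(i), int(j)) for (i, j) in zip(*np.nonzero(
        cfg.coupling_patients != cfg.coupling_controls))]
    regional_planted = set(cfg.effect_networks) if gap != 0 else set()
    planted_networks = sorted(regional_planted | {
        k for k in range(cfg.n_networks)
        if cfg.effect_map[0, k] != cfg.effect_map[1, k]})
    truth = GroundTruth(source_maps=maps, grid=cfg.grid, timecourses=timecourses,
                        amplitudes=amplitudes,
                        regional_multipliers=regionals, core_masks=core_masks,
                        coupling_patients=cfg.coupling_patients,
                        coupling_controls=cfg.coupling_controls,
                        planted_edges=planted_edges,
                        planted_networks=planted_networks,
                        severity_coupling=rho, seed=cfg.seed)
    return runs, truth


def _run_by_id(runs, sid):
    for r in runs:
        if r.subject_id == sid:
            return r
    raise KeyError(sid)


def write_cohort(runs, truth, config: CohortConfig, outdir) -> dict:
    """Persist a cohort: per-subject NIfTI, subject table TSV, truth JSON,
    config YAML.  Returns a manifest of written paths."""
    from .preprocess import write_run

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    paths = {}
    for run in runs:
        p = outdir / f"{run.subject_id}_bold.nii.gz"
        write_run(run, p)
        paths[run.subject_id] = str(p)
        rows.append((run.subject_id, run.group, run.age, run.sex,
                     "" if run.severity is None else f"{run.severity:.4f}"))
    table = outdir / "participants.tsv"
    with open(table, "w") as fh:
        fh.write("subject_id\tgroup\tage\tsex\tseverity\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    (outdir / "ground_truth.json").write_text(truth.to_json())
    cfg = config.resolve()
    cfg_dict = dataclasses.asdict(cfg)
    for key in ("coupling_patients", "coupling_controls", "effect_map"):
        cfg_dict[key] = np.asarray(cfg_dict[key]).tolist()
    for key in ("grid", "voxel_size_mm", "effect_networks"):
        cfg_dict[key] = list(cfg_dict[key])
    (outdir / "cohort_config.yaml").write_text(yaml.safe_dump(cfg_dict))
    return {"runs": paths, "participants": str(table),
            "ground_truth": str(outdir / "ground_truth.json"),
            "config": str(outdir / "cohort_config.yaml")}
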