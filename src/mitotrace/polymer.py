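"""Coarse-grained bead-spring chromosome polymer with soft self-repulsion.

The chromosome is a chain of monomers (default 1 kb per monomer at a 12 nm
bond, the physical scale obtained by calibrating an unconstrained chain
against condensin-depleted high-resolution traces).  Neighbouring monomers
are bonded harmonically; loop-extruder anchors are bridged by harmonic bonds
with half the backbone rest length; non-neighbouring monomers repel through
a finite soft-core potential U(r) = Emax (1 - (r/rc)^2)^3 (r < rc) so that
strands may cross, emulating topoisomerase activity.  Dynamics are overdamped
Langevin (Brownian) at kT = 1 with no confinement.

Coarse-grained runs (g kb per monomer) scale the bond length by sqrt(g)
under the equilibrium-globule assumption.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .extrusion import ExtrusionTrajectory, anchors_at_time
from .traceops import (ScalingCurve, Trace, distances_to_polyline,
                       rolling_mean_axis)

__all__ = [
    "PolymerConfig",
    "ForceFieldParams",
    "Conformation",
    "BondSet",
    "ProbePlan",
    "MitoticSimResult",
    "init_random_walk",
    "evaluate_forces",
    "integrate",
    "run_dynamic_mitosis",
    "apply_condition_tsa",
    "sample_probes",
    "condensin_radial_distribution",
    "calibrate_scaling",
]

REFERENCE_BOND_NM = 12.0  # calibrated nm per 1-kb monomer
DIVERGENCE_NM = 1e9


def default_bond_length(bp_per_monomer: int) -> float:
    """12 nm per kb monomer, scaled by sqrt(g) for g-kb monomers."""
    return REFERENCE_BOND_NM * math.sqrt(bp_per_monomer / 1000.0)


@dataclass(frozen=True)
class PolymerConfig:
    n_monomers: int
    bp_per_monomer: int = 1000
    bond_length: float | None = None  # nm; default 12 * sqrt(kb per monomer)
    bond_stiffness: float = 35.0  # kT per bond_length^2
    thermal_energy: float = 1.0  # kT
    friction: float = 1.0
    timestep: float | None = None  # auto: bond relaxation resolved by >= 10 steps
    equilibration_steps: int = 100_000
    steps_per_update: int = 20_000
    neighbor_skin: float = 0.3  # Verlet skin, in bond lengths
    neighbor_every: int = 5  # steps between pair-list rebuilds

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("n_monomers must be >= 2")
        if self.bond_length is None:
            object.__setattr__(self, "bond_length",
                               default_bond_length(self.bp_per_monomer))
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")

    @property
    def chromosome_length(self) -> int:
        return self.n_monomers * self.bp_per_monomer

    @property
    def stiffness_nm(self) -> float:
        """Backbone spring constant in kT / nm^2."""
        return self.bond_stiffness * self.thermal_energy / self.bond_length ** 2

    @property
    def dt(self) -> float:
        if self.timestep is not None:
            return self.timestep
        # bond relaxation time friction / k, resolved by 12 steps
        return self.friction / (12.0 * self.stiffness_nm)


@dataclass(frozen=True)
class ForceFieldParams:
    repulsion_emax: float = 1.0  # kT
    repulsion_radius: float = 1.05  # bond lengths
    extruder_bond_rest_frac: float = 0.5  # fraction of bond_length
    extruder_bond_stiffness: float | None = None  # default: backbone stiffness

    def __post_init__(self) -> None:
        if self.repulsion_emax < 0:
            raise ValueError("repulsion_emax must be >= 0")
        if self.repulsion_radius <= 0:
            raise ValueError("repulsion_radius must be > 0")


def apply_condition_tsa(ff_params: ForceFieldParams) -> ForceFieldParams:
    """Hyperacetylated (TSA-treated) chromatin: 5x the maximum repulsion and
    repulsion radius widened from 1.05 to 1.5 bond lengths."""
    return replace(ff_params,
                   repulsion_emax=ff_params.repulsion_emax * 5.0,
                   repulsion_radius=1.5)


@dataclass
class Conformation:
    """N x 3 monomer coordinates (nm) with genomic start positions (bp)."""

    coords: np.ndarray
    genomic_start: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.genomic_start = np.asarray(self.genomic_start, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if self.genomic_start.shape[0] != self.coords.shape[0]:
            raise ValueError("genomic_start length mismatch")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), self.genomic_start.copy())


@dataclass
class BondSet:
    """Backbone bonds are implicit (i, i+1); extruder bonds are explicit."""

    n_monomers: int
    extruder_bonds: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.extruder_bonds = np.asarray(self.extruder_bonds,
                                         dtype=np.int64).reshape(-1, 2)
        if self.extruder_bonds.size:
            if self.extruder_bonds.min() < 0 or \
                    self.extruder_bonds.max() >= self.n_monomers:
                raise ValueError("extruder bond index out of range")
            if np.any(self.extruder_bonds[:, 0] == self.extruder_bonds[:, 1]):
                raise ValueError("self-bonds not allowed")


def init_random_walk(n: int, bond_length: float,
                     rng: np.random.Generator) -> Conformation:
    """Freely jointed chain: successive steps of length bond_length with
    isotropic random orientation."""
    if n < 2:
        raise ValueError("n must be >= 2")
    steps = rng.normal(size=(n - 1, 3))
    steps *= bond_length / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    genomic = np.arange(n, dtype=np.int64)  # placeholder 1-bp spacing
    return Conformation(coords, genomic)


def _bond_arrays(config: PolymerConfig, ff: ForceFieldParams, bonds: BondSet):
    n = config.n_monomers
    b = config.bond_length
    k_bb = config.stiffness_nm
    k_ext = (ff.extruder_bond_stiffness * config.thermal_energy / b ** 2
             if ff.extruder_bond_stiffness is not None else k_bb)
    bb_i = np.arange(n - 1, dtype=np.int64)
    bb_j = bb_i + 1
    ext = bonds.extruder_bonds
    bond_i = np.concatenate([bb_i, ext[:, 0]])
    bond_j = np.concatenate([bb_j, ext[:, 1]])
    k_nm = np.concatenate([np.full(n - 1, k_bb),
                           np.full(ext.shape[0], k_ext)])
    r0 = np.concatenate([np.full(n - 1, b),
                         np.full(ext.shape[0], ff.extruder_bond_rest_frac * b)])
    return bond_i, bond_j, k_nm, r0


def _candidate_pairs(coords: np.ndarray, cutoff: float) -> np.ndarray:
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    return np.ascontiguousarray(pairs.astype(np.int64))


def evaluate_forces(conformation: Conformation, bonds: BondSet,
                    config: PolymerConfig, ff: ForceFieldParams
                    ) -> tuple[np.ndarray, float]:
    """Per-monomer force vectors (kT/nm) and total energy (kT)."""
    coords = conformation.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    bond_i, bond_j, k_nm, r0 = _bond_arrays(config, ff, bonds)
    forces = np.zeros_like(coords)
    energy = _kernels.bonded_forces(coords, bond_i, bond_j, k_nm, r0, forces)
    if ff.repulsion_emax > 0:
        rc = ff.repulsion_radius * config.bond_length
        pairs = _candidate_pairs(coords, rc)
        energy += _kernels.repulsive_forces(coords, pairs, pairs.shape[0],
                                            ff.repulsion_emax, rc, forces)
    return forces, float(energy)


def integrate(conformation: Conformation, bonds: BondSet,
              config: PolymerConfig, ff: ForceFieldParams,
              n_steps: int, rng: np.random.Generator) -> Conformation:
    """Overdamped Langevin dynamics, in place on a copy; returns the evolved
    conformation.  Raises on divergence (unstable timestep)."""
    conf = conformation.copy()
    if n_steps <= 0:
        return conf
    coords = conf.coords
    bond_i, bond_j, k_nm, r0 = _bond_arrays(config, ff, bonds)
    dt = config.dt
    mobility_dt = dt / config.friction
    noise_scale = math.sqrt(2.0 * config.thermal_energy * dt / config.friction)
    rc = ff.repulsion_radius * config.bond_length
    search = rc + config.neighbor_skin * config.bond_length
    rebuild = max(1, config.neighbor_every)
    chunk = 250
    cap = max(100_000, 40 * conf.n)
    pairs = np.empty((cap, 2), dtype=np.int64)
    head = np.empty(max(300_000, 8 * conf.n), dtype=np.int64)
    nxt = np.empty(conf.n, dtype=np.int64)
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.standard_normal(size=(m, conf.n, 3), dtype=np.float32)
        while True:
            before = coords.copy()
            status = _kernels.brownian_block(
                coords, bond_i, bond_j, k_nm, r0, ff.repulsion_emax, rc,
                search, rebuild, mobility_dt, noise_scale, noise,
                pairs, head, nxt)
            if status == 0:
                break
            coords[:] = before  # workspace overflow: enlarge and redo
            if status == -1:
                cap = min(cap * 2, conf.n * (conf.n - 1) // 2 + 1)
                pairs = np.empty((cap, 2), dtype=np.int64)
            else:
                head = np.empty(head.size * 2, dtype=np.int64)
            if head.size > 50_000_000:
                # a runaway cell grid means the coordinates exploded mid-block
                raise FloatingPointError(
                    "polymer dynamics diverged; decrease the timestep")
        if not np.all(np.isfinite(coords)) or \
                np.abs(coords).max() > DIVERGENCE_NM:
            raise FloatingPointError(
                "polymer dynamics diverged; decrease the timestep")
        done += m
    return conf


@dataclass
class MitoticSimResult:
    """Conformations and extruder bond sets sampled along the mitotic schedule."""

    config: PolymerConfig
    ff_params: ForceFieldParams
    sample_times_min: tuple[float, ...]
    conformations: dict[float, Conformation] = field(default_factory=dict)
    bond_sets: dict[float, BondSet] = field(default_factory=dict)


def _bonds_from_anchors(anchors: list[tuple[str, int, int]],
                        config: PolymerConfig) -> BondSet:
    g = config.bp_per_monomer
    n = config.n_monomers
    pairs = []
    species = []
    for name, left_bp, right_bp in anchors:
        i = min(left_bp // g, n - 1)
        j = min(right_bp // g, n - 1)
        if i == j:
            continue  # zero-length loops create no bond
        pairs.append((i, j))
        species.append(name)
    bonds = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return BondSet(n_monomers=n, extruder_bonds=bonds, species=species)


def run_dynamic_mitosis(trajectory: ExtrusionTrajectory,
                        polymer_config: PolymerConfig,
                        ff_params: ForceFieldParams,
                        sample_times_min: tuple[float, ...] = (0.0, 10.0, 32.0, 40.0),
                        rng: np.random.Generator | None = None,
                        n_updates: int = 125) -> MitoticSimResult:
    """Couple a 1D extrusion trajectory to the 3D polymer.

    Equilibrates from a random walk, then walks through ~n_updates 1D
    snapshots evenly spread over the schedule (always ending on the final
    snapshot), replacing extruder bonds and relaxing ``steps_per_update``
    Brownian steps per update.  Conformations are stored at the first update
    whose 1D time reaches each requested sample time (minutes).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cfg = polymer_config
    if trajectory.config.chromosome_length != cfg.chromosome_length:
        raise ValueError("trajectory and polymer chromosome lengths differ")

    conf = init_random_walk(cfg.n_monomers, cfg.bond_length, rng)
    conf.genomic_start = np.arange(cfg.n_monomers, dtype=np.int64) * cfg.bp_per_monomer
    empty = BondSet(n_monomers=cfg.n_monomers)
    conf = integrate(conf, empty, cfg, ff_params, cfg.equilibration_steps, rng)

    result = MitoticSimResult(cfg, ff_params, tuple(sample_times_min))
    pending = sorted(sample_times_min)
    if pending and pending[0] <= 0.0:
        result.conformations[pending[0]] = conf.copy()
        result.bond_sets[pending[0]] = empty
        pending = pending[1:]

    duration = trajectory.duration
    times = np.asarray(trajectory.times)
    targets = np.linspace(duration / n_updates, duration, n_updates)
    idx = np.unique(np.searchsorted(times, targets, side="right") - 1)
    idx = idx[idx >= 0]
    if idx.size == 0 or idx[-1] != times.size - 1:
        idx = np.append(idx, times.size - 1)

    for i in idx:
        t_1d = times[i]
        anchors = anchors_at_time(trajectory, t_1d)
        bonds = _bonds_from_anchors(anchors, cfg)
        conf = integrate(conf, bonds, cfg, ff_params, cfg.steps_per_update, rng)
        while pending and t_1d >= pending[0] * 60.0 - 1e-9:
            result.conformations[pending[0]] = conf.copy()
            result.bond_sets[pending[0]] = bonds
            pending = pending[1:]
    for t in pending:  # sample times beyond the schedule: final state
        result.conformations[t] = conf.copy()
        result.bond_sets[t] = bonds
    return result


@dataclass(frozen=True)
class ProbePlan:
    """Genomic sampling design: footprint (spot size), stride, and offset, bp."""

    footprint: int
    spacing: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.footprint <= 0 or self.spacing <= 0:
            raise ValueError("footprint and spacing must be > 0")
        if self.footprint > self.spacing:
            raise ValueError("footprint must be <= spacing")


def sample_probes(conformation: Conformation, plan: ProbePlan,
                  trace_id: str = "sim", cell_id: str = "sim",
                  stage: str = "metaphase") -> Trace:
    """Sample a conformation with a probe plan: one point per probe, at the
    centroid of the monomers whose genomic span intersects the probe window;
    the point's genomic coordinate is the probe midpoint."""
    g = int(np.diff(conformation.genomic_start[:2])[0]) \
        if conformation.n > 1 else 1
    if plan.footprint < g:
        raise ValueError("footprint must cover at least one monomer")
    length = conformation.genomic_start[-1] + g
    starts = np.arange(plan.offset, length, plan.spacing, dtype=np.int64)
    if starts.size and starts[-1] + plan.footprint > length:
        keep = starts + plan.footprint <= length
        if not np.all(keep):
            warnings.warn("probe plan extends past chromosome end; truncated")
            starts = starts[keep]
    points = np.empty((starts.size, 3))
    for k, s in enumerate(starts):
        i0 = int(np.searchsorted(conformation.genomic_start, s, side="right")) - 1
        i0 = max(i0, 0)
        i1 = int(np.searchsorted(conformation.genomic_start, s + plan.footprint,
                                 side="left"))
        points[k] = conformation.coords[i0:i1].mean(axis=0)
    genomic = starts + plan.footprint // 2
    return Trace(trace_id=trace_id, cell_id=cell_id, stage=stage,
                 genomic=genomic, xyz=points,
                 present=np.ones(starts.size, dtype=bool))


def condensin_radial_distribution(result: MitoticSimResult,
                                  window_bp: float = 20e6,
                                  time_min: float | None = None
                                  ) -> dict[str, np.ndarray]:
    """Radial distances (nm) of extruder anchors — and of all chromatin — to
    the 20-Mb rolling-mean chromosome axis, per species."""
    if time_min is None:
        time_min = max(result.conformations)
    conf = result.conformations[time_min]
    bonds = result.bond_sets[time_min]
    if bonds.extruder_bonds.size == 0:
        raise ValueError("no extruder bonds at the requested time")
    extent = conf.genomic_start[-1] - conf.genomic_start[0]
    if extent <= window_bp:
        raise ValueError("chromosome shorter than the axis window")
    axis = rolling_mean_axis(conf.genomic_start, conf.coords, window_bp)
    all_d = distances_to_polyline(conf.coords, axis)
    out: dict[str, np.ndarray] = {"chromatin": all_d}
    species = np.asarray(bonds.species)
    for name in np.unique(species):
        sel = bonds.extruder_bonds[species == name]
        monomers = np.unique(sel.ravel())
        out[str(name)] = all_d[monomers]
    return out


def calibrate_scaling(simulated: ScalingCurve, reference: ScalingCurve) -> float:
    """Least-squares multiplicative factor aligning simulated median distances
    to a reference curve over their common genomic-separation interval."""
    lo = max(simulated.separation[0], reference.separation[0])
    hi = min(simulated.separation[-1], reference.separation[-1])
    if lo > hi:
        raise ValueError("curves cover disjoint separation intervals")
    sel = (simulated.separation >= lo) & (simulated.separation <= hi)
    s = simulated.separation[sel].astype(float)
    sim_d = simulated.median_distance[sel]
    ref_d = np.interp(np.log(s), np.log(reference.separation.astype(float)),
                      reference.median_distance)
    denom = float(np.sum(sim_d * sim_d))
    if denom == 0:
        raise ValueError("degenerate simulated curve")
    return float(np.sum(ref_d * sim_d) / denom)
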