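"""Synthetic-data generators with ground truth.

Everything the tests and the desk-scale analyses need can be generated
here: regular and noisy helices (12-Mb pitch, sigma = 200 nm Gaussian
localization noise), freely-jointed phantom chains (the Rouse-regime
reference with scaling exponent 0.5), traces with planted base / nested /
Z-loop contacts, multi-copy localization fields with ambiguous barcode
assignments, and power-law scaling curves with a planted dip.  All
generators are seeded and emit ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .assembly import BarcodeScheme
from .traceops import LoopCallSet, ScalingCurve, Trace

__all__ = [
    "HelixParams",
    "PlantedLoopSpec",
    "make_helix_trace",
    "make_phantom_chain_traces",
    "make_planted_loop_trace",
    "make_localization_field",
    "make_planted_dip_curve",
]


@dataclass(frozen=True)
class HelixParams:
    """Circular helix parameterized by genomic coordinate.

    Defaults give a 100-Mb chromosome with 12-Mb pitch, 300 nm radius and a
    rise chosen so the full helix spans a few micrometres, with optional
    isotropic Gaussian localization noise (default sigma = 200 nm per axis).
    """

    pitch_bp: float = 12e6
    radius_nm: float = 300.0
    rise_nm_per_bp: float = 4e-5
    sampling_interval_bp: int = 1_000_000
    length_bp: int = 100_000_000
    noise_sd_nm: float = 200.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch_bp <= 0:
            raise ValueError("pitch must be > 0")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd must be >= 0")


def make_helix_trace(params: HelixParams,
                     rng: np.random.Generator | None = None,
                     trace_id: str = "helix") -> Trace:
    """Points on a circular helix, with independent Gaussian noise per axis."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    g = np.arange(0, params.length_bp, params.sampling_interval_bp,
                  dtype=np.int64)
    phase = 2.0 * np.pi * g / params.pitch_bp
    xyz = np.column_stack([
        params.radius_nm * np.cos(phase),
        params.radius_nm * np.sin(phase),
        params.rise_nm_per_bp * g,
    ])
    if params.noise_sd_nm > 0:
        xyz = xyz + rng.normal(scale=params.noise_sd_nm, size=xyz.shape)
    return Trace(trace_id=trace_id, cell_id="synthetic", stage="metaphase",
                 genomic=g, xyz=xyz)


def make_phantom_chain_traces(n_traces: int, n_points: int, bond_nm: float,
                              rng: np.random.Generator,
                              genomic_step: int = 12_000) -> list[Trace]:
    """Freely-jointed chains sampled as traces with uniform genomic spacing;
    the analytic reference for ideal-chain (Rouse) scaling."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    traces = []
    g = np.arange(n_points, dtype=np.int64) * genomic_step
    for t in range(n_traces):
        steps = rng.normal(size=(n_points - 1, 3))
        steps *= bond_nm / np.linalg.norm(steps, axis=1, keepdims=True)
        xyz = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        traces.append(Trace(trace_id=f"phantom_{t}", cell_id="synthetic",
                            stage="interphase", genomic=g.copy(), xyz=xyz))
    return traces


@dataclass(frozen=True)
class PlantedLoopSpec:
    """Ground-truth loop layout: (anchor_a bp, anchor_b bp, intended class).

    The backbone step must exceed distance_cutoff + anchor_distance so the
    only close contacts are the planted ones.
    """

    loops: tuple[tuple[int, int, str], ...]
    genomic_step: int = 12_000
    backbone_step_nm: float = 160.0
    anchor_distance_nm: float = 40.0
    n_points: int | None = None

    def __post_init__(self) -> None:
        for a, b, cls in self.loops:
            if a >= b:
                raise ValueError("anchors must be ordered a < b")
            if b - a < 30_000:
                raise ValueError("loop spans must be >= 30 kb")
            if cls not in ("base", "nested", "z_loop"):
                raise ValueError(f"unknown loop class {cls!r}")


def _simplex_offsets(m: int, d: float, rng: np.random.Generator) -> np.ndarray:
    """m points in 3D with all pairwise distances exactly d (m <= 4)."""
    if m > 4:
        raise ValueError("at most 4 mutually merged anchors are satisfiable in 3D")
    verts = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, np.sqrt(3) / 2, 0.0],
        [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3],
    ])[:m] * d
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    return verts @ q.T


def make_planted_loop_trace(spec: PlantedLoopSpec,
                            rng: np.random.Generator
                            ) -> tuple[Trace, LoopCallSet]:
    """Trace whose only close contacts are the specified anchor pairs.

    The backbone is a randomly oriented, lightly jittered straight path with
    a step larger than the contact cutoff, so genomically distant points are
    spatially distant by construction; anchors connected by planted contacts
    are relocated into small clusters at the requested anchor distance.
    """
    step = spec.genomic_step
    max_bp = max(b for _, b, _ in spec.loops)
    n = spec.n_points or (max_bp // step + 10)
    g = np.arange(n, dtype=np.int64) * step

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    xyz = np.outer(np.arange(n, dtype=float) * spec.backbone_step_nm, direction)
    xyz = xyz + rng.normal(scale=5.0, size=xyz.shape)

    def to_index(bp: int) -> int:
        idx = int(round(bp / step))
        if not (0 <= idx < n):
            raise ValueError(f"anchor {bp} outside trace")
        return idx

    pairs = [(to_index(a), to_index(b)) for a, b, _ in spec.loops]
    # union-find over anchors sharing planted contacts
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for node in parent:
        clusters.setdefault(find(node), []).append(node)
    for members in clusters.values():
        members.sort()
        anchor0 = members[0]
        offsets = _simplex_offsets(len(members), spec.anchor_distance_nm, rng)
        for m, off in zip(members, offsets):
            xyz[m] = xyz[anchor0] + off

    trace = Trace(trace_id="planted", cell_id="synthetic", stage="metaphase",
                  genomic=g, xyz=xyz)
    # verify satisfiability: the planted pairs, and only they, are contacts
    ii, jj = np.triu_indices(n, k=1)
    dist = np.linalg.norm(xyz[jj] - xyz[ii], axis=1)
    span = g[jj] - g[ii]
    close = set(zip(ii[(dist < 100.0) & (span >= 30_000)].tolist(),
                    jj[(dist < 100.0) & (span >= 30_000)].tolist()))
    wanted = {tuple(sorted(p)) for p in pairs}
    if close != wanted:
        raise ValueError("planted-loop spec not geometrically satisfiable: "
                         f"unintended contacts {close ^ wanted}")
    idx = np.array(sorted(wanted), dtype=np.int64).reshape(-1, 2)
    order = {tuple(sorted(p)): cls for p, (_, _, cls)
             in zip(pairs, spec.loops)}
    labels = [order[tuple(p)] for p in idx.tolist()]
    truth = LoopCallSet(anchors_index=idx,
                        anchors_bp=np.stack([g[idx[:, 0]], g[idx[:, 1]]],
                                            axis=1),
                        labels=labels)
    return trace, truth


def make_localization_field(n_copies: int, scheme: BarcodeScheme,
                            rng: np.random.Generator,
                            spatial_offset_nm: float = 4000.0,
                            dropout: float = 0.0,
                            position_noise_nm: float = 50.0,
                            intensity_noise: float = 0.1,
                            misassign_rate: float = 0.0,
                            signal_intensity: float = 10.0,
                            territory_radius_nm: float = 800.0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic whole-chromosome localization field for decoding tests.

    Each chromosome copy is a smoothed random walk sampled at the scheme's
    spot coordinates and displaced by a spatial offset; per-spot segment
    intensity vectors carry planted noise, with an optional fraction of
    segment intensities deliberately mis-assigned.  Returns the fit table
    and a ground-truth table (record_id, copy, coordinate).
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    coords = np.arange(0, scheme.chromosome_length, scheme.spot_spacing,
                       dtype=np.int64)
    n_seg = scheme.n_segments
    rows = []
    truth = []
    rec = 0
    for copy in range(n_copies):
        steps = rng.normal(scale=600.0, size=(coords.size, 3))
        walk = uniform_filter1d(np.cumsum(steps, axis=0), size=7, axis=0)
        walk -= walk.mean(axis=0)
        # rescale to a compact territory of fixed RMS radius, as a
        # chromosome territory rather than an open random coil
        rms = np.sqrt((walk ** 2).sum(axis=1).mean())
        if rms > 0:
            walk *= territory_radius_nm / rms
        walk = walk + np.array([copy * spatial_offset_nm, 0.0, 0.0])
        for k, c in enumerate(coords):
            if dropout > 0 and rng.random() < dropout:
                continue
            true_seg = scheme.segment_id_of(int(c))
            inten = np.abs(rng.normal(scale=intensity_noise * signal_intensity,
                                      size=n_seg))
            sig_seg = true_seg
            if misassign_rate > 0 and rng.random() < misassign_rate:
                others = [s for s in range(n_seg) if s != true_seg]
                sig_seg = int(rng.choice(others))
            inten[sig_seg] += signal_intensity * \
                (1.0 + rng.normal(scale=intensity_noise))
            pos = walk[k] + rng.normal(scale=position_noise_nm, size=3)
            row = {
                "record_id": rec,
                "spot_barcode_id": scheme.spot_id_of(int(c)),
                "x_nm": pos[0], "y_nm": pos[1], "z_nm": pos[2],
                "fit_sd_nm": float(abs(rng.normal(25.0, 5.0))),
                "snr": float(abs(rng.normal(5.0, 1.0))),
                "region_id": 0,
            }
            for s in range(n_seg):
                row[f"intensity_seg{s}"] = inten[s]
            rows.append(row)
            truth.append({"record_id": rec, "copy": copy,
                          "coordinate_bp": int(c)})
            rec += 1
    return pd.DataFrame(rows), pd.DataFrame(truth)


def make_planted_dip_curve(base_exponent: float = 0.33,
                           prefactor: float = 30.0,
                           dip_position_bp: float = 7e6,
                           dip_depth: float = 0.2,
                           noise: float = 0.0,
                           rng: np.random.Generator | None = None,
                           separations: np.ndarray | None = None,
                           dip_width_decades: float = 0.12) -> ScalingCurve:
    """Power-law scaling curve with a localized multiplicative depression.

    The dip is a Gaussian (in log separation) of fractional depth
    ``dip_depth`` centered at ``dip_position_bp``; optional multiplicative
    Gaussian noise per bin.
    """
    if separations is None:
        separations = np.logspace(6, np.log10(30e6), 40)
    s = np.asarray(separations, dtype=np.float64)
    if dip_depth > 0 and not (s[0] < dip_position_bp < s[-1]):
        raise ValueError("dip position outside curve support")

    def shape(x, center):
        base = prefactor * (x / 1e6) ** base_exponent
        logs = np.log10(x / center)
        return base * (1.0 - dip_depth * np.exp(-(logs ** 2)
                                                / (2 * dip_width_decades ** 2)))

    y = prefactor * (s / 1e6) ** base_exponent
    if dip_depth > 0:
        # the rising power law drags the minimum below the Gaussian center;
        # shift the center so the realized minimum sits at dip_position
        center = dip_position_bp
        for _ in range(4):
            # interior local minimum of the dip region (the rising power law
            # makes the window's absolute minimum sit at its left edge)
            dense = np.logspace(np.log10(center) - 0.35,
                                np.log10(center) + 0.35, 2001)
            yy = shape(dense, center)
            interior = np.nonzero((yy[1:-1] < yy[:-2])
                                  & (yy[1:-1] < yy[2:]))[0] + 1
            if interior.size == 0:
                break
            k = interior[np.argmin(np.abs(np.log(dense[interior] / center)))]
            center *= dip_position_bp / dense[k]
        y = shape(s, center)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y * (1.0 + rng.normal(scale=noise, size=s.size))
    return ScalingCurve(separation=s, median_distance=y,
                        sem=np.zeros_like(s),
                        count=np.ones(s.size, dtype=np.int64))
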