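"""End-to-end simulation pipelines at desk scale.

The full-scale system (100-Mb chromosome, 1-kb monomers) is expensive, so
the standard desk-scale configuration runs a 50-Mb chromosome at 10 kb per
monomer with the bond length scaled by sqrt(10) under the
equilibrium-globule assumption, the default condensin parameters (2/Mb
stable condensin II from t = 0, 10/Mb dynamic condensin I from t = 600 s,
one-sided extrusion at Normal(4, 2) kb/s with free traversal) and the
2400 x 1 s mitotic schedule.  Metaphase conformations are sampled with
100-kb probes at 1-Mb spacing, ten genomic offsets per chromosome.
"""

from __future__ import annotations

import numpy as np

from .extrusion import ExtrusionConfig, run_mitotic_schedule
from .polymer import (ForceFieldParams, MitoticSimResult, PolymerConfig,
                      ProbePlan, apply_condition_tsa, integrate,
                      run_dynamic_mitosis, sample_probes)
from .traceops import ScalingCurve, Trace, find_scaling_minimum, scaling_curve

__all__ = [
    "reduced_scale_configs",
    "run_mitotic_replicate",
    "metaphase_traces",
    "pooled_metaphase_curve",
    "locate_scaling_dip_mb",
]

#: Desk-scale numerical settings: enough Brownian relaxation per bond update
#: to develop loop-scale structure while keeping a replicate to ~1 CPU-minute.
REDUCED_EQUILIBRATION_STEPS = 7_000
REDUCED_STEPS_PER_UPDATE = 700
REDUCED_N_UPDATES = 60
#: extra Brownian relaxation at the final extruder configuration before
#: sampling; compensates the shorter per-update relaxation of desk-scale runs
REDUCED_SETTLE_STEPS = 100_000


def reduced_scale_configs(chromosome_mb: int = 50,
                          bp_per_monomer: int = 10_000,
                          seed: int = 0
                          ) -> tuple[ExtrusionConfig, PolymerConfig]:
    length = chromosome_mb * 1_000_000
    ext = ExtrusionConfig(chromosome_length=length, rng_seed=seed)
    poly = PolymerConfig(
        n_monomers=length // bp_per_monomer,
        bp_per_monomer=bp_per_monomer,
        equilibration_steps=REDUCED_EQUILIBRATION_STEPS,
        steps_per_update=REDUCED_STEPS_PER_UPDATE,
    )
    return ext, poly


def run_mitotic_replicate(seed: int, tsa: bool = False,
                          chromosome_mb: int = 50,
                          bp_per_monomer: int = 10_000,
                          sample_times_min: tuple[float, ...] = (40.0,),
                          ) -> MitoticSimResult:
    """One dynamic mitotic replicate (1D extrusion coupled to 3D polymer)."""
    if isinstance(sample_times_min, (int, float)):
        sample_times_min = (float(sample_times_min),)
    ext_cfg, poly_cfg = reduced_scale_configs(chromosome_mb, bp_per_monomer,
                                              seed=seed)
    rng = np.random.default_rng(seed)
    trajectory = run_mitotic_schedule(ext_cfg, rng)
    ff = ForceFieldParams()
    if tsa:
        ff = apply_condition_tsa(ff)
    result = run_dynamic_mitosis(trajectory, poly_cfg, ff,
                                 sample_times_min=tuple(sample_times_min),
                                 rng=rng, n_updates=REDUCED_N_UPDATES)
    # settle the final (metaphase) state at its extruder configuration
    t_final = max(result.conformations)
    if REDUCED_SETTLE_STEPS > 0 and t_final >= 40.0 - 1e-9:
        settled = integrate(result.conformations[t_final],
                            result.bond_sets[t_final], poly_cfg, ff,
                            REDUCED_SETTLE_STEPS, rng)
        result.conformations[t_final] = settled
    return result


def metaphase_traces(result: MitoticSimResult, n_offsets: int = 10,
                     footprint: int = 100_000, spacing: int = 1_000_000,
                     time_min: float = 40.0, label: str = "sim"
                     ) -> list[Trace]:
    """Sample a metaphase conformation as the experiments do: 100-kb probes
    at 1-Mb spacing, several genomic offsets per chromosome."""
    conf = result.conformations[time_min]
    offsets = np.linspace(0, spacing, n_offsets, endpoint=False).astype(int)
    return [
        sample_probes(conf, ProbePlan(footprint=footprint, spacing=spacing,
                                      offset=int(off)),
                      trace_id=f"{label}_off{off}", cell_id=label,
                      stage="metaphase")
        for off in offsets
    ]


def pooled_metaphase_curve(n_replicates: int = 5, base_seed: int = 0,
                           tsa: bool = False, chromosome_mb: int = 50,
                           bp_per_monomer: int = 10_000,
                           n_offsets: int = 10
                           ) -> tuple[list[Trace], ScalingCurve]:
    """Pooled median distance-scaling curve over simulated metaphase
    chromosomes (a desk-scale stand-in for a full multi-chromosome ensemble)."""
    traces: list[Trace] = []
    for r in range(n_replicates):
        res = run_mitotic_replicate(base_seed + r, tsa=tsa,
                                    chromosome_mb=chromosome_mb,
                                    bp_per_monomer=bp_per_monomer)
        traces.extend(metaphase_traces(res, n_offsets=n_offsets,
                                       label=f"rep{r}"))
    return traces, scaling_curve(traces, min_points_per_trace=30)


def locate_scaling_dip_mb(curve: ScalingCurve,
                          interval_mb: tuple[float, float] = (2.0, 20.0),
                          smooth_bins: int | None = None) -> float | None:
    """Interior local minimum of the scaling curve, in Mb.

    Pooled multi-replicate curves are already heavily averaged per bin, so
    the raw strict-local-minimum definition is used (the most prominent
    candidate in log space); pass ``smooth_bins`` to pre-smooth a noisy
    single-trace curve instead.
    """
    sep = find_scaling_minimum(
        curve, (interval_mb[0] * 1e6, interval_mb[1] * 1e6),
        smooth_bins=smooth_bins)
    return None if sep is None else sep / 1e6
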