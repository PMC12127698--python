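"""Numba force/integration kernels for the bead-spring polymer engine.

All quantities in nm and k_BT; friction sets the time unit (overdamped
dynamics, so only D = kT/friction matters).  The soft-core repulsion
U(r) = Emax (1 - (r/rc)^2)^3 for r < rc is finite at the origin, so chains
can pass through each other (implicit topoisomerase activity).

Non-bonded pairs are found with a cell list rebuilt inside the integration
loop every few steps, with a Verlet skin on the search radius.
"""

from __future__ import annotations

import numba
import numpy as np

_HALF_STENCIL = np.array(
    [[1, 0, 0], [0, 1, 0], [0, 0, 1],
     [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
     [0, 1, 1], [0, 1, -1],
     [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=np.int64)


@numba.njit(cache=True, fastmath=True)
def bonded_forces(coords, bond_i, bond_j, k_nm, r0, forces):
    """Harmonic bonds U = k/2 (r - r0)^2; accumulates into forces, returns energy."""
    energy = 0.0
    for m in range(bond_i.size):
        i = bond_i[m]
        j = bond_j[m]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[m]
        energy += 0.5 * k_nm[m] * dr * dr
        if r > 1e-12:
            f = -k_nm[m] * dr / r  # force on j along (j - i)
            forces[j, 0] += f * dx
            forces[j, 1] += f * dy
            forces[j, 2] += f * dz
            forces[i, 0] -= f * dx
            forces[i, 1] -= f * dy
            forces[i, 2] -= f * dz
    return energy


@numba.njit(cache=True, fastmath=True)
def repulsive_forces(coords, pairs, n_pairs, emax, rc, forces):
    """Soft-core pair repulsion over a candidate pair list.

    Pairs with |i-j| == 1 (backbone neighbours) are skipped.
    """
    energy = 0.0
    rc2 = rc * rc
    for m in range(n_pairs):
        i = pairs[m, 0]
        j = pairs[m, 1]
        if i + 1 == j or j + 1 == i:
            continue
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        s = 1.0 - r2 / rc2
        energy += emax * s * s * s
        # -dU/dr / r = 6 Emax s^2 / rc^2  (repulsive, pushes j away from i)
        f = 6.0 * emax * s * s / rc2
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    return energy


@numba.njit(cache=True)
def build_pairs(coords, cutoff, pairs, head, nxt):
    """Cell-list neighbour search: all pairs closer than cutoff.

    Fills ``pairs`` (preallocated (cap, 2) int64) using the workspace arrays
    ``head`` (cell linked-list heads) and ``nxt``; returns the pair count,
    -1 if pair capacity was exceeded, -2 if the cell workspace is too small
    (caller enlarges and retries).
    """
    n = coords.shape[0]
    cap = pairs.shape[0]
    xmin = coords[:, 0].min()
    ymin = coords[:, 1].min()
    zmin = coords[:, 2].min()
    inv = 1.0 / cutoff
    nx = int((coords[:, 0].max() - xmin) * inv) + 1
    ny = int((coords[:, 1].max() - ymin) * inv) + 1
    nz = int((coords[:, 2].max() - zmin) * inv) + 1
    ncell = nx * ny * nz
    if ncell > head.size:
        return -2
    head[:ncell] = -1
    for i in range(n):
        cx = int((coords[i, 0] - xmin) * inv)
        cy = int((coords[i, 1] - ymin) * inv)
        cz = int((coords[i, 2] - zmin) * inv)
        c = (cx * ny + cy) * nz + cz
        nxt[i] = head[c]
        head[c] = i
    cut2 = cutoff * cutoff
    count = 0
    # half stencil: own cell (j after i in the list) plus 13 forward cells
    for cx in range(nx):
        for cy in range(ny):
            for cz in range(nz):
                c = (cx * ny + cy) * nz + cz
                i = head[c]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        dx = coords[j, 0] - coords[i, 0]
                        dy = coords[j, 1] - coords[i, 1]
                        dz = coords[j, 2] - coords[i, 2]
                        if dx * dx + dy * dy + dz * dz < cut2:
                            if count >= cap:
                                return -1
                            if i < j:
                                pairs[count, 0] = i
                                pairs[count, 1] = j
                            else:
                                pairs[count, 0] = j
                                pairs[count, 1] = i
                            count += 1
                        j = nxt[j]
                    i = nxt[i]
                for m in range(13):
                    gx = cx + _HALF_STENCIL[m, 0]
                    gy = cy + _HALF_STENCIL[m, 1]
                    gz = cz + _HALF_STENCIL[m, 2]
                    if gx < 0 or gx >= nx or gy < 0 or gy >= ny \
                            or gz < 0 or gz >= nz:
                        continue
                    c2 = (gx * ny + gy) * nz + gz
                    i = head[c]
                    while i >= 0:
                        j = head[c2]
                        while j >= 0:
                            dx = coords[j, 0] - coords[i, 0]
                            dy = coords[j, 1] - coords[i, 1]
                            dz = coords[j, 2] - coords[i, 2]
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if count >= cap:
                                    return -1
                                if i < j:
                                    pairs[count, 0] = i
                                    pairs[count, 1] = j
                                else:
                                    pairs[count, 0] = j
                                    pairs[count, 1] = i
                                count += 1
                            j = nxt[j]
                        i = nxt[i]
    return count


@numba.njit(cache=True, fastmath=True)
def _block_f32(coords, bond_i, bond_j, k_nm, r0, emax, rc, search,
               rebuild_every, mobility_dt, noise_scale, noise,
               pairs, head, nxt):
    n_steps = noise.shape[0]
    n = coords.shape[0]
    forces = np.zeros((n, 3), dtype=np.float32)
    rc2 = rc * rc
    n_pairs = 0
    for s in range(n_steps):
        if emax > np.float32(0.0) and s % rebuild_every == 0:
            n_pairs = build_pairs(coords, search, pairs, head, nxt)
            if n_pairs < 0:
                return n_pairs
        forces[:] = np.float32(0.0)
        for m in range(bond_i.size):
            i = bond_i[m]
            j = bond_j[m]
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > np.float32(1e-12):
                f = -k_nm[m] * (r - r0[m]) / r
                forces[j, 0] += f * dx
                forces[j, 1] += f * dy
                forces[j, 2] += f * dz
                forces[i, 0] -= f * dx
                forces[i, 1] -= f * dy
                forces[i, 2] -= f * dz
        if emax > np.float32(0.0):
            for m in range(n_pairs):
                i = pairs[m, 0]
                j = pairs[m, 1]
                if i + 1 == j or j + 1 == i:
                    continue
                dx = coords[j, 0] - coords[i, 0]
                dy = coords[j, 1] - coords[i, 1]
                dz = coords[j, 2] - coords[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= rc2:
                    continue
                t = np.float32(1.0) - r2 / rc2
                f = np.float32(6.0) * emax * t * t / rc2
                forces[j, 0] += f * dx
                forces[j, 1] += f * dy
                forces[j, 2] += f * dz
                forces[i, 0] -= f * dx
                forces[i, 1] -= f * dy
                forces[i, 2] -= f * dz
        for i in range(n):
            coords[i, 0] += mobility_dt * forces[i, 0] + noise_scale * noise[s, i, 0]
            coords[i, 1] += mobility_dt * forces[i, 1] + noise_scale * noise[s, i, 1]
            coords[i, 2] += mobility_dt * forces[i, 2] + noise_scale * noise[s, i, 2]
    return 0


def brownian_block(coords, bond_i, bond_j, k_nm, r0, emax, rc, search,
                   rebuild_every, mobility_dt, noise_scale, noise,
                   pairs, head, nxt):
    """Integrate noise.shape[0] steps of overdamped Langevin dynamics.

    The non-bonded pair list is rebuilt every ``rebuild_every`` steps with
    search radius ``search`` (= rc + skin).  noise is unit-variance float32;
    it is scaled by noise_scale = sqrt(2 kT dt / friction) here.
    mobility_dt = dt / friction.  Returns a negative status when a workspace
    overflowed (caller enlarges and retries the block).

    Arithmetic runs in float32 (sub-picometre rounding at cellular
    coordinates, far below the thermal noise); positions are kept in the
    caller's float64 array.
    """
    c32 = coords.astype(np.float32)
    status = _block_f32(
        c32, bond_i, bond_j,
        k_nm.astype(np.float32), r0.astype(np.float32),
        np.float32(emax), np.float32(rc), np.float32(search),
        rebuild_every, np.float32(mobility_dt), np.float32(noise_scale),
        noise, pairs, head, nxt)
    if status == 0:
        coords[:] = c32
    return status
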