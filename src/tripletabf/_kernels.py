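"""Numba inner loops for the toy samplers and the ABF engine.

The public API (TripletPotential.energy/gradient, WallParams.energy_force,
langevin_step, accumulate, bias_force) is plain numpy; these kernels
replicate the same arithmetic for the long per-step loops that drive the
synthetic simulations. Cross-consistency between the two routes is covered
by tests.

Potential parameters arrive as the flat float64 vector produced by
``TripletPotential.packed()``:

    [0:3]   k_bg      [3:6]   c_bg
    [6:9]   a_bound   [9:12]  m_bound   [12:15] s_bound
    [15:18] a_unbound [18:21] m_unbound [21:24] s_unbound
    [24:27] a_mid     [27:30] m_mid     [30:33] s_mid
    [33] d_switch [34] w_switch [35] j12 [36] j13 [37] j23
"""

import numpy as np
from numba import njit

__all__ = ["abf_loop", "unbiased_loop", "metropolis_loop", "pot_energy_force"]


@njit(cache=False)
def pot_energy_force(d, p):
    """Energy (kT) and force -dU/dd (kT/Å) of the packed triplet potential."""
    u = 0.0
    f = np.zeros(3)
    s = np.empty(3)
    dsw = np.empty(3)
    for i in range(3):
        x = d[i]
        u += 0.5 * p[i] * (x - p[3 + i]) ** 2
        du = p[i] * (x - p[3 + i])
        for blk in range(3):
            base = 6 + 9 * blk
            amp = p[base + i]
            mu = p[base + 3 + i]
            sig = p[base + 6 + i]
            g = np.exp(-((x - mu) ** 2) / (2.0 * sig * sig))
            u -= amp * g
            du += amp * g * (x - mu) / (sig * sig)
        si = 1.0 / (1.0 + np.exp((x - p[33]) / p[34]))
        s[i] = si
        dsw[i] = -si * (1.0 - si) / p[34]
        f[i] = -du
    j12, j13, j23 = p[35], p[36], p[37]
    u += j12 * s[0] * s[1] + j13 * s[0] * s[2] + j23 * s[1] * s[2]
    f[0] -= dsw[0] * (j12 * s[1] + j13 * s[2])
    f[1] -= dsw[1] * (j12 * s[0] + j23 * s[2])
    f[2] -= dsw[2] * (j13 * s[0] + j23 * s[1])
    return u, f


@njit(cache=False)
def _wall_force(d, low, high, k, f_out):
    """Add half-harmonic wall forces to f_out; returns wall energy."""
    u = 0.0
    for i in range(3):
        x = 0.0
        if d[i] < low:
            x = d[i] - low
        elif d[i] > high:
            x = d[i] - high
        u += 0.5 * k * x * x
        f_out[i] += -k * x
    return u


@njit(cache=False)
def abf_loop(d0, p, wlow, whigh, wk, glow, gup, gwidth, nb,
             full_samples, dt, diff, n_steps, record_stride,
             checkpoint_stride, seed):
    """Overdamped Langevin dynamics with adaptive-biasing-force accumulation.

    Returns (trajectory, counts, force_sum, chk_counts, chk_fsum, ok) where
    trajectory rows are (step, d1, d2, d3) at the record stride, the chk_*
    arrays are accumulator snapshots at each checkpoint stride, and ok is
    False if the coordinates became non-finite.
    """
    np.random.seed(seed)
    counts = np.zeros((nb, nb, nb), dtype=np.int64)
    fsum = np.zeros((nb, nb, nb, 3))
    n_rec = n_steps // record_stride
    traj = np.zeros((n_rec, 4))
    n_chk = n_steps // checkpoint_stride
    chk_counts = np.zeros((n_chk, nb, nb, nb), dtype=np.int64)
    chk_fsum = np.zeros((n_chk, nb, nb, nb, 3))
    d = d0.copy()
    sq = np.empty(3)
    for i in range(3):
        sq[i] = np.sqrt(2.0 * diff[i] * dt)
    i_rec = 0
    i_chk = 0
    for step in range(1, n_steps + 1):
        u, fs = pot_energy_force(d, p)
        _wall_force(d, wlow, whigh, wk, fs)
        ftot = fs.copy()
        in_grid = True
        for i in range(3):
            if d[i] < glow or d[i] > gup:
                in_grid = False
        if in_grid:
            i0 = int((d[0] - glow) / gwidth)
            i1 = int((d[1] - glow) / gwidth)
            i2 = int((d[2] - glow) / gwidth)
            if i0 >= nb:
                i0 = nb - 1
            if i1 >= nb:
                i1 = nb - 1
            if i2 >= nb:
                i2 = nb - 1
            counts[i0, i1, i2] += 1
            c = counts[i0, i1, i2]
            for i in range(3):
                fsum[i0, i1, i2, i] += fs[i]
            if c >= full_samples:
                for i in range(3):
                    ftot[i] -= fsum[i0, i1, i2, i] / c
        for i in range(3):
            d[i] += diff[i] * ftot[i] * dt + sq[i] * np.random.normal()
            if not np.isfinite(d[i]):
                return traj, counts, fsum, chk_counts, chk_fsum, False
        if step % record_stride == 0 and i_rec < n_rec:
            traj[i_rec, 0] = step
            traj[i_rec, 1] = d[0]
            traj[i_rec, 2] = d[1]
            traj[i_rec, 3] = d[2]
            i_rec += 1
        if step % checkpoint_stride == 0 and i_chk < n_chk:
            chk_counts[i_chk] = counts
            chk_fsum[i_chk] = fsum
            i_chk += 1
    return traj, counts, fsum, chk_counts, chk_fsum, True


@njit(cache=False)
def unbiased_loop(d0, p, wlow, whigh, wk, dt, diff, n_steps,
                  record_stride, seed):
    """Plain overdamped Langevin trajectory (no bias, no accumulation)."""
    np.random.seed(seed)
    n_rec = n_steps // record_stride
    traj = np.zeros((n_rec, 4))
    d = d0.copy()
    sq = np.empty(3)
    for i in range(3):
        sq[i] = np.sqrt(2.0 * diff[i] * dt)
    i_rec = 0
    for step in range(1, n_steps + 1):
        u, fs = pot_energy_force(d, p)
        _wall_force(d, wlow, whigh, wk, fs)
        for i in range(3):
            d[i] += diff[i] * fs[i] * dt + sq[i] * np.random.normal()
        if step % record_stride == 0 and i_rec < n_rec:
            traj[i_rec, 0] = step
            traj[i_rec, 1] = d[0]
            traj[i_rec, 2] = d[1]
            traj[i_rec, 3] = d[2]
            i_rec += 1
    return traj


@njit(cache=False)
def metropolis_loop(d0, p, wlow, whigh, wk, glow, gup, gwidth, nb,
                    n_samples, step_size, seed):
    """Random-walk Metropolis over d; returns the in-grid bin histogram."""
    np.random.seed(seed)
    counts = np.zeros((nb, nb, nb), dtype=np.int64)
    d = d0.copy()
    fdum = np.zeros(3)
    u, _ = pot_energy_force(d, p)
    fdum[:] = 0.0
    u += _wall_force(d, wlow, whigh, wk, fdum)
    prop = np.empty(3)
    for it in range(n_samples):
        for i in range(3):
            prop[i] = d[i] + step_size * (2.0 * np.random.random() - 1.0)
        unew, _ = pot_energy_force(prop, p)
        fdum[:] = 0.0
        unew += _wall_force(prop, wlow, whigh, wk, fdum)
        if unew <= u or np.random.random() < np.exp(u - unew):
            d[0], d[1], d[2] = prop[0], prop[1], prop[2]
            u = unew
        in_grid = True
        for i in range(3):
            if d[i] < glow or d[i] > gup:
                in_grid = False
        if in_grid:
            i0 = min(int((d[0] - glow) / gwidth), nb - 1)
            i1 = min(int((d[1] - glow) / gwidth), nb - 1)
            i2 = min(int((d[2] - glow) / gwidth), nb - 1)
            counts[i0, i1, i2] += 1
    return counts
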