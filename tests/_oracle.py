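"""Independent time-marching Bloch integrator used as a test oracle.

Marches the longitudinal magnetization sequentially through every event of
the cycle (inversion, free relaxation, each individual excitation) for many
cycles until the periodic steady state is reached — no affine composition or
fixed-point algebra is used, so this is an independent route to the same
physics as the closed-form model.  ``substep`` forces the free-relaxation
intervals to be integrated in steps of at most that many milliseconds
(exponential decay applied per step), which is mathematically identical but
exercises a literal time-stepping path.
"""

import numpy as np


def march_cycle(p, t1, b1=1.0, m0=1.0, n_cycles=40, substep=None):
    """Steady-state center-excitation signals by brute-force cycle marching.

    Returns ``(s1, s2_first_echo, uni, mz_start)`` without T2* decay.
    """
    t1_ms = t1 * 1000.0
    half = p.n_lines / 2.0
    ta = p.ti1 - half * p.tr_block1
    tb = (p.ti2 - p.ti1) - half * (p.tr_block1 + p.tr_block2)
    tc = p.tr_cycle * 1000.0 - p.ti2 - half * p.tr_block2
    a1 = np.deg2rad(b1 * p.alpha1)
    a2 = np.deg2rad(b1 * p.alpha2)

    def relax(mz, duration):
        if duration <= 0:
            return mz
        if substep is None:
            e = np.exp(-duration / t1_ms)
            return mz * e + m0 * (1.0 - e)
        n = int(np.ceil(duration / substep))
        e = np.exp(-(duration / n) / t1_ms)
        for _ in range(n):
            mz = mz * e + m0 * (1.0 - e)
        return mz

    mz = m0
    s1 = s2 = 0.0
    c = p.n_lines // 2
    for _ in range(n_cycles):
        mz_start = mz
        mz = -p.inv_efficiency * mz
        mz = relax(mz, ta)
        for k in range(p.n_lines):
            if k == c:
                s1 = np.sin(a1) * mz
            mz = mz * np.cos(a1)
            mz = relax(mz, p.tr_block1)
        mz = relax(mz, tb)
        for k in range(p.n_lines):
            if k == c:
                s2 = np.sin(a2) * mz
            mz = mz * np.cos(a2)
            mz = relax(mz, p.tr_block2)
        mz = relax(mz, tc)
    uni = s1 * s2 / (s1 * s1 + s2 * s2)
    return s1, s2, uni, mz_start


def flash_fixed_point(alpha, tr, t1, m0=1.0, n_iter=5000):
    """Spoiled-GRE steady state by fixed-point iteration of the recursion."""
    e = np.exp(-tr / (1000.0 * t1))
    a = np.deg2rad(alpha)
    mz = m0
    for _ in range(n_iter):
        mz = mz * np.cos(a) * e + m0 * (1.0 - e)
    return np.sin(a) * mz
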