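"""Compiled inner loops for the serial-chain dynamics.

Numerically identical to the reference numpy path in ``arm.py`` (the
test suite asserts agreement to machine precision); only the execution
strategy differs.  Import of numba is optional: if unavailable, the
backend silently falls back to the reference implementation.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _chain(q, offsets, axes_local):
    positions = np.zeros((7, 3))
    axes = np.zeros((7, 3))
    Rstack = np.zeros((7, 3, 3))
    R = np.eye(3)
    p = np.zeros(3)
    for k in range(7):
        p = p + R @ offsets[k]
        axes[k] = R @ axes_local[k]
        ax = axes_local[k]
        c = np.cos(q[k])
        s = np.sin(q[k])
        K = np.zeros((3, 3))
        K[0, 1] = -ax[2]
        K[0, 2] = ax[1]
        K[1, 0] = ax[2]
        K[1, 2] = -ax[0]
        K[2, 0] = -ax[1]
        K[2, 1] = ax[0]
        R = R @ (np.eye(3) + s * K + (1.0 - c) * (K @ K))
        positions[k] = p
        Rstack[k] = R
    return positions, axes, Rstack


@njit(cache=False)
def fk_jac(q, offsets, axes_local, hand_length):
    """Fingertip position and 3x7 linear Jacobian."""
    positions, axes, Rstack = _chain(q, offsets, axes_local)
    tip = positions[6] + Rstack[6] @ np.array([0.0, -hand_length, 0.0])
    J = np.zeros((3, 7))
    for k in range(7):
        J[:, k] = np.cross(axes[k], tip - positions[k])
    return tip, J


@njit(cache=False)
def substep(
    q,
    qdot,
    tau,
    dt,
    offsets,
    axes_local,
    body_frame,
    com_local,
    inertia_diag,
    masses,
    gravity,
    armature,
    lo,
    hi,
    locked,
):
    """One semi-implicit Euler substep; returns (q_new, qdot_new)."""
    positions, axes, Rstack = _chain(q, offsets, axes_local)

    # angular velocity / acceleration / joint-origin acceleration
    # recursion with qddot = 0 and base acceleration -g (gravity trick)
    omega = np.zeros((8, 3))
    alpha = np.zeros((8, 3))
    acc = np.zeros((8, 3))
    acc[0] = -gravity
    prev_p = np.zeros(3)
    for k in range(7):
        r = positions[k] - prev_p
        acc[k + 1] = (
            acc[k]
            + np.cross(alpha[k], r)
            + np.cross(omega[k], np.cross(omega[k], r))
        )
        alpha[k + 1] = alpha[k] + np.cross(omega[k], axes[k]) * qdot[k]
        omega[k + 1] = omega[k] + axes[k] * qdot[k]
        prev_p = positions[k]

    M = np.zeros((7, 7))
    Q = np.zeros(7)
    for b in range(3):
        frame = body_frame[b]
        kf = frame + 1
        Rb = Rstack[frame]
        com = positions[frame] + Rb @ com_local[b]
        Iw = Rb @ np.diag(inertia_diag[b]) @ Rb.T
        w = omega[kf]
        al = alpha[kf]
        r = com - positions[frame]
        a_com = acc[kf] + np.cross(al, r) + np.cross(w, np.cross(w, r))
        f = masses[b] * a_com
        nmom = Iw @ al + np.cross(w, Iw @ w)
        Jv = np.zeros((kf, 3))
        for k in range(kf):
            Jv[k] = np.cross(axes[k], com - positions[k])
        M[:kf, :kf] += masses[b] * (Jv @ Jv.T) + axes[:kf] @ Iw @ axes[:kf].T
        Q[:kf] += Jv @ f + axes[:kf] @ nmom

    # reflected rotor/soft-tissue inertia keeps M invertible at aligned-axis
    # postures (e.g. the hanging arm, where two shoulder axes coincide)
    for i in range(7):
        M[i, i] += armature

    qddot = np.zeros(7)
    nfree = 0
    for i in range(7):
        if not locked[i]:
            nfree += 1
    if nfree == 7:
        qddot = np.linalg.solve(M, tau - Q)
    elif nfree > 0:
        idx = np.empty(nfree, np.int64)
        j = 0
        for i in range(7):
            if not locked[i]:
                idx[j] = i
                j += 1
        Mf = np.empty((nfree, nfree))
        bf = np.empty(nfree)
        for a in range(nfree):
            bf[a] = tau[idx[a]] - Q[idx[a]]
            for c in range(nfree):
                Mf[a, c] = M[idx[a], idx[c]]
        sol = np.linalg.solve(Mf, bf)
        for a in range(nfree):
            qddot[idx[a]] = sol[a]

    qdot_new = qdot + dt * qddot
    for i in range(7):
        if locked[i]:
            qdot_new[i] = 0.0
    q_new = q + dt * qdot_new
    for i in range(7):
        if q_new[i] < lo[i]:
            q_new[i] = lo[i]
            qdot_new[i] = 0.0
        elif q_new[i] > hi[i]:
            q_new[i] = hi[i]
            qdot_new[i] = 0.0
    return q_new, qdot_new
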