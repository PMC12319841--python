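"""Elementary magnetization operators.

Each spin carries a classical magnetization 3-vector m = (mx, my, mz), with
equilibrium m0 = (0, 0, 1).  Three operators act on it:

* ``rotate_rf`` -- an instantaneous hard RF pulse: a right-handed rotation by
  the flip angle about the transverse axis (cos phase, sin phase, 0).
* ``relax`` -- Bloch relaxation over a time step: transverse decay with T2,
  longitudinal recovery towards 1 with T1.
* ``precess`` -- rotation of the transverse components about z by an
  accumulated phase, positive phase for positive field offset.

All operators are vectorized over leading axes: ``m`` may be shaped (3,) or
(Ns, 3).  Sign conventions (handedness of the RF rotation, sign of the
precession phase) are fixed here once; every reported quantity in the package
is a magnitude or a magnitude ratio and is insensitive to them.
"""

from __future__ import annotations

import numpy as np


def rotate_rf(m: np.ndarray, flip: float, phase: float) -> np.ndarray:
    """Rotate magnetization by ``flip`` about the axis (cos phase, sin phase, 0).

    Right-handed rotation (Rodrigues formula); preserves |m| exactly up to
    floating point.  ``flip`` and ``phase`` are radians.
    """
    m = np.asarray(m, dtype=float)
    n = np.array([np.cos(phase), np.sin(phase), 0.0])
    c, s = np.cos(flip), np.sin(flip)
    ndotm = m @ n
    cross = np.cross(np.broadcast_to(n, m.shape), m)
    return m * c + cross * s + np.multiply.outer(ndotm, n) * (1.0 - c)


def relax(m: np.ndarray, dt: float, t1, t2) -> np.ndarray:
    """Apply Bloch relaxation over ``dt`` ms.

    Transverse components decay with exp(-dt/T2); the longitudinal component
    recovers towards the equilibrium value 1 with exp(-dt/T1).  ``t1`` and
    ``t2`` may be scalars or per-spin arrays (shape (Ns,)).
    """
    m = np.array(m, dtype=float, copy=True)
    e2 = np.exp(-dt / np.asarray(t2, dtype=float))
    e1 = np.exp(-dt / np.asarray(t1, dtype=float))
    m[..., 0] *= e2
    m[..., 1] *= e2
    m[..., 2] = 1.0 + (m[..., 2] - 1.0) * e1
    return m


def precess(m: np.ndarray, dphi) -> np.ndarray:
    """Rotate the transverse components about z by ``dphi`` rad.

    ``dphi`` is the phase accumulated by the caller over one time step,
    gamma * (B0 * db0 + G . r) * dt; it may be scalar or per-spin.
    """
    m = np.array(m, dtype=float, copy=True)
    dphi = np.asarray(dphi, dtype=float)
    c, s = np.cos(dphi), np.sin(dphi)
    mx = m[..., 0] * c - m[..., 1] * s
    my = m[..., 0] * s + m[..., 1] * c
    m[..., 0] = mx
    m[..., 1] = my
    return m


def dephase_phases(n_spins: int, span: float) -> np.ndarray:
    """Deterministic ideal-dephasing phase ramp: spin s receives span*s/Ns."""
    return span * np.arange(n_spins) / n_spins


def ideal_dephase(m: np.ndarray, span: float) -> np.ndarray:
    """Spread transverse phase linearly across the ensemble.

    Emulates a perfect crusher gradient: spin s of Ns gets extra transverse
    phase span*s/Ns.  With span an integer multiple of 2*pi the transverse sum
    of an otherwise uniform ensemble vanishes; because the ramp is
    deterministic in the spin index, a later pulse plus a second application
    refocuses it (crusher pair).
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    return precess(m, dephase_phases(m.shape[0], span))
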