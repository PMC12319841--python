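"""Random-walk engine: Gaussian steps, boundaries, substrates, permeability.

Spins take Gaussian steps with per-axis standard deviation sqrt(2*D*dt) where
D is the diffusivity of the substrate the spin currently occupies.  A step
that would carry a spin from substrate i into substrate j is accepted with
probability perm[i, j]; on rejection a fresh step is drawn for the same time
step, up to ``max_redraw`` times, after which the spin rests in place.

Virtual FoV scaling: a phantom of native FoV L used with scale factor c
behaves as a physical box of size c*L (all lengths, including cylinder radii,
scale by c).  Internally positions are kept in native phantom units and the
*step* is divided by c, so the stored geometry and field map are reused
unchanged at any scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import VoxelPhantom


@dataclass
class SubstrateSet:
    """Per-substrate tissue properties.

    t1, t2: relaxation times, ms, length N arrays.
    d: diffusivities, um^2/ms.
    perm: N x N matrix; perm[i, j] is the probability that a step crossing
    from substrate i into substrate j is accepted.  Diagonal entries are 1
    (staying put is always allowed); perm[i, j] = 0 is an impermeable wall.
    """

    t1: np.ndarray
    t2: np.ndarray
    d: np.ndarray
    perm: np.ndarray | None = None

    def __post_init__(self):
        self.t1 = np.atleast_1d(np.asarray(self.t1, dtype=float))
        self.t2 = np.atleast_1d(np.asarray(self.t2, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        n = len(self.t1)
        if len(self.t2) != n or len(self.d) != n:
            raise ValueError("t1, t2, d must have equal lengths")
        if np.any(self.t1 <= 0) or np.any(self.t2 <= 0):
            raise ValueError("relaxation times must be positive")
        if np.any(self.d < 0):
            raise ValueError("diffusivities must be non-negative")
        if self.perm is None:
            self.perm = np.ones((n, n))
        self.perm = np.asarray(self.perm, dtype=float)
        if self.perm.shape != (n, n):
            raise ValueError(f"perm must be {n}x{n}")
        if np.any(self.perm < 0) or np.any(self.perm > 1):
            raise ValueError("permeabilities must lie in [0, 1]")
        if not np.allclose(np.diag(self.perm), 1.0):
            raise ValueError("perm diagonal must be 1 (staying is always allowed)")

    @property
    def n(self) -> int:
        return len(self.t1)


@dataclass
class SpinEnsemble:
    """Positions (native phantom um), magnetizations, substrate labels."""

    pos: np.ndarray
    m: np.ndarray
    sub_now: np.ndarray
    sub_init: np.ndarray
    rest_events: int = 0

    @classmethod
    def initialize(
        cls,
        phantom: VoxelPhantom,
        n_spins: int,
        rng: np.random.Generator,
        labels=None,
    ) -> "SpinEnsemble":
        """Uniform placement over the FoV at equilibrium magnetization [0,0,1].

        ``labels``: optional collection of substrate labels to restrict the
        initial placement to (rejection sampling).
        """
        pos = rng.random((n_spins, 3)) * phantom.fov
        sub = lookup_labels(pos, phantom)
        if labels is not None:
            allowed = np.asarray(sorted(set(int(v) for v in labels)))
            bad = ~np.isin(sub, allowed)
            while bad.any():
                pos[bad] = rng.random((int(bad.sum()), 3)) * phantom.fov
                sub = lookup_labels(pos, phantom)
                bad = ~np.isin(sub, allowed)
        m = np.zeros((n_spins, 3))
        m[:, 2] = 1.0
        return cls(pos=pos, m=m, sub_now=sub, sub_init=sub.copy())

    @property
    def n_spins(self) -> int:
        return self.pos.shape[0]


def draw_step(d: float, dt: float, rng: np.random.Generator, n: int | None = None):
    """Gaussian step(s): each component i.i.d. Normal(0, 2*D*dt).

    Per-axis standard deviation sqrt(2*D*dt) um; D = 0 gives exact zeros.
    Returns shape (3,) when ``n`` is None, else (n, 3).
    """
    if d < 0 or dt <= 0:
        raise ValueError("need d >= 0 and dt > 0")
    shape = (3,) if n is None else (n, 3)
    if d == 0.0:
        return np.zeros(shape)
    return rng.standard_normal(shape) * np.sqrt(2.0 * d * dt)


def apply_boundary(pos, fov, mode: str):
    """Map positions back into [0, fov) coordinate-wise.

    periodic: modulo; reflect: mirror about the violated face.  Excursions
    larger than one FoV are a contract violation (they cannot occur at sane
    time steps) and raise.
    """
    pos = np.asarray(pos, dtype=float)
    fov = np.asarray(fov, dtype=float)
    if np.any(pos < -fov) or np.any(pos >= 2 * fov):
        raise ValueError("boundary excursion exceeds one FoV; reduce the time step")
    if mode == "periodic":
        return np.mod(pos, fov)
    if mode == "reflect":
        out = np.where(pos < 0, -pos, pos)
        out = np.where(out >= fov, 2 * fov - out, out)
        # an exact landing on the far face mirrors to the face itself; fold once more
        return np.mod(out, fov)
    raise ValueError(f"unknown boundary mode {mode!r}")


def lookup_labels(pos_native: np.ndarray, phantom: VoxelPhantom) -> np.ndarray:
    """Substrate labels at native-unit positions (half-open voxel convention)."""
    vox = phantom.voxel_size
    idx = np.floor(np.atleast_2d(pos_native) / vox).astype(np.intp)
    np.clip(idx, 0, phantom.grid - 1, out=idx)
    return phantom.substrate[idx[:, 0], idx[:, 1], idx[:, 2]]


def locate_substrate(pos, phantom: VoxelPhantom, fov_scale: float = 1.0):
    """Label of the voxel containing physical position(s) ``pos``.

    ``pos`` lives in the scaled box [0, fov*fov_scale); the native position is
    pos/fov_scale.  Scalar 3-vector in, scalar label out.
    """
    pos = np.asarray(pos, dtype=float)
    native = pos / fov_scale
    if np.any(native < 0) or np.any(native >= phantom.fov):
        raise ValueError("position outside the (scaled) phantom box")
    lab = lookup_labels(native, phantom)
    return int(lab[0]) if pos.ndim == 1 else lab


def effective_step_scale(fov_scale: float) -> float:
    """Native-unit step multiplier under virtual FoV scaling.

    Physical lengths are native lengths times fov_scale, so a physical step
    maps to a native step divided by fov_scale; the stored field map is
    reused unchanged.
    """
    if fov_scale <= 0:
        raise ValueError("fov_scale must be positive")
    return 1.0 / fov_scale


def step_ensemble(
    es: SpinEnsemble,
    phantom: VoxelPhantom,
    ss: SubstrateSet,
    dt: float,
    rng: np.random.Generator,
    fov_scale: float = 1.0,
    boundary: str = "reflect",
    max_redraw: int = 100,
) -> int:
    """Advance every spin by one time step (vectorized attempt_move).

    The candidate step uses the diffusivity of the spin's current substrate
    (step origin).  Substrate crossings i -> j are accepted with probability
    perm[i, j]; rejected spins redraw a fresh step, up to ``max_redraw``
    times, then rest in place for this step.  Returns the number of resting
    spins (also accumulated on ``es.rest_events``).
    """
    sigma_nat = np.sqrt(2.0 * ss.d * dt) * effective_step_scale(fov_scale)
    pending = np.arange(es.n_spins)
    for _ in range(max_redraw + 1):
        sub_i = es.sub_now[pending]
        step = rng.standard_normal((len(pending), 3)) * sigma_nat[sub_i][:, None]
        cand = apply_boundary(es.pos[pending] + step, phantom.fov, boundary)
        lab = lookup_labels(cand, phantom)
        crossing = lab != sub_i
        accept = ~crossing
        if crossing.any():
            p = ss.perm[sub_i[crossing], lab[crossing]]
            accept[crossing] = rng.random(int(crossing.sum())) < p
        idx = pending[accept]
        es.pos[idx] = cand[accept]
        es.sub_now[idx] = lab[accept]
        pending = pending[~accept]
        if len(pending) == 0:
            break
    es.rest_events += len(pending)
    return len(pending)


@dataclass
class OccupancyTrack:
    """Recorded walk: times (ms), per-substrate spin counts, optional labels."""

    times: np.ndarray
    counts: np.ndarray  # (n_recorded, N)
    sub_init: np.ndarray
    labels: np.ndarray | None = None  # (n_recorded, Ns) if recorded
    positions: np.ndarray | None = None  # (n_recorded, Ns, 3) physical um
    rest_events: int = 0
    final: SpinEnsemble | None = field(default=None, repr=False)


def simulate_walk(
    phantom: VoxelPhantom,
    ss: SubstrateSet,
    n_steps: int,
    dt: float,
    n_spins: int,
    seed: int = 0,
    boundary: str = "reflect",
    fov_scale: float = 1.0,
    record_every: int = 0,
    record_labels: bool = False,
    record_positions: bool = False,
    max_redraw: int = 100,
) -> OccupancyTrack:
    """Pure diffusion run (no magnetization): occupancy and trajectories.

    ``record_every`` = k records every k-th step (0 records only start/end).
    """
    rng = np.random.default_rng(seed)
    es = SpinEnsemble.initialize(phantom, n_spins, rng)
    n_sub = ss.n
    rec_steps = (
        list(range(0, n_steps + 1, record_every)) if record_every else [0, n_steps]
    )
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    counts = np.zeros((len(rec_steps), n_sub), dtype=np.int64)
    labels = np.zeros((len(rec_steps), n_spins), dtype=np.int16) if record_labels else None
    positions = (
        np.zeros((len(rec_steps), n_spins, 3), dtype=np.float32)
        if record_positions
        else None
    )
    rec = {s: i for i, s in enumerate(rec_steps)}

    def snapshot(step):
        i = rec[step]
        counts[i] = np.bincount(es.sub_now, minlength=n_sub)
        if labels is not None:
            labels[i] = es.sub_now
        if positions is not None:
            positions[i] = es.pos * fov_scale

    snapshot(0)
    for n in range(1, n_steps + 1):
        step_ensemble(es, phantom, ss, dt, rng, fov_scale, boundary, max_redraw)
        if n in rec:
            snapshot(n)
    return OccupancyTrack(
        times=np.asarray(rec_steps, dtype=float) * dt,
        counts=counts,
        sub_init=es.sub_init,
        labels=labels,
        positions=positions,
        rest_events=es.rest_events,
        final=es,
    )
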