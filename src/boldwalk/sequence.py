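"""Pulse-sequence timelines and the Monte Carlo simulation loop.

A :class:`Timeline` is a dt-gridded event list: instantaneous hard RF pulses
(step index, flip, phase), ideal-dephasing events (step index, span), optional
per-step gradient samples, and echo recording steps.  Builders are provided
for GRE, SE, bSSFP, GRASE and STE protocols; arbitrary timelines can be
assembled directly.

The simulation loop applies, at every time step, in order: random walk,
ideal dephasing, gradient + off-resonance precession (with relaxation),
RF pulses, echo recording.  RF and gradients are never simultaneous.
Relaxation uses the T1/T2 of the substrate the spin occupied at the start of
the step; the off-resonance phase is looked up at the end-of-step position.
The phantom's stored field map (Tesla at B0 = 1 T) is scaled by
B0 * field_scale at run time, where field_scale absorbs the oxygenation
rescaling (1-Y_state)/(1-Y_generated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import __version__
from .constants import GAMMA_PROTON, MS_TO_S
from .phantom import VoxelPhantom
from .physics import dephase_phases, rotate_rf
from .walk import SpinEnsemble, SubstrateSet, step_ensemble

DEG = np.pi / 180.0


def _steps(t_ms: float, dt: float, what: str) -> int:
    n = t_ms / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{what} = {t_ms} ms is not an integer multiple of dt = {dt} ms")
    return int(round(n))


@dataclass
class Timeline:
    """dt-gridded event schedule for one simulation.

    rf_events: (step, flip rad, phase rad); dephase_events: (step, span rad);
    gradient: optional (n_steps+1, 3) array, mT/um, sampled at each step;
    echo_steps: steps at which the complex transverse sums are recorded.
    """

    dt: float
    n_steps: int
    rf_events: list = field(default_factory=list)
    dephase_events: list = field(default_factory=list)
    gradient: np.ndarray | None = None
    echo_steps: list = field(default_factory=list)
    tr_steps: int | None = None
    n_prep: int = 0
    name: str = "custom"

    def __post_init__(self):
        if self.dt <= 0 or self.n_steps < 0:
            raise ValueError("need dt > 0 and n_steps >= 0")
        for s, *_ in self.rf_events + self.dephase_events:
            if not 0 <= s <= self.n_steps:
                raise ValueError(f"event step {s} outside [0, {self.n_steps}]")
        if sorted(self.echo_steps) != list(self.echo_steps) or len(
            set(self.echo_steps)
        ) != len(self.echo_steps):
            raise ValueError("echo_steps must be strictly increasing")
        for s in self.echo_steps:
            if not 0 <= s <= self.n_steps:
                raise ValueError(f"echo step {s} outside [0, {self.n_steps}]")
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float)
            if self.gradient.shape != (self.n_steps + 1, 3):
                raise ValueError("gradient must have shape (n_steps + 1, 3)")

    @property
    def echo_times(self) -> np.ndarray:
        return np.asarray(self.echo_steps, dtype=float) * self.dt


def build_gre(te: float, dt: float) -> Timeline:
    """Gradient-recalled echo: 90x at t = 0, free dephasing, echo at TE."""
    n = _steps(te, dt, "TE")
    return Timeline(dt, n, rf_events=[(0, 90 * DEG, 0.0)], echo_steps=[n], name="gre")


def build_se(te: float, dt: float) -> Timeline:
    """Spin echo: 90x at 0, 180y refocusing at TE/2, echo at TE."""
    n = _steps(te, dt, "TE")
    if n % 2:
        raise ValueError("TE must be an even multiple of dt for a spin echo")
    rf = [(0, 90 * DEG, 0.0), (n // 2, 180 * DEG, 90 * DEG)]
    return Timeline(dt, n, rf_events=rf, echo_steps=[n], name="se")


def build_bssfp(
    te: float,
    tr: float,
    fa: float,
    phase_cycle: float = np.pi,
    n_prep: int = 0,
    dt: float = 0.05,
) -> Timeline:
    """Balanced SSFP: pulses every TR with linearly incremented phase.

    ``fa`` and ``phase_cycle`` in radians.  n_prep preparation TRs precede the
    recorded echo, which falls TE after the final pulse; TE must equal TR/2.
    Reaching steady state needs a preparation span of roughly 5*T1.
    """
    if abs(te - tr / 2) > 1e-9:
        raise ValueError("bSSFP requires TE = TR/2")
    tr_steps = _steps(tr, dt, "TR")
    te_steps = _steps(te, dt, "TE")
    rf = [(k * tr_steps, fa, (k * phase_cycle) % (2 * np.pi)) for k in range(n_prep + 1)]
    echo = n_prep * tr_steps + te_steps
    return Timeline(
        dt,
        echo,
        rf_events=rf,
        echo_steps=[echo],
        tr_steps=tr_steps,
        n_prep=n_prep,
        name="bssfp",
    )


def build_grase(n_se: int, echo_spacing: float, dt: float) -> Timeline:
    """Hybrid gradient/spin-echo train.

    90x excitation, then n_se perfect 180 refocusing pulses with alternating
    +/-y phase at odd multiples of echo_spacing/2.  Echoes are recorded every
    echo_spacing/2 starting at echo_spacing/2: 2*n_se + 1 echoes, the
    even-numbered ones coinciding with the spin-echo refocusing points.
    """
    if n_se < 1:
        raise ValueError("need at least one refocusing pulse")
    half = _steps(echo_spacing, dt, "echo spacing")
    if half % 2:
        raise ValueError("echo spacing must be an even multiple of dt")
    half //= 2
    rf = [(0, 90 * DEG, 0.0)]
    for k in range(n_se):
        phase = 90 * DEG if k % 2 == 0 else -90 * DEG
        rf.append(((2 * k + 1) * half, 180 * DEG, phase))
    echoes = [(k + 1) * half for k in range(2 * n_se + 1)]
    return Timeline(dt, echoes[-1], rf_events=rf, echo_steps=echoes, name="grase")


def build_ste(tau: float, tm: float, dt: float) -> Timeline:
    """Stimulated echo: 90x -- tau -- 90y -- Tm -- 90y, STE at 2*tau + Tm.

    Pathway selection uses the ideal-dephasing mechanism in place of crusher
    gradients: a span-2pi dephase immediately before and after the second
    pulse, a spoiler during the mixing period, and a span-2pi rephasing event
    at the stimulated-echo step.  The primary spin echo of the first pulse
    pair is recorded at 2*tau; the stimulated echo at tau + Tm + tau.  For
    static spins in a uniform field the recorded amplitudes follow the
    classic closed forms Ns/2*exp(-2tau/T2) and
    Ns/2*exp(-2tau/T2)*exp(-Tm/T1).
    """
    s_tau = _steps(tau, dt, "tau")
    s_tm = _steps(tm, dt, "Tm")
    span = 2 * np.pi
    rf = [(0, 90 * DEG, 0.0), (s_tau, 90 * DEG, 90 * DEG)]
    deph = [(s_tau, span)]
    if s_tm > 0:
        deph.append((s_tau + 1, span))
    se_step = 2 * s_tau
    ste_step = 2 * s_tau + s_tm
    rf.append((s_tau + s_tm, 90 * DEG, 90 * DEG))
    if s_tm > s_tau + 1:
        # mixing-period spoiler, placed after the primary SE has been recorded;
        # double span so no transverse pathway through the mixing period can be
        # re-phased by the final crusher
        deph.append((se_step + max(1, (s_tm - s_tau) // 2), 2 * span))
    if s_tm > 0:
        deph.append((ste_step, span))
    echoes = [se_step, ste_step] if ste_step > se_step else [se_step]
    return Timeline(dt, ste_step, rf_events=rf, dephase_events=deph,
                    echo_steps=echoes, name="ste")


# ---------------------------------------------------------------------------
# Echo records and the simulation loop
# ---------------------------------------------------------------------------


@dataclass
class EchoRecord:
    """Complex transverse sums at one echo, total and per compartment.

    ``by_current`` keys compartments by the substrate at echo time,
    ``by_initial`` by the substrate at t = 0; both sum to ``total``.
    """

    step: int
    time: float
    total: complex
    by_current: np.ndarray
    by_initial: np.ndarray
    n_current: np.ndarray
    n_initial: np.ndarray


@dataclass
class SimResult:
    """Echo records plus provenance for one simulation run."""

    echoes: list
    config: dict
    rest_events: int = 0
    trajectory: np.ndarray | None = None
    substrate_track: np.ndarray | None = None
    trajectory_times: np.ndarray | None = None

    @property
    def signal(self) -> np.ndarray:
        """Complex total signal per echo."""
        return np.array([e.total for e in self.echoes])

    def compartment_signal(self, label: int, by: str = "current") -> np.ndarray:
        """Complex per-echo signal of one compartment ('current' or 'initial')."""
        key = {"current": "by_current", "initial": "by_initial"}[by]
        return np.array([getattr(e, key)[label] for e in self.echoes])


def run_simulation(
    phantom: VoxelPhantom,
    ss: SubstrateSet,
    tl: Timeline,
    *,
    n_spins: int,
    b0: float = 1.0,
    seed: int = 0,
    boundary: str = "reflect",
    fov_scale: float = 1.0,
    field_scale: float = 1.0,
    init_labels=None,
    max_redraw: int = 100,
    record_trajectory: bool = False,
    record_every: int = 1,
) -> SimResult:
    """Run the Monte Carlo loop for one timeline and one physiological state.

    Per step: walk, ideal dephasing, gradients + off-resonance precession
    (with relaxation), RF, echo/trajectory recording.  The stored unit-field
    map is scaled by ``b0 * field_scale``.  Same inputs and seed give
    bit-identical output.
    """
    if phantom.n_substrates > ss.n:
        raise ValueError(
            f"phantom uses {phantom.n_substrates} substrates but only "
            f"{ss.n} substrate property sets were given"
        )
    rng = np.random.default_rng(seed)
    es = SpinEnsemble.initialize(phantom, n_spins, rng, labels=init_labels)
    n_sub = ss.n

    # per-step lookup tables
    e1 = np.exp(-tl.dt / ss.t1)
    e2 = np.exp(-tl.dt / ss.t2)
    phase_per_tesla = GAMMA_PROTON * tl.dt * MS_TO_S
    phase_tab = (b0 * field_scale * phase_per_tesla) * phantom.db0.astype(
        np.float64
    ).ravel()
    grid = phantom.grid
    vox = phantom.voxel_size
    strides = np.array([grid[1] * grid[2], grid[2], 1], dtype=np.intp)

    rf_at: dict[int, list] = {}
    for s, flip, phase in tl.rf_events:
        rf_at.setdefault(s, []).append((flip, phase))
    deph_at: dict[int, list] = {}
    for s, span in tl.dephase_events:
        deph_at.setdefault(s, []).append(span)
    echo_at = set(tl.echo_steps)

    static = bool(np.all(ss.d == 0.0))
    deph_ramp_cache: dict[float, np.ndarray] = {}

    echoes: list[EchoRecord] = []
    traj_steps = (
        list(range(0, tl.n_steps + 1, max(1, record_every))) if record_trajectory else []
    )
    if record_trajectory and traj_steps[-1] != tl.n_steps:
        traj_steps.append(tl.n_steps)
    traj = (
        np.zeros((len(traj_steps), n_spins, 3), dtype=np.float32)
        if record_trajectory
        else None
    )
    strack = (
        np.zeros((len(traj_steps), n_spins), dtype=np.int16) if record_trajectory else None
    )
    traj_index = {s: i for i, s in enumerate(traj_steps)}

    def precess_relax(sub_prev, dphi):
        mx, my = es.m[:, 0], es.m[:, 1]
        c, s = np.cos(dphi), np.sin(dphi)
        nx = mx * c - my * s
        ny = mx * s + my * c
        f2 = e2[sub_prev]
        es.m[:, 0] = nx * f2
        es.m[:, 1] = ny * f2
        es.m[:, 2] = 1.0 + (es.m[:, 2] - 1.0) * e1[sub_prev]

    def apply_phase(dphi):
        mx, my = es.m[:, 0].copy(), es.m[:, 1]
        c, s = np.cos(dphi), np.sin(dphi)
        es.m[:, 0] = mx * c - my * s
        es.m[:, 1] = mx * s + my * c

    def flat_index():
        idx = np.floor(es.pos / vox).astype(np.intp)
        np.clip(idx, 0, grid - 1, out=idx)
        return idx @ strides

    def record_echo(n):
        c = es.m[:, 0] + 1j * es.m[:, 1]
        total = c.sum()
        by_cur = np.zeros(n_sub, dtype=complex)
        by_ini = np.zeros(n_sub, dtype=complex)
        np.add.at(by_cur, es.sub_now, c)
        np.add.at(by_ini, es.sub_init, c)
        echoes.append(
            EchoRecord(
                step=n,
                time=n * tl.dt,
                total=total,
                by_current=by_cur,
                by_initial=by_ini,
                n_current=np.bincount(es.sub_now, minlength=n_sub),
                n_initial=np.bincount(es.sub_init, minlength=n_sub),
            )
        )

    def do_events(n, walked: bool):
        if n in deph_at:
            for span in deph_at[n]:
                if span not in deph_ramp_cache:
                    deph_ramp_cache[span] = dephase_phases(n_spins, span)
                apply_phase(deph_ramp_cache[span])
        if n in rf_at:
            for flip, phase in rf_at[n]:
                es.m = rotate_rf(es.m, flip, phase)
        if n in echo_at:
            record_echo(n)
        if traj is not None and n in traj_index:
            i = traj_index[n]
            traj[i] = es.pos * fov_scale
            strack[i] = es.sub_now

    do_events(0, walked=False)
    for n in range(1, tl.n_steps + 1):
        sub_prev = es.sub_now
        if not static:
            sub_prev = es.sub_now.copy()
            step_ensemble(es, phantom, ss, tl.dt, rng, fov_scale, boundary, max_redraw)
        dphi = phase_tab[flat_index()]
        if tl.gradient is not None:
            g = tl.gradient[n]
            if np.any(g):
                # gradient in mT/um; physical position = native * fov_scale
                dphi = dphi + (es.pos * fov_scale) @ (
                    g * 1e-3 * GAMMA_PROTON * tl.dt * MS_TO_S
                )
        precess_relax(sub_prev, dphi)
        do_events(n, walked=True)

    config = {
        "sequence": tl.name,
        "n_spins": n_spins,
        "n_steps": tl.n_steps,
        "dt_ms": tl.dt,
        "b0_T": b0,
        "field_scale": field_scale,
        "fov_scale": fov_scale,
        "boundary": boundary,
        "seed": seed,
        "max_redraw": max_redraw,
        "version": __version__,
    }
    return SimResult(
        echoes=echoes,
        config=config,
        rest_events=es.rest_events,
        trajectory=traj,
        substrate_track=strack,
        trajectory_times=np.asarray(traj_steps, dtype=float) * tl.dt if traj_steps else None,
    )


def save_result(results, path, extra_attrs=None):
    """Write one or more named SimResults to an HDF5 file.

    ``results``: dict mapping group name (e.g. 'rest/scale_000') to SimResult.
    Layout per group: /echoes/step_index, /echoes/signal_real & signal_imag
    (rows: total, per current-substrate, per initial-substrate compartments),
    /echoes/n_current & n_initial, optional /trajectory & /substrate_track.
    """
    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v
        for name, res in results.items():
            g = f.create_group(name)
            for ck, cv in res.config.items():
                g.attrs[ck] = cv
            ge = g.create_group("echoes")
            steps = np.array([e.step for e in res.echoes])
            sig = np.array(
                [
                    np.concatenate(([e.total], e.by_current, e.by_initial))
                    for e in res.echoes
                ]
            )
            ge.create_dataset("step_index", data=steps)
            ge.create_dataset("signal_real", data=sig.real)
            ge.create_dataset("signal_imag", data=sig.imag)
            ge.create_dataset(
                "n_current", data=np.array([e.n_current for e in res.echoes])
            )
            ge.create_dataset(
                "n_initial", data=np.array([e.n_initial for e in res.echoes])
            )
            g.attrs["rest_events"] = res.rest_events
            if res.trajectory is not None:
                # stored spin-major: (Ns, n_recorded, 3) physical um
                g.create_dataset("trajectory", data=res.trajectory.transpose(1, 0, 2))
                g.create_dataset(
                    "substrate_track", data=res.substrate_track.transpose(1, 0)
                )
                g.create_dataset("trajectory_times", data=res.trajectory_times)
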