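"""INI configuration parsing and validation.

One configuration file describes one experiment: general settings, the scan
(sequence type and timing), tissue properties per physiological state, file
paths, and optional simulation extras.  Keys are case-sensitive; unknown keys
or sections are errors.  Arrays are comma-separated.  Angles are given in
degrees in the file and converted to radians internally; times are ms,
fields Tesla, diffusivities um^2/ms.

Schema (defaults in parentheses; * = required):

[GENERAL]
    b0*            static field, Tesla
    n_spins*       number of random walkers
    dt             time step, ms (0.05)
    seed           RNG seed (0)
    boundary       periodic | reflect (reflect)
    fov_scales     comma list of virtual FoV scale factors (1)

[SCAN]
    sequence*      gre | se | bssfp | grase | ste
    te             ms (gre, se)
    tr, flip, phase_cycle, n_prep   (bssfp; flip/phase_cycle in degrees)
    n_se, echo_spacing              (grase)
    tau, tm                         (ste)

[TISSUE]
    t1*            per-substrate T1, ms
    t2_rest*       per-substrate T2 at rest, ms
    t2_active      per-substrate T2 active (t2_rest)
    d*             per-substrate diffusivity, um^2/ms
    perm           N*N row-major crossing probabilities (all 1)
    y_rest         blood oxygenation at rest (0.78)
    y_active       blood oxygenation active (0.85)

[FILES]
    phantom*       HDF5 phantom path(s), comma separated
    output*        HDF5 result path (suffix _<k> added for multiple phantoms)

[SIMULATION]
    record_trajectory   true/false (false)
    record_every        trajectory decimation, steps (10)
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

DEG = np.pi / 180.0

_SCHEMA = {
    "GENERAL": {"b0", "n_spins", "dt", "seed", "boundary", "fov_scales"},
    "SCAN": {"sequence", "te", "tr", "flip", "phase_cycle", "n_prep", "n_se",
             "echo_spacing", "tau", "tm"},
    "TISSUE": {"t1", "t2_rest", "t2_active", "d", "perm", "y_rest", "y_active"},
    "FILES": {"phantom", "output"},
    "SIMULATION": {"record_trajectory", "record_every"},
}
_REQUIRED_SECTIONS = ("GENERAL", "SCAN", "TISSUE", "FILES")

_SEQ_PARAMS = {
    "gre": {"te"},
    "se": {"te"},
    "bssfp": {"tr", "flip"},
    "grase": {"n_se", "echo_spacing"},
    "ste": {"tau", "tm"},
}


class ConfigError(ValueError):
    """Raised for any invalid or incomplete configuration file."""


@dataclass
class SimConfig:
    """Fully validated simulation configuration."""

    b0: float
    n_spins: int
    dt: float
    seed: int
    boundary: str
    fov_scales: list
    sequence: str
    scan: dict
    t1: np.ndarray
    t2_rest: np.ndarray
    t2_active: np.ndarray
    d: np.ndarray
    perm: np.ndarray
    y_rest: float
    y_active: float
    phantom_paths: list
    output_path: str
    record_trajectory: bool = False
    record_every: int = 10
    source_text: str = dfield(default="", repr=False)

    @property
    def n_substrates(self) -> int:
        return len(self.t1)


def _floats(s: str) -> np.ndarray:
    try:
        return np.array([float(v) for v in s.split(",") if v.strip() != ""])
    except ValueError as e:
        raise ConfigError(f"cannot parse number list {s!r}") from e


def parse_config(path) -> SimConfig:
    """Parse and validate one INI file into a SimConfig (fail loud)."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"configuration file not found: {path}")
    cp = configparser.ConfigParser()
    cp.optionxform = str  # case-sensitive keys
    text = path.read_text()
    try:
        cp.read_string(text, source=str(path))
    except configparser.Error as e:
        raise ConfigError(f"{path}: {e}") from e

    missing = [s for s in _REQUIRED_SECTIONS if s not in cp]
    if missing:
        raise ConfigError(f"{path}: missing required sections {missing}")
    for sec in cp.sections():
        if sec not in _SCHEMA:
            raise ConfigError(f"{path}: unknown section [{sec}]")
        unknown = set(cp[sec]) - _SCHEMA[sec]
        if unknown:
            raise ConfigError(f"{path}: unknown keys in [{sec}]: {sorted(unknown)}")

    g = cp["GENERAL"]
    for key in ("b0", "n_spins"):
        if key not in g:
            raise ConfigError(f"{path}: [GENERAL] requires {key}")
    b0 = float(g["b0"])
    n_spins = int(g["n_spins"])
    if n_spins <= 0:
        raise ConfigError("n_spins must be positive")
    dt = float(g.get("dt", "0.05"))
    if dt <= 0:
        raise ConfigError("dt must be positive")
    seed = int(g.get("seed", "0"))
    boundary = g.get("boundary", "reflect")
    if boundary not in ("periodic", "reflect"):
        raise ConfigError(f"boundary must be periodic or reflect, got {boundary!r}")
    fov_scales = list(_floats(g.get("fov_scales", "1")))
    if any(s <= 0 for s in fov_scales):
        raise ConfigError("fov_scales must be positive")

    sc = cp["SCAN"]
    if "sequence" not in sc:
        raise ConfigError(f"{path}: [SCAN] requires sequence")
    sequence = sc["sequence"].lower()
    if sequence not in _SEQ_PARAMS:
        raise ConfigError(f"unknown sequence {sequence!r}")
    missing_p = _SEQ_PARAMS[sequence] - set(sc)
    if missing_p:
        raise ConfigError(f"sequence {sequence} requires {sorted(missing_p)}")
    scan = {}
    for key in _SCHEMA["SCAN"] - {"sequence"}:
        if key in sc:
            scan[key] = float(sc[key]) if key not in ("n_prep", "n_se") else int(sc[key])
    if sequence == "bssfp":
        scan.setdefault("te", scan["tr"] / 2.0)
        scan.setdefault("phase_cycle", 180.0)
        scan.setdefault("n_prep", 0)

    t = cp["TISSUE"]
    for key in ("t1", "t2_rest", "d"):
        if key not in t:
            raise ConfigError(f"{path}: [TISSUE] requires {key}")
    t1 = _floats(t["t1"])
    t2_rest = _floats(t["t2_rest"])
    t2_active = _floats(t["t2_active"]) if "t2_active" in t else t2_rest.copy()
    d = _floats(t["d"])
    n = len(t1)
    for name, arr in (("t2_rest", t2_rest), ("t2_active", t2_active), ("d", d)):
        if len(arr) != n:
            raise ConfigError(f"{name} must list {n} substrates like t1")
    if "perm" in t:
        pv = _floats(t["perm"])
        if len(pv) != n * n:
            raise ConfigError(f"perm must have {n * n} entries (row-major {n}x{n})")
        perm = pv.reshape(n, n)
        if np.any(perm < 0) or np.any(perm > 1):
            raise ConfigError("permeability entries must lie in [0, 1]")
    else:
        perm = np.ones((n, n))
    y_rest = float(t.get("y_rest", "0.78"))
    y_active = float(t.get("y_active", "0.85"))
    for y in (y_rest, y_active):
        if not 0 <= y <= 1:
            raise ConfigError("oxygenation fractions must lie in [0, 1]")

    fsec = cp["FILES"]
    for key in ("phantom", "output"):
        if key not in fsec:
            raise ConfigError(f"{path}: [FILES] requires {key}")
    phantom_paths = [p.strip() for p in fsec["phantom"].split(",") if p.strip()]
    for p in phantom_paths:
        if not Path(p).is_file():
            raise ConfigError(f"phantom file not found: {p}")

    sim = cp["SIMULATION"] if "SIMULATION" in cp else {}
    record_trajectory = str(sim.get("record_trajectory", "false")).lower() in (
        "1", "true", "yes",
    )
    record_every = int(sim.get("record_every", 10))
    if record_every <= 0:
        raise ConfigError("record_every must be positive")

    return SimConfig(
        b0=b0,
        n_spins=n_spins,
        dt=dt,
        seed=seed,
        boundary=boundary,
        fov_scales=fov_scales,
        sequence=sequence,
        scan=scan,
        t1=t1,
        t2_rest=t2_rest,
        t2_active=t2_active,
        d=d,
        perm=perm,
        y_rest=y_rest,
        y_active=y_active,
        phantom_paths=phantom_paths,
        output_path=fsec["output"],
        record_trajectory=record_trajectory,
        record_every=record_every,
        source_text=text,
    )


def build_timeline(cfg: SimConfig):
    """Construct the Timeline requested by a SimConfig."""
    from . import sequence as seq

    s = cfg.scan
    if cfg.sequence == "gre":
        return seq.build_gre(s["te"], cfg.dt)
    if cfg.sequence == "se":
        return seq.build_se(s["te"], cfg.dt)
    if cfg.sequence == "bssfp":
        return seq.build_bssfp(
            s["te"], s["tr"], s["flip"] * DEG, s["phase_cycle"] * DEG,
            int(s["n_prep"]), cfg.dt,
        )
    if cfg.sequence == "grase":
        return seq.build_grase(int(s["n_se"]), s["echo_spacing"], cfg.dt)
    if cfg.sequence == "ste":
        return seq.build_ste(s["tau"], s["tm"], cfg.dt)
    raise ConfigError(f"unknown sequence {cfg.sequence!r}")


def state_pair(cfg: SimConfig, y_generated: float = 0.0):
    """Rest/active SubstrateSets and oxygenation scaling from a SimConfig."""
    from .analysis import StatePair
    from .walk import SubstrateSet

    return StatePair(
        substrates_rest=SubstrateSet(cfg.t1, cfg.t2_rest, cfg.d, cfg.perm),
        substrates_active=SubstrateSet(cfg.t1, cfg.t2_active, cfg.d, cfg.perm),
        y_rest=cfg.y_rest,
        y_active=cfg.y_active,
        y_generated=y_generated,
    )
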