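"""Scenario orchestration: germ disc formation, germ band formation,
and the perturbation variants.

A scenario couples the continuous dynamics (polarity consensus ->
adhesion refresh -> force step -> optional gene network -> preferred
area growth) with periodic discrete event sweeps (T1 / T2 / division)
and scripted differentiation, and records per-frame morphometrics into
a :class:`Trajectory`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from . import core, events, mechanics, mesh, metrics, polarity
from . import reaction_diffusion as rd
from .core import EMBRYONIC, ABEMBRYONIC, EXTRAEMBRYONIC, CELL_TYPE_CODES


def load_defaults():
    """Packaged reference parameter file (both phase tables)."""
    with resources.files("sphervert.data").joinpath(
            "defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    phase: str = "germ_disc"
    seed: int = 0
    radius: float = 270.0
    spring_k: float = 30.0
    boundary_beta0: float = 40.0
    n_initial: int = 64
    target_count: int = 1500
    initial_area0: float = 6400.0
    perim0: float = 0.0
    t_end: float = 1.0
    dt: float = 1e-3
    event_interval: int = 10
    frame_interval: int = 50
    relaxation_iters: int = 50
    thresholds: events.EventThresholds = field(
        default_factory=events.EventThresholds)
    cycle_mean: float = 0.2
    #: cycle spread, read as a standard deviation by default; set
    #: spread_is_variance to read it as a variance instead
    cycle_spread: float = 0.05
    spread_is_variance: bool = False
    first_division_window: float = 0.25
    differentiation_time: float = 0.5
    abembryonic_count: int = 100
    extraembryonic_count: int = 150
    disc_area_fraction: float = 0.295
    dorsal_tilt_deg: float = 25.0
    extraembryonic_placement: str = "dorsal_rim"
    polarity_init: str = "rim_apdv"
    adhesion_orientation: str = "unsigned"
    modulate_boundary_adhesion: bool = True
    #: energy-term variants; the defaults are the printed model forms
    adhesion_model: str = "tension"
    contraction_model: str = "perimeter"
    area_model: str = "absolute"
    type_params: dict = field(default_factory=dict)
    with_rd: bool = False
    rd_params: rd.RDParams = field(default_factory=rd.RDParams)
    store_frames: bool = False

    @property
    def cycle_sd(self):
        v = self.cycle_spread
        return math.sqrt(v) if self.spread_is_variance else v

    def schedule(self):
        return events.DivisionSchedule(
            cycle_mean=self.cycle_mean, cycle_sd=self.cycle_sd,
            first_division_window=self.first_division_window,
            target_count=self.target_count)

    @classmethod
    def _common(cls, d, phase_key, seed):
        ph = d[phase_key]
        tp = {}
        for name, pars in ph["cell_types"].items():
            tp[CELL_TYPE_CODES[name]] = dict(
                alpha=pars["alpha"], beta0=pars["beta0"],
                gamma=pars["gamma"], k_fd=pars["k_fd"], G=pars["G"],
                divides=pars["divides"],
                growth=pars["growth_um2_per_time"])
        ev = d["events"]
        return cls(
            phase=phase_key, seed=seed, radius=d["radius_um"],
            spring_k=d["vertex_spring_constant"],
            boundary_beta0=d["boundary_beta0_um"],
            n_initial=ph["initial_cells"], target_count=ph["target_cells"],
            initial_area0=ph["initial_area0_um2"],
            perim0=ph["preferred_perimeter_um"], t_end=ph["t_end"],
            dt=ph.get("dt", 1e-3),
            thresholds=events.EventThresholds(
                ev["t1_min_edge_um"], ev["t1_new_edge_um"],
                ev["t2_min_area_um2"]),
            cycle_mean=ph["cycle_mean"],
            cycle_spread=ph["cycle_sd"],
            first_division_window=ph["first_division_window"],
            differentiation_time=ph.get("differentiation_time", 0.5),
            abembryonic_count=ph.get("abembryonic_count", 100),
            extraembryonic_count=ph.get("extraembryonic_count", 150),
            disc_area_fraction=ph.get("disc_area_fraction", 0.295),
            dorsal_tilt_deg=ph.get("dorsal_tilt_deg", 25.0),
            type_params=tp)

    @classmethod
    def germ_disc_defaults(cls, seed=0, **over):
        cfg = cls._common(load_defaults(), "germ_disc", seed)
        for k, v in over.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def germ_band_defaults(cls, seed=0, **over):
        cfg = cls._common(load_defaults(), "germ_band", seed)
        for k, v in over.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class Trajectory:
    frames: list
    final_state: core.EmbryoState
    config: ScenarioConfig
    event_counts: dict
    states: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame([asdict(f) for f in self.frames])


def _apply_type_params(state, cfg, cells=None, type_code=None):
    """Write the per-type parameter table into the per-cell columns."""
    if cells is None:
        cells = state.alive_cells
    for t, pars in cfg.type_params.items():
        if type_code is not None and t != type_code:
            continue
        sel = cells[state.cell_type[cells] == t]
        state.alpha[sel] = pars["alpha"]
        state.beta0[sel] = pars["beta0"]
        state.gamma[sel] = pars["gamma"]
        state.pol_kfd[sel] = pars["k_fd"]
        state.pol_G[sel] = pars["G"]
        state.divides[sel] = pars["divides"]
    return state


def _growth_rates(cfg):
    ab = cfg.type_params.get(ABEMBRYONIC, {}).get("growth", 0.0)
    ex = cfg.type_params.get(EXTRAEMBRYONIC, {}).get("growth", 0.0)
    return ab, ex


def differentiate_abembryonic(state, cfg):
    """Scripted disc-phase differentiation: the ``abembryonic_count``
    cells forming a connected cap around the +x pole become abembryonic
    (non-proliferative, weakly contractile); heterotypic boundary edges
    automatically acquire the high boundary adhesion."""
    cap = mesh.place_polar_cap(state, (1.0, 0.0, 0.0),
                               cfg.abembryonic_count)
    cap = np.asarray(cap)
    state.cell_type[cap] = ABEMBRYONIC
    _apply_type_params(state, cfg, type_code=ABEMBRYONIC)
    state.next_division[cap] = np.inf
    state.invalidate_topology()
    state.log_event("differentiation", cap)
    return state


def run_phase(state, cfg: ScenarioConfig):
    """Main loop shared by both scenarios."""
    state.adhesion_model = cfg.adhesion_model
    state.contraction_model = cfg.contraction_model
    state.area_model = cfg.area_model
    sched = cfg.schedule()
    if sched.target_count < state.n_cells:
        raise ConfigError("target_count below current cell count")
    icfg = mechanics.IntegratorConfig(cfg.dt, cfg.t_end,
                                      cfg.event_interval)
    events.initialize_division_times(state, sched)
    rate_ab, rate_ex = _growth_rates(cfg)
    polarity_on = any(p["k_fd"] > 0 or p["G"] > 0
                      for p in cfg.type_params.values())
    frames = [metrics.morphometrics(state)]
    states = [state.copy()] if cfg.store_frames else []
    counts = {"t1": 0, "t2": 0, "division": 0}
    differentiated = state.phase != "germ_disc"
    n_steps = int(round((cfg.t_end - state.time) / cfg.dt))
    for k in range(n_steps):
        if (not differentiated
                and state.time >= cfg.differentiation_time - 0.5 * cfg.dt):
            differentiate_abembryonic(state, cfg)
            differentiated = True
        if polarity_on:
            polarity.polarity_update(state)
            polarity.refresh_adhesion(
                state, orientation=cfg.adhesion_orientation,
                modulate_boundary=cfg.modulate_boundary_adhesion)
        mechanics.euler_step(state, icfg)
        if cfg.with_rd:
            rd.rd_step(state, cfg.rd_params, cfg.dt)
        events.grow_preferred_area(state, cfg.dt, rate_ab, rate_ex)
        if (k + 1) % cfg.event_interval == 0:
            c = events.sweep_events(state, cfg.thresholds, sched)
            for key in counts:
                counts[key] += c[key]
        if (k + 1) % cfg.frame_interval == 0 or k == n_steps - 1:
            frames.append(metrics.morphometrics(state))
            if cfg.store_frames:
                states.append(state.copy())
    return Trajectory(frames, state, cfg, counts, states)


def run_germ_disc(cfg: ScenarioConfig | None = None, **over):
    """Germ disc formation: 64-cell blastoderm to a 1,500-cell embryo
    with a smooth-bounded disc of embryonic cells and a cap of 100
    abembryonic cells differentiated at mid-time."""
    if cfg is None:
        cfg = ScenarioConfig.germ_disc_defaults(**over)
    if cfg.phase != "germ_disc":
        raise ConfigError("phase must be germ_disc")
    emb = cfg.type_params[EMBRYONIC]
    state = mesh.build_initial_blastoderm(
        mesh.InitMeshConfig(cfg.n_initial, cfg.radius,
                            cfg.relaxation_iters, cfg.seed),
        cell_type=EMBRYONIC, alpha=emb["alpha"], gamma=emb["gamma"],
        beta0=emb["beta0"], area0=cfg.initial_area0, perim0=cfg.perim0,
        divides=emb["divides"])
    state.phase = "germ_disc"
    state.boundary_beta0 = cfg.boundary_beta0
    state.rng = np.random.default_rng(cfg.seed)
    return run_phase(state, cfg)


def build_germ_band_initial(cfg: ScenarioConfig):
    """Fresh 1,500-cell germ-band initial state.

    ``dorsal_rim`` placement: the embryonic disc is a dense cap whose
    axis is tilted from the posterior pole (+x) towards ventral, so the
    sparse extraembryonic field lies closest to the dorsal side of the
    disc rim.  ``central`` placement: the extraembryonic population sits
    in a cap around the posterior pole at uniform density (the
    knockdown-mimicking condition that develops a barrel shape).
    """
    n_ext = cfg.extraembryonic_count
    n_emb = cfg.n_initial - n_ext
    emb = cfg.type_params[EMBRYONIC]
    cell_kw = dict(cell_type=EMBRYONIC, alpha=emb["alpha"],
                   gamma=emb["gamma"], beta0=emb["beta0"],
                   area0=cfg.initial_area0, perim0=cfg.perim0,
                   divides=emb["divides"])
    if cfg.extraembryonic_placement == "dorsal_rim":
        chi = math.radians(cfg.dorsal_tilt_deg)
        axis = np.array([math.cos(chi), 0.0, -math.sin(chi)])
        cap_angle = math.acos(1.0 - 2.0 * cfg.disc_area_fraction)
        state, inside = mesh.build_cap_tessellation(
            n_emb, n_ext, cfg.radius, axis, cap_angle, cfg.seed,
            relaxation_iters=30, **cell_kw)
        ext_ids = np.array(sorted(set(range(cfg.n_initial)) - set(inside)))
    elif cfg.extraembryonic_placement == "central":
        cap_angle = math.acos(1.0 - 2.0 * n_ext / cfg.n_initial)
        state, inside = mesh.build_cap_tessellation(
            n_ext, n_emb, cfg.radius, np.array([1.0, 0.0, 0.0]),
            cap_angle, cfg.seed, relaxation_iters=30, **cell_kw)
        ext_ids = np.array(sorted(inside))
    else:
        raise ConfigError(
            f"unknown placement {cfg.extraembryonic_placement!r}")
    state.phase = "germ_band"
    state.boundary_beta0 = cfg.boundary_beta0
    state.rng = np.random.default_rng(cfg.seed)
    state.cell_type[ext_ids] = EXTRAEMBRYONIC
    _apply_type_params(state, cfg)
    state.invalidate_topology()
    polarity.init_rim_polarity(state, cfg.polarity_init)
    if cfg.with_rd:
        rd.assign_rim_source(state)
    return state


def run_germ_band(cfg: ScenarioConfig | None = None, initial_state=None,
                  **over):
    """Germ band formation: 1,500-cell disc/extraembryonic state to a
    6,000-cell embryo; polarity-coupled anisotropic adhesion drives the
    disc-to-band elongation."""
    if cfg is None:
        cfg = ScenarioConfig.germ_band_defaults(**over)
    if cfg.phase != "germ_band":
        raise ConfigError("phase must be germ_band")
    state = initial_state if initial_state is not None else \
        build_germ_band_initial(cfg)
    return run_phase(state, cfg)


PERTURBATIONS = ("kfd_zero", "G_zero", "ap_only_polarity",
                 "central_extraembryonic", "beta_scale", "gamma_scale",
                 "G_scale")


def apply_perturbation(cfg: ScenarioConfig, variant, scale=None):
    """Return a copy of a germ-band config with exactly one named change
    applied (the published perturbation panel)."""
    new = copy.deepcopy(cfg)
    if variant == "kfd_zero":
        new.type_params[EMBRYONIC]["k_fd"] = 0.0
    elif variant == "G_zero":
        new.type_params[EMBRYONIC]["G"] = 0.0
    elif variant == "ap_only_polarity":
        new.polarity_init = "rim_ap_only"
    elif variant == "central_extraembryonic":
        new.extraembryonic_placement = "central"
    elif variant == "beta_scale":
        new.type_params[EMBRYONIC]["beta0"] *= _check_scale(scale)
    elif variant == "gamma_scale":
        new.type_params[EMBRYONIC]["gamma"] *= _check_scale(scale)
    elif variant == "G_scale":
        new.type_params[EMBRYONIC]["G"] *= _check_scale(scale)
    else:
        raise ConfigError(f"unknown perturbation variant {variant!r}")
    return new


def _check_scale(s):
    if s is None:
        raise ConfigError("this variant needs a scale factor")
    return float(s)
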