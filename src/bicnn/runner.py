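"""Closed-loop scenario orchestration, trial logging and repeats.

One control tick (10 ms): read sensors -> encode mossy fibers -> build the
directional climbing-fiber pair -> advance both hemispheres -> combine into
the vestibular-nucleus motor command -> apply plasticity -> step the plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import dynamics as dyn
from .control import DEFAULT_GAINS, PdGains, pd_control, vn_combine
from .microcircuit import AerNetwork, build_hemisphere
from .plant import (
    PlantParams,
    PlantState,
    Perturbation,
    SensorNoise,
    make_perturbation,
    plant_step,
    read_sensors,
    reference_trajectory,
)

__all__ = [
    "SCENARIOS",
    "ExperimentConfig",
    "TrialLog",
    "run_scenario",
    "run_repeats",
]

#: scenario name -> (perturbation kind or None, cf_spont_left, cf_spont_right)
SCENARIOS: dict[str, tuple[str | None, float, float]] = {
    "baseline": (None, 0.05, 0.05),
    "load_center": ("load_center", 0.05, 0.05),
    "load_front": ("load_front", 0.05, 0.05),
    "load_back": ("load_back", 0.05, 0.05),
    "incline": ("incline", 0.05, 0.05),
    "decline": ("decline", 0.05, 0.05),
    "cf_no_spont": ("load_center", 0.0, 0.0),
    "cf_one_sided": (None, 0.05, 0.0),
    "cf_asymmetric": (None, 0.08, 0.01),
}

CONTROLLERS = ("pd_only", "uni_cnn", "bicnn")

#: built networks memoized by seed; they are treated as immutable after build
_NET_CACHE: dict[int, AerNetwork] = {}


def _hemisphere_net(seed: int) -> AerNetwork:
    net = _NET_CACHE.get(seed)
    if net is None:
        net, _, _ = build_hemisphere(seed)
        if len(_NET_CACHE) > 8:
            _NET_CACHE.clear()
        _NET_CACHE[seed] = net
    return net


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment bit-for-bit."""

    scenario: str = "baseline"
    n_cycles: int = 100
    freq: float = 0.25  # Hz
    amplitude: float = math.pi  # rad
    dt: float = 0.010  # s
    perturbation_onset_cycle: int = 50
    perturbation_kind: str | None = None  # None -> scenario default
    cf_spont_left: float | None = None  # None -> scenario default
    cf_spont_right: float | None = None
    controller: str = "bicnn"
    seed_builder: int = 1
    seed_noise: int = 0
    n_repeats: int = 6
    #: mirror-symmetric hemispheres (same wiring seed, identical mossy
    #: layout): the untrained hemispheres cancel exactly and the
    #: bi-hemispheric output grows purely out of directional cf plasticity.
    mirror_hemispheres: bool = True
    gr_input_gain: float | None = None  # None -> dynamics default
    rate_tau: float | None = None  # s; None -> dynamics default
    plant: PlantParams = field(default_factory=PlantParams)
    gains: PdGains = DEFAULT_GAINS
    plasticity: dyn.PlasticityParams = field(default_factory=dyn.PlasticityParams)
    cf: dyn.CfParams = field(default_factory=dyn.CfParams)
    mossy_scales: dyn.MossyScales = field(default_factory=dyn.MossyScales)
    sensor_noise: SensorNoise | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.controller not in CONTROLLERS:
            raise ValueError(f"unknown controller {self.controller!r}")
        if not 0 <= self.perturbation_onset_cycle < self.n_cycles:
            raise ValueError("perturbation onset must precede n_cycles")

    def resolved(self) -> tuple[Perturbation | None, float, float]:
        """Perturbation and per-hemisphere cf_spont after scenario defaults."""
        kind_default, sl, sr = SCENARIOS[self.scenario]
        kind = self.perturbation_kind if self.perturbation_kind is not None else kind_default
        pert = make_perturbation(kind) if kind not in (None, "none") else None
        left = self.cf_spont_left if self.cf_spont_left is not None else sl
        right = self.cf_spont_right if self.cf_spont_right is not None else sr
        return pert, left, right


@dataclass
class TrialLog:
    """Per-step record of one closed-loop run (truncated at a fall)."""

    t: np.ndarray
    phi_ref: np.ndarray
    phi_dot_ref: np.ndarray
    phi: np.ndarray
    phi_dot: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    pd_out: np.ndarray
    bicnn_out: np.ndarray
    vn_out: np.ndarray
    cf_left: np.ndarray
    cf_right: np.ndarray
    pk_left: np.ndarray  # mean Purkinje rate, left hemisphere
    pk_right: np.ndarray
    w_pf_pk_mean_left: np.ndarray  # per-cycle weight summaries
    w_pf_pk_mean_right: np.ndarray
    fallen_step: int | None
    n_cycles: int
    steps_per_cycle: int
    freq: float
    dt: float
    repeat: int = 0

    @property
    def completed_cycles(self) -> int:
        return len(self.t) // self.steps_per_cycle


_LOG_FIELDS = (
    "t", "phi_ref", "phi_dot_ref", "phi", "phi_dot", "theta", "theta_dot",
    "pd_out", "bicnn_out", "vn_out", "cf_left", "cf_right",
    "pk_left", "pk_right",
)


def run_scenario(cfg: ExperimentConfig, repeat: int = 0) -> TrialLog:
    """Execute one closed-loop experiment; deterministic given the config."""
    pert, spont_left, spont_right = cfg.resolved()
    spc = int(round(1.0 / (cfg.freq * cfg.dt)))
    n_steps = cfg.n_cycles * spc

    use_net = cfg.controller != "pd_only"
    bi = cfg.controller == "bicnn"
    if use_net:
        net_l = _hemisphere_net(cfg.seed_builder)
        left = dyn.HemisphereStepper(net_l, cfg.gr_input_gain, cfg.rate_tau)
        st_l = left.create_state("left")
        n_mf = left.mf_hi - left.mf_lo
        if bi:
            if cfg.mirror_hemispheres:
                right = left
            else:
                net_r = _hemisphere_net(cfg.seed_builder + 10_000)
                right = dyn.HemisphereStepper(net_r, cfg.gr_input_gain, cfg.rate_tau)
            st_r = right.create_state("right")
        plast_l = replace(cfg.plasticity, cf_spont=spont_left)
        plast_r = replace(cfg.plasticity, cf_spont=spont_right)
        cf_params = replace(
            cfg.cf, cf_spont_left=spont_left, cf_spont_right=spont_right
        )

    rng = np.random.default_rng(cfg.seed_noise)
    state = PlantState()
    buf = {name: np.zeros(n_steps) for name in _LOG_FIELDS}
    w_mean_l = np.zeros(cfg.n_cycles)
    w_mean_r = np.zeros(cfg.n_cycles)
    fallen_step: int | None = None
    prev_vn = 0.0

    for i in range(n_steps):
        t = i * cfg.dt
        cycle = i // spc
        phi_ref, phi_dot_ref, _, _ = reference_trajectory(t, cfg.freq, cfg.amplitude)
        th, thd, ph, phd = read_sensors(state, cfg.sensor_noise, rng)
        theta_e, theta_dot_e = -th, -thd
        phi_e, phi_dot_e = phi_ref - ph, phi_dot_ref - phd

        pd_out = pd_control(theta_e, theta_dot_e, phi_e, phi_dot_e, cfg.gains)

        bicnn_out = 0.0
        cf = None
        if use_net:
            # both hemispheres share the same 7 signals, round-robin over
            # each hemisphere's glomeruli (562 channels model-wide)
            mf_hemi = dyn.encode_mossy(
                dyn.MossySignals(phi_ref, phi_dot_ref, theta_e, theta_dot_e,
                                 phi_e, phi_dot_e, prev_vn),
                cfg.mossy_scales,
                n_channels=n_mf,
            )
            # sensory error: desired minus actual motion
            cf = dyn.compute_cf(phi_e, phi_dot_e, cf_params,
                                absolute=cfg.controller == "uni_cnn")
            left.step(st_l, mf_hemi)
            if bi:
                right.step(st_r, mf_hemi)
                bicnn_out = dyn.bicnn_output(
                    left.pk_rates(st_l), right.pk_rates(st_r),
                    st_l.w_pk_vn, st_r.w_pk_vn,
                )
            else:
                bicnn_out = dyn.unicnn_output(left.pk_rates(st_l), st_l.w_pk_vn)

        cmd = vn_combine(pd_out, bicnn_out)

        if use_net:
            st_l.w_pf_pk = dyn.update_pf_pk(
                st_l.w_pf_pk, left.pf_rates(st_l), cf.cf_left, plast_l)
            st_l.w_pk_vn = dyn.update_pk_vn(
                st_l.w_pk_vn, left.pk_rates(st_l), cmd.vn_out, plast_l)
            if bi:
                st_r.w_pf_pk = dyn.update_pf_pk(
                    st_r.w_pf_pk, right.pf_rates(st_r), cf.cf_right, plast_r)
                st_r.w_pk_vn = dyn.update_pk_vn(
                    st_r.w_pk_vn, right.pk_rates(st_r), cmd.vn_out, plast_r)

        buf["t"][i] = t
        buf["phi_ref"][i], buf["phi_dot_ref"][i] = phi_ref, phi_dot_ref
        buf["phi"][i], buf["phi_dot"][i] = state.phi, state.phi_dot
        buf["theta"][i], buf["theta_dot"][i] = state.theta, state.theta_dot
        buf["pd_out"][i], buf["bicnn_out"][i] = cmd.pd_out, cmd.bicnn_out
        buf["vn_out"][i] = cmd.vn_out
        if cf is not None:
            buf["cf_left"][i], buf["cf_right"][i] = cf.cf_left, cf.cf_right
        if use_net:
            buf["pk_left"][i] = float(left.pk_rates(st_l).mean())
            if bi:
                buf["pk_right"][i] = float(right.pk_rates(st_r).mean())
        if use_net and (i + 1) % spc == 0:
            w_mean_l[cycle] = float(st_l.w_pf_pk.mean())
            w_mean_r[cycle] = float(st_r.w_pf_pk.mean()) if bi else 0.0

        active = pert if (pert is not None and cycle >= cfg.perturbation_onset_cycle) else None
        plant_step(state, cmd.vn_out, cfg.plant, active, dt=cfg.dt)
        prev_vn = cmd.vn_out
        if state.fallen:
            fallen_step = i + 1
            break

    n_kept = fallen_step if fallen_step is not None else n_steps
    return TrialLog(
        **{name: buf[name][:n_kept] for name in _LOG_FIELDS},
        w_pf_pk_mean_left=w_mean_l,
        w_pf_pk_mean_right=w_mean_r,
        fallen_step=fallen_step,
        n_cycles=cfg.n_cycles,
        steps_per_cycle=spc,
        freq=cfg.freq,
        dt=cfg.dt,
        repeat=repeat,
    )


def run_repeats(cfg: ExperimentConfig) -> list[TrialLog]:
    """N repetitions with distinct builder seeds and a shared plant."""
    logs = []
    for r in range(cfg.n_repeats):
        cfg_r = replace(cfg, seed_builder=cfg.seed_builder + 137 * r,
                        seed_noise=cfg.seed_noise + r)
        logs.append(run_scenario(cfg_r, repeat=r))
    return logs
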