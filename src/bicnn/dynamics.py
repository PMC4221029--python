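"""Per-tick rate dynamics of a hemisphere and its two plasticity rules.

Neurons are memoryless saturated-affine rate units centered at 0.5: a
neuron's new rate is ``clip(0.5 + sum_k w_k (r_k - 0.5), 0, 1)`` over its
presynaptic slice.  Granule, Golgi and basket/stellate cells update
synchronously from the previous tick; Purkinje cells are produced last
within the tick from the fresh granule (parallel-fiber) and basket rates,
through the plastic pf-Pk weight table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from .microcircuit import AerNetwork, decode_aer

__all__ = [
    "MOSSY_SIGNALS",
    "N_MOSSY_CHANNELS",
    "MossySignals",
    "MossyScales",
    "encode_mossy",
    "CfParams",
    "CfPair",
    "compute_cf",
    "PlasticityParams",
    "HemisphereState",
    "HemisphereStepper",
    "create_state",
    "step_hemisphere",
    "step_hemisphere_naive",
    "bicnn_output",
    "unicnn_output",
    "update_pf_pk",
    "update_pk_vn",
]

# ---------------------------------------------------------------------------
# mossy-fiber encoding

MOSSY_SIGNALS = (
    "phi_ref",
    "phi_dot_ref",
    "theta_e",
    "theta_dot_e",
    "phi_e",
    "phi_dot_e",
    "efference",
)

#: total mossy channels across both hemispheres (281 glomeruli each)
N_MOSSY_CHANNELS = 562


@dataclass(frozen=True)
class MossySignals:
    """The seven control signals carried by the mossy fibers."""

    phi_ref: float = 0.0
    phi_dot_ref: float = 0.0
    theta_e: float = 0.0
    theta_dot_e: float = 0.0
    phi_e: float = 0.0
    phi_dot_e: float = 0.0
    efference: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MOSSY_SIGNALS])


@dataclass(frozen=True)
class MossyScales:
    """Full-scale value per signal; x maps to rate 0.5 + 0.5 x / fullscale."""

    phi_ref: float = math.pi
    phi_dot_ref: float = 5.0
    theta_e: float = math.pi / 6
    theta_dot_e: float = 5.0
    phi_e: float = math.pi
    phi_dot_e: float = 10.0
    efference: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MOSSY_SIGNALS])


def encode_mossy(
    signals: MossySignals,
    scales: MossyScales | None = None,
    n_channels: int = N_MOSSY_CHANNELS,
) -> np.ndarray:
    """Affine-encode the seven signals into ``n_channels`` rates in [0, 1].

    Channel ``k`` carries signal ``k mod 7`` (round-robin replication,
    truncated at ``n_channels``).
    """
    if scales is None:
        scales = MossyScales()
    fs = scales.as_array()
    if np.any(fs <= 0):
        raise ValueError("full-scale values must be positive")
    base = np.clip(0.5 + 0.5 * signals.as_array() / fs, 0.0, 1.0)
    reps = -(-n_channels // len(base))  # ceil
    return np.tile(base, reps)[:n_channels]


# ---------------------------------------------------------------------------
# climbing fiber

@dataclass(frozen=True)
class CfParams:
    """Directional climbing-fiber construction parameters."""

    cf_spont_left: float = 0.05
    cf_spont_right: float = 0.05
    error_gain: float = 0.1 / math.pi  # 1/rad
    w_p: float = 1.0
    w_v: float = 0.4  # seconds, velocity-error weight


@dataclass(frozen=True)
class CfPair:
    """Instantaneous directional climbing-fiber rates and their baselines."""

    cf_left: float
    cf_right: float
    cf_spont_left: float = 0.05
    cf_spont_right: float = 0.05


def compute_cf(
    error_pos: float,
    error_vel: float,
    params: CfParams | None = None,
    absolute: bool = False,
) -> CfPair:
    """Split the signed kinematic error into two directional cf channels.

    ``raw = error_gain * (w_p * error_pos + w_v * error_vel)`` is added to the
    left channel's spontaneous rate and subtracted from the right one's, each
    clipped to [0, 1]: the left channel prefers errors of forward motion, the
    right backward, and each dips below its spontaneous rate for
    contradirectional error.  With ``absolute=True`` (single-hemisphere
    ablation) both channels carry the full-wave error ``|raw|``.
    """
    if params is None:
        params = CfParams()
    raw = params.error_gain * (params.w_p * error_pos + params.w_v * error_vel)
    if absolute:
        raw_l, raw_r = abs(raw), abs(raw)
    else:
        raw_l, raw_r = raw, -raw
    return CfPair(
        cf_left=min(max(params.cf_spont_left + raw_l, 0.0), 1.0),
        cf_right=min(max(params.cf_spont_right + raw_r, 0.0), 1.0),
        cf_spont_left=params.cf_spont_left,
        cf_spont_right=params.cf_spont_right,
    )


# ---------------------------------------------------------------------------
# plasticity

@dataclass(frozen=True)
class PlasticityParams:
    """Learning rates and thresholds for the two plastic synapse classes."""

    gamma_ltd: float = -4e-6
    gamma_ltp: float = 0.3e-6
    gamma_pkvn: float = 1e-4
    cf_spont: float = 0.05  # LTD/LTP switching threshold
    w_max: float = 2.0 / 1024  # pf-Pk clip bound; 2x the max initial weight
    w_pkvn_max: float = 2.0 / 15

    def __post_init__(self) -> None:
        if not (self.gamma_ltd < 0 < self.gamma_ltp):
            raise ValueError("need gamma_ltd < 0 < gamma_ltp")


def update_pf_pk(
    w_pf_pk: np.ndarray,
    pf_rates: np.ndarray,
    cf: float,
    params: PlasticityParams,
) -> np.ndarray:
    """One LTD/LTP step on the pf-Pk weight table.

    Per synapse: ``dW = gamma_ltd * cf * pf`` when the climbing fiber fires
    above its spontaneous rate, ``dW = gamma_ltp * pf`` below it, and no
    change at exactly the spontaneous rate.  Result clipped to [0, w_max].
    ``pf_rates`` must be broadcastable to ``w_pf_pk`` (one pf rate per
    synapse).
    """
    if cf > params.cf_spont:
        dw = params.gamma_ltd * cf * pf_rates
    elif cf < params.cf_spont:
        dw = params.gamma_ltp * pf_rates
    else:
        return w_pf_pk
    return np.clip(w_pf_pk + dw, 0.0, params.w_max)


def update_pk_vn(
    w_pk_vn: np.ndarray,
    pk_rates: np.ndarray,
    vn: float,
    params: PlasticityParams,
) -> np.ndarray:
    """One step on the Pk-Vn weights: ``dW_j = gamma * vn * (Pk_j - 0.5)``.

    Same signs of vn and the centered Pk rate potentiate, opposite signs
    depress; clipped to [0, w_pkvn_max].
    """
    dw = params.gamma_pkvn * vn * (pk_rates - 0.5)
    return np.clip(w_pk_vn + dw, 0.0, params.w_pkvn_max)


# ---------------------------------------------------------------------------
# hemisphere stepping

@dataclass
class HemisphereState:
    """Firing rates and plastic weights of one hemisphere."""

    rates: np.ndarray  # per-neuron rate in [0, 1], indexed by neuron id
    w_pf_pk: np.ndarray  # (n_pk, pf_convergence) plastic weights
    w_pk_vn: np.ndarray  # (n_pk,) plastic Pk->Vn weights
    side: str = "left"

    def copy(self) -> "HemisphereState":
        return replace(
            self,
            rates=self.rates.copy(),
            w_pf_pk=self.w_pf_pk.copy(),
            w_pk_vn=self.w_pk_vn.copy(),
        )


#: Input sensitivity of granule cells to their mossy-fiber synapses.  The
#: 1/in-degree weight normalization plus the Golgi feedback loop attenuates
#: mossy deviations by ~12x at the granule layer; the companion neuron model
#: is not published, so the relay slope is a free transfer-function
#: parameter chosen to restore command-scale hemisphere outputs.
DEFAULT_GR_INPUT_GAIN = 1.0

#: Rate-unit membrane/synaptic time constant (s).  Each non-mf unit relaxes
#: toward its saturated-affine drive with this first-order lag, low-passing
#: the circuit's response; 0 recovers the memoryless unit.  The value is a
#: neuron-model stand-in (the reference neuron model is unpublished) chosen
#: so the circuit is transparent at the 0.25 Hz task but inert to the
#: multi-Hz body-wobble band.
DEFAULT_RATE_TAU = 0.1

#: Control tick (s); the rate-unit lag is discretized at this step.
TICK_DT = 0.01


class HemisphereStepper:
    """Vectorized one-tick updater compiled from an :class:`AerNetwork`.

    Splits the network into a static sparse matrix (every class except the
    plastic gr->Pk synapses and the ba->Pk synapses that feed the
    last-updated Purkinje stage) plus gather indices for the Purkinje stage.
    ``gr_input_gain`` scales the granule cells' sensitivity to their
    mossy-fiber inputs (a neuron-model slope; stored weights are untouched).
    """

    def __init__(
        self,
        net: AerNetwork,
        gr_input_gain: float | None = None,
        rate_tau: float | None = None,
    ):
        self.net = net
        self.gr_input_gain = (
            DEFAULT_GR_INPUT_GAIN if gr_input_gain is None else gr_input_gain
        )
        tau = DEFAULT_RATE_TAU if rate_tau is None else rate_tau
        #: per-tick relaxation factor toward the affine drive
        self.alpha = 1.0 if tau <= 0 else 1.0 - math.exp(-TICK_DT / tau)
        ranges = net.population_ranges
        for lb in ("mf", "gr", "ba", "Pk"):
            if lb not in ranges:
                raise ValueError(f"network lacks population range for {lb!r}")
        self.n = net.n_neurons
        self.mf_lo, self.mf_hi = ranges["mf"]
        self.gr_lo, self.gr_hi = ranges["gr"]
        self.ba_lo, self.ba_hi = ranges["ba"]
        self.pk_lo, self.pk_hi = ranges["Pk"]
        self.n_pk = self.pk_hi - self.pk_lo

        pre, post, w = decode_aer(net)
        is_pk_post = (post >= self.pk_lo) & (post < self.pk_hi)
        is_gr_pre = (pre >= self.gr_lo) & (pre < self.gr_hi)

        stat = ~is_pk_post
        w_eff = w.copy()
        mf_gr = (
            (pre >= self.mf_lo) & (pre < self.mf_hi)
            & (post >= self.gr_lo) & (post < self.gr_hi)
        )
        w_eff[mf_gr] *= self.gr_input_gain
        self.matrix = sparse.csr_matrix(
            (w_eff[stat], (post[stat], pre[stat])), shape=(self.n, self.n)
        )

        # Purkinje stage: gr (plastic) and ba (static) presynapse tables
        pf_mask = is_pk_post & is_gr_pre
        ba_mask = is_pk_post & ~is_gr_pre
        self.pf_idx = self._stack(pre[pf_mask], post[pf_mask])
        self.init_w_pf_pk = self._stack_w(w[pf_mask], post[pf_mask], self.pf_idx.shape)
        self.ba_idx = self._stack(pre[ba_mask], post[ba_mask])
        self.ba_w = self._stack_w(w[ba_mask], post[ba_mask], self.ba_idx.shape)

    def _stack(self, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
        """(n_pk, k) presynaptic-id matrix; requires equal per-Pk counts."""
        counts = np.bincount(post - self.pk_lo, minlength=self.n_pk)
        if len(np.unique(counts)) != 1:
            raise ValueError("unequal Purkinje in-degrees within a class")
        k = int(counts[0])
        order = np.lexsort((pre, post))
        return pre[order].reshape(self.n_pk, k)

    def _stack_w(
        self, w: np.ndarray, post: np.ndarray, shape: tuple[int, int]
    ) -> np.ndarray:
        order = np.lexsort((np.arange(len(w)), post))
        return w[order].reshape(shape)

    def create_state(self, side: str = "left") -> HemisphereState:
        return HemisphereState(
            rates=np.full(self.n, 0.5),
            w_pf_pk=self.init_w_pf_pk.copy(),
            w_pk_vn=np.full(self.n_pk, 1.0 / self.n_pk),
            side=side,
        )

    def step(self, state: HemisphereState, mf_rates: np.ndarray) -> HemisphereState:
        """Advance one 10 ms tick in place; returns the same state object."""
        r = state.rates
        if len(mf_rates) != self.mf_hi - self.mf_lo:
            raise ValueError(
                f"expected {self.mf_hi - self.mf_lo} mf rates, got {len(mf_rates)}"
            )
        r[self.mf_lo : self.mf_hi] = mf_rates
        a = self.alpha
        drive = self.matrix.dot(r - 0.5)
        new = r + a * (np.clip(0.5 + drive, 0.0, 1.0) - r)
        new[self.mf_lo : self.mf_hi] = np.clip(mf_rates, 0.0, 1.0)
        # Purkinje last, from fresh pf (= gr) and ba rates
        pf_c = new[self.pf_idx] - 0.5
        ba_c = new[self.ba_idx] - 0.5
        pk_drive = (state.w_pf_pk * pf_c).sum(axis=1) + (self.ba_w * ba_c).sum(axis=1)
        pk_old = r[self.pk_lo : self.pk_hi]
        new[self.pk_lo : self.pk_hi] = pk_old + a * (
            np.clip(0.5 + pk_drive, 0.0, 1.0) - pk_old
        )
        state.rates = new
        return state

    def pf_rates(self, state: HemisphereState) -> np.ndarray:
        """Current parallel-fiber rate per pf-Pk synapse, shaped like w_pf_pk."""
        return state.rates[self.pf_idx]

    def pk_rates(self, state: HemisphereState) -> np.ndarray:
        return state.rates[self.pk_lo : self.pk_hi]


_STEPPER_CACHE: dict[int, HemisphereStepper] = {}


def _stepper_for(net: AerNetwork) -> HemisphereStepper:
    stepper = _STEPPER_CACHE.get(id(net))
    if stepper is None or stepper.net is not net:
        stepper = HemisphereStepper(net)
        _STEPPER_CACHE.clear()
        _STEPPER_CACHE[id(net)] = stepper
    return stepper


def create_state(net: AerNetwork, side: str = "left") -> HemisphereState:
    return _stepper_for(net).create_state(side)


def step_hemisphere(
    net: AerNetwork, state: HemisphereState, mf_rates: np.ndarray
) -> HemisphereState:
    """Functional wrapper around :meth:`HemisphereStepper.step`."""
    return _stepper_for(net).step(state, mf_rates)


def step_hemisphere_naive(
    net: AerNetwork,
    state: HemisphereState,
    mf_rates: np.ndarray,
    gr_input_gain: float | None = None,
    rate_tau: float | None = None,
) -> HemisphereState:
    """Reference per-synapse loop implementing the identical update.

    Independent of the sparse-matrix path; used as an oracle on toy nets.
    """
    if gr_input_gain is None:
        gr_input_gain = DEFAULT_GR_INPUT_GAIN
    tau = DEFAULT_RATE_TAU if rate_tau is None else rate_tau
    alpha = 1.0 if tau <= 0 else 1.0 - math.exp(-TICK_DT / tau)
    ranges = net.population_ranges
    mf_lo, mf_hi = ranges["mf"]
    gr_lo, gr_hi = ranges["gr"]
    pk_lo, pk_hi = ranges["Pk"]
    old = state.rates.copy()
    old[mf_lo:mf_hi] = np.clip(mf_rates, 0.0, 1.0)
    new = old.copy()
    offsets = net.offsets
    # stage 1: every non-mf, non-Pk neuron from previous-tick rates
    for i, nid in enumerate(net.ID):
        if mf_lo <= nid < mf_hi or pk_lo <= nid < pk_hi:
            continue
        acc = 0.0
        for p, w in zip(
            net.P[offsets[i] : offsets[i + 1]], net.W[offsets[i] : offsets[i + 1]]
        ):
            if gr_lo <= nid < gr_hi and mf_lo <= p < mf_hi:
                w = w * gr_input_gain
            acc += w * (old[p] - 0.5)
        target = min(max(0.5 + acc, 0.0), 1.0)
        new[nid] = old[nid] + alpha * (target - old[nid])
    # stage 2: Purkinje from fresh rates; gr presynapses use plastic weights
    for i, nid in enumerate(net.ID):
        if not pk_lo <= nid < pk_hi:
            continue
        j = nid - pk_lo
        acc = 0.0
        k_pf = 0
        for p, w in zip(
            net.P[offsets[i] : offsets[i + 1]], net.W[offsets[i] : offsets[i + 1]]
        ):
            if gr_lo <= p < gr_hi:
                acc += state.w_pf_pk[j, k_pf] * (new[p] - 0.5)
                k_pf += 1
            else:
                acc += w * (new[p] - 0.5)
        target = min(max(0.5 + acc, 0.0), 1.0)
        new[nid] = old[nid] + alpha * (target - old[nid])
    state.rates = new
    return state


# ---------------------------------------------------------------------------
# vestibular-nucleus combination of the two hemispheres

def bicnn_output(
    left_pk: np.ndarray,
    right_pk: np.ndarray,
    w_pk_vn_left: np.ndarray,
    w_pk_vn_right: np.ndarray,
) -> float:
    """Bi-hemispheric output: right minus inverted-left, clipped to [-1, 1].

    With the uniform default weights 1/n_pk this is mean(right) - mean(left).
    """
    out = float(np.dot(w_pk_vn_right, right_pk) - np.dot(w_pk_vn_left, left_pk))
    return min(max(out, -1.0), 1.0)


def unicnn_output(pk: np.ndarray, w_pk_vn: np.ndarray) -> float:
    """Single-hemisphere ablation output, centered so untrained rest is 0."""
    out = 2.0 * float(np.dot(w_pk_vn, pk) - 0.5 * np.sum(w_pk_vn))
    return min(max(out, -1.0), 1.0)
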