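"""Single-step dynamics of the predictive-plasticity recurrent network.

The network is a pool of Poisson spiking neurons. Presynaptic spikes are
low-pass filtered into traces with an exponential kernel
``eps(s) = exp(-s/tau)``; the membrane potential is a weighted sum of
afferent and recurrent traces; the instantaneous rate is a sigmoidal
function of the potential whose gain and threshold are rescaled by a slow
homeostatic variable ``h`` tracking the running maximum of the potential.
Spikes are drawn per time step by Bernoulli thinning of the rate.

Three wiring variants are supported:

``nDL``
    a single population with signed recurrent matrix ``M`` plus an
    inhibitory-only matrix ``G`` (no Dale's law),
``signed``
    a single population where every ordered neuron pair is permanently
    excitatory (``M_exc``) or inhibitory (``M_inh`` or ``G``),
``DL``
    distinct excitatory and inhibitory pools; inhibitory neurons project
    through two separately trained paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "ModelKind",
    "NetworkWeights",
    "NetworkState",
    "decay_and_jump_trace",
    "static_sigmoid",
    "dynamic_sigmoid",
    "update_h",
    "sample_spikes",
    "membrane_potential",
    "step_network",
    "init_weights",
    "init_state",
]


@dataclass(frozen=True)
class NeuronParams:
    """Fixed constants of the neuron model and the learning rules.

    Attributes
    ----------
    dt : float
        Euler integration step in ms.
    tau : float
        Membrane/synaptic-trace time constant in ms.
    tau_h : float
        Decay time constant of the homeostatic variable ``h`` in ms;
        ``h`` tracks the maximum membrane potential over roughly this
        window.
    phi0 : float
        Maximum instantaneous firing rate in Hz.
    g : float
        Dimensionless scale entering both sigmoids' gain (``g*beta0``)
        and the *static* sigmoid's threshold (``g*theta0``).  The static
        prediction decoder therefore half-activates at ``g*theta0`` = 3,
        so an under-predicted burst at a neuron's potential maximum
        yields a large positive error — the pressure that recruits every
        neuron into an assembly.  The somatic rate function keeps its
        threshold at ``theta0*h`` (half-activation exactly at the
        running potential maximum tracked by ``h``) and its steep gain
        makes the baseline rate at ``u = 0`` negligible, so background
        epochs exert no uniform weight-inflation pressure.
    beta0 : float
        Base gain of the sigmoids.
    theta0 : float
        Base threshold of the sigmoids.
    eta : float
        Learning rate shared by all plasticity rules.
    h_floor : float
        Lower clamp for ``h`` guaranteeing a finite gain.
    """

    dt: float = 1.0
    tau: float = 15.0
    tau_h: float = 10_000.0
    phi0: float = 50.0
    g: float = 3.0
    beta0: float = 5.0
    theta0: float = 1.0
    eta: float = 1e-4
    h_floor: float = 1e-2

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau <= 0 or self.tau_h <= 0:
            raise ValueError("dt, tau and tau_h must be positive")
        if self.tau_h <= self.tau:
            raise ValueError("tau_h must exceed tau")
        if self.phi0 <= 0 or self.eta <= 0 or self.h_floor <= 0:
            raise ValueError("phi0, eta and h_floor must be positive")
        if self.phi0 * self.dt / 1000.0 > 1.0:
            raise ValueError("phi0*dt must correspond to a spike probability <= 1")

    @property
    def trace_decay(self) -> float:
        return float(np.exp(-self.dt / self.tau))

    @property
    def h_decay(self) -> float:
        return float(np.exp(-self.dt / self.tau_h))

    @property
    def midpoint(self) -> float:
        """Prediction potential at which the static sigmoid reaches
        ``phi0/2``."""
        return self.g * self.theta0


class ModelKind(str, Enum):
    NDL = "nDL"
    SIGNED = "signed"
    DL = "DL"


@dataclass
class NetworkWeights:
    """Synaptic matrices of one network variant.

    Only the fields of the active :class:`ModelKind` are populated.  For
    the ``DL`` variant the excitatory and inhibitory pools are stored
    stacked (rows ``0..n_exc`` are E neurons, the rest I neurons), so
    ``W`` is (N, K), ``M_EE``-like blocks live inside ``M_XE`` (N, N_E)
    and the two inhibitory paths in ``G_path1``/``G_path2`` (N, N_I).
    """

    kind: ModelKind
    W: np.ndarray
    # nDL
    M: Optional[np.ndarray] = None
    G: Optional[np.ndarray] = None
    # signed variant
    M_exc: Optional[np.ndarray] = None
    M_inh: Optional[np.ndarray] = None
    mask_exc: Optional[np.ndarray] = None
    mask_inh: Optional[np.ndarray] = None
    mask_G: Optional[np.ndarray] = None
    # DL variant
    M_XE: Optional[np.ndarray] = None
    G_path1: Optional[np.ndarray] = None
    G_path2: Optional[np.ndarray] = None
    n_exc: Optional[int] = None
    # optional afferent wiring constraint (e.g. block-structured input
    # routing in the two-subnetwork conditioning protocol); W entries
    # outside the mask stay zero under plasticity
    W_mask: Optional[np.ndarray] = None

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def K(self) -> int:
        return self.W.shape[1]

    @property
    def n_inh(self) -> Optional[int]:
        if self.n_exc is None:
            return None
        return self.N - self.n_exc

    def matrices(self) -> dict[str, np.ndarray]:
        """Name -> array mapping of the populated matrices."""
        names = {
            ModelKind.NDL: ("W", "M", "G"),
            ModelKind.SIGNED: ("W", "M_exc", "M_inh", "G"),
            ModelKind.DL: ("W", "M_XE", "G_path1", "G_path2"),
        }[self.kind]
        return {n: getattr(self, n) for n in names}

    def copy(self) -> "NetworkWeights":
        kw = {}
        for f_ in self.__dataclass_fields__:
            v = getattr(self, f_)
            kw[f_] = v.copy() if isinstance(v, np.ndarray) else v
        return NetworkWeights(**kw)

    def check_consistency(self) -> None:
        N, K = self.N, self.K
        for name, m in self.matrices().items():
            if name == "W":
                continue
            if m.shape[0] != N:
                raise ValueError(f"{name} has {m.shape[0]} rows, expected {N}")
        if self.kind == ModelKind.NDL:
            if self.G.min() < 0:
                raise ValueError("G must be non-negative")
        elif self.kind == ModelKind.SIGNED:
            for name in ("M_exc", "M_inh", "G"):
                if getattr(self, name).min() < 0:
                    raise ValueError(f"{name} must be non-negative")
        elif self.kind == ModelKind.DL:
            if self.n_exc is None:
                raise ValueError("DL weights need n_exc")
            for name in ("M_XE", "G_path1", "G_path2"):
                if getattr(self, name).min() < 0:
                    raise ValueError(f"{name} must be non-negative")


@dataclass
class NetworkState:
    """Per-neuron dynamical variables at one time step."""

    x: np.ndarray  # afferent presynaptic traces (K,)
    y: np.ndarray  # recurrent presynaptic traces (N,)
    u: np.ndarray  # membrane potentials (N,)
    h: np.ndarray  # homeostatic history variables (N,)
    f: np.ndarray  # instantaneous rates, Hz (N,)
    spikes: np.ndarray  # binary spike indicators of the current step (N,)
    t: float = 0.0  # current time, ms

    def copy(self) -> "NetworkState":
        return NetworkState(
            x=self.x.copy(), y=self.y.copy(), u=self.u.copy(), h=self.h.copy(),
            f=self.f.copy(), spikes=self.spikes.copy(), t=self.t,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def decay_and_jump_trace(trace, spiked, dt: float, tau: float):
    """One Euler step of a presynaptic trace.

    The trace is the spike train convolved with ``eps(s) = exp(-s/tau)``;
    a spike arriving at the current step contributes ``eps(0) = 1``
    immediately.  Works element-wise on arrays.
    """
    if dt <= 0 or tau <= 0:
        raise ValueError("dt and tau must be positive")
    return np.asarray(trace) * np.exp(-dt / tau) + np.asarray(spiked, dtype=float)


def static_sigmoid(v, p: NeuronParams):
    """Rate decoded from a prediction potential (Hz).

    ``phi(v) = phi0 / (1 + exp(g*beta0*(-v + g*theta0)))``: gain
    ``g*beta0`` (15 with defaults) and half-activation at ``g*theta0``
    (3 with defaults).  This is the reference nonlinearity inside every
    plasticity error term; its fixed point ``phi(v) = f`` places trained
    prediction potentials on the ``g*theta0`` scale.
    """
    z = p.g * p.beta0 * (p.g * p.theta0 - np.asarray(v, dtype=float))
    # clip keeps exp finite; phi saturates far before the clip matters
    return p.phi0 / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


def dynamic_sigmoid(u, h, p: NeuronParams):
    """Somatic firing rate given potential ``u`` and homeostatic ``h`` (Hz).

    Gain ``g*beta0/h`` and threshold ``theta0*h``:

    ``phi_hat(u; h) = phi0 / (1 + exp(g*(beta0/h)*(-u + theta0*h)))``,

    equivalently a fixed sigmoid applied to the normalized potential
    ``u/h``.  The neuron fires at ``phi0/2`` when its potential reaches
    ``theta0`` times the running maximum tracked by ``h`` and saturates
    on upward excursions past it; the baseline at ``u = 0`` is
    ``phi0/(1+e^(g*beta0*theta0))`` (~1.5e-5 Hz), low enough that
    background-free epochs are silent and prediction weights feel no
    uniform baseline-matching pressure.
    """
    h_ = np.maximum(np.asarray(h, dtype=float), p.h_floor)
    z = p.g * p.beta0 * (p.theta0 - np.asarray(u, dtype=float) / h_)
    return p.phi0 / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


def update_h(h, u, p: NeuronParams):
    """One step of the homeostatic variable.

    While ``h`` exceeds the current potential it decays with ``tau_h``;
    otherwise it jumps to the potential.  ``h`` therefore tracks the
    maximum of ``u`` over roughly the last ``tau_h`` ms.  A lower clamp
    at ``h_floor`` keeps the sigmoid gain finite.
    """
    h = np.asarray(h, dtype=float)
    u = np.asarray(u, dtype=float)
    decayed = np.maximum(h * p.h_decay, p.h_floor)
    return np.where(h > u, decayed, np.maximum(u, p.h_floor))


def sample_spikes(f, dt: float, rng: np.random.Generator):
    """Bernoulli thinning of instantaneous rates into binary spikes."""
    f = np.asarray(f, dtype=float)
    prob = f * dt / 1000.0
    if prob.size and (prob.max() > 1.0 or prob.min() < 0.0):
        raise ValueError("spike probability outside [0, 1]; check rates and dt")
    return (rng.random(f.shape) < prob).astype(np.uint8)


# ---------------------------------------------------------------------------
# membrane potential and prediction components
# ---------------------------------------------------------------------------

def membrane_potential(
    weights: NetworkWeights, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Potential ``u`` plus the per-connection-class component potentials.

    Returns ``(u, components)`` where ``components`` holds the prediction
    potentials consumed by the plasticity rules: ``v_W`` always, plus
    ``v_M``/``v_G`` (nDL), ``v_M_exc``/``v_M_inh``/``v_G`` (signed) or
    ``v_M2``/``v_M1`` (DL; ``v_M1`` enters ``u`` with a minus sign).
    """
    if x.shape[0] != weights.K or y.shape[0] != weights.N:
        raise ValueError("trace lengths do not match weight shapes")
    v_W = weights.W @ x
    if weights.kind == ModelKind.NDL:
        v_M = weights.M @ y
        v_G = weights.G @ y
        return v_W + v_M - v_G, {"v_W": v_W, "v_M": v_M, "v_G": v_G}
    if weights.kind == ModelKind.SIGNED:
        v_exc = weights.M_exc @ y
        v_inh = weights.M_inh @ y
        v_G = weights.G @ y
        u = v_W + v_exc - v_inh - v_G
        return u, {"v_W": v_W, "v_M_exc": v_exc, "v_M_inh": v_inh, "v_G": v_G}
    if weights.kind == ModelKind.DL:
        y_E = y[: weights.n_exc]
        y_I = y[weights.n_exc :]
        v_M2 = weights.M_XE @ y_E - weights.G_path2 @ y_I
        v_M1 = weights.G_path1 @ y_I
        return v_W + v_M2 - v_M1, {"v_W": v_W, "v_M2": v_M2, "v_M1": v_M1}
    raise ValueError(f"unknown kind {weights.kind}")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _gauss(rng, shape, scale_dim, width):
    sd = 0.1 / np.sqrt(scale_dim) if width == "sd" else np.sqrt(0.1 / np.sqrt(scale_dim))
    return rng.normal(0.0, sd, size=shape)


def init_weights(
    kind: ModelKind | str,
    N: int,
    K: int,
    rng: np.random.Generator,
    n_exc: Optional[int] = None,
    init_width: str = "variance",
) -> NetworkWeights:
    """Draw initial synaptic matrices for a network variant.

    ``W`` and ``M`` start as zero-mean Gaussians with variances
    ``0.1/sqrt(K)`` and ``0.1/sqrt(N)``; inhibitory-only matrices start
    uniformly at ``1/sqrt(N)`` (``1/sqrt(N_I)`` for the DL paths).
    ``init_width='sd'`` reads ``0.1/sqrt(dim)`` as the standard
    deviation instead (a tenfold narrower start), exposed because the
    two readings are both defensible fan-in normalizations.

    For the ``signed`` variant every ordered pair is assigned one matrix
    (50 % ``M_exc``, 25 % ``M_inh``, 25 % ``G``) by a seeded draw; the
    masks stay fixed for the lifetime of the network.
    """
    kind = ModelKind(kind)
    if init_width not in ("sd", "variance"):
        raise ValueError("init_width must be 'sd' or 'variance'")
    W = _gauss(rng, (N, K), K, init_width)
    if kind == ModelKind.NDL:
        M = _gauss(rng, (N, N), N, init_width)
        G = np.full((N, N), 1.0 / np.sqrt(N))
        return NetworkWeights(kind=kind, W=W, M=M, G=G)
    if kind == ModelKind.SIGNED:
        lab = rng.choice(3, size=(N, N), p=[0.5, 0.25, 0.25])
        mask_exc, mask_inh, mask_G = lab == 0, lab == 1, lab == 2
        M_exc = np.where(mask_exc, np.abs(_gauss(rng, (N, N), N, init_width)), 0.0)
        M_inh = np.where(mask_inh, np.abs(_gauss(rng, (N, N), N, init_width)), 0.0)
        G = np.where(mask_G, 1.0 / np.sqrt(N), 0.0)
        return NetworkWeights(
            kind=kind, W=W, M_exc=M_exc, M_inh=M_inh, G=G,
            mask_exc=mask_exc, mask_inh=mask_inh, mask_G=mask_G,
        )
    if kind == ModelKind.DL:
        if n_exc is None:
            n_exc = N // 2
        n_inh = N - n_exc
        M_XE = np.abs(_gauss(rng, (N, n_exc), N, init_width))
        G1 = np.full((N, n_inh), 1.0 / np.sqrt(n_inh))
        G2 = np.full((N, n_inh), 1.0 / np.sqrt(n_inh))
        return NetworkWeights(
            kind=kind, W=W, M_XE=M_XE, G_path1=G1, G_path2=G2, n_exc=n_exc
        )
    raise ValueError(kind)


def init_state(N: int, K: int, p: NeuronParams) -> NetworkState:
    """Fresh state: silent network with ``h = theta0`` so the dynamic
    sigmoid starts identical to the static one."""
    return NetworkState(
        x=np.zeros(K),
        y=np.zeros(N),
        u=np.zeros(N),
        h=np.full(N, p.theta0, dtype=float),
        f=np.zeros(N),
        spikes=np.zeros(N, dtype=np.uint8),
        t=0.0,
    )


# ---------------------------------------------------------------------------
# one Euler step
# ---------------------------------------------------------------------------

def step_network(
    state: NetworkState,
    weights: NetworkWeights,
    input_spikes: Optional[np.ndarray],
    p: NeuronParams,
    rng: np.random.Generator,
    mode: str = "evoked",
    plastic: Optional[set] = None,
    plasticity_config=None,
) -> dict[str, np.ndarray]:
    """Advance the network by one Euler step, in place.

    Order of operations: afferent traces -> membrane potential -> ``h``
    -> rate -> spikes -> recurrent traces, with plasticity applied
    synchronously from the same-step rates, predictions and traces.  In
    ``spontaneous`` mode afferent input is ignored and the ``x`` traces
    simply decay.  Returns the component potentials of the step.
    """
    if mode not in ("evoked", "spontaneous"):
        raise ValueError(f"unknown mode {mode!r}")
    state.x *= p.trace_decay
    if mode == "evoked" and input_spikes is not None:
        state.x += input_spikes
    u, comps = membrane_potential(weights, state.x, state.y)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError(f"non-finite membrane potential at t={state.t} ms")
    state.u = u
    state.h = update_h(state.h, u, p)
    state.f = dynamic_sigmoid(u, state.h, p)
    state.spikes = sample_spikes(state.f, p.dt, rng)
    if plastic:
        from . import plasticity as _pl

        _pl.apply_updates(weights, state, comps, p, plastic)
    state.y *= p.trace_decay
    state.y += state.spikes
    state.t += p.dt
    return comps
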