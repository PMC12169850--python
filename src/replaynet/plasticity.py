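"""Predictive plasticity: error term x presynaptic trace, for every
connection class of every network variant.

Each connection class C contributes a prediction potential ``v_C`` to its
postsynaptic neuron.  Learning drives the statically decoded prediction
``phi(v_C)`` toward the neuron's instantaneous rate ``f`` by descending
the Kullback-Leibler divergence between the two Poisson processes, which
yields the shared update

    dWeight_ij = eta * E(f_i, v_i_C) * trace_j,
    E(f, v) = phi0^-1 * (1 - phi(v)/phi0) * (f - phi(v)).

Inhibitory-only matrices are clamped at zero from below after every
update; in the sign-constrained variants all recurrent matrices are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import ModelKind, NetworkState, NetworkWeights, NeuronParams, static_sigmoid

__all__ = [
    "PlasticityConfig",
    "error_term",
    "update_W",
    "update_M_nDL",
    "update_G_nDL",
    "apply_updates",
    "apply_gating",
]

# matrices whose entries may never become negative, per variant
NONNEGATIVE = {
    ModelKind.NDL: ("G",),
    ModelKind.SIGNED: ("M_exc", "M_inh", "G"),
    ModelKind.DL: ("M_XE", "G_path1", "G_path2"),
}

ALL_MATRICES = {
    ModelKind.NDL: frozenset({"W", "M", "G"}),
    ModelKind.SIGNED: frozenset({"W", "M_exc", "M_inh", "G"}),
    ModelKind.DL: frozenset({"W", "M_XE", "G_path1", "G_path2"}),
}


@dataclass
class PlasticityConfig:
    """Which matrices learn, and when.

    ``gating_schedule`` is a list of ``(t_start_ms, t_end_ms, names)``
    intervals; outside every interval nothing learns.  Intervals must not
    overlap.
    """

    eta: float = 1e-4
    gating_schedule: Sequence[tuple[float, float, frozenset]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted((t0, t1) for t0, t1, _ in self.gating_schedule)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError("gating intervals overlap")


def apply_gating(config: PlasticityConfig, t: float) -> frozenset:
    """The set of matrix names that learn at time ``t`` (ms)."""
    for t0, t1, names in config.gating_schedule:
        if t0 <= t < t1:
            return frozenset(names)
    return frozenset()


def error_term(f, v, p: NeuronParams):
    """Shared prediction-error factor of all update rules.

    ``phi0^-1 (1 - phi(v)/phi0) (f - phi(v))``; vanishes at the fixed
    point ``f = phi(v)`` and is killed by the saturation factor for
    ``v -> +inf``.  Sign equals the sign of ``f - phi(v)``.
    """
    phi = static_sigmoid(v, p)
    return (1.0 - phi / p.phi0) * (np.asarray(f, dtype=float) - phi) / p.phi0


# ---------------------------------------------------------------------------
# per-matrix rules (in-place)
# ---------------------------------------------------------------------------

def update_W(W: np.ndarray, err: np.ndarray, x: np.ndarray, eta: float) -> None:
    """Afferent rule: ``W_ij += eta * err_i * x_j``; stays signed."""
    W += eta * np.multiply.outer(err, x)


def update_M_nDL(M: np.ndarray, err: np.ndarray, y: np.ndarray, eta: float) -> None:
    """Recurrent rule of the nDL variant; signed, no truncation."""
    M += eta * np.multiply.outer(err, y)


def update_G_nDL(G: np.ndarray, err: np.ndarray, y: np.ndarray, eta: float) -> None:
    """Inhibitory balance rule; clamped non-negative after the step."""
    G += eta * np.multiply.outer(err, y)
    np.maximum(G, 0.0, out=G)


# ---------------------------------------------------------------------------
# variant dispatch used by the integrator
# ---------------------------------------------------------------------------

def apply_updates(
    weights: NetworkWeights,
    state: NetworkState,
    comps: dict[str, np.ndarray],
    p: NeuronParams,
    enabled: Iterable[str],
) -> None:
    """Apply one synchronous plasticity step to all enabled matrices.

    ``comps`` are the same-step prediction potentials returned by
    :func:`replaynet.core.membrane_potential`; ``state.f``, ``state.x``
    and ``state.y`` are the same-step rate and presynaptic traces.
    """
    enabled = set(enabled)
    f, x, y, eta = state.f, state.x, state.y, p.eta
    kind = weights.kind
    if "W" in enabled:
        update_W(weights.W, error_term(f, comps["v_W"], p), x, eta)
        if weights.W_mask is not None:
            weights.W *= weights.W_mask
    if kind == ModelKind.NDL:
        if "M" in enabled:
            update_M_nDL(weights.M, error_term(f, comps["v_M"], p), y, eta)
        if "G" in enabled:
            update_G_nDL(weights.G, error_term(f, comps["v_G"], p), y, eta)
    elif kind == ModelKind.SIGNED:
        # M_exc and M_inh share the joint prediction v_exc - v_inh and
        # move in opposite directions; all three recurrent matrices are
        # truncated at zero and confined to their fixed pair masks.
        err_joint = error_term(f, comps["v_M_exc"] - comps["v_M_inh"], p)
        if "M_exc" in enabled:
            weights.M_exc += eta * np.multiply.outer(err_joint, y) * weights.mask_exc
            np.maximum(weights.M_exc, 0.0, out=weights.M_exc)
        if "M_inh" in enabled:
            weights.M_inh -= eta * np.multiply.outer(err_joint, y) * weights.mask_inh
            np.maximum(weights.M_inh, 0.0, out=weights.M_inh)
        if "G" in enabled:
            weights.G += eta * np.multiply.outer(error_term(f, comps["v_G"], p), y) * weights.mask_G
            np.maximum(weights.G, 0.0, out=weights.G)
    elif kind == ModelKind.DL:
        y_E = y[: weights.n_exc]
        y_I = y[weights.n_exc :]
        err2 = error_term(f, comps["v_M2"], p)
        if "M_XE" in enabled:
            weights.M_XE += eta * np.multiply.outer(err2, y_E)
            np.maximum(weights.M_XE, 0.0, out=weights.M_XE)
        if "G_path2" in enabled:
            weights.G_path2 -= eta * np.multiply.outer(err2, y_I)
            np.maximum(weights.G_path2, 0.0, out=weights.G_path2)
        if "G_path1" in enabled:
            err1 = error_term(f, comps["v_M1"], p)
            weights.G_path1 += eta * np.multiply.outer(err1, y_I)
            np.maximum(weights.G_path1, 0.0, out=weights.G_path1)
    else:  # pragma: no cover
        raise ValueError(kind)
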