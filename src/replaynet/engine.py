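"""Vectorized multi-step integrator.

`run_phase` advances a network through one experimental phase (evoked or
spontaneous) with optional plasticity and lightweight recording.  It
performs the same per-step math as :func:`replaynet.core.step_network`
(unit tests assert agreement to floating-point round-off) but fuses the
per-step work into a handful of BLAS calls so minute-scale training runs
stay fast.  The nDL variant additionally stacks ``M`` and ``G`` into one
matrix for single-gemv recurrence and single-ger plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ModelKind, NetworkState, NetworkWeights, NeuronParams
from ._kernels import HAVE_NUMBA, ndl_steps

__all__ = ["PhaseRecording", "run_phase"]


@dataclass
class PhaseRecording:
    """What a phase leaves behind for analysis."""

    n_steps: int
    dt: float
    counts: np.ndarray  # per-neuron spike counts over the phase
    binned: Optional[np.ndarray] = None  # (n_bins, N) spike counts
    bin_ms: Optional[float] = None
    hbar: Optional[np.ndarray] = None  # population-mean h, subsampled
    hbar_every_ms: Optional[float] = None
    pred_err: Optional[dict[str, np.ndarray]] = None  # mean |f - phi(v)| per window
    pred_err_window_ms: Optional[float] = None
    events: Optional[np.ndarray] = None  # (n_spikes, 2): neuron id, time ms

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt / 1000.0

    def rates(self) -> np.ndarray:
        """Mean firing rate per neuron over the phase, Hz."""
        return self.counts / self.duration_s


class _Recorder:
    """Accumulates the optional per-step observables."""

    def __init__(self, N, n_steps, dt, bin_ms, hbar_every_ms, pred_err_window_ms,
                 record_events, err_names, t0):
        self.counts = np.zeros(N)
        self.dt = dt
        self.bin_steps = int(round(bin_ms / dt)) if bin_ms else 0
        self.binned = (
            np.zeros((int(np.ceil(n_steps / self.bin_steps)), N)) if self.bin_steps else None
        )
        self.bin_ms = bin_ms
        self.hbar_every = int(round(hbar_every_ms / dt)) if hbar_every_ms else 0
        self.hbar_every_ms = hbar_every_ms
        self.hbar: list[float] = []
        self.err_window = int(round(pred_err_window_ms / dt)) if pred_err_window_ms else 0
        self.err_window_ms = pred_err_window_ms
        self.err_names = err_names
        self.err_acc = np.zeros(len(err_names))
        self.err_out: list[np.ndarray] = []
        self.record_events = record_events
        self.ev_n: list[np.ndarray] = []
        self.ev_t: list[np.ndarray] = []
        self.t0 = t0

    def per_step(self, step, spk_f, h, err_abs=None, spk_bool=None):
        self.counts += spk_f
        if self.binned is not None:
            self.binned[step // self.bin_steps] += spk_f
        if self.hbar_every and step % self.hbar_every == 0:
            self.hbar.append(float(h.mean()))
        if self.err_window:
            self.err_acc += err_abs
            if (step + 1) % self.err_window == 0:
                self.err_out.append(self.err_acc / self.err_window)
                self.err_acc = np.zeros(len(self.err_names))
        if self.record_events and spk_bool is not None and spk_bool.any():
            ids = np.nonzero(spk_bool)[0]
            self.ev_n.append(ids)
            self.ev_t.append(np.full(ids.shape, self.t0 + (step + 1) * self.dt))

    def finish(self, n_steps) -> PhaseRecording:
        events = None
        if self.record_events:
            if self.ev_n:
                events = np.column_stack(
                    [np.concatenate(self.ev_n), np.concatenate(self.ev_t)]
                )
            else:
                events = np.zeros((0, 2))
        pred_err = None
        if self.err_window and self.err_out:
            arr = np.vstack(self.err_out)
            pred_err = {n: arr[:, i] for i, n in enumerate(self.err_names)}
        elif self.err_window:
            pred_err = {n: np.zeros(0) for n in self.err_names}
        return PhaseRecording(
            n_steps=n_steps, dt=self.dt, counts=self.counts,
            binned=self.binned, bin_ms=self.bin_ms,
            hbar=np.asarray(self.hbar) if self.hbar_every else None,
            hbar_every_ms=self.hbar_every_ms,
            pred_err=pred_err, pred_err_window_ms=self.err_window_ms,
            events=events,
        )


def _expand_spans(input_segments, dt, n_steps, p_scale):
    spans: list[tuple[int, int, Optional[np.ndarray]]] = []
    if input_segments is None:
        spans.append((0, n_steps, None))
        return spans
    for t0, t1, rates in input_segments:
        s0, s1 = int(round(t0 / dt)), int(round(t1 / dt))
        s0, s1 = max(s0, 0), min(s1, n_steps)
        if s1 > s0:
            spans.append((s0, s1, rates * p_scale))
    if not spans or spans[0][0] != 0 or spans[-1][1] != n_steps:
        raise ValueError("input segments must cover the whole phase")
    return spans


def run_phase(
    weights: NetworkWeights,
    state: NetworkState,
    p: NeuronParams,
    rng: np.random.Generator,
    n_steps: int,
    input_segments: Optional[list[tuple[float, float, np.ndarray]]] = None,
    plastic: frozenset = frozenset(),
    bin_ms: Optional[float] = None,
    hbar_every_ms: Optional[float] = None,
    pred_err_window_ms: Optional[float] = None,
    record_events: bool = False,
    h_frozen: bool = False,
) -> PhaseRecording:
    """Advance ``n_steps`` Euler steps in place and return the recording.

    ``input_segments`` is a piecewise-constant rate program in ms
    relative to the phase start; ``None`` runs the phase in spontaneous
    mode (afferent traces decay to zero).  ``plastic`` names the matrices
    updated each step; ``h_frozen`` disables the homeostatic dynamics
    (ablation experiments).
    """
    if weights.kind == ModelKind.NDL:
        return _run_ndl(
            weights, state, p, rng, n_steps, input_segments, plastic,
            bin_ms, hbar_every_ms, pred_err_window_ms, record_events, h_frozen,
        )
    return _run_generic(
        weights, state, p, rng, n_steps, input_segments, plastic,
        bin_ms, hbar_every_ms, pred_err_window_ms, record_events, h_frozen,
    )


def _run_ndl(weights, state, p, rng, n_steps, input_segments, plastic,
             bin_ms, hbar_every_ms, pred_err_window_ms, record_events, h_frozen):
    if HAVE_NUMBA:
        return _run_ndl_compiled(
            weights, state, p, rng, n_steps, input_segments, plastic,
            bin_ms, hbar_every_ms, pred_err_window_ms, record_events, h_frozen,
        )
    return _run_ndl_numpy(
        weights, state, p, rng, n_steps, input_segments, plastic,
        bin_ms, hbar_every_ms, pred_err_window_ms, record_events, h_frozen,
    )


def _run_ndl_compiled(weights, state, p, rng, n_steps, input_segments, plastic,
                      bin_ms, hbar_every_ms, pred_err_window_ms, record_events,
                      h_frozen=False):
    """Numba path; draw-for-draw identical to the numpy loop."""
    N, K = weights.N, weights.K
    dt, phi0 = p.dt, p.phi0
    gb, gt = p.g * p.beta0, p.g * p.theta0
    b0, t0 = p.g * p.beta0, p.theta0
    p_scale = dt / 1000.0

    W = weights.W
    W_mask = weights.W_mask if weights.W_mask is not None else np.zeros((0, 0))
    R = np.vstack([weights.M, weights.G])
    x, y, h = state.x, state.y, state.h
    state_uf = np.vstack([state.u, state.f])

    spans = _expand_spans(input_segments, dt, n_steps, p_scale)

    counts = np.zeros(N)
    bin_steps = int(round(bin_ms / dt)) if bin_ms else 0
    binned = (
        np.zeros((int(np.ceil(n_steps / bin_steps)), N)) if bin_steps else np.zeros((0, N))
    )
    hbar_every = int(round(hbar_every_ms / dt)) if hbar_every_ms else 0
    hbar = np.zeros(n_steps // hbar_every + 2) if hbar_every else np.zeros(0)
    hbar_fill = np.zeros(1, dtype=np.int64)
    err_window = int(round(pred_err_window_ms / dt)) if pred_err_window_ms else 0
    err_acc = np.zeros(3)
    err_out = np.zeros((n_steps // err_window + 2, 3)) if err_window else np.zeros((0, 3))
    err_fill = np.zeros(1, dtype=np.int64)

    ev_n: list[np.ndarray] = []
    ev_t: list[np.ndarray] = []
    last_spikes = np.zeros(N, dtype=np.uint8)
    for s0, s1, prob in spans:
        n_span = s1 - s0
        if prob is not None:
            inp = (rng.random((n_span, K)) < prob).astype(np.uint8)
        else:
            inp = np.zeros((0, K), dtype=np.uint8)
        spikes_out = (
            np.zeros((n_span, N), dtype=np.uint8) if record_events
            else np.zeros((0, N), dtype=np.uint8)
        )
        # one block draw per span; same stream order as per-step draws
        draws = rng.random((n_span, N))
        ndl_steps(
            draws, n_span, W, R, W_mask, x, y, h, state_uf, inp,
            counts, binned, hbar, err_acc, err_out, err_fill, spikes_out,
            last_spikes,
            s0, dt, phi0, gb, gt, b0, t0,
            p.trace_decay, p.h_decay, p.h_floor, p.eta,
            "W" in plastic, "M" in plastic, "G" in plastic, h_frozen,
            bin_steps, hbar_every, hbar_fill, err_window, p_scale,
        )
        if not np.all(np.isfinite(state_uf[0])):
            raise FloatingPointError(f"non-finite potential in span at step {s0}")
        if record_events and spikes_out.any():
            ii, nn = np.nonzero(spikes_out)
            ev_n.append(nn)
            ev_t.append(state.t + (s0 + ii + 1) * dt)

    weights.M[...] = R[:N]
    weights.G[...] = R[N:]
    state.u = state_uf[0]
    state.f = state_uf[1]
    state.spikes = last_spikes
    state.t += n_steps * dt

    events = None
    if record_events:
        if ev_n:
            events = np.column_stack([np.concatenate(ev_n), np.concatenate(ev_t)])
        else:
            events = np.zeros((0, 2))
    pred_err = None
    if err_window:
        out = err_out[: err_fill[0]]
        pred_err = {"v_W": out[:, 0], "v_M": out[:, 1], "v_G": out[:, 2]}
    return PhaseRecording(
        n_steps=n_steps, dt=dt, counts=counts,
        binned=binned if bin_steps else None, bin_ms=bin_ms,
        hbar=hbar[: hbar_fill[0]] if hbar_every else None,
        hbar_every_ms=hbar_every_ms,
        pred_err=pred_err, pred_err_window_ms=pred_err_window_ms,
        events=events,
    )


def _run_ndl_numpy(weights, state, p, rng, n_steps, input_segments, plastic,
                   bin_ms, hbar_every_ms, pred_err_window_ms, record_events, h_frozen):
    N, K = weights.N, weights.K
    dt, phi0 = p.dt, p.phi0
    gb, gt = p.g * p.beta0, p.g * p.theta0  # prediction decoder
    b0, t0 = p.g * p.beta0, p.theta0  # somatic rate function
    dtr, dh, h_floor, eta = p.trace_decay, p.h_decay, p.h_floor, p.eta
    p_scale = dt / 1000.0

    x, y, h = state.x, state.y, state.h
    W = weights.W
    W_mask = weights.W_mask
    R = np.vstack([weights.M, weights.G])  # stacked recurrent matrix
    pl_W = "W" in plastic
    pl_M = "M" in plastic
    pl_G = "G" in plastic
    rec = _Recorder(N, n_steps, dt, bin_ms, hbar_every_ms, pred_err_window_ms,
                    record_events, ("v_W", "v_M", "v_G"), state.t)
    spans = _expand_spans(input_segments, dt, n_steps, p_scale)

    u = state.u
    f = state.f
    spk = np.zeros(N, dtype=bool)
    want_err = rec.err_window > 0
    eMG = np.zeros(2 * N)
    for s0, s1, prob in spans:
        n_span = s1 - s0
        inp = rng.random((n_span, K)) < prob if prob is not None else None
        for i in range(n_span):
            step = s0 + i
            x *= dtr
            if inp is not None:
                x += inp[i]
            v_W = W @ x
            v_MG = R @ y
            u = v_W + v_MG[:N] - v_MG[N:]
            if not h_frozen:
                np.copyto(h, np.where(h > u, np.maximum(h * dh, h_floor),
                                      np.maximum(u, h_floor)))
            # one fused exp: somatic rate on u/h, prediction decoder on v's
            z = np.concatenate(
                [b0 * (t0 - u / np.maximum(h, h_floor)),
                 gb * (gt - v_W), gb * (gt - v_MG)]
            )
            phi_all = phi0 / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))
            f = phi_all[:N]
            spk = rng.random(N) < f * p_scale
            spk_f = spk.astype(float)
            err_abs = None
            if plastic or want_err:
                phiV = phi_all[N:]
                ftile = np.tile(f, 3)
                eV = (1.0 - phiV / phi0) * (ftile - phiV) / phi0
                if want_err:
                    d = np.abs(ftile - phiV)
                    err_abs = np.array([d[:N].mean(), d[N:2*N].mean(), d[2*N:].mean()])
                if pl_W:
                    W += eta * np.multiply.outer(eV[:N], x)
                    if W_mask is not None:
                        W *= W_mask
                if pl_M or pl_G:
                    eMG[:N] = eV[N:2*N] if pl_M else 0.0
                    eMG[N:] = eV[2*N:] if pl_G else 0.0
                    R += eta * np.multiply.outer(eMG, y)
                    if pl_G:
                        np.maximum(R[N:], 0.0, out=R[N:])
            rec.per_step(step, spk_f, h, err_abs, spk if record_events else None)
            y *= dtr
            y += spk_f
            if (step + 1) % 1024 == 0 and not np.all(np.isfinite(u)):
                raise FloatingPointError(f"non-finite potential at step {step}")

    weights.M[...] = R[:N]
    weights.G[...] = R[N:]
    state.u = u
    state.f = f.copy() if f is state.f else f
    state.spikes = spk.astype(np.uint8)
    state.t += n_steps * dt
    return rec.finish(n_steps)


def _run_generic(weights, state, p, rng, n_steps, input_segments, plastic,
                 bin_ms, hbar_every_ms, pred_err_window_ms, record_events, h_frozen):
    """Reference loop for the signed and DL variants."""
    N, K = weights.N, weights.K
    kind = weights.kind
    dt, phi0 = p.dt, p.phi0
    gb, gt = p.g * p.beta0, p.g * p.theta0  # prediction decoder
    b0, t0 = p.g * p.beta0, p.theta0  # somatic rate function
    dtr, dh, h_floor, eta = p.trace_decay, p.h_decay, p.h_floor, p.eta
    p_scale = dt / 1000.0

    def phi(v):
        return phi0 / (1.0 + np.exp(np.clip(gb * (gt - v), -500.0, 500.0)))

    def phi_dyn(z):
        return phi0 / (1.0 + np.exp(np.clip(b0 * (t0 - z), -500.0, 500.0)))

    x, y, h = state.x, state.y, state.h
    W = weights.W
    err_names = ("v_W", "v_M", "v_G") if kind == ModelKind.SIGNED else ("v_W", "v_M2", "v_M1")
    rec = _Recorder(N, n_steps, dt, bin_ms, hbar_every_ms, pred_err_window_ms,
                    record_events, err_names, state.t)
    spans = _expand_spans(input_segments, dt, n_steps, p_scale)

    if kind == ModelKind.SIGNED:
        Me, Mi, G = weights.M_exc, weights.M_inh, weights.G
        mask_e, mask_i, mask_g = weights.mask_exc, weights.mask_inh, weights.mask_G
    else:
        MXE, G1, G2 = weights.M_XE, weights.G_path1, weights.G_path2
        nE = weights.n_exc

    u = state.u
    f = state.f
    spk = np.zeros(N, dtype=bool)
    want_err = rec.err_window > 0
    for s0, s1, prob in spans:
        n_span = s1 - s0
        inp = rng.random((n_span, K)) < prob if prob is not None else None
        for i in range(n_span):
            step = s0 + i
            x *= dtr
            if inp is not None:
                x += inp[i]
            v_W = W @ x
            if kind == ModelKind.SIGNED:
                v_M = Me @ y - Mi @ y
                v_G = G @ y
                u = v_W + v_M - v_G
            else:
                yE, yI = y[:nE], y[nE:]
                v_M2 = MXE @ yE - G2 @ yI
                v_M1 = G1 @ yI
                u = v_W + v_M2 - v_M1
            if not h_frozen:
                np.copyto(h, np.where(h > u, np.maximum(h * dh, h_floor),
                                      np.maximum(u, h_floor)))
            f = phi_dyn(u / np.maximum(h, h_floor))
            spk = rng.random(N) < f * p_scale
            spk_f = spk.astype(float)
            err_abs = None
            if plastic or want_err:
                if kind == ModelKind.SIGNED:
                    phiW, phiM, phiG = phi(v_W), phi(v_M), phi(v_G)
                    if want_err:
                        err_abs = np.array([np.abs(f - phiW).mean(),
                                            np.abs(f - phiM).mean(),
                                            np.abs(f - phiG).mean()])
                    if "W" in plastic:
                        eW = (1 - phiW / phi0) * (f - phiW) / phi0
                        W += eta * np.multiply.outer(eW, x)
                    eJ = (1 - phiM / phi0) * (f - phiM) / phi0
                    outerJ = np.multiply.outer(eJ, y)
                    if "M_exc" in plastic:
                        Me += eta * outerJ * mask_e
                        np.maximum(Me, 0.0, out=Me)
                    if "M_inh" in plastic:
                        Mi -= eta * outerJ * mask_i
                        np.maximum(Mi, 0.0, out=Mi)
                    if "G" in plastic:
                        eG = (1 - phiG / phi0) * (f - phiG) / phi0
                        G += eta * np.multiply.outer(eG, y) * mask_g
                        np.maximum(G, 0.0, out=G)
                else:
                    phiW, phi2, phi1 = phi(v_W), phi(v_M2), phi(v_M1)
                    if want_err:
                        err_abs = np.array([np.abs(f - phiW).mean(),
                                            np.abs(f - phi2).mean(),
                                            np.abs(f - phi1).mean()])
                    if "W" in plastic:
                        eW = (1 - phiW / phi0) * (f - phiW) / phi0
                        W += eta * np.multiply.outer(eW, x)
                    e2 = (1 - phi2 / phi0) * (f - phi2) / phi0
                    if "M_XE" in plastic:
                        MXE += eta * np.multiply.outer(e2, yE)
                        np.maximum(MXE, 0.0, out=MXE)
                    if "G_path2" in plastic:
                        G2 -= eta * np.multiply.outer(e2, yI)
                        np.maximum(G2, 0.0, out=G2)
                    if "G_path1" in plastic:
                        e1 = (1 - phi1 / phi0) * (f - phi1) / phi0
                        G1 += eta * np.multiply.outer(e1, yI)
                        np.maximum(G1, 0.0, out=G1)
            rec.per_step(step, spk_f, h, err_abs, spk if record_events else None)
            y *= dtr
            y += spk_f
            if (step + 1) % 1024 == 0 and not np.all(np.isfinite(u)):
                raise FloatingPointError(f"non-finite potential at step {step}")

    state.u = u
    state.f = np.asarray(f, dtype=float)
    state.spikes = spk.astype(np.uint8)
    state.t += n_steps * dt
    return rec.finish(n_steps)
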