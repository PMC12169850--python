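"""Numba-compiled inner loop for the nDL integrator.

The kernel consumes the same random stream in the same order as the
numpy span loop of the integrator (input block first, then one uniform
per neuron per step) and uses the same BLAS matrix-vector products, so
the two paths produce identical spike trains (asserted in the test
suite) and weights agreeing to floating-point round-off.  Falls back
transparently if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def ndl_steps(
    draws,  # (n_span, N) uniform randoms for spike thinning
    n_span,
    W,
    R,
    W_mask,
    x,
    y,
    h,
    state_uf,  # (2, N): row 0 = u, row 1 = f (written back)
    inp,  # (n_span, K) uint8; empty first dim -> no input
    counts,
    binned,
    hbar,
    err_acc,  # (3,)
    err_out,  # (max_windows, 3)
    err_fill,  # (1,) int64: windows already written
    spikes_out,
    last_spikes,  # (N,) uint8: spikes of the final step
    step0,
    dt,
    phi0,
    gb,
    gt,
    b0,
    t0,
    dtr,
    dh,
    h_floor,
    eta,
    pl_W,
    pl_M,
    pl_G,
    h_frozen,
    bin_steps,
    hbar_every,
    hbar_fill,  # (1,) int64
    err_window,
    p_scale,
):
    N = y.shape[0]
    K = x.shape[0]
    has_inp = inp.shape[0] > 0
    has_mask = W_mask.shape[0] > 0
    want_err = err_window > 0
    plastic = pl_W or pl_M or pl_G
    u = state_uf[0]
    f = state_uf[1]
    for i in range(n_span):
        step = step0 + i
        # afferent traces
        for k in range(K):
            x[k] *= dtr
        if has_inp:
            for k in range(K):
                x[k] += inp[i, k]
        # potentials via BLAS (same accumulation order as the numpy path)
        v_W = np.dot(W, x)
        v_MG = np.dot(R, y)
        v_M = v_MG[:N]
        v_G = v_MG[N:]
        for n in range(N):
            u[n] = v_W[n] + v_M[n] - v_G[n]
            # homeostatic envelope
            if not h_frozen:
                if h[n] > u[n]:
                    hd = h[n] * dh
                    h[n] = hd if hd > h_floor else h_floor
                else:
                    h[n] = u[n] if u[n] > h_floor else h_floor
            # somatic rate
            z = b0 * (t0 - u[n] / (h[n] if h[n] > h_floor else h_floor))
            if z > 500.0:
                z = 500.0
            elif z < -500.0:
                z = -500.0
            f[n] = phi0 / (1.0 + np.exp(z))
        if plastic or want_err:
            e0 = 0.0
            e1 = 0.0
            e2 = 0.0
            for n in range(N):
                zW = gb * (gt - v_W[n])
                zM = gb * (gt - v_M[n])
                zG = gb * (gt - v_G[n])
                if zW > 500.0:
                    zW = 500.0
                if zM > 500.0:
                    zM = 500.0
                if zG > 500.0:
                    zG = 500.0
                if zW < -500.0:
                    zW = -500.0
                if zM < -500.0:
                    zM = -500.0
                if zG < -500.0:
                    zG = -500.0
                phiW = phi0 / (1.0 + np.exp(zW))
                phiM = phi0 / (1.0 + np.exp(zM))
                phiG = phi0 / (1.0 + np.exp(zG))
                if want_err:
                    e0 += abs(f[n] - phiW)
                    e1 += abs(f[n] - phiM)
                    e2 += abs(f[n] - phiG)
                if pl_W:
                    eW = (1.0 - phiW / phi0) * (f[n] - phiW) / phi0 * eta
                    if has_mask:
                        for k in range(K):
                            W[n, k] = (W[n, k] + eW * x[k]) * W_mask[n, k]
                    else:
                        for k in range(K):
                            W[n, k] += eW * x[k]
                if pl_M:
                    eM = (1.0 - phiM / phi0) * (f[n] - phiM) / phi0 * eta
                    for m in range(N):
                        R[n, m] += eM * y[m]
                if pl_G:
                    eG = (1.0 - phiG / phi0) * (f[n] - phiG) / phi0 * eta
                    for m in range(N):
                        val = R[N + n, m] + eG * y[m]
                        R[N + n, m] = val if val > 0.0 else 0.0
            if want_err:
                err_acc[0] += e0 / N
                err_acc[1] += e1 / N
                err_acc[2] += e2 / N
                if (step + 1) % err_window == 0:
                    w_idx = err_fill[0]
                    err_out[w_idx, 0] = err_acc[0] / err_window
                    err_out[w_idx, 1] = err_acc[1] / err_window
                    err_out[w_idx, 2] = err_acc[2] / err_window
                    err_fill[0] = w_idx + 1
                    err_acc[0] = 0.0
                    err_acc[1] = 0.0
                    err_acc[2] = 0.0
        # spikes, recording, recurrent traces
        if hbar_every > 0 and step % hbar_every == 0:
            hs = 0.0
            for n in range(N):
                hs += h[n]
            hbar[hbar_fill[0]] = hs / N
            hbar_fill[0] += 1
        bin_idx = step // bin_steps if bin_steps > 0 else 0
        for n in range(N):
            spk = 1.0 if draws[i, n] < f[n] * p_scale else 0.0
            counts[n] += spk
            if bin_steps > 0:
                binned[bin_idx, n] += spk
            if spikes_out.shape[0] > 0:
                spikes_out[i, n] = np.uint8(spk)
            if i == n_span - 1:
                last_spikes[n] = np.uint8(spk)
            y[n] = y[n] * dtr + spk
    return 0
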