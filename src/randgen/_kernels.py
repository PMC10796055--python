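"""Compiled chain kernels behind the sequence samplers.

One unified kernel advances ``C`` tempered chains (C = 1 gives the plain,
untempered algorithm) with either random-walk or Hamiltonian proposals and
optional partial momentum refreshment.  Keeping a single kernel makes the
reduction identities (coupled sampler with one chain = base sampler;
recycling coefficient 0 = full momentum refresh) hold exactly, draw for
draw, under a shared random stream.

Family codes match :mod:`randgen.domains`: 0 Gaussian(a=mean, b=sd),
1 scaled Beta(a, b) on [lo, hi], 2 flat on [lo, hi], 3 flat on the hex
hull.  Log densities here are unnormalized (constants cancel in every
acceptance ratio).
"""

import math

import numpy as np
from numba import njit

_SQ3_2 = math.sqrt(3.0) / 2.0
# Outward unit normals of the hex-hull edges (offsets all equal the apothem).
_HEX_N = np.array(
    [
        [math.cos(math.radians(30 + 60 * k)), math.sin(math.radians(30 + 60 * k))]
        for k in range(6)
    ]
)
_HEX_OFF = _SQ3_2

NEG_INF = -math.inf


@njit(cache=True)
def logp_u(fam, a, b, lo, hi, x):
    """Unnormalized log target density at position x (length-d array)."""
    if fam == 0:
        return -0.5 * ((x[0] - a) / b) ** 2
    if fam == 1:
        z = (x[0] - lo) / (hi - lo)
        if z <= 0.0 or z >= 1.0:
            return NEG_INF
        return (a - 1.0) * math.log(z) + (b - 1.0) * math.log(1.0 - z)
    if fam == 2:
        if x[0] < lo or x[0] > hi:
            return NEG_INF
        return 0.0
    for k in range(6):
        if _HEX_N[k, 0] * x[0] + _HEX_N[k, 1] * x[1] > _HEX_OFF + 1e-12:
            return NEG_INF
    return 0.0


@njit(cache=True)
def grad_logp_u(fam, a, b, lo, hi, x, out):
    if fam == 0:
        out[0] = (a - x[0]) / (b * b)
    elif fam == 1:
        z = (x[0] - lo) / (hi - lo)
        out[0] = ((a - 1.0) / z - (b - 1.0) / (1.0 - z)) / (hi - lo)
    else:
        for i in range(out.shape[0]):
            out[i] = 0.0


@njit(cache=True)
def reflect(fam, lo, hi, x, p):
    """Reflect a position back into the support, negating the momentum
    component normal to each crossed boundary.  In-place."""
    if fam == 3:
        for _ in range(200):
            worst = -1
            wv = 1e-12
            for k in range(6):
                v = _HEX_N[k, 0] * x[0] + _HEX_N[k, 1] * x[1] - _HEX_OFF
                if v > wv:
                    wv = v
                    worst = k
            if worst < 0:
                break
            nx = _HEX_N[worst, 0]
            ny = _HEX_N[worst, 1]
            x[0] -= 2.0 * wv * nx
            x[1] -= 2.0 * wv * ny
            pd = p[0] * nx + p[1] * ny
            p[0] -= 2.0 * pd * nx
            p[1] -= 2.0 * pd * ny
    elif fam != 0:  # Gaussian support is unbounded
        for _ in range(200):
            if x[0] < lo:
                x[0] = 2.0 * lo - x[0]
                p[0] = -p[0]
            elif x[0] > hi:
                x[0] = 2.0 * hi - x[0]
                p[0] = -p[0]
            else:
                break


@njit(cache=True)
def leapfrog(fam, a, b, lo, hi, x, p, eps, n_leap, inv_temp):
    """Leapfrog integration of the tempered Hamiltonian, in-place.

    Each step: half-step momentum, full-step position (with boundary
    reflection), half-step momentum.  Unit mass.
    """
    d = x.shape[0]
    g = np.empty(d)
    grad_logp_u(fam, a, b, lo, hi, x, g)
    for _ in range(n_leap):
        for i in range(d):
            p[i] += 0.5 * eps * inv_temp * g[i]
        for i in range(d):
            x[i] += eps * p[i]
        reflect(fam, lo, hi, x, p)
        grad_logp_u(fam, a, b, lo, hi, x, g)
        for i in range(d):
            p[i] += 0.5 * eps * inv_temp * g[i]


@njit(cache=True)
def run_chain(rng, fam, a, b, lo, hi, d, use_grad, sigma, eps, n_leap,
              alpha, n_chains, delta, swap_prob, burn, n_emit, flip_on_reject):
    """Advance the (possibly coupled) chain and emit the cold chain's states.

    Chain c targets p(x)^(1/T_c) with T_c = (1 + delta)^c; only chain 0
    (T = 1) is observed.  Returns an (n_emit, d) array of raw, pre-rounding
    positions, one per post-burn-in iteration (rejections repeat the
    previous position).
    """
    out = np.empty((n_emit, d))
    X = np.empty((n_chains, d))
    P = np.zeros((n_chains, d))
    inv_t = np.empty(n_chains)
    for c in range(n_chains):
        inv_t[c] = (1.0 + delta) ** (-c)

    # Initial positions: a target draw for the Gaussian, uniform over the
    # support otherwise (the burn-in absorbs the difference).
    for c in range(n_chains):
        if fam == 0:
            X[c, 0] = a + b * rng.standard_normal()
        elif fam == 3:
            while True:
                xx = -1.0 + 2.0 * rng.random()
                yy = -_SQ3_2 + 2.0 * _SQ3_2 * rng.random()
                ok = True
                for k in range(6):
                    if _HEX_N[k, 0] * xx + _HEX_N[k, 1] * yy > _HEX_OFF:
                        ok = False
                        break
                if ok:
                    X[c, 0] = xx
                    X[c, 1] = yy
                    break
        else:
            X[c, 0] = lo + (hi - lo) * rng.random()

    sq = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    xprop = np.empty(d)
    pprop = np.empty(d)

    for t in range(burn + n_emit):
        for c in range(n_chains):
            if use_grad:
                # partial momentum refresh (alpha = 0: full refresh)
                for i in range(d):
                    P[c, i] = alpha * P[c, i] + sq * rng.standard_normal()
                for i in range(d):
                    xprop[i] = X[c, i]
                    pprop[i] = P[c, i]
                h0 = -logp_u(fam, a, b, lo, hi, xprop) * inv_t[c]
                for i in range(d):
                    h0 += 0.5 * pprop[i] * pprop[i]
                leapfrog(fam, a, b, lo, hi, xprop, pprop, eps, n_leap, inv_t[c])
                h1 = -logp_u(fam, a, b, lo, hi, xprop) * inv_t[c]
                for i in range(d):
                    h1 += 0.5 * pprop[i] * pprop[i]
                u = rng.random()
                if math.log(u) < h0 - h1:
                    for i in range(d):
                        X[c, i] = xprop[i]
                        P[c, i] = pprop[i]
                elif flip_on_reject:
                    for i in range(d):
                        P[c, i] = -P[c, i]
            else:
                for i in range(d):
                    xprop[i] = X[c, i] + sigma * rng.standard_normal()
                lp1 = logp_u(fam, a, b, lo, hi, xprop)
                u = rng.random()
                if lp1 > NEG_INF:
                    lp0 = logp_u(fam, a, b, lo, hi, X[c])
                    if math.log(u) < (lp1 - lp0) * inv_t[c]:
                        for i in range(d):
                            X[c, i] = xprop[i]

        if n_chains > 1 and swap_prob > 0.0:
            if rng.random() < swap_prob:
                j = rng.integers(0, n_chains - 1)
                lpj = logp_u(fam, a, b, lo, hi, X[j])
                lpk = logp_u(fam, a, b, lo, hi, X[j + 1])
                lr = (inv_t[j] - inv_t[j + 1]) * (lpk - lpj)
                if math.log(rng.random()) < lr:
                    for i in range(d):
                        tmp = X[j, i]
                        X[j, i] = X[j + 1, i]
                        X[j + 1, i] = tmp
                        tmp = P[j, i]
                        P[j, i] = P[j + 1, i]
                        P[j + 1, i] = tmp

        if t >= burn:
            for i in range(d):
                out[t - burn, i] = X[0, i]
    return out
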