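"""Generative models of random-sequence production.

Eight candidate generators share one emission contract: after a 50-step
unemitted burn-in, every iteration of the underlying process utters exactly
one (grid-rounded) response, so Metropolis rejections surface as repeated
items — the mapping between chain iterations and utterances that lets the
chain's local moves show up in the behavioral indices.

* ``iid`` — independent draws from the target (the normative baseline).
* ``schema`` — habitual transformation rules (+1, -1, +2, -2, repeat,
  random jump) applied to the previous item, with a persistence probability
  of keeping the active rule; univariate domains only.
* Six MCMC "local samplers" built semi-factorially on Metropolis-Hastings:
  ``MH``, ``MC3`` (Metropolis-coupled chains), ``HMC`` (Hamiltonian /
  gradient-based proposals), ``REC`` (HMC with partially recycled
  momentum), and the coupled versions ``MCHMC`` and ``MCREC``.

Every sampler draws its parameters from independent uniform priors scaled
to the width of the target's support; see :func:`prior_ranges`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _kernels
from .domains import TargetDistribution
from .sumstats import Sequence

__all__ = [
    "MODELS",
    "LOCAL_MODELS",
    "SamplerSpec",
    "prior_ranges",
    "draw_params_from_prior",
    "generate_sequence",
    "generate_small_transitions_sequence",
    "step_iid",
    "step_mh",
    "step_hmc",
    "step_rec",
    "step_coupled",
    "step_schema",
    "leapfrog",
]

MODELS = ("iid", "schema", "MH", "MC3", "HMC", "REC", "MCHMC", "MCREC")
LOCAL_MODELS = ("MH", "MC3", "HMC", "REC", "MCHMC", "MCREC")

#: Which qualitative features each local sampler carries.
FEATURES = {
    "MH": frozenset(),
    "MC3": frozenset({"multiple_chains"}),
    "HMC": frozenset({"gradient"}),
    "REC": frozenset({"gradient", "recycled"}),
    "MCHMC": frozenset({"multiple_chains", "gradient"}),
    "MCREC": frozenset({"multiple_chains", "gradient", "recycled"}),
}

_PARAM_NAMES = {
    "iid": (),
    "schema": ("weights", "rho"),
    "MH": ("sigma",),
    "MC3": ("sigma", "n_chains", "delta", "swap_prob"),
    "HMC": ("eps", "n_leap"),
    "REC": ("eps", "n_leap", "alpha"),
    "MCHMC": ("eps", "n_leap", "n_chains", "delta", "swap_prob"),
    "MCREC": ("eps", "n_leap", "alpha", "n_chains", "delta", "swap_prob"),
}

N_SCHEMAS = 6  # +1, -1, +2, -2, repeat, random jump
_SCHEMA_DELTAS = (1, -1, 2, -2)
DEFAULT_BURN_IN = 50


@dataclass(frozen=True)
class SamplerSpec:
    """A generative model identity plus a concrete parameter assignment."""

    model_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model_id {self.model_id!r}; known: {MODELS}")
        expected = set(_PARAM_NAMES[self.model_id])
        got = set(self.params)
        if expected != got:
            raise ValueError(
                f"{self.model_id} expects parameters {sorted(expected)}, got {sorted(got)}"
            )
        if self.model_id == "schema":
            w = np.asarray(self.params["weights"], dtype=float)
            if w.shape != (N_SCHEMAS,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-8):
                raise ValueError("schema weights must be 6 nonnegative values summing to 1")


def prior_ranges(model_id: str, domain: TargetDistribution) -> dict:
    """Uniform prior range per parameter, scaled to the support width W.

    ``sigma`` (random-walk proposal sd) ~ U(0.005 W, 0.5 W); ``eps``
    (leapfrog step size) ~ U(0.005 W, 0.3 W); ``n_leap`` ~ U{1..20};
    ``alpha`` (momentum recycling) ~ U(0, 0.99); ``n_chains`` ~ U{2..6};
    ``delta`` (temperature spacing) ~ U(0.1, 5); ``swap_prob`` ~ U(0, 1).
    The schema model puts a flat Dirichlet on its six rule weights and
    U(0, 1) on the rule-persistence probability ``rho``.
    """
    w = domain.width
    all_ranges = {
        "sigma": (0.005 * w, 0.5 * w),
        "eps": (0.005 * w, 0.3 * w),
        "n_leap": (1, 20),
        "alpha": (0.0, 0.99),
        "n_chains": (2, 6),
        "delta": (0.1, 5.0),
        "swap_prob": (0.0, 1.0),
        "rho": (0.0, 1.0),
        "weights": ("dirichlet", N_SCHEMAS),
    }
    return {name: all_ranges[name] for name in _PARAM_NAMES[model_id]}


def draw_params_from_prior(model_id: str, domain: TargetDistribution,
                           rng: np.random.Generator) -> dict:
    """One independent draw of every parameter from its uniform prior."""
    params = {}
    for name, rng_spec in prior_ranges(model_id, domain).items():
        if name == "weights":
            params[name] = tuple(rng.dirichlet(np.ones(N_SCHEMAS)))
        elif name in ("n_leap", "n_chains"):
            lo, hi = rng_spec
            params[name] = int(rng.integers(lo, hi + 1))
        else:
            lo, hi = rng_spec
            params[name] = float(rng.uniform(lo, hi))
    return params


# --------------------------------------------------------------------------
# single-step operations (thin wrappers over the compiled kernels; the toy
# oracles in the test suite exercise these directly)
# --------------------------------------------------------------------------

def _logp_fn(domain) -> Callable:
    if callable(domain):
        return domain
    return domain.log_density


def step_iid(domain: TargetDistribution, rng: np.random.Generator):
    """One independent draw from the target (continuous state or item id)."""
    if domain.family == "gaussian":
        return domain.params["mean"] + domain.params["sd"] * rng.standard_normal()
    if domain.family == "scaled_beta":
        lo, hi = domain.support
        a, b = domain.params["alpha"], domain.params["beta"]
        return lo + (hi - lo) * rng.beta(a, b)
    return int(rng.integers(1, domain.layout.n_items + 1))


def step_mh(x, domain, sigma: float, rng: np.random.Generator, inv_temp: float = 1.0):
    """One random-walk Metropolis step.  ``domain`` may be a
    :class:`TargetDistribution` or any log-density callable (out-of-support
    points must return ``-inf``, which auto-rejects)."""
    logp = _logp_fn(domain)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    prop = x + sigma * rng.standard_normal(x.shape[0])
    lp1 = float(logp(prop if x.shape[0] > 1 else prop[0]))
    u = rng.random()
    if lp1 > -math.inf:
        lp0 = float(logp(x if x.shape[0] > 1 else x[0]))
        if math.log(u) < (lp1 - lp0) * inv_temp:
            x = prop
    return x if x.shape[0] > 1 else float(x[0])


def leapfrog(x, p, eps: float, n_leap: int, domain: TargetDistribution,
             inv_temp: float = 1.0):
    """Leapfrog-integrate Hamiltonian dynamics on the (tempered) target,
    reflecting positions at support boundaries.  Returns (x', p')."""
    fam, a, b, lo, hi = domain.kernel_spec()
    xa = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    pa = np.atleast_1d(np.asarray(p, dtype=float)).copy()
    _kernels.leapfrog(fam, a, b, lo, hi, xa, pa, eps, n_leap, inv_temp)
    if np.ndim(x) == 0:
        return float(xa[0]), float(pa[0])
    return xa, pa


def step_rec(x, p, domain: TargetDistribution, eps: float, n_leap: int,
             alpha: float, rng: np.random.Generator, inv_temp: float = 1.0,
             flip_on_reject: bool = False):
    """One Hamiltonian step with partial momentum refreshment.

    The momentum is recycled as ``p <- alpha * p + sqrt(1 - alpha^2) * z``
    with standard-normal ``z`` (``alpha = 0`` is plain HMC), then a leapfrog
    trajectory is accepted with the Metropolis rule on the Hamiltonian
    error.  On rejection the refreshed momentum is retained unflipped
    unless ``flip_on_reject`` is set.  Returns ``(x', p', accepted)``.
    """
    fam, a, b, lo, hi = domain.kernel_spec()
    scalar = np.ndim(x) == 0
    xa = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    pa = np.atleast_1d(np.asarray(p, dtype=float)).copy()
    d = xa.shape[0]
    sq = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    for i in range(d):
        pa[i] = alpha * pa[i] + sq * rng.standard_normal()
    xprop, pprop = xa.copy(), pa.copy()
    h0 = -_kernels.logp_u(fam, a, b, lo, hi, xprop) * inv_temp + 0.5 * float(pprop @ pprop)
    _kernels.leapfrog(fam, a, b, lo, hi, xprop, pprop, eps, n_leap, inv_temp)
    h1 = -_kernels.logp_u(fam, a, b, lo, hi, xprop) * inv_temp + 0.5 * float(pprop @ pprop)
    u = rng.random()
    accepted = math.log(u) < h0 - h1
    if accepted:
        xa, pa = xprop, pprop
    elif flip_on_reject:
        pa = -pa
    if scalar:
        return float(xa[0]), float(pa[0]), accepted
    return xa, pa, accepted


def step_hmc(x, domain: TargetDistribution, eps: float, n_leap: int,
             rng: np.random.Generator, inv_temp: float = 1.0):
    """One HMC step: fresh standard-normal momentum, leapfrog, Metropolis
    accept on the Hamiltonian error.  Returns (x', accepted)."""
    x2, _, acc = step_rec(x, np.zeros(np.shape(np.atleast_1d(x))), domain, eps,
                          n_leap, 0.0, rng, inv_temp)
    return x2, acc


def step_coupled(positions: list, domain, base_step: Callable, delta: float,
                 swap_prob: float, rng: np.random.Generator):
    """Advance C tempered chains by ``base_step`` and attempt one stochastic
    neighbor swap.

    ``base_step(x, inv_temp, rng)`` advances one chain against the tempered
    density p(x)^inv_temp.  Chain i runs at temperature (1 + delta)^i; the
    cold chain (index 0) is the observed one.  ``domain`` may be a
    log-density callable for toy targets.  Mutates and returns ``positions``.
    """
    logp = _logp_fn(domain)
    n_chains = len(positions)
    inv_t = [(1.0 + delta) ** (-i) for i in range(n_chains)]
    for i in range(n_chains):
        positions[i] = base_step(positions[i], inv_t[i], rng)
    if n_chains > 1 and swap_prob > 0 and rng.random() < swap_prob:
        j = int(rng.integers(0, n_chains - 1))
        lr = (inv_t[j] - inv_t[j + 1]) * (float(logp(positions[j + 1])) - float(logp(positions[j])))
        if math.log(rng.random()) < lr:
            positions[j], positions[j + 1] = positions[j + 1], positions[j]
    return positions


def step_schema(item: int, schema: int, domain: TargetDistribution,
                weights, rho: float, rng: np.random.Generator):
    """One schema-model step on a univariate ordered response range.

    With probability ``rho`` the active schema is reapplied, otherwise a
    fresh schema is drawn according to ``weights`` over
    (+1, -1, +2, -2, repeat, random jump).  Results outside the range are
    reflected.  Returns ``(item', schema')``.
    """
    if domain.ndim == 2:
        raise ValueError("the schema model cannot sample in two-dimensional domains")
    grid = domain.schema_grid
    gmin, gmax = int(grid[0]), int(grid[-1])
    if rng.random() >= rho:
        schema = int(np.searchsorted(np.cumsum(weights), rng.random(), side="right"))
        schema = min(schema, N_SCHEMAS - 1)
    if schema < 4:
        new = item + _SCHEMA_DELTAS[schema]
        if new > gmax:
            new = 2 * gmax - new
        elif new < gmin:
            new = 2 * gmin - new
    elif schema == 4:  # repeat
        new = item
    else:  # random jump
        new = int(rng.integers(gmin, gmax + 1))
    return new, schema


# --------------------------------------------------------------------------
# sequence generation
# --------------------------------------------------------------------------

def _iid_raw(domain: TargetDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    if domain.family == "gaussian":
        draws = domain.params["mean"] + domain.params["sd"] * rng.standard_normal(n)
        return draws[:, None]
    if domain.family == "scaled_beta":
        lo, hi = domain.support
        a, b = domain.params["alpha"], domain.params["beta"]
        return (lo + (hi - lo) * rng.beta(a, b, size=n))[:, None]
    items = rng.integers(1, domain.layout.n_items + 1, size=n)
    return domain.layout.positions[items - 1].astype(float)


def _schema_sequence(params: dict, domain: TargetDistribution, length: int,
                     burn_in: int, rng: np.random.Generator) -> np.ndarray:
    if domain.ndim == 2:
        raise ValueError("the schema model cannot sample in two-dimensional domains")
    weights = np.asarray(params["weights"], dtype=float)
    rho = params["rho"]
    grid = domain.schema_grid
    item = int(rng.integers(int(grid[0]), int(grid[-1]) + 1))
    schema = int(np.searchsorted(np.cumsum(weights), rng.random(), side="right"))
    schema = min(schema, N_SCHEMAS - 1)
    out = np.empty(length, dtype=int)
    for t in range(burn_in + length):
        item, schema = step_schema(item, schema, domain, weights, rho, rng)
        if t >= burn_in:
            out[t - burn_in] = item
    return out


def generate_sequence(spec: SamplerSpec, domain: TargetDistribution,
                      length: int = 400, seed=None, rng=None,
                      burn_in: int = DEFAULT_BURN_IN, return_raw: bool = False,
                      flip_on_reject: bool = False, meta: dict | None = None) -> Sequence:
    """Emit one response sequence from a generative model.

    Stateful generators (the MCMC samplers and the schema model) run a
    ``burn_in`` of unemitted steps, then utter one rounded response per
    iteration, so rejected proposals emit repetitions.  ``return_raw``
    additionally exposes the pre-rounding continuous states on
    ``Sequence.raw`` (iid draws are their own raw states).

    A fixed ``(model, params, seed)`` triple reproduces the sequence
    byte-identically.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    model = spec.model_id
    p = spec.params

    if model == "iid":
        raw = _iid_raw(domain, length, rng)
    elif model == "schema":
        responses = _schema_sequence(p, domain, length, burn_in, rng)
        raw = responses.astype(float)[:, None]
        seq = Sequence(responses=responses, domain=domain, meta=_meta(model, p, seed, meta))
        if return_raw:
            seq.raw = raw
        return seq
    else:
        fam, a, b, lo, hi = domain.kernel_spec()
        raw = _kernels.run_chain(
            rng, fam, a, b, lo, hi, domain.ndim,
            "gradient" in FEATURES[model],
            float(p.get("sigma", 0.0)), float(p.get("eps", 0.0)),
            int(p.get("n_leap", 1)), float(p.get("alpha", 0.0)),
            int(p.get("n_chains", 1)), float(p.get("delta", 0.0)),
            float(p.get("swap_prob", 0.0)), burn_in, length, flip_on_reject,
        )

    if domain.ndim == 2:
        responses = domain.round_to_grid(raw)
    else:
        responses = domain.round_to_grid(raw[:, 0])
    responses = np.asarray(responses)
    seq = Sequence(responses=responses, domain=domain, meta=_meta(model, p, seed, meta))
    if return_raw:
        seq.raw = raw
    return seq


def _meta(model, params, seed, extra):
    meta = {"model": model, "params": dict(params), "seed": seed}
    if extra:
        meta.update(extra)
    return meta


def generate_small_transitions_sequence(domain: TargetDistribution, length: int,
                                        seed=None, rng=None,
                                        window_sd: float = 1.0) -> Sequence:
    """iid sampling constrained to small transitions.

    Each draw is resampled from the target until it lies within
    ``window_sd`` target standard deviations of the previous (continuous)
    item — the sampler behind the "small jumps alone do not explain
    direction persistence" demonstration.  Continuous targets only.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if domain.family == "gaussian":
        sd = domain.params["sd"]
    elif domain.family == "scaled_beta":
        a, b = domain.params["alpha"], domain.params["beta"]
        lo, hi = domain.support
        sd = (hi - lo) * math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    else:
        raise ValueError("small-transitions sampling is defined for continuous targets")
    window = window_sd * sd
    out = np.empty(length)
    prev = step_iid(domain, rng)
    out[0] = prev
    for t in range(1, length):
        x = step_iid(domain, rng)
        while abs(x - prev) > window:
            x = step_iid(domain, rng)
        out[t] = x
        prev = x
    responses = domain.round_to_grid(out)
    seq = Sequence(responses=np.asarray(responses), domain=domain,
                   meta={"model": "iid_small_transitions", "seed": seed})
    seq.raw = out[:, None]
    return seq
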