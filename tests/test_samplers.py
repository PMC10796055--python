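"""Chain kernels, step operations, priors, and the emission contract."""

import math

import numpy as np
import pytest
from scipy import stats

import randgen as rg
from randgen import samplers as S
from randgen import sumstats as st
from randgen.domains import make_domain

UNIT_GAUSS = make_domain("gaussian", mean=0.0, sd=1.0)


class ScriptedRng:
    """Replays scripted normal/uniform draws to force specific proposals."""

    def __init__(self, normals=(), uniforms=()):
        self._n = list(normals)
        self._u = list(uniforms)

    def standard_normal(self, size=None):
        if size is None:
            return self._n.pop(0)
        return np.array([self._n.pop(0) for _ in range(size)])

    def random(self):
        return self._u.pop(0)


# ----------------------------------------------------------------- leapfrog

def test_leapfrog_hand_computed_step():
    """One leapfrog step on H = p^2/2 + x^2/2 from (x, p) = (1, 0)."""
    x, p = S.leapfrog(1.0, 0.0, eps=0.1, n_leap=1, domain=UNIT_GAUSS)
    assert x == pytest.approx(0.995, abs=1e-12)
    assert p == pytest.approx(-0.09975, abs=1e-12)


def test_leapfrog_energy_error_second_order():
    """Hamiltonian error on the unit Gaussian shrinks ~4x when eps halves."""
    def energy_err(eps):
        x0, p0 = 1.3, 0.4
        n = int(round(2.0 / eps))
        x, p = S.leapfrog(x0, p0, eps=eps, n_leap=n, domain=UNIT_GAUSS)
        h = lambda x_, p_: 0.5 * p_**2 + 0.5 * x_**2
        return abs(h(x, p) - h(x0, p0))

    e1, e2 = energy_err(0.05), energy_err(0.025)
    assert e1 / e2 == pytest.approx(4.0, rel=0.25)


def test_leapfrog_flat_target_is_straight_line(line7_domain):
    x, p = S.leapfrog(3.0, 0.5, eps=0.2, n_leap=5, domain=line7_domain)
    assert x == pytest.approx(3.0 + 0.2 * 5 * 0.5)
    assert p == pytest.approx(0.5)


def test_leapfrog_reflects_at_boundaries(line7_domain):
    # flat target: motion is ballistic with reflections off [1, 7]
    x, p = S.leapfrog(6.5, 1.0, eps=1.0, n_leap=1, domain=line7_domain)
    assert x == pytest.approx(2 * 7 - 7.5)  # 7.5 reflected at 7
    assert p == pytest.approx(-1.0)
    xs, _ = S.leapfrog(3.0, 9.7, eps=1.0, n_leap=50, domain=line7_domain)
    assert 1.0 <= xs <= 7.0


def test_hex_reflection_stays_in_hull(hex7_domain):
    rng = np.random.default_rng(0)
    for _ in range(200):
        x = np.zeros(2)
        p = rng.standard_normal(2) * 3
        x2, _ = S.leapfrog(x, p, eps=0.5, n_leap=8, domain=hex7_domain)
        assert hex7_domain.in_support(x2)


# ----------------------------------------------------------------- MH

def test_mh_uphill_proposal_always_accepted():
    # from x = 2 propose x' = 1 (higher density): accepted even at u -> 1
    rng = ScriptedRng(normals=[-1.0], uniforms=[1.0 - 1e-12])
    assert S.step_mh(2.0, UNIT_GAUSS, sigma=1.0, rng=rng) == pytest.approx(1.0)


def test_mh_acceptance_probability_closed_form():
    """Move 0 -> 1 on N(0, 1) is accepted with probability exp(-1/2)."""
    urng = np.random.default_rng(7)
    accepts = 0
    n = 4000
    for _ in range(n):
        rng = ScriptedRng(normals=[1.0], uniforms=[urng.random()])
        accepts += S.step_mh(0.0, UNIT_GAUSS, sigma=1.0, rng=rng) == 1.0
    p_hat = accepts / n
    se = math.sqrt(math.exp(-0.5) * (1 - math.exp(-0.5)) / n)
    assert abs(p_hat - math.exp(-0.5)) < 4 * se


def test_mh_out_of_support_auto_rejects(line7_domain):
    rng = ScriptedRng(normals=[100.0], uniforms=[0.0])
    assert S.step_mh(4.0, line7_domain, sigma=1.0, rng=rng) == 4.0


def test_mh_detailed_balance_on_binned_target(uniform_domain):
    """Empirical flows between 5 coarse bins are symmetric (reversibility)."""
    spec = rg.SamplerSpec("MH", {"sigma": 25.0})
    seq = rg.generate_sequence(spec, uniform_domain, length=1_000_000, seed=3,
                               return_raw=True)
    x = seq.raw[:, 0]
    lo, hi = uniform_domain.support
    bins = np.clip(((x - lo) / (hi - lo) * 5).astype(int), 0, 4)
    flow = np.zeros((5, 5))
    np.add.at(flow, (bins[:-1], bins[1:]), 1.0)
    imbalance = np.abs(flow - flow.T) / len(x)
    assert imbalance.max() < 1e-2


# ----------------------------------------------------------------- HMC / REC

def test_hmc_flat_target_always_accepts(line7_domain, rng):
    for _ in range(50):
        _, accepted = S.step_hmc(4.0, line7_domain, eps=0.3, n_leap=5, rng=rng)
        assert accepted


def test_hmc_tiny_step_accepts(rng):
    # eps -> 0: exact Hamiltonian flow, acceptance probability -> 1
    for _ in range(100):
        _, accepted = S.step_hmc(1.5, UNIT_GAUSS, eps=1e-4, n_leap=3, rng=rng)
        assert accepted


def test_rec_momentum_marginal_remains_standard_normal(line7_domain):
    """alpha p + sqrt(1 - alpha^2) z preserves the N(0, 1) momentum marginal."""
    rng = np.random.default_rng(42)
    x, p = 4.0, 0.0
    ps = np.empty(20_000)
    for i in range(ps.size):
        x, p, _ = S.step_rec(x, p, line7_domain, eps=0.05, n_leap=1,
                             alpha=0.7, rng=rng)
        ps[i] = p
    # AR(1) with coefficient .7: effective n ~ n (1-a)/(1+a) ~ 3500
    assert abs(ps.mean()) < 0.05
    assert ps.var() == pytest.approx(1.0, abs=0.06)


@pytest.mark.parametrize("pair", [
    ("MC3", {"sigma": 9.0, "n_chains": 1, "delta": 1.0, "swap_prob": 0.5},
     "MH", {"sigma": 9.0}),
    ("REC", {"eps": 3.0, "n_leap": 7, "alpha": 0.0},
     "HMC", {"eps": 3.0, "n_leap": 7}),
    ("MCHMC", {"eps": 3.0, "n_leap": 7, "n_chains": 1, "delta": 2.0, "swap_prob": 0.9},
     "HMC", {"eps": 3.0, "n_leap": 7}),
    ("MCREC", {"eps": 3.0, "n_leap": 7, "alpha": 0.0, "n_chains": 1, "delta": 2.0,
               "swap_prob": 0.9},
     "HMC", {"eps": 3.0, "n_leap": 7}),
])
def test_reduction_identities_exact_under_shared_seed(pair, uniform_domain):
    """Degenerate feature settings reproduce the base sampler draw-for-draw."""
    m1, p1, m2, p2 = pair
    a = rg.generate_sequence(rg.SamplerSpec(m1, p1), uniform_domain, length=300, seed=5)
    b = rg.generate_sequence(rg.SamplerSpec(m2, p2), uniform_domain, length=300, seed=5)
    assert np.array_equal(a.responses, b.responses)


@pytest.mark.parametrize("model,params", [
    ("MH", {"sigma": 18.0}),
    ("MC3", {"sigma": 18.0, "n_chains": 3, "delta": 1.0, "swap_prob": 0.3}),
    ("HMC", {"eps": 8.0, "n_leap": 10}),
    ("REC", {"eps": 8.0, "n_leap": 10, "alpha": 0.5}),
    ("MCHMC", {"eps": 8.0, "n_leap": 10, "n_chains": 3, "delta": 1.0, "swap_prob": 0.3}),
    ("MCREC", {"eps": 8.0, "n_leap": 10, "alpha": 0.5, "n_chains": 3, "delta": 1.0,
               "swap_prob": 0.3}),
])
def test_stationarity_ks_against_target(model, params, gauss_domain):
    """Pre-rounding states of every sampler match the target CDF (KS < .02)."""
    seq = rg.generate_sequence(rg.SamplerSpec(model, params), gauss_domain,
                               length=100_000, seed=8, return_raw=True)
    d = stats.kstest(seq.raw[:, 0], stats.norm(176.4, 12).cdf).statistic
    assert d < 0.02


def test_turning_points_non_increasing_in_recycling(gauss_domain):
    means = []
    for alpha in (0.0, 0.3, 0.6, 0.9):
        vals = []
        for seed in range(20):
            seq = rg.generate_sequence(
                rg.SamplerSpec("REC", {"eps": 4.0, "n_leap": 10, "alpha": alpha}),
                gauss_domain, length=400, seed=seed)
            vals.append(st.turning_points(st.strip_repeats(seq)))
        means.append(np.nanmean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


def test_coupled_chains_cross_bimodal_valley():
    """Tempered chains traverse a deep bimodal target where plain MH cannot."""
    def logp(x):
        return np.logaddexp(-0.5 * (x - 10.0) ** 2, -0.5 * (x + 10.0) ** 2)

    def visited_both(seed, coupled):
        rng = np.random.default_rng(seed)
        if coupled:
            chains = [-10.0] * 4

            def base(x, inv_t, r):
                return S.step_mh(x, logp, sigma=1.0, rng=r, inv_temp=inv_t)

            seen_pos = False
            for _ in range(4000):
                S.step_coupled(chains, logp, base, delta=4.0, swap_prob=0.5, rng=rng)
                seen_pos = seen_pos or chains[0] > 5
            return seen_pos
        x = -10.0
        for _ in range(4000):
            x = S.step_mh(x, logp, sigma=1.0, rng=rng)
            if x > 5:
                return True
        return False

    coupled_hits = sum(visited_both(s, True) for s in range(6))
    plain_hits = sum(visited_both(s, False) for s in range(6))
    assert coupled_hits >= 4
    assert plain_hits == 0


# ----------------------------------------------------------------- schema

def test_schema_steps_and_reflection(line7_domain, rng):
    w = (1.0, 0, 0, 0, 0, 0)  # always "+1"
    item, _ = S.step_schema(5, 0, line7_domain, w, rho=1.0, rng=rng)
    assert item == 6
    item, _ = S.step_schema(7, 0, line7_domain, w, rho=1.0, rng=rng)
    assert item == 6  # reflected at the top of the range


def test_schema_persistent_ramp_turns_only_at_boundary(line7_domain):
    """A permanently active "+1" schema ramps upward in unit steps and can
    only reverse direction where reflection kicks in (items 6/7)."""
    spec = rg.SamplerSpec("schema", {"weights": (1.0, 0, 0, 0, 0, 0), "rho": 1.0})
    seq = rg.generate_sequence(spec, line7_domain, length=60, seed=4)
    x = seq.responses
    assert st.repetitions(seq) == 0.0
    assert st.adjacencies(st.strip_repeats(seq)) == 1.0
    turns = np.flatnonzero(st._turn_flags(x.astype(float)[:, None])) + 1
    assert np.all(np.isin(x[turns], [6, 7]))


def test_schema_rejects_two_dimensional_domain(hex7_domain, rng):
    with pytest.raises(ValueError, match="two-dimensional"):
        S.step_schema(4, 0, hex7_domain, (1, 0, 0, 0, 0, 0), 0.5, rng)
    with pytest.raises(ValueError, match="two-dimensional"):
        rg.generate_sequence(
            rg.SamplerSpec("schema", {"weights": (1, 0, 0, 0, 0, 0), "rho": 0.5}),
            hex7_domain, length=50, seed=0)


# ----------------------------------------------------------------- iid

def test_iid_moments_and_independence(gauss_domain):
    rng = np.random.default_rng(10)
    seq = rg.generate_sequence(rg.SamplerSpec("iid", {}), gauss_domain,
                               length=100_000, rng=rng, return_raw=True)
    x = seq.raw[:, 0]
    assert abs(x.mean() - 176.4) < 3 * 12 / math.sqrt(x.size)
    assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.01


def test_iid_uniform_item_frequencies(line7_domain):
    seq = rg.generate_sequence(rg.SamplerSpec("iid", {}), line7_domain,
                               length=70_000, seed=2)
    freqs = np.bincount(seq.responses, minlength=8)[1:] / len(seq)
    np.testing.assert_allclose(freqs, 1 / 7, atol=0.01)


def test_small_transitions_respects_window(gauss_domain):
    seq = S.generate_small_transitions_sequence(gauss_domain, 500, seed=6)
    steps = np.abs(np.diff(seq.raw[:, 0]))
    assert steps.max() <= 12.0


# ----------------------------------------------------------------- priors & contract

def test_spec_validates_model_and_parameter_names():
    with pytest.raises(ValueError, match="unknown model_id"):
        rg.SamplerSpec("NUTS", {})
    with pytest.raises(ValueError, match="expects parameters"):
        rg.SamplerSpec("MH", {"sigma": 1.0, "extra": 2.0})
    with pytest.raises(ValueError, match="weights"):
        rg.SamplerSpec("schema", {"weights": (0.5, 0.5), "rho": 0.1})


def test_prior_draws_respect_ranges(uniform_domain):
    rng = np.random.default_rng(3)
    w = uniform_domain.width
    alphas, chains = [], []
    for _ in range(10_000):
        p = S.draw_params_from_prior("MCREC", uniform_domain, rng)
        assert 0.005 * w <= p["eps"] <= 0.3 * w
        assert 1 <= p["n_leap"] <= 20
        assert 0 <= p["alpha"] <= 0.99
        assert p["n_chains"] in (2, 3, 4, 5, 6)
        assert 0.1 <= p["delta"] <= 5.0
        alphas.append(p["alpha"])
        chains.append(p["n_chains"])
    assert np.mean(alphas) == pytest.approx(0.99 / 2, abs=0.02)
    counts = np.bincount(chains)[2:]
    assert counts.min() > 0.8 * counts.max()  # near-equal chain-count frequencies


@pytest.mark.parametrize("model", rg.MODELS)
def test_prior_draws_always_generate(model, uniform_domain):
    """Fuzz: any prior draw yields a valid on-grid sequence."""
    rng = np.random.default_rng(99)
    grid = set(uniform_domain.grid_values)
    for _ in range(40):
        p = S.draw_params_from_prior(model, uniform_domain, rng)
        seq = rg.generate_sequence(rg.SamplerSpec(model, p), uniform_domain,
                                   length=60, rng=rng)
        assert len(seq) == 60
        assert set(np.asarray(seq.responses).tolist()) <= grid


def test_generation_is_deterministic_per_seed(uniform_domain):
    spec = rg.SamplerSpec("MCREC", {"eps": 3.0, "n_leap": 5, "alpha": 0.5,
                                    "n_chains": 3, "delta": 1.0, "swap_prob": 0.5})
    a = rg.generate_sequence(spec, uniform_domain, length=200, seed=11)
    b = rg.generate_sequence(spec, uniform_domain, length=200, seed=11)
    c = rg.generate_sequence(spec, uniform_domain, length=200, seed=12)
    assert np.array_equal(a.responses, b.responses)
    assert not np.array_equal(a.responses, c.responses)


def test_frozen_chain_emits_repetitions(uniform_domain):
    """sigma -> 0: the rounded chain barely moves, so repetitions dominate."""
    seq = rg.generate_sequence(rg.SamplerSpec("MH", {"sigma": 1e-4}),
                               uniform_domain, length=400, seed=1)
    assert st.repetitions(seq) > 0.95
    assert st.distances(st.strip_repeats(seq)) <= 1.0 or math.isnan(
        st.distances(st.strip_repeats(seq)))


def test_length_contract():
    with pytest.raises(ValueError, match="length"):
        rg.generate_sequence(rg.SamplerSpec("iid", {}), UNIT_GAUSS, length=1, seed=0)
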