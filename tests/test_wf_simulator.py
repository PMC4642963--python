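"""Individual-based Wright-Fisher engine: sampling laws and protocols."""

import dataclasses

import numpy as np
import pytest

from enhancer_runaway import (
    InvalidParameterError,
    ModelParams,
    Population,
    TrialTimeoutError,
    burn_in_deleterious_frequency,
    estimate_fixation_probability,
    life_cycle_step,
    mutate_enhancer,
    mutate_gene,
    mutate_tf,
    run_escalation,
    run_fixation_trial,
    seed_kernels,
)
from enhancer_runaway.analysis import replicate_slopes


def make_params(**kw):
    base = dict(s_mean=0.1, h=0.25, u_gene=1e-3, u_enh=1e-3, r=1e-6, N_pop=500, seed=0)
    base.update(kw)
    return ModelParams(**base)


# ---------------------------------------------------------------------------
# structural invariants and reproducibility
# ---------------------------------------------------------------------------


def test_population_layouts():
    p = make_params(N_pop=40)
    assert Population.monomorphic(p, 1).z.shape == (40, 2)
    assert Population.monomorphic(p, 2).z.shape == (40, 2, 2)
    m3 = Population.monomorphic(p, 3)
    assert m3.z_tf is not None and m3.z_tf.shape == (40, 2)
    with pytest.raises(InvalidParameterError):
        Population.monomorphic(p, 5)


def test_population_size_constant_through_life_cycle():
    params = make_params(N_pop=120)
    seed_kernels(11)
    for model in (1, 2, 3, 4):
        pop = Population.monomorphic(params, model)
        for _ in range(5):
            pop = life_cycle_step(pop, params)
        assert pop.N == 120
        assert np.all(pop.w > 0.0) and np.all(pop.w <= 1.0)
        assert pop.generation == 5


def test_seeded_runs_are_bit_reproducible():
    params = make_params(N_pop=100, n_gen=500, n_iter=3, seed=77)
    a = run_escalation(params, model=1)
    b = run_escalation(params, model=1)
    assert np.array_equal(a.mean_z, b.mean_z)
    ta = run_fixation_trial(params, 3.0, seed=5)
    tb = run_fixation_trial(params, 3.0, seed=5)
    assert (ta.outcome, ta.generations) == (tb.outcome, tb.generations)


# ---------------------------------------------------------------------------
# sampling-law checks
# ---------------------------------------------------------------------------


def test_selfing_gives_mendelian_offspring_ratios():
    """Selfed heterozygotes segregate 1/4 : 1/2 : 1/4 at the tagged locus."""
    N = 4000
    params = make_params(N_pop=N, p_self=1.0, u_gene=0.0, u_enh=0.0)
    pop = Population.monomorphic(params, 4)
    pop.tag[:, 0] = 1  # every individual heterozygous mutant/resident
    seed_kernels(3)
    nxt = life_cycle_step(pop, params)
    counts = np.bincount(nxt.tag.sum(axis=1), minlength=3)
    frac = counts / N
    # 4 SE of a binomial proportion around 1/4 and 1/2
    assert frac[0] == pytest.approx(0.25, abs=4 * np.sqrt(0.25 * 0.75 / N))
    assert frac[1] == pytest.approx(0.50, abs=4 * np.sqrt(0.5 * 0.5 / N))
    assert frac[2] == pytest.approx(0.25, abs=4 * np.sqrt(0.25 * 0.75 / N))


def test_gene_mutation_event_counts_match_poisson_expectation():
    params = make_params(N_pop=500, u_gene=1e-3)
    pop = Population.monomorphic(params, 1)
    seed_kernels(9)
    n_rounds = 4000
    lam = 2 * params.N_pop * params.u_gene  # = 1 per round
    total = sum(mutate_gene(pop, params, "two_allele") for _ in range(n_rounds))
    expect = n_rounds * lam
    assert abs(total - expect) < 4 * np.sqrt(expect)
    assert mutate_gene(pop, dataclasses.replace(params, u_gene=0.0)) == 0


def test_infinite_allele_effects_are_exponential_with_mean_s():
    params = make_params(N_pop=50_000, u_gene=5e-3, s_mean=0.1)
    pop = Population.monomorphic(params, 1)
    seed_kernels(21)
    mutate_gene(pop, params, "infinite_allele")
    eff = 1.0 - pop.w[pop.w < 1.0]
    assert eff.size > 300
    assert np.all(eff > 0.0) and np.all(eff < 1.0)
    assert eff.mean() == pytest.approx(0.1, abs=4 * 0.1 / np.sqrt(eff.size))


def test_enhancer_increments_unbiased_with_sd_sigma():
    params = make_params(N_pop=50_000, u_enh=5e-3, sigma_E=0.1)
    pop = Population.monomorphic(params, 1)
    seed_kernels(22)
    mutate_enhancer(pop, params)
    eps = pop.z[pop.z != 0.0]
    assert eps.size > 300
    assert eps.mean() == pytest.approx(0.0, abs=4 * 0.1 / np.sqrt(eps.size))
    assert eps.std() == pytest.approx(0.1, rel=0.15)
    with pytest.raises(InvalidParameterError):
        mutate_tf(pop, params)


def test_neutral_fixation_probability_is_initial_frequency():
    """With selection off, a single-copy tag fixes at rate 1/(2N)."""
    params = make_params(N_pop=100, u_gene=0.0, u_enh=0.0)
    est = estimate_fixation_probability(params, 1.0, n_trials=4000, seed=123, burn_in=0)
    assert est.ci_low < 1.0 / 200.0 < est.ci_high
    assert est.ratio_to_neutral == pytest.approx(1.0, abs=0.6)


# ---------------------------------------------------------------------------
# protocol-level behavior
# ---------------------------------------------------------------------------


def test_burn_in_reaches_mutation_selection_balance():
    params = make_params(N_pop=1000)
    pas = [burn_in_deleterious_frequency(params, seed=s) for s in range(40)]
    # deterministic balance is ~0.0371; replicate sd ~0.018
    assert np.mean(pas) == pytest.approx(0.037, abs=3 * 0.018 / np.sqrt(40))


def test_trial_timeout_raises():
    # a single-generation cap cannot absorb a fresh single-copy mutant
    params = make_params(N_pop=2000, u_gene=0.0)
    with pytest.raises(TrialTimeoutError):
        run_fixation_trial(params, 1.0, seed=0, burn_in=0, max_gen=1)


def test_estimator_input_validation():
    params = make_params()
    with pytest.raises(InvalidParameterError):
        estimate_fixation_probability(params, 3.0, n_trials=10)
    with pytest.raises(InvalidParameterError):
        run_fixation_trial(params, -2.0)


def test_escalation_flat_without_enhancer_mutation():
    params = make_params(N_pop=100, u_enh=0.0, n_gen=400, n_iter=2, seed=5)
    res = run_escalation(params, model=1)
    assert np.all(res.mean_z == 0.0)


def test_model2_with_no_stabilizing_selection_matches_two_model1_copies():
    """At gamma = 0 the dosage model is two independent single-pair models."""
    common = dict(N_pop=200, n_gen=5000, n_iter=12, u_enh=1e-3, sigma_E=0.1)
    m1 = run_escalation(make_params(seed=31, **common), model=1)
    m2 = run_escalation(make_params(seed=32, gamma=0.0, **common), model=2)
    s1, s2 = replicate_slopes(m1), replicate_slopes(m2)
    pooled = np.sqrt(s1.var(ddof=1) / s1.size + s2.var(ddof=1) / s2.size)
    assert abs(s1.mean() - s2.mean()) < 4 * pooled


def test_model2_dosage_is_held_while_strengths_escalate():
    """With gamma > 0 the two loci coevolve: Z1 - Z2 stays pinned near 0."""
    common = dict(N_pop=300, n_gen=10_000, n_iter=8, u_enh=1e-3, sigma_E=0.1)
    free = run_escalation(make_params(seed=41, gamma=0.0, **common), model=2)
    held = run_escalation(make_params(seed=41, gamma=10.0, **common), model=2)
    gap_free = np.abs(free.mean_z1[:, -1] - free.mean_z2[:, -1])
    gap_held = np.abs(held.mean_z1[:, -1] - held.mean_z2[:, -1])
    assert np.median(gap_held) < np.median(gap_free)
    assert gap_held.max() < 0.5


def test_model3_tf_strength_compensates_enhancer_strength():
    """Total expression Z1 + Z2 is pinned while the two loci drift apart.

    Under stabilizing selection the summed log strength is an
    Ornstein-Uhlenbeck-like variable with bounded spread, whereas without
    it (gamma = 0) it accumulates mutation-drift variance linearly in time;
    the difference Z1 - Z2 is unconstrained in both cases.
    """
    common = dict(N_pop=300, n_gen=20_000, n_iter=8, u_enh=1e-3, u_tf=1e-3, sigma_E=0.1)
    pinned = run_escalation(make_params(seed=51, gamma=10.0, **common), model=3)
    free = run_escalation(make_params(seed=51, gamma=0.0, **common), model=3)

    def totals(res):
        return 2.0 * (res.mean_z[:, -1] + res.mean_z_tf[:, -1])

    t_pin, t_free = totals(pinned), totals(free)
    # the summed trait is held an order of magnitude tighter than free drift;
    # the enhancer-up/TF-down divergence itself is below drift noise at this
    # population size and is exercised by the escalation-ordering checks
    assert np.var(t_pin) < 0.5 * np.var(t_free)
    assert np.abs(t_pin).max() < 1.0
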