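"""Compiled inner loops of the individual-based Wright-Fisher engine.

Everything here is numba-njitted and operates on plain numpy arrays:
haplotype layouts are (N, 2) for a single enhancer-gene pair (models 1 and
4), (N, 2, 2) indexed (individual, locus, haplotype) for the two-pair dosage
model (model 2), plus a free-recombining (N, 2) TF locus for model 3.

The life cycle is: diploid selection (parents drawn uniformly and accepted
with probability equal to their fitness, i.e. fitness-proportional
sampling), meiosis with recombination at rate ``r`` within each enhancer-
gene pair and free recombination between pairs / the TF locus, mutation
(Poisson numbers of events hitting uniformly chosen allele copies, with
replacement), and syngamy.  With probability ``p_self`` the second gamete is
sampled from the same parent as the first (only the first parent is
fitness-sampled).

Performance-critical exact rewrites, all distributionally identical to the
reference operations:

* the gene-locus burn-in (monomorphic enhancer, bi-allelic gene) is run on
  genotype counts — offspring alleles are iid Bernoulli draws from the
  fitness-weighted gamete pool, so the counts are a conditional-binomial
  multinomial and mutation hits shift counts according to which copy class
  a uniformly chosen copy falls into;
* the long-run escalation drivers draw parents from an alias table built
  once per generation (the same categorical distribution the rejection
  sampler realizes, at one uniform deviate per draw) and, when ``r`` is
  small, draw the per-generation number of crossovers as Binomial(2N, r)
  instead of testing every gamete;
* the high-volume uniform deviates (parent choice, chromosome choice,
  crossover and selfing tests) come from an inline SplitMix64 stream —
  a published, statistically tested 64-bit generator — which is several
  times faster than the boxed legacy generator; low-volume distributional
  draws (Poisson event counts, normal increments, exponential effects,
  binomials) stay on numpy's generator.

Every driver takes an explicit 31-bit seed that initializes both streams,
so runs are bit-reproducible.
"""

import math

import numpy as np
from numba import njit

# below this recombination rate the escalation drivers draw crossover
# counts globally instead of testing each gamete
_R_GLOBAL = 0.01

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_MIX2 = np.uint64(0x94D049BB133111EB)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(inline="always")
def _sm_next(st):
    # SplitMix64: one additive step + finalizer; uint64 arithmetic wraps
    st[0] = st[0] + _SM_GAMMA
    z = st[0]
    z = (z ^ (z >> np.uint64(30))) * _SM_MIX1
    z = (z ^ (z >> np.uint64(27))) * _SM_MIX2
    return z ^ (z >> np.uint64(31))


@njit(inline="always")
def _rand_f(st):
    # uniform in [0, 1) from the top 53 bits
    return float(_sm_next(st) >> np.uint64(11)) * _INV_2_53


@njit(inline="always")
def _randint(n, st):
    return int(_rand_f(st) * n)


@njit(cache=False)
def _init_state(seed):
    st = np.empty(1, np.uint64)
    st[0] = np.uint64(seed)
    # warm up past the low-entropy seed
    _sm_next(st)
    _sm_next(st)
    return st


@njit(inline="always")
def _pick_parent(W, st):
    n = W.shape[0]
    while True:
        i = int(_rand_f(st) * n)
        if _rand_f(st) < W[i]:
            return i


@njit(inline="always")
def _pair_fitness(z0, z1, w0, w1, k):
    # fitness of one enhancer-gene pair; the w1 == w0 shortcut covers the
    # common case of a gene-homozygous individual (no expression split)
    if w0 == w1:
        return w0
    e0 = math.exp(z0)
    e1 = math.exp(z1)
    if w0 < w1:
        f = e0 / (e0 + e1)
        return w1 - f**k * (w1 - w0)
    f = e1 / (e0 + e1)
    return w0 - f**k * (w0 - w1)


# ---------------------------------------------------------------------------
# alias-table categorical sampling (exact fitness-proportional parent choice)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _alias_build(W, prob, alias, small, large):
    n = W.shape[0]
    tot = 0.0
    for i in range(n):
        tot += W[i]
    ns = 0
    nl = 0
    for i in range(n):
        p = W[i] * n / tot
        prob[i] = p
        if p < 1.0:
            small[ns] = i
            ns += 1
        else:
            large[nl] = i
            nl += 1
    while ns > 0 and nl > 0:
        ns -= 1
        s_i = small[ns]
        l_i = large[nl - 1]
        alias[s_i] = l_i
        prob[l_i] -= 1.0 - prob[s_i]
        if prob[l_i] < 1.0:
            nl -= 1
            small[ns] = l_i
            ns += 1
    while nl > 0:
        nl -= 1
        prob[large[nl]] = 1.0
        alias[large[nl]] = large[nl]
    while ns > 0:
        ns -= 1
        prob[small[ns]] = 1.0
        alias[small[ns]] = small[ns]


@njit(inline="always")
def _alias_pick(prob, alias, st):
    n = prob.shape[0]
    u = _rand_f(st) * n
    i = int(u)
    if i >= n:
        i = n - 1
    if u - i < prob[i]:
        return i
    return alias[i]


# ---------------------------------------------------------------------------
# fitness sweeps (one value per individual); return max fitness for the
# zero-mass guard
# ---------------------------------------------------------------------------


@njit(cache=False)
def fitness_m1(z, w, k, W):
    wmax = 0.0
    for i in range(z.shape[0]):
        Wi = _pair_fitness(z[i, 0], z[i, 1], w[i, 0], w[i, 1], k)
        if Wi > 1.0:
            Wi = 1.0
        W[i] = Wi
        if Wi > wmax:
            wmax = Wi
    return wmax


@njit(cache=False)
def fitness_m2(z, w, k, I, W):
    wmax = 0.0
    for i in range(z.shape[0]):
        wa1 = _pair_fitness(z[i, 0, 0], z[i, 0, 1], w[i, 0, 0], w[i, 0, 1], k)
        wa2 = _pair_fitness(z[i, 1, 0], z[i, 1, 1], w[i, 1, 0], w[i, 1, 1], k)
        d = (z[i, 0, 0] + z[i, 0, 1]) - (z[i, 1, 0] + z[i, 1, 1])
        Wi = wa1 * wa2 * math.exp(-I * d * d)
        if Wi > 1.0:
            Wi = 1.0
        W[i] = Wi
        if Wi > wmax:
            wmax = Wi
    return wmax


@njit(cache=False)
def fitness_m3(z, w, z_tf, k, I, W):
    wmax = 0.0
    for i in range(z.shape[0]):
        wa = _pair_fitness(z[i, 0], z[i, 1], w[i, 0], w[i, 1], k)
        d = (z[i, 0] + z[i, 1]) + (z_tf[i, 0] + z_tf[i, 1])
        Wi = wa * math.exp(-I * d * d)
        if Wi > 1.0:
            Wi = 1.0
        W[i] = Wi
        if Wi > wmax:
            wmax = Wi
    return wmax


# ---------------------------------------------------------------------------
# reference single-generation reproduction (rejection sampler, per-gamete
# crossover test); used by the unit-level Population API
# ---------------------------------------------------------------------------


@njit(cache=False)
def reproduce_m1(z, w, tag, W, r, p_self, z2, w2, tag2, st):
    N = z.shape[0]
    for i in range(N):
        pa = _pick_parent(W, st)
        pb = pa if _rand_f(st) < p_self else _pick_parent(W, st)
        for hap in range(2):
            par = pa if hap == 0 else pb
            c = _randint(2, st)
            g = c
            if _rand_f(st) < r:
                g = 1 - c
            z2[i, hap] = z[par, c]
            tag2[i, hap] = tag[par, c]
            w2[i, hap] = w[par, g]


@njit(cache=False)
def reproduce_m2(z, w, W, r, z2, w2, st):
    # the two enhancer-gene pairs segregate independently (separate
    # chromosome pairs); crossover at rate r within each pair
    N = z.shape[0]
    for i in range(N):
        pa = _pick_parent(W, st)
        pb = _pick_parent(W, st)
        for hap in range(2):
            par = pa if hap == 0 else pb
            for loc in range(2):
                c = _randint(2, st)
                g = c
                if _rand_f(st) < r:
                    g = 1 - c
                z2[i, loc, hap] = z[par, loc, c]
                w2[i, loc, hap] = w[par, loc, g]


@njit(cache=False)
def reproduce_m3(z, w, z_tf, W, r, z2, w2, z_tf2, st):
    # TF locus recombines freely with the enhancer-gene pair
    N = z.shape[0]
    for i in range(N):
        pa = _pick_parent(W, st)
        pb = _pick_parent(W, st)
        for hap in range(2):
            par = pa if hap == 0 else pb
            c = _randint(2, st)
            g = c
            if _rand_f(st) < r:
                g = 1 - c
            z2[i, hap] = z[par, c]
            w2[i, hap] = w[par, g]
            z_tf2[i, hap] = z_tf[par, _randint(2, st)]


# ---------------------------------------------------------------------------
# mutation operators; each returns the number of events drawn
# ---------------------------------------------------------------------------


@njit(cache=False)
def mutate_gene_two_allele(w, u, s, st):
    # one-way wild type -> deleterious; hitting an already-deleterious copy
    # is a no-op, keeping the per-copy rate interpretation
    N = w.shape[0]
    nm = np.random.poisson(2.0 * N * u)
    for _ in range(nm):
        w[_randint(N, st), _randint(2, st)] = 1.0 - s
    return nm


@njit(cache=False)
def mutate_gene_infinite(w, u, s_mean, replace_mode, st):
    # effects ~ Exponential(mean s_mean), redrawn if >= 1 so fitness stays
    # positive; multiplicative accumulation by default, replacement when
    # replace_mode is set
    N = w.shape[0]
    nm = np.random.poisson(2.0 * N * u)
    for _ in range(nm):
        si = np.random.exponential(s_mean)
        while si >= 1.0:
            si = np.random.exponential(s_mean)
        i = _randint(N, st)
        hap = _randint(2, st)
        if replace_mode:
            w[i, hap] = 1.0 - si
        else:
            w[i, hap] *= 1.0 - si
    return nm


@njit(cache=False)
def mutate_trait(z, u, sigma, st):
    # unbiased normal increments on log strength
    N = z.shape[0]
    nm = np.random.poisson(2.0 * N * u)
    for _ in range(nm):
        z[_randint(N, st), _randint(2, st)] += np.random.normal(0.0, sigma)
    return nm


# ---------------------------------------------------------------------------
# fixation-trial protocol (model 1, bi-allelic gene)
# ---------------------------------------------------------------------------


@njit(cache=False)
def burn_in_counts(N, h, s, u, n_gen):
    """Exact genotype-count burn-in with a monomorphic enhancer.

    With one enhancer allele, each offspring's two gene alleles are iid
    draws from the fitness-weighted gamete pool (recombination drops out),
    so genotype counts follow a multinomial whose deleterious-gamete
    probability is ``pi = (n_het*w_het/2 + n_hom*w_hom) / sum(n_g*w_g)``.
    Mutation moves a uniformly chosen copy's carrier between count classes.
    Returns (n wild-type homozygotes, n heterozygotes, n mutant homozygotes).
    """
    w_het = 1.0 - h * s
    w_hom = 1.0 - s
    n0 = N
    n1 = 0
    n2 = 0
    for _ in range(n_gen):
        tot = n0 + n1 * w_het + n2 * w_hom
        pi = (0.5 * n1 * w_het + n2 * w_hom) / tot
        p2 = pi * pi
        nn2 = np.random.binomial(N, p2)
        rem = 1.0 - p2
        if rem > 0.0:
            nn1 = np.random.binomial(N - nn2, 2.0 * pi * (1.0 - pi) / rem)
        else:
            nn1 = 0
        n2 = nn2
        n1 = nn1
        n0 = N - nn2 - nn1
        nm = np.random.poisson(2.0 * N * u)
        for _ in range(nm):
            x = np.random.random() * 2.0 * N
            if x < 2.0 * n0:
                n0 -= 1
                n1 += 1
            elif x < 2.0 * n0 + n1:
                n1 -= 1
                n2 += 1
            # else: hit an already-deleterious copy, no-op
    return n0, n1, n2


@njit(cache=False)
def burn_in_two_allele(N, h, s, u, n_gen, dele, st):
    """Individual-based reference burn-in (used to validate burn_in_counts)."""
    w_het = 1.0 - h * s
    w_hom = 1.0 - s
    dele2 = np.empty_like(dele)
    W = np.empty(N)
    for _ in range(n_gen):
        for i in range(N):
            c = dele[i, 0] + dele[i, 1]
            W[i] = 1.0 if c == 0 else (w_het if c == 1 else w_hom)
        for i in range(N):
            pa = _pick_parent(W, st)
            pb = _pick_parent(W, st)
            dele2[i, 0] = dele[pa, _randint(2, st)]
            dele2[i, 1] = dele[pb, _randint(2, st)]
        nm = np.random.poisson(2.0 * N * u)
        for _ in range(nm):
            dele2[_randint(N, st), _randint(2, st)] = 1
        tmp = dele
        dele = dele2
        dele2 = tmp
    return dele


@njit(cache=False)
def fixation_trial(N, h, s, u, r, ratio, burn_gen, max_gen, seed):
    """One burn-in + mutant-enhancer trial; returns (outcome, generations).

    outcome: 1 fixed, 0 lost, -1 generation cap hit.  During burn-in and
    trial there is no enhancer mutation; the mutant enhancer (strength
    ``ratio`` x resident) is tracked by a tag so the neutral case
    ``ratio == 1`` stays well defined.
    """
    np.random.seed(seed)
    st = _init_state(seed)
    k = -math.log(h) / math.log(2.0)
    n0, n1, n2 = burn_in_counts(N, h, s, u, burn_gen)
    # individuals are exchangeable: lay genotypes out by class
    dele = np.zeros((N, 2), np.uint8)
    idx = 0
    for _ in range(n2):
        dele[idx, 0] = 1
        dele[idx, 1] = 1
        idx += 1
    for _ in range(n1):
        dele[idx, _randint(2, st)] = 1
        idx += 1
    tag = np.zeros((N, 2), np.uint8)
    tag[_randint(N, st), _randint(2, st)] = 1
    tag2 = np.empty_like(tag)
    dele2 = np.empty_like(dele)
    W = np.empty(N)
    w_hom = 1.0 - s
    f_mut = ratio / (1.0 + ratio)  # defective share when a is cis to mutant
    h_mut = f_mut**k
    h_res = (1.0 - f_mut) ** k
    h_bal = 0.5**k
    for t in range(max_gen):
        cnt = 0
        for i in range(N):
            cnt += tag[i, 0] + tag[i, 1]
        if cnt == 0:
            return 0, t
        if cnt == 2 * N:
            return 1, t
        for i in range(N):
            d0 = dele[i, 0]
            d1 = dele[i, 1]
            if d0 == d1:
                W[i] = 1.0 if d0 == 0 else w_hom
            else:
                t_del = tag[i, 0] if d0 == 1 else tag[i, 1]
                t_ok = tag[i, 1] if d0 == 1 else tag[i, 0]
                if t_del == t_ok:
                    W[i] = 1.0 - h_bal * s
                elif t_del == 1:
                    W[i] = 1.0 - h_mut * s
                else:
                    W[i] = 1.0 - h_res * s
        for i in range(N):
            pa = _pick_parent(W, st)
            pb = _pick_parent(W, st)
            for hap in range(2):
                par = pa if hap == 0 else pb
                c = _randint(2, st)
                g = c
                if _rand_f(st) < r:
                    g = 1 - c
                tag2[i, hap] = tag[par, c]
                dele2[i, hap] = dele[par, g]
        nm = np.random.poisson(2.0 * N * u)
        for _ in range(nm):
            dele2[_randint(N, st), _randint(2, st)] = 1
        tmp = tag
        tag = tag2
        tag2 = tmp
        tmpd = dele
        dele = dele2
        dele2 = tmpd
    return -1, max_gen


@njit(cache=False)
def burn_in_deleterious_freq(N, h, s, u, n_gen, seed):
    """Deleterious-allele frequency after a bi-allelic burn-in."""
    np.random.seed(seed)
    n0, n1, n2 = burn_in_counts(N, h, s, u, n_gen)
    return (n1 + 2.0 * n2) / (2.0 * N)


# ---------------------------------------------------------------------------
# escalation drivers (infinite-allele gene, mutating enhancer/TF traits)
# ---------------------------------------------------------------------------


@njit(cache=False)
def escalation_m1(
    N, n_gen, sample_every, h, s_mean, u_gene, u_enh, sigma, r, p_self, seed, out
):
    """Model 1/4 escalation; writes population-mean z per sample into out."""
    np.random.seed(seed)
    st = _init_state(seed)
    k = -math.log(h) / math.log(2.0)
    z = np.zeros((N, 2))
    w = np.ones((N, 2))
    z2 = np.empty_like(z)
    w2 = np.empty_like(w)
    W = np.empty(N)
    prob = np.empty(N)
    alias = np.empty(N, np.int64)
    small = np.empty(N, np.int64)
    large = np.empty(N, np.int64)
    par_s = np.empty((N, 2), np.int64)
    c_s = np.empty((N, 2), np.uint8)
    global_cross = r < _R_GLOBAL
    idx = 0
    for t in range(n_gen + 1):
        if t % sample_every == 0 and idx < out.shape[0]:
            out[idx] = z.mean()
            idx += 1
        if t == n_gen:
            break
        wmax = fitness_m1(z, w, k, W)
        if wmax <= 0.0:
            return -1
        _alias_build(W, prob, alias, small, large)
        for i in range(N):
            pa = _alias_pick(prob, alias, st)
            if p_self > 0.0 and _rand_f(st) < p_self:
                pb = pa
            else:
                pb = _alias_pick(prob, alias, st)
            for hap in range(2):
                par = pa if hap == 0 else pb
                c = _randint(2, st)
                if not global_cross and _rand_f(st) < r:
                    g = 1 - c
                else:
                    g = c
                z2[i, hap] = z[par, c]
                w2[i, hap] = w[par, g]
                par_s[i, hap] = par
                c_s[i, hap] = c
        if global_cross and r > 0.0:
            ncross = np.random.binomial(2 * N, r)
            for _ in range(ncross):
                i = _randint(N, st)
                hap = _randint(2, st)
                par = par_s[i, hap]
                c = c_s[i, hap]
                w2[i, hap] = w[par, 1 - c]
        tmpz = z
        z = z2
        z2 = tmpz
        tmpw = w
        w = w2
        w2 = tmpw
        mutate_gene_infinite(w, u_gene, s_mean, False, st)
        mutate_trait(z, u_enh, sigma, st)
    return idx


@njit(cache=False)
def escalation_m2(
    N, n_gen, sample_every, h, s_mean, u_gene, u_enh, sigma, r, I, seed, out1, out2
):
    """Model 2 (dosage) escalation; per-locus mean z per sample."""
    np.random.seed(seed)
    st = _init_state(seed)
    k = -math.log(h) / math.log(2.0)
    z = np.zeros((N, 2, 2))
    w = np.ones((N, 2, 2))
    z2 = np.empty_like(z)
    w2 = np.empty_like(w)
    W = np.empty(N)
    prob = np.empty(N)
    alias = np.empty(N, np.int64)
    small = np.empty(N, np.int64)
    large = np.empty(N, np.int64)
    par_s = np.empty((N, 2), np.int64)
    c_s = np.empty((N, 2, 2), np.uint8)
    global_cross = r < _R_GLOBAL
    idx = 0
    for t in range(n_gen + 1):
        if t % sample_every == 0 and idx < out1.shape[0]:
            out1[idx] = z[:, 0, :].mean()
            out2[idx] = z[:, 1, :].mean()
            idx += 1
        if t == n_gen:
            break
        wmax = fitness_m2(z, w, k, I, W)
        if wmax <= 0.0:
            return -1
        _alias_build(W, prob, alias, small, large)
        for i in range(N):
            pa = _alias_pick(prob, alias, st)
            pb = _alias_pick(prob, alias, st)
            for hap in range(2):
                par = pa if hap == 0 else pb
                par_s[i, hap] = par
                for loc in range(2):
                    c = _randint(2, st)
                    if not global_cross and _rand_f(st) < r:
                        g = 1 - c
                    else:
                        g = c
                    z2[i, loc, hap] = z[par, loc, c]
                    w2[i, loc, hap] = w[par, loc, g]
                    c_s[i, loc, hap] = c
        if global_cross and r > 0.0:
            ncross = np.random.binomial(4 * N, r)
            for _ in range(ncross):
                i = _randint(N, st)
                loc = _randint(2, st)
                hap = _randint(2, st)
                par = par_s[i, hap]
                c = c_s[i, loc, hap]
                w2[i, loc, hap] = w[par, loc, 1 - c]
        tmpz = z
        z = z2
        z2 = tmpz
        tmpw = w
        w = w2
        w2 = tmpw
        for loc in range(2):
            mutate_gene_infinite(w[:, loc, :], u_gene, s_mean, False, st)
            mutate_trait(z[:, loc, :], u_enh, sigma, st)
    return idx


@njit(cache=False)
def escalation_m3(
    N, n_gen, sample_every, h, s_mean, u_gene, u_enh, u_tf, sigma, r, I, seed, out_e, out_t
):
    """Model 3 (enhancer-TF coevolution) escalation."""
    np.random.seed(seed)
    st = _init_state(seed)
    k = -math.log(h) / math.log(2.0)
    z = np.zeros((N, 2))
    w = np.ones((N, 2))
    z_tf = np.zeros((N, 2))
    z2 = np.empty_like(z)
    w2 = np.empty_like(w)
    z_tf2 = np.empty_like(z_tf)
    W = np.empty(N)
    prob = np.empty(N)
    alias = np.empty(N, np.int64)
    small = np.empty(N, np.int64)
    large = np.empty(N, np.int64)
    par_s = np.empty((N, 2), np.int64)
    c_s = np.empty((N, 2), np.uint8)
    global_cross = r < _R_GLOBAL
    idx = 0
    for t in range(n_gen + 1):
        if t % sample_every == 0 and idx < out_e.shape[0]:
            out_e[idx] = z.mean()
            out_t[idx] = z_tf.mean()
            idx += 1
        if t == n_gen:
            break
        wmax = fitness_m3(z, w, z_tf, k, I, W)
        if wmax <= 0.0:
            return -1
        _alias_build(W, prob, alias, small, large)
        for i in range(N):
            pa = _alias_pick(prob, alias, st)
            pb = _alias_pick(prob, alias, st)
            for hap in range(2):
                par = pa if hap == 0 else pb
                c = _randint(2, st)
                if not global_cross and _rand_f(st) < r:
                    g = 1 - c
                else:
                    g = c
                z2[i, hap] = z[par, c]
                w2[i, hap] = w[par, g]
                z_tf2[i, hap] = z_tf[par, _randint(2, st)]
                par_s[i, hap] = par
                c_s[i, hap] = c
        if global_cross and r > 0.0:
            ncross = np.random.binomial(2 * N, r)
            for _ in range(ncross):
                i = _randint(N, st)
                hap = _randint(2, st)
                par = par_s[i, hap]
                c = c_s[i, hap]
                w2[i, hap] = w[par, 1 - c]
        tmpz = z
        z = z2
        z2 = tmpz
        tmpw = w
        w = w2
        w2 = tmpw
        tmpt = z_tf
        z_tf = z_tf2
        z_tf2 = tmpt
        mutate_gene_infinite(w, u_gene, s_mean, False, st)
        mutate_trait(z, u_enh, sigma, st)
        mutate_trait(z_tf, u_tf, sigma, st)
    return idx
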