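"""Individual-based Wright-Fisher simulation of enhancer-strength evolution.

Two protocols are implemented on top of the compiled life cycle in
:mod:`enhancer_runaway._kernels`:

* **Fixation trials** (model 1, bi-allelic gene): a population monomorphic
  for the wild-type gene and a resident enhancer is burned in for 2000
  generations to mutation-selection balance, a single chromosome then
  receives an enhancer allele whose strength differs by ``strength_ratio``,
  and the mutant is followed to fixation or loss.  No enhancer mutation
  occurs during burn-in or trial.

* **Escalation runs** (models 1-4, infinite alleles at every locus): gene
  mutations multiply allelic fitness by ``1 - s_i`` with ``s_i`` exponential
  (mean ``s_mean``); enhancer (and TF) mutations add normal increments
  (sd ``sigma_E``) to log strength.  All strengths start at ``e0 = 1``
  (``z = 0``) and the population mean of ``z`` is recorded at a fixed
  sampling interval.

Model layouts: 1 — enhancer + gene, constant total expression; 2 — two
independent enhancer-gene pairs with stabilizing selection on the dosage
``Z1 - Z2``; 3 — enhancer + gene plus a freely recombining TF locus with
stabilizing selection on ``Z1 + Z2``; 4 — model 1 with partial selfing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import _kernels as _k
from .core_model import (
    DegenerateStateError,
    InvalidParameterError,
    ModelParams,
    dominance_exponent,
    stabilizing_intensity,
)

__all__ = [
    "TrialTimeoutError",
    "Population",
    "FixationTrialResult",
    "FixationEstimate",
    "EscalationResult",
    "seed_kernels",
    "life_cycle_step",
    "mutate_gene",
    "mutate_enhancer",
    "mutate_tf",
    "run_fixation_trial",
    "estimate_fixation_probability",
    "burn_in_deleterious_frequency",
    "run_escalation",
]

_SEED_MOD = 2**31


class TrialTimeoutError(RuntimeError):
    """A fixation trial exceeded its hard generation cap."""


def _derive_seeds(master: int, n: int) -> np.ndarray:
    """Deterministic per-replicate 31-bit seeds from one master seed."""
    return (np.random.SeedSequence(master).generate_state(n) % _SEED_MOD).astype(np.int64)


# uniform-deviate stream used by the single-step API (long-run drivers hold
# their own per-replicate streams)
_STATE = np.array([0x853C49E6748FEA9B], dtype=np.uint64)


def seed_kernels(seed: int) -> None:
    """Seed the compiled engine's RNG streams (for single-step use)."""
    s = int(seed) % _SEED_MOD
    _k.seed_rng(s)
    _STATE[0] = np.uint64(s)


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """N diploid individuals; array layout depends on the model.

    ``z`` and ``w`` are (N, 2) for models 1/3/4 and (N, 2, 2) — indexed
    (individual, locus, haplotype) — for model 2.  ``tag`` optionally marks
    enhancer alleles (used to follow a mutant lineage); ``z_tf`` is the TF
    locus of model 3.  Cis relationships live in the shared last axis and
    are only broken by explicit recombination.
    """

    model: int
    z: np.ndarray
    w: np.ndarray
    tag: np.ndarray | None = None
    z_tf: np.ndarray | None = None
    generation: int = 0

    @classmethod
    def monomorphic(cls, params: ModelParams, model: int = 1) -> "Population":
        """All-wild-type population with every strength at e0 = 1 (z = 0)."""
        N = params.N_pop
        if model in (1, 4):
            return cls(
                model=model,
                z=np.zeros((N, 2)),
                w=np.ones((N, 2)),
                tag=np.zeros((N, 2), np.uint8),
            )
        if model == 2:
            return cls(model=2, z=np.zeros((N, 2, 2)), w=np.ones((N, 2, 2)))
        if model == 3:
            return cls(
                model=3, z=np.zeros((N, 2)), w=np.ones((N, 2)), z_tf=np.zeros((N, 2))
            )
        raise InvalidParameterError(f"model must be 1-4, got {model}")

    @property
    def N(self) -> int:
        return self.z.shape[0]

    @property
    def mean_z(self) -> float:
        """Population mean log enhancer strength (over all enhancer copies)."""
        return float(self.z.mean())

    def mutant_frequency(self) -> float:
        if self.tag is None:
            raise InvalidParameterError("population carries no mutant tag")
        return float(self.tag.mean())


def _intensity(params: ModelParams) -> float:
    if params.gamma == 0.0:
        return 0.0
    return stabilizing_intensity(
        params.gamma, params.u_gene, params.h, params.s_mean, params.sigma_E
    )


# ---------------------------------------------------------------------------
# single-generation API (unit-level building blocks)
# ---------------------------------------------------------------------------


def life_cycle_step(
    pop: Population, params: ModelParams, gene_mode: str = "infinite_allele"
) -> Population:
    """One full generation: selection, meiosis, mutation, syngamy.

    Uses the same compiled fitness/reproduction/mutation routines as the
    long-run drivers.  Mutation rates are taken from ``params``; set a rate
    to 0 to disable that mutation class.  The kernel RNG stream must have
    been seeded (see :func:`seed_kernels`).
    """
    k = dominance_exponent(params.h)
    N = pop.N
    W = np.empty(N)
    if pop.model in (1, 4):
        wmax = _k.fitness_m1(pop.z, pop.w, k, W)
        if wmax <= 0.0:
            raise DegenerateStateError("all individual fitnesses are zero")
        z2 = np.empty_like(pop.z)
        w2 = np.empty_like(pop.w)
        tag = pop.tag if pop.tag is not None else np.zeros((N, 2), np.uint8)
        tag2 = np.empty_like(tag)
        _k.reproduce_m1(pop.z, pop.w, tag, W, params.r, params.p_self, z2, w2, tag2, _STATE)
        new = Population(pop.model, z2, w2, tag2, None, pop.generation + 1)
    elif pop.model == 2:
        wmax = _k.fitness_m2(pop.z, pop.w, k, _intensity(params), W)
        if wmax <= 0.0:
            raise DegenerateStateError("all individual fitnesses are zero")
        z2 = np.empty_like(pop.z)
        w2 = np.empty_like(pop.w)
        _k.reproduce_m2(pop.z, pop.w, W, params.r, z2, w2, _STATE)
        new = Population(2, z2, w2, None, None, pop.generation + 1)
    elif pop.model == 3:
        wmax = _k.fitness_m3(pop.z, pop.w, pop.z_tf, k, _intensity(params), W)
        if wmax <= 0.0:
            raise DegenerateStateError("all individual fitnesses are zero")
        z2 = np.empty_like(pop.z)
        w2 = np.empty_like(pop.w)
        zt2 = np.empty_like(pop.z_tf)
        _k.reproduce_m3(pop.z, pop.w, pop.z_tf, W, params.r, z2, w2, zt2, _STATE)
        new = Population(3, z2, w2, None, zt2, pop.generation + 1)
    else:
        raise InvalidParameterError(f"model must be 1-4, got {pop.model}")
    mutate_gene(new, params, gene_mode)
    mutate_enhancer(new, params)
    if new.model == 3:
        mutate_tf(new, params)
    return new


def mutate_gene(pop: Population, params: ModelParams, mode: str = "infinite_allele") -> int:
    """Apply one round of gene mutation in place; returns the event count.

    A Poisson(2*N*u_gene) number of uniformly chosen allele copies is hit
    (with replacement).  ``two_allele``: the copy becomes deleterious with
    fitness 1-s (no-op if it already is).  ``infinite_allele``: the copy's
    fitness is multiplied by 1-s_i, s_i ~ Exponential(mean s_mean) truncated
    below 1.
    """
    if params.u_gene == 0.0:
        return 0
    targets = [pop.w] if pop.w.ndim == 2 else [pop.w[:, 0, :], pop.w[:, 1, :]]
    n = 0
    for arr in targets:
        if mode == "two_allele":
            n += _k.mutate_gene_two_allele(arr, params.u_gene, params.s_mean, _STATE)
        elif mode == "infinite_allele":
            n += _k.mutate_gene_infinite(arr, params.u_gene, params.s_mean, False, _STATE)
        else:
            raise InvalidParameterError(f"unknown gene mutation mode {mode!r}")
    return n


def mutate_enhancer(pop: Population, params: ModelParams) -> int:
    """Poisson(2*N*u_enh) normal increments on log enhancer strength."""
    if params.u_enh == 0.0:
        return 0
    targets = [pop.z] if pop.z.ndim == 2 else [pop.z[:, 0, :], pop.z[:, 1, :]]
    return sum(_k.mutate_trait(arr, params.u_enh, params.sigma_E, _STATE) for arr in targets)


def mutate_tf(pop: Population, params: ModelParams) -> int:
    """Poisson(2*N*u_tf) normal increments on log TF strength (model 3)."""
    if pop.z_tf is None:
        raise InvalidParameterError("population has no TF locus")
    if params.u_tf == 0.0:
        return 0
    return _k.mutate_trait(pop.z_tf, params.u_tf, params.sigma_E, _STATE)


# ---------------------------------------------------------------------------
# fixation-trial protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixationTrialResult:
    outcome: str  # "fixed" | "lost"
    generations: int
    strength_ratio: float
    params: ModelParams


def run_fixation_trial(
    params: ModelParams,
    strength_ratio: float,
    seed: int | None = None,
    burn_in: int = 2000,
    max_gen: int = 1_000_000,
) -> FixationTrialResult:
    """Burn in, introduce one mutant-enhancer copy, follow it to absorption."""
    if not strength_ratio > 0.0:
        raise InvalidParameterError("strength_ratio must be > 0")
    if seed is None:
        seed = params.seed
    outcome, gens = _k.fixation_trial(
        params.N_pop,
        params.h,
        params.s_mean,
        params.u_gene,
        params.r,
        float(strength_ratio),
        burn_in,
        max_gen,
        int(seed) % _SEED_MOD,
    )
    if outcome < 0:
        raise TrialTimeoutError(f"trial still segregating after {max_gen} generations")
    return FixationTrialResult(
        "fixed" if outcome == 1 else "lost", int(gens), strength_ratio, params
    )


@dataclass(frozen=True)
class FixationEstimate:
    p_fix: float
    ci_low: float
    ci_high: float
    ratio_to_neutral: float
    ratio_ci_low: float
    ratio_ci_high: float
    n_fixed: int
    n_trials: int
    outcomes: np.ndarray

    def summary(self) -> str:
        return (
            f"{self.n_fixed}/{self.n_trials} fixed; "
            f"p_fix = {self.p_fix:.3e} (95% CI {self.ci_low:.3e}-{self.ci_high:.3e}); "
            f"ratio to neutral = {self.ratio_to_neutral:.3g} "
            f"({self.ratio_ci_low:.3g}-{self.ratio_ci_high:.3g})"
        )


def estimate_fixation_probability(
    params: ModelParams,
    strength_ratio: float,
    n_trials: int,
    seed: int | None = None,
    burn_in: int = 2000,
    max_gen: int = 1_000_000,
) -> FixationEstimate:
    """Monte-Carlo fixation probability over independent trials.

    Each trial runs its own burn-in from a deterministically derived seed.
    Returns the fixation fraction with a Wilson 95% CI and the ratio to the
    neutral expectation ``1/(2*N_pop)``.
    """
    if n_trials < 100:
        raise InvalidParameterError("n_trials must be >= 100")
    if seed is None:
        seed = params.seed
    seeds = _derive_seeds(int(seed), n_trials)
    outcomes = np.empty(n_trials, np.uint8)
    for j in range(n_trials):
        res = run_fixation_trial(
            params, strength_ratio, seed=int(seeds[j]), burn_in=burn_in, max_gen=max_gen
        )
        outcomes[j] = 1 if res.outcome == "fixed" else 0
    n_fixed = int(outcomes.sum())
    p_fix = n_fixed / n_trials
    lo, hi = proportion_confint(n_fixed, n_trials, alpha=0.05, method="wilson")
    two_n = 2.0 * params.N_pop
    return FixationEstimate(
        p_fix, float(lo), float(hi), p_fix * two_n, float(lo) * two_n, float(hi) * two_n,
        n_fixed, n_trials, outcomes,
    )


def burn_in_deleterious_frequency(
    params: ModelParams, seed: int | None = None, burn_in: int = 2000
) -> float:
    """Deleterious-allele frequency after one bi-allelic burn-in."""
    if seed is None:
        seed = params.seed
    return float(
        _k.burn_in_deleterious_freq(
            params.N_pop, params.h, params.s_mean, params.u_gene, burn_in,
            int(seed) % _SEED_MOD,
        )
    )


# ---------------------------------------------------------------------------
# escalation protocol
# ---------------------------------------------------------------------------


@dataclass
class EscalationResult:
    """Replicate trajectories of population-mean log strength.

    ``mean_z`` has shape (n_iter, T).  For model 2, ``mean_z`` averages the
    two enhancer loci, whose per-locus series are in ``mean_z1``/``mean_z2``.
    For model 3 ``mean_z`` is the enhancer locus and ``mean_z_tf`` the TF.
    """

    model: int
    params: ModelParams
    sample_every: int
    generations: np.ndarray
    mean_z: np.ndarray
    mean_z1: np.ndarray | None = None
    mean_z2: np.ndarray | None = None
    mean_z_tf: np.ndarray | None = None

    def to_frame(self):
        """Tidy per-replicate trajectory table (for TSV export)."""
        import pandas as pd

        n_iter, T = self.mean_z.shape
        frames = {
            "iteration": np.repeat(np.arange(n_iter), T),
            "generation": np.tile(self.generations, n_iter),
            "mean_z": self.mean_z.ravel(),
        }
        if self.mean_z1 is not None:
            frames["mean_Z1"] = self.mean_z1.ravel()
            frames["mean_Z2"] = self.mean_z2.ravel()
        if self.mean_z_tf is not None:
            frames["mean_Z_tf"] = self.mean_z_tf.ravel()
        return pd.DataFrame(frames)


def run_escalation(
    params: ModelParams, model: int = 1, sample_every: int = 100
) -> EscalationResult:
    """Long-term strength evolution under recurrent enhancer mutation.

    Runs ``params.n_iter`` independent replicates of ``params.n_gen``
    generations each (replicate seeds derived from ``params.seed``) and
    records population-mean log strength every ``sample_every`` generations.
    """
    if model not in (1, 2, 3, 4):
        raise InvalidParameterError(f"model must be 1-4, got {model}")
    n_samp = params.n_gen // sample_every + 1
    gens = np.arange(n_samp) * sample_every
    seeds = _derive_seeds(params.seed, params.n_iter)
    I = _intensity(params)
    mz = np.empty((params.n_iter, n_samp))
    mz1 = mz2 = mzt = None
    if model == 2:
        mz1 = np.empty_like(mz)
        mz2 = np.empty_like(mz)
    if model == 3:
        mzt = np.empty_like(mz)
    for j in range(params.n_iter):
        sj = int(seeds[j])
        if model in (1, 4):
            p_self = params.p_self if model == 4 else 0.0
            rc = _k.escalation_m1(
                params.N_pop, params.n_gen, sample_every, params.h, params.s_mean,
                params.u_gene, params.u_enh, params.sigma_E, params.r, p_self, sj, mz[j],
            )
        elif model == 2:
            rc = _k.escalation_m2(
                params.N_pop, params.n_gen, sample_every, params.h, params.s_mean,
                params.u_gene, params.u_enh, params.sigma_E, params.r, I, sj,
                mz1[j], mz2[j],
            )
            mz[j] = 0.5 * (mz1[j] + mz2[j])
        else:
            rc = _k.escalation_m3(
                params.N_pop, params.n_gen, sample_every, params.h, params.s_mean,
                params.u_gene, params.u_enh, params.u_tf, params.sigma_E, params.r, I,
                sj, mz[j], mzt[j],
            )
        if rc < 0:
            raise DegenerateStateError(f"replicate {j}: all fitnesses collapsed to zero")
    return EscalationResult(model, params, sample_every, gens, mz, mz1, mz2, mzt)
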