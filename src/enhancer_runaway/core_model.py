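"""Fitness and dominance calculus for cis-regulated diploid loci.

In a diploid, each gene copy is driven by the enhancer sitting in *cis* on
the same chromosome.  When total expression is buffered (e.g. by a negative
feedback loop), an enhancer of strength ``e1`` facing an enhancer of strength
``e2`` on the homolog contributes a fraction ``e1 / (e1 + e2)`` of the
protein pool.  A deleterious gene allele therefore produces more (or less)
defective protein when linked to the stronger (or weaker) enhancer, which
shifts its *effective* dominance away from the baseline ``h``.

Fitness is a concave, monotonically decreasing power function of the
defective-protein fraction ``f``::

    W(f) = 1 - s * f ** kappa,        kappa = -log(h) / log(2)

so that ``W(1/2) = 1 - h*s`` recovers the usual heterozygote fitness, and
``h = 1/2`` recovers additivity.  Concavity (partial recessivity, ``h < 1/2``)
makes the mean of the two effective dominances exceed ``h`` whenever the two
enhancers differ in strength (Jensen's inequality) — the engine of the
runaway process modelled by the rest of the package.

Strengths are handled on the natural-log scale, ``z = ln(e)``, everywhere:
the exponent ``kappa`` is base-invariant and additive mutation on ``z`` keeps
relative strength variation from vanishing as strengths escalate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "InvalidParameterError",
    "DegenerateStateError",
    "ModelParams",
    "EnhancerAllele",
    "GeneAllele",
    "Haplotype",
    "DiploidGenotype",
    "dominance_exponent",
    "fitness_from_fraction",
    "effective_dominances",
    "EffectiveDominance",
    "gene_pair_fitness",
    "genotype_fitness_gene",
    "stabilizing_intensity",
    "stabilizing_fitness",
]


class InvalidParameterError(ValueError):
    """A parameter is outside its admissible domain."""


class DegenerateStateError(RuntimeError):
    """A dynamical state from which the model cannot proceed (e.g. zero mass)."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """All rates, sizes and intensities of models 1-4, in one place.

    Parameters
    ----------
    s_mean : float
        Selection coefficient against deleterious gene alleles.  In the
        bi-allelic mode this is *the* selection coefficient ``s``; in the
        infinite-allele mode it is the mean of the exponential distribution
        of per-mutation effects.
    h : float
        Baseline dominance of deleterious mutations (0.25 is the canonical
        value for mildly deleterious mutations).
    u_gene, u_enh, u_tf : float
        Mutation rates per allele copy per generation at the gene, enhancer
        and transcription-factor loci (Poisson expectation ``2*N_pop*u`` events
        per generation).
    r : float
        Recombination rate between an enhancer and its cis gene, per meiosis.
    r_TE : float
        Recombination rate between the TF locus and the enhancer-gene block
        (model 3).  Fixed at 0.5 — the TF segregates independently.
    N_pop : int
        Number of diploid individuals.
    sigma_E : float
        Standard deviation of the normal mutational increments applied to
        log enhancer (and TF) strength.
    gamma : float
        Scaling of stabilizing-selection intensity against the per-generation
        fitness cost of gene mutation, ``u*h*s`` (models 2 and 3); 0 switches
        stabilizing selection off.
    p_self : float
        Probability that an individual self-fertilizes, i.e. that its second
        gamete is sampled from the same parent (model 4).
    n_gen : int
        Generations per escalation run.
    n_iter : int
        Independent replicates per escalation experiment.
    seed : int
        Master RNG seed; replicate ``j`` uses a deterministically derived
        stream.
    """

    s_mean: float = 0.1
    h: float = 0.25
    u_gene: float = 1e-3
    u_enh: float = 1e-3
    u_tf: float = 1e-3
    r: float = 1e-6
    r_TE: float = 0.5
    N_pop: int = 5000
    sigma_E: float = 0.1
    gamma: float = 0.0
    p_self: float = 0.0
    n_gen: int = 100_000
    n_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.h < 1.0:
            raise InvalidParameterError(f"h must be in (0, 1), got h={self.h}")
        if not 0.0 < self.s_mean <= 1.0:
            raise InvalidParameterError(
                f"s_mean must be in (0, 1], got s_mean={self.s_mean}"
            )
        for name in ("u_gene", "u_enh", "u_tf"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.r <= 0.5:
            raise InvalidParameterError(f"r must be in [0, 0.5], got r={self.r}")
        if not 0.0 <= self.r_TE <= 0.5:
            raise InvalidParameterError(f"r_TE must be in [0, 0.5], got r_TE={self.r_TE}")
        if not 0.0 <= self.p_self <= 1.0:
            raise InvalidParameterError(f"p_self must be in [0, 1], got p_self={self.p_self}")
        if self.N_pop < 2:
            raise InvalidParameterError(f"N_pop must be >= 2, got N_pop={self.N_pop}")
        if self.u_enh > 0.0 and not self.sigma_E > 0.0:
            raise InvalidParameterError("sigma_E must be > 0 when enhancer mutation is active")
        if self.gamma < 0.0:
            raise InvalidParameterError(f"gamma must be >= 0, got gamma={self.gamma}")
        if self.gamma * self.u_gene * self.h * self.s_mean >= 1.0:
            raise InvalidParameterError(
                "gamma*u_gene*h*s_mean must be < 1 for the stabilizing intensity to be defined"
            )
        if self.n_gen < 1 or self.n_iter < 1:
            raise InvalidParameterError("n_gen and n_iter must be >= 1")


# ---------------------------------------------------------------------------
# domain types (reference single-pair layout; simulators use flat arrays)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnhancerAllele:
    """An enhancer allele, stored as log strength ``z = ln(e)``."""

    z: float

    @property
    def e(self) -> float:
        """Strength on the natural scale; always positive."""
        return math.exp(self.z)

    @classmethod
    def from_strength(cls, e: float) -> "EnhancerAllele":
        if not e > 0.0:
            raise InvalidParameterError(f"enhancer strength must be > 0, got {e}")
        return cls(z=math.log(e))


@dataclass(frozen=True)
class GeneAllele:
    """A gene allele carrying its marginal fitness value ``w`` in (0, 1]."""

    w: float

    def __post_init__(self) -> None:
        if not 0.0 < self.w <= 1.0:
            raise InvalidParameterError(f"gene allele fitness must be in (0, 1], got {self.w}")


@dataclass(frozen=True)
class Haplotype:
    """One chromosome: an enhancer allele in cis with its gene allele."""

    enhancer: EnhancerAllele
    gene: GeneAllele


@dataclass(frozen=True)
class DiploidGenotype:
    """Two haplotypes; cis pairing is preserved except through recombination."""

    hap1: Haplotype
    hap2: Haplotype


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def dominance_exponent(h: float) -> float:
    """Exponent ``kappa = -log(h)/log(2)`` of the concave fitness map.

    ``kappa = 1`` for the additive case ``h = 1/2``; ``kappa > 1`` (concavity)
    for partially recessive mutations ``h < 1/2``.
    """
    if not 0.0 < h < 1.0:
        raise InvalidParameterError(f"h must be in (0, 1), got h={h}")
    return -math.log(h) / math.log(2.0)


def fitness_from_fraction(f_a, h: float, s: float):
    """Fitness of a genotype producing a fraction ``f_a`` of defective protein.

    ``W = 1 - s * f_a ** kappa`` — monotone decreasing in ``f_a``, concave for
    ``h < 1/2``, with ``W(0) = 1``, ``W(1/2) = 1 - h*s`` and ``W(1) = 1 - s``.

    Accepts scalars or arrays for ``f_a``.
    """
    f = np.asarray(f_a, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise InvalidParameterError("f_a must lie in [0, 1]")
    if not 0.0 <= s <= 1.0:
        raise InvalidParameterError(f"s must be in [0, 1], got s={s}")
    kappa = dominance_exponent(h)
    w = 1.0 - s * f**kappa
    return float(w) if np.isscalar(f_a) else w


class EffectiveDominance(NamedTuple):
    h1: float
    h2: float
    Delta_h: float
    delta_h: float
    swapped: bool


def effective_dominances(e1: float, e2: float, h: float) -> EffectiveDominance:
    """Effective dominances of a deleterious allele linked to each enhancer.

    With the weaker/stronger strengths ``e1 <= e2`` (inputs are swapped if
    given in the other order; ``swapped`` reports this),

    ``h1 = (e1/(e1+e2))**kappa`` (deleterious allele cis to the weaker
    enhancer) and ``h2 = (e2/(e1+e2))**kappa`` (cis to the stronger one).
    ``Delta_h = (h1+h2)/2 - h`` is the excess mean dominance created by the
    enhancer polymorphism (>= 0, zero iff ``e1 == e2`` or ``h == 1/2``) and
    ``delta_h = h2 - h1`` the dominance contrast.
    """
    if not (e1 > 0.0 and e2 > 0.0):
        raise InvalidParameterError("enhancer strengths must be > 0")
    swapped = e2 < e1
    if swapped:
        e1, e2 = e2, e1
    kappa = dominance_exponent(h)
    tot = e1 + e2
    h1 = (e1 / tot) ** kappa
    h2 = (e2 / tot) ** kappa
    return EffectiveDominance(h1, h2, (h1 + h2) / 2.0 - h, h2 - h1, swapped)


def gene_pair_fitness(w_a: float, w_b: float, e_a: float, e_b: float, h: float) -> float:
    """Fitness contribution of one enhancer-gene pair of a diploid.

    ``w_a`` (``w_b``) is the fitness value of the gene allele in cis with the
    enhancer of strength ``e_a`` (``e_b``).  With ``w1 >= w2`` the relabelled
    fitnesses, the defective fraction is the expression share of the less-fit
    allele and ``W = w1 - f ** kappa * (w1 - w2)``.  When ``w_a == w_b`` the
    enhancers are irrelevant and ``W = w_a`` exactly.
    """
    if w_a == w_b:
        return w_a
    if w_a > w_b:
        w1, w2, f = w_a, w_b, e_b / (e_a + e_b)
    else:
        w1, w2, f = w_b, w_a, e_a / (e_a + e_b)
    kappa = dominance_exponent(h)
    return w1 - f**kappa * (w1 - w2)


def genotype_fitness_gene(genotype: DiploidGenotype, h: float) -> float:
    """Gene-locus fitness of a diploid genotype (single enhancer-gene pair)."""
    g = genotype
    return gene_pair_fitness(
        g.hap1.gene.w, g.hap2.gene.w, g.hap1.enhancer.e, g.hap2.enhancer.e, h
    )


def stabilizing_intensity(
    gamma: float, u_gene: float, h: float, s_mean: float, sigma_E: float
) -> float:
    """Intensity ``I`` of stabilizing selection on summed log strengths.

    Calibrated so that the expected fitness cost of one round of random
    enhancer mutation, ``1 - exp(-I * 4*sigma_E**2)``, equals ``gamma`` times
    the cost ``u*h*s`` of one round of gene mutation::

        I = -ln(1 - gamma*u*h*s) / (4 * sigma_E**2)

    ``I = 0`` for ``gamma = 0``; ``I`` is strictly increasing in ``gamma``.
    """
    if not sigma_E > 0.0:
        raise InvalidParameterError("sigma_E must be > 0")
    if gamma < 0.0:
        raise InvalidParameterError("gamma must be >= 0")
    arg = 1.0 - gamma * u_gene * h * s_mean
    if arg <= 0.0:
        raise InvalidParameterError(
            "gamma*u_gene*h*s_mean must be < 1 for the stabilizing intensity to be defined"
        )
    return -math.log(arg) / (4.0 * sigma_E**2)


def stabilizing_fitness(Z1: float, Z2: float, I: float, mode: str = "dosage") -> float:
    """Stabilizing-selection fitness component on summed log strengths.

    mode ``"dosage"`` (model 2): ``W_E = exp(-I * (Z1 - Z2)**2)`` — selection
    on the expression *ratio* of two genes, optimum at equal dosage.
    mode ``"absolute"`` (model 3): ``W_E = exp(-I * (Z1 + Z2)**2)`` — the
    summed TF log strength ``Z2`` must oppose the summed enhancer log
    strength ``Z1``; optimum at ``Z1 + Z2 = 0``.
    """
    if I < 0.0:
        raise InvalidParameterError("stabilizing intensity I must be >= 0")
    if mode == "dosage":
        d = Z1 - Z2
    elif mode == "absolute":
        d = Z1 + Z2
    else:
        raise InvalidParameterError(f"unknown stabilizing mode {mode!r}")
    return math.exp(-I * d * d)
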