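"""Synthetic diverged bison populations, hybrid crosses and trios.

Reference allele frequencies for the two subspecies are generated under the
Balding-Nichols model: given an ancestral frequency ``p`` and a
differentiation parameter ``Fst``, each daughter population's frequency is
Beta-distributed with shapes ``p (1 - Fst) / Fst`` and
``(1 - p)(1 - Fst) / Fst``.  Loci are rejection-sampled until the absolute
frequency difference between the two populations reaches a floor, emulating
the allelic-differentiation screen used to pick composition SNPs.

Genotypes are sampled per locus with unlinked loci (panel SNPs are thinned
and LD-pruned, so downstream statistics assume independence anyway).  The
per-locus sampling rules give each cross type its textbook marginal
distribution:

====== =============================================================
PURE_P Binomial(2, f_P)
PURE_W Binomial(2, f_W)
F1     Bernoulli(f_P) + Bernoulli(f_W)
F2     two alleles Bernoulli((f_P + f_W) / 2)   (gametes of random F1s)
BC_P   Bernoulli((f_P + f_W) / 2) + Bernoulli(f_P)
BC_W   Bernoulli((f_P + f_W) / 2) + Bernoulli(f_W)
====== =============================================================

The default study scenario mirrors the validation design: 17,018 composition
loci at Fst 0.15 with |f_P - f_W| >= 0.2, reference groups of 203 plains and
57 wood animals, and 500 animals per simulated population.  All randomness
flows through a single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import ReferenceFrequencies, reference_freqs
from .genotype_io import GenotypeMatrix, SampleRecord


class CrossType(str, Enum):
    PURE_P = "pure_plains"
    PURE_W = "pure_wood"
    F1 = "f1"
    F2 = "f2"
    BC_P = "backcross_plains"
    BC_W = "backcross_wood"


#: Expected plains genome fraction of each cross type.
TRUE_PLAINS_FRACTION: dict[CrossType, float] = {
    CrossType.PURE_P: 1.0,
    CrossType.PURE_W: 0.0,
    CrossType.F1: 0.5,
    CrossType.F2: 0.5,
    CrossType.BC_P: 0.75,
    CrossType.BC_W: 0.25,
}


@dataclass(frozen=True)
class DivergenceModel:
    """Parameters of the two-population divergence generator."""

    m: int = 17_018
    fst: float = 0.15
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    min_abs_freq_diff: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 <= self.min_abs_freq_diff < 1.0:
            raise ValueError("min_abs_freq_diff must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("ancestral_freq_range must be within [0, 1]")


@dataclass
class SimulatedPopulation:
    cross_type: CrossType
    n: int
    gm: GenotypeMatrix
    true_plains_fraction: float


@dataclass
class TrioSet:
    """Simulated parent-offspring trios with a truth table.

    ``gm`` holds dams, sires and offspring; ``truth`` maps each offspring to
    its true parents."""

    gm: GenotypeMatrix
    dam_ids: list[str]
    sire_ids: list[str]
    offspring_ids: list[str]
    truth: pd.DataFrame


def simulate_divergent_freqs(model: DivergenceModel) -> ReferenceFrequencies:
    """Draw diverged (f_P, f_W) reference frequency vectors.

    Balding-Nichols sampling with rejection until
    ``|f_P - f_W| >= model.min_abs_freq_diff``; raises if the acceptance
    rate falls below 0.1% (infeasible parameter combination).
    """
    rng = np.random.default_rng(model.seed)
    lo, hi = model.ancestral_freq_range
    scale = (1.0 - model.fst) / model.fst
    collected_p: list[np.ndarray] = []
    collected_w: list[np.ndarray] = []
    n_have = 0
    n_drawn = 0
    while n_have < model.m:
        batch = max(4 * (model.m - n_have), 1024)
        anc = rng.uniform(lo, hi, size=batch)
        a = np.maximum(anc * scale, 1e-12)
        b = np.maximum((1.0 - anc) * scale, 1e-12)
        f_p = rng.beta(a, b)
        f_w = rng.beta(a, b)
        keep = np.abs(f_p - f_w) >= model.min_abs_freq_diff
        n_drawn += batch
        n_have += int(keep.sum())
        collected_p.append(f_p[keep])
        collected_w.append(f_w[keep])
        if n_drawn >= max(100_000, 1000 * model.m) and n_have / n_drawn < 0.001:
            raise RuntimeError(
                "rejection sampling acceptance below 0.1%; relax "
                "min_abs_freq_diff or increase fst"
            )
    f_p = np.concatenate(collected_p)[: model.m]
    f_w = np.concatenate(collected_w)[: model.m]
    ids = [f"snp{j + 1:06d}" for j in range(model.m)]
    return ReferenceFrequencies(locus_ids=ids, f_p=f_p, f_w=f_w, n_p=0, n_w=0)


def _allele_freq_pair(
    ref: ReferenceFrequencies, cross_type: CrossType
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus success probabilities of the two transmitted alleles."""
    mid = (ref.f_p + ref.f_w) / 2.0
    return {
        CrossType.PURE_P: (ref.f_p, ref.f_p),
        CrossType.PURE_W: (ref.f_w, ref.f_w),
        CrossType.F1: (ref.f_p, ref.f_w),
        CrossType.F2: (mid, mid),
        CrossType.BC_P: (mid, ref.f_p),
        CrossType.BC_W: (mid, ref.f_w),
    }[cross_type]


def _draw_genotypes(
    ref: ReferenceFrequencies,
    cross_type: CrossType,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    fa, fb = _allele_freq_pair(ref, cross_type)
    a = rng.random((n, ref.m)) < fa
    b = rng.random((n, ref.m)) < fb
    return (a.astype(np.int8) + b.astype(np.int8))


def simulate_population(
    ref: ReferenceFrequencies,
    cross_type: CrossType | str,
    n: int,
    seed: int | None = None,
    sample_prefix: str | None = None,
) -> SimulatedPopulation:
    """Simulate ``n`` animals of one cross type from reference frequencies."""
    cross_type = CrossType(cross_type)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dosages = _draw_genotypes(ref, cross_type, n, rng)
    prefix = sample_prefix or cross_type.value
    gm = GenotypeMatrix(
        sample_ids=[f"{prefix}_{i + 1:04d}" for i in range(n)],
        locus_ids=list(ref.locus_ids),
        dosages=dosages,
    )
    return SimulatedPopulation(
        cross_type=cross_type,
        n=n,
        gm=gm,
        true_plains_fraction=TRUE_PLAINS_FRACTION[cross_type],
    )


def _mendelian_offspring(
    dams: np.ndarray, sires: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One offspring per dam/sire row: a uniform allele from each parent."""

    def gamete(parents: np.ndarray) -> np.ndarray:
        # dosage 0 -> allele 0, dosage 2 -> allele 1, het -> fair coin
        coin = rng.random(parents.shape) < 0.5
        return np.where(parents == 1, coin, parents == 2).astype(np.int8)

    return gamete(dams) + gamete(sires)


def simulate_trios(
    ref: ReferenceFrequencies,
    population: CrossType | str = CrossType.PURE_P,
    n_trios: int = 100,
    genotyping_error_rate: float = 0.0,
    seed: int | None = None,
) -> TrioSet:
    """Simulate parent-offspring trios within one population.

    Parents are drawn from the population's genotype distribution; each
    offspring receives one uniformly chosen allele from each parent per
    locus.  With probability ``genotyping_error_rate`` a reported genotype
    (any member) is replaced by an independent draw from the population
    genotype distribution."""
    population = CrossType(population)
    rng = np.random.default_rng(seed)
    dams = _draw_genotypes(ref, population, n_trios, rng)
    sires = _draw_genotypes(ref, population, n_trios, rng)
    kids = _mendelian_offspring(dams, sires, rng)

    if genotyping_error_rate > 0.0:
        for block in (dams, sires, kids):
            err = rng.random(block.shape) < genotyping_error_rate
            replacement = _draw_genotypes(ref, population, block.shape[0], rng)
            block[err] = replacement[err]

    dam_ids = [f"dam_{i + 1:04d}" for i in range(n_trios)]
    sire_ids = [f"sire_{i + 1:04d}" for i in range(n_trios)]
    kid_ids = [f"kid_{i + 1:04d}" for i in range(n_trios)]
    gm = GenotypeMatrix(
        sample_ids=dam_ids + sire_ids + kid_ids,
        locus_ids=list(ref.locus_ids),
        dosages=np.vstack([dams, sires, kids]),
    )
    truth = pd.DataFrame(
        {"offspring_id": kid_ids, "dam_id": dam_ids, "sire_id": sire_ids}
    )
    return TrioSet(
        gm=gm, dam_ids=dam_ids, sire_ids=sire_ids, offspring_ids=kid_ids, truth=truth
    )


# ---------------------------------------------------------------------------
# The full study scenario
# ---------------------------------------------------------------------------


@dataclass
class StudySimulation:
    """Everything the validation-style analysis needs, from one seed."""

    true_freqs: ReferenceFrequencies
    reference_gm: GenotypeMatrix
    reference_metadata: list[SampleRecord]
    ref_freqs: ReferenceFrequencies  # estimated from the reference animals
    populations: dict[CrossType, SimulatedPopulation]


def simulate_study(
    seed: int,
    m: int = 17_018,
    fst: float = 0.15,
    min_abs_freq_diff: float = 0.2,
    n_plains_ref: int = 203,
    n_wood_ref: int = 57,
    n_per_population: int = 500,
    cross_types: Sequence[CrossType] = tuple(CrossType),
) -> StudySimulation:
    """Run the default study scenario end to end.

    True diverged frequencies are drawn, reference animals are simulated
    from them, reference frequencies are *estimated* from those animals, and
    the six populations are then simulated from the estimated reference
    frequencies — the same two-step structure as the validation analysis,
    where simulated populations derive from the reference animals' sample
    frequencies."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3 + len(cross_types))
    model = DivergenceModel(
        m=m,
        fst=fst,
        min_abs_freq_diff=min_abs_freq_diff,
        seed=int(seeds[0]),
    )
    true_freqs = simulate_divergent_freqs(model)

    plains_ref = simulate_population(
        true_freqs, CrossType.PURE_P, n_plains_ref, seed=int(seeds[1]), sample_prefix="refP"
    )
    wood_ref = simulate_population(
        true_freqs, CrossType.PURE_W, n_wood_ref, seed=int(seeds[2]), sample_prefix="refW"
    )
    reference_gm = GenotypeMatrix(
        sample_ids=plains_ref.gm.sample_ids + wood_ref.gm.sample_ids,
        locus_ids=list(true_freqs.locus_ids),
        dosages=np.vstack([plains_ref.gm.dosages, wood_ref.gm.dosages]),
    )
    metadata = [
        SampleRecord(s, "plains", 1, "simulated") for s in plains_ref.gm.sample_ids
    ] + [SampleRecord(s, "wood", 1, "simulated") for s in wood_ref.gm.sample_ids]
    ref_freqs = reference_freqs(reference_gm, metadata, min_confidence=1)

    populations = {
        ct: simulate_population(
            ref_freqs, ct, n_per_population, seed=int(seeds[3 + i])
        )
        for i, ct in enumerate(cross_types)
    }
    return StudySimulation(
        true_freqs=true_freqs,
        reference_gm=reference_gm,
        reference_metadata=metadata,
        ref_freqs=ref_freqs,
        populations=populations,
    )
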