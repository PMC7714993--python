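"""Parentage exclusion probabilities and Mendelian verification.

Three exclusion scenarios are supported for a biallelic SNP panel:

* **Q1** — exclude a random unrelated candidate *parent* when the other
  parent is known;
* **Q2** — exclude a random unrelated candidate parent when the other parent
  is unknown (a parent-offspring duo alone);
* **Q3** — exclude a random unrelated candidate *offspring* when both
  members of a mated parent pair are known.

Per-locus exclusion probabilities (PE) follow from Hardy-Weinberg genotype
frequencies and random mating.  For a locus with allele frequencies
``p = 1 - maf`` and ``q = maf``::

    PE_Q1 = p q (1 - p q)
    PE_Q2 = 2 p^2 q^2
    PE_Q3 = p^4 (1 - p^2) + q^4 (1 - q^2) + 8 p^3 q^3 + 2 p^2 q^2 (p^2 + q^2)

These closed forms are validated against :func:`pe_enumerate`, a brute-force
enumeration over the finite genotype space that serves as the normative
definition (it guards against transcription errors in the closed forms).
Multi-locus power assumes unlinked loci: the non-exclusion probability is
``PN = prod_l (1 - PE_l)`` and ``PE = 1 - PN``.

Verification is pure Mendelian-compatibility counting: a duo mismatch is a
pair of opposite homozygotes; a trio mismatch is a locus where no allele
pair drawn from the candidate and the known parent can produce the
offspring genotype.  Loci where the offspring conflicts with the *known*
parent are reported separately and never held against the candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

Scenario = Literal["Q1", "Q2", "Q3"]

#: Alleles carried by each dosage (0 = ref, 1 = alt).
_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


@dataclass(frozen=True)
class ExclusionProfile:
    """Single-locus exclusion probabilities for the three scenarios."""

    locus_id: str
    maf: float
    pe_q1: float
    pe_q2: float
    pe_q3: float

    def pe(self, scenario: Scenario) -> float:
        return {"Q1": self.pe_q1, "Q2": self.pe_q2, "Q3": self.pe_q3}[scenario]


@dataclass(frozen=True)
class PanelPower:
    """Multi-locus exclusion power of a panel under one scenario."""

    scenario: Scenario
    n_loci: int
    pe_multi: float
    pn_multi: float


@dataclass(frozen=True)
class ParentageResult:
    offspring_id: str
    candidate_id: str
    known_parent_id: str | None
    scenario: Scenario
    n_loci_compared: int
    n_mismatch: int
    n_known_parent_conflicts: int
    verdict: Literal["not_excluded", "excluded"]


def _check_maf(maf: float) -> None:
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")


def _genotype_probs(q: float) -> dict[int, float]:
    """HWE genotype probabilities by alt dosage for alt frequency q."""
    p = 1.0 - q
    return {0: p * p, 1: 2 * p * q, 2: q * q}


def _offspring_dosages(g1: int, g2: int) -> set[int]:
    return {a + b for a in _ALLELES[g1] for b in _ALLELES[g2]}


def pe_enumerate(maf: float, scenario: Scenario) -> float:
    """Brute-force single-locus exclusion probability.

    Enumerates every genotype configuration under Hardy-Weinberg equilibrium
    and random mating and sums the probability of configurations in which
    the random unrelated candidate is Mendelian-incompatible.  Slow but
    exhaustive; the normative oracle for :func:`pe_single_locus`.
    """
    _check_maf(maf)
    g = _genotype_probs(maf)
    q = maf
    p = 1.0 - q

    if scenario == "Q2":
        # duo: exclusion iff offspring and candidate are opposite homozygotes
        return g[0] * g[2] + g[2] * g[0]

    if scenario == "Q1":
        # known parent M + offspring O; candidate must be able to supply the
        # second-parent allele
        total = 0.0
        for gm_, p_gm in g.items():
            maternal = _ALLELES[gm_]
            for a in maternal:
                p_a = p_gm / len(maternal)
                for b, p_b in ((0, p), (1, q)):  # true second-parent allele
                    o = a + b
                    # second-parent alleles consistent with (M, O)
                    needed = {
                        o - am for am in maternal if o - am in (0, 1)
                    }
                    for gc, p_gc in g.items():
                        if not needed & set(_ALLELES[gc]):
                            total += p_a * p_b * p_gc
        return total

    if scenario == "Q3":
        # known parent pair; candidate offspring outside the Mendelian set
        total = 0.0
        for g1, p1 in g.items():
            for g2, p2 in g.items():
                allowed = _offspring_dosages(g1, g2)
                for go, po in g.items():
                    if go not in allowed:
                        total += p1 * p2 * po
        return total

    raise ValueError(f"unknown scenario: {scenario!r}")


def pe_single_locus(maf: float, locus_id: str = "") -> ExclusionProfile:
    """Closed-form single-locus exclusion probabilities at a given MAF."""
    _check_maf(maf)
    q = maf
    p = 1.0 - q
    pq = p * q
    pe_q1 = pq * (1.0 - pq)
    pe_q2 = 2.0 * pq * pq
    pe_q3 = (
        p**4 * (1.0 - p * p)
        + q**4 * (1.0 - q * q)
        + 8.0 * p**3 * q**3
        + 2.0 * p * p * q * q * (p * p + q * q)
    )
    return ExclusionProfile(locus_id, maf, pe_q1, pe_q2, pe_q3)


def panel_power(mafs: Iterable[float], scenario: Scenario) -> PanelPower:
    """Multi-locus exclusion power assuming independent loci.

    ``PN = prod(1 - PE_l)`` accumulated in log space so panels of hundreds
    of loci do not underflow.  An empty panel has PN 1 (nothing excluded).
    """
    mafs = list(mafs)
    for m in mafs:
        _check_maf(m)
    pes = np.array([pe_single_locus(m).pe(scenario) for m in mafs])
    pn = float(np.exp(np.log1p(-pes).sum())) if len(pes) else 1.0
    return PanelPower(scenario=scenario, n_loci=len(mafs), pe_multi=1.0 - pn, pn_multi=pn)


def power_curve(
    mafs: Iterable[float], scenario: Scenario
) -> list[tuple[int, float, float]]:
    """(k, PE, PN) using the top-k loci by MAF, for k = 1..len(mafs).

    "Top" loci are those with the greatest MAF; PN is non-increasing in k.
    """
    ordered = sorted(mafs, reverse=True)
    for m in ordered:
        _check_maf(m)
    pes = np.array([pe_single_locus(m).pe(scenario) for m in ordered])
    log_pn = np.cumsum(np.log1p(-pes))
    pns = np.exp(log_pn)
    return [(k + 1, float(1.0 - pn), float(pn)) for k, pn in enumerate(pns)]


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


def _duo_mismatch(o: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Opposite-homozygote mask (the only duo impossibility for biallelics)."""
    return ((o == 0) & (c == 2)) | ((o == 2) & (c == 0))


def _trio_compat_table() -> np.ndarray:
    """ok[o, kp, c]: candidate dosage c can co-parent offspring o with kp."""
    ok = np.zeros((3, 3, 3), dtype=bool)
    for o in range(3):
        for kp in range(3):
            for c in range(3):
                ok[o, kp, c] = any(
                    ak + ac == o for ak in _ALLELES[kp] for ac in _ALLELES[c]
                )
    return ok


_TRIO_OK = _trio_compat_table()


def verify_duo(
    gm: GenotypeMatrix,
    offspring_id: str,
    candidate_id: str,
    max_mismatch: int = 0,
) -> ParentageResult:
    """Parent-offspring duo check (scenario Q2).

    A mismatch is a locus where both individuals are called and are opposite
    homozygotes.  The candidate is excluded when the mismatch count exceeds
    ``max_mismatch`` (default 0)."""
    o = gm.dosage_row(offspring_id)
    c = gm.dosage_row(candidate_id)
    both = (o != MISSING) & (c != MISSING)
    if not both.any():
        raise ValueError(
            f"no comparable loci for ({offspring_id}, {candidate_id})"
        )
    mism = int(_duo_mismatch(o[both], c[both]).sum())
    return ParentageResult(
        offspring_id=offspring_id,
        candidate_id=candidate_id,
        known_parent_id=None,
        scenario="Q2",
        n_loci_compared=int(both.sum()),
        n_mismatch=mism,
        n_known_parent_conflicts=0,
        verdict="excluded" if mism > max_mismatch else "not_excluded",
    )


def verify_trio(
    gm: GenotypeMatrix,
    offspring_id: str,
    known_parent_id: str,
    candidate_id: str,
    max_mismatch: int = 0,
) -> ParentageResult:
    """Candidate-parent check conditioned on a known parent (scenario Q1).

    Only loci where all three individuals are called contribute.  Loci where
    the offspring is incompatible with the *known* parent (opposite
    homozygotes) are tallied in ``n_known_parent_conflicts`` and excluded
    from candidate scoring; at the rest, the candidate mismatches when no
    allele pair (one from the candidate, one from the known parent) yields
    the offspring genotype."""
    o = gm.dosage_row(offspring_id)
    k = gm.dosage_row(known_parent_id)
    c = gm.dosage_row(candidate_id)
    all_called = (o != MISSING) & (k != MISSING) & (c != MISSING)
    if not all_called.any():
        raise ValueError(
            f"no comparable loci for ({offspring_id}, {known_parent_id}, {candidate_id})"
        )
    o, k, c = o[all_called], k[all_called], c[all_called]
    kp_conflict = _duo_mismatch(o, k)
    scoreable = ~kp_conflict
    compat = _TRIO_OK[o[scoreable], k[scoreable], c[scoreable]]
    mism = int((~compat).sum())
    return ParentageResult(
        offspring_id=offspring_id,
        candidate_id=candidate_id,
        known_parent_id=known_parent_id,
        scenario="Q1",
        n_loci_compared=int(scoreable.sum()),
        n_mismatch=mism,
        n_known_parent_conflicts=int(kp_conflict.sum()),
        verdict="excluded" if mism > max_mismatch else "not_excluded",
    )
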