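"""Per-locus QC statistics and two-stage SNP selection filters.

Panel design proceeds in two stages.  Stage 1 screens sequencing-derived
candidates: flanking-polymorphism exclusion, caller QUAL, missing rate and
(for parentage candidates) a high MAF floor with Hardy-Weinberg filtering,
followed by 1-Mbp distance thinning; composition candidates instead require
allelic differentiation between the two subspecies.  Stage 2 re-screens the
array-genotyped loci on call rates, MAF overall and per subspecies, HWE and
array conversion type, then prunes linkage disequilibrium with a sliding
r-squared window, always dropping the lower-MAF member of an offending pair.

The HWE test is the exact conditional test on the heterozygote count, the
standard genotype-QC choice; a chi-square variant is available.  The allelic
differentiation test is the 1-df chi-square on the 2x2 allele-count table
(the allele-frequency-difference GWAS), with Fisher's exact test as an
option for small counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix, LocusRecord

logger = logging.getLogger("panelkit")


# ---------------------------------------------------------------------------
# Per-locus statistics
# ---------------------------------------------------------------------------


@dataclass
class LocusStats:
    """QC summary for one locus.

    Frequencies are computed over non-missing calls only.  A group (or the
    whole column) with zero calls yields ``nan`` frequencies and call rate 0;
    such loci are flagged ``undefined_freq`` rather than raising.
    """

    locus_id: str
    call_rate_overall: float
    call_rate_by_group: dict[str, float]
    alt_freq: float
    maf_overall: float
    maf_by_group: dict[str, float]
    hwe_p: float
    allelic_p: float | None = None
    undefined_freq: bool = False

    @property
    def monomorphic(self) -> bool:
        return self.maf_overall == 0.0


def _column_freqs(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(call_rate, alt_freq) per column; alt_freq is nan where no calls."""
    called = dos != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    call_rate = n_called / dos.shape[0] if dos.shape[0] else np.zeros(dos.shape[1])
    return call_rate, freq


def genotype_counts(dos_column: np.ndarray) -> tuple[int, int, int]:
    """(n_hom_ref, n_het, n_hom_alt) of one dosage column, ignoring missing."""
    return (
        int(np.sum(dos_column == 0)),
        int(np.sum(dos_column == 1)),
        int(np.sum(dos_column == 2)),
    )


def locus_stats(
    gm: GenotypeMatrix,
    group_labels: Mapping[str, str] | None = None,
    allelic_groups: tuple[str, str] | None = None,
    hwe_method: Literal["exact", "chi2"] = "exact",
) -> list[LocusStats]:
    """Compute :class:`LocusStats` for every locus.

    Parameters
    ----------
    group_labels:
        sample_id -> group name; unlisted samples count as ``"ungrouped"``.
    allelic_groups:
        optional pair of group names between which the allelic
        differentiation test is run (fills ``allelic_p``).
    """
    dos = gm.dosages
    call_rate, alt_freq = _column_freqs(dos)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    groups: dict[str, np.ndarray] = {}
    if group_labels:
        names = [group_labels.get(s, "ungrouped") for s in gm.sample_ids]
        for g in dict.fromkeys(names):
            groups[g] = np.array([n == g for n in names])

    group_stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g, mask in groups.items():
        if mask.sum() == 0:
            group_stats[g] = (
                np.full(gm.n_loci, np.nan),
                np.full(gm.n_loci, np.nan),
            )
        else:
            cr, f = _column_freqs(dos[mask])
            group_stats[g] = (cr, f)

    out: list[LocusStats] = []
    for j, locus_id in enumerate(gm.locus_ids):
        counts = genotype_counts(dos[:, j])
        if hwe_method == "exact":
            p_hwe = hwe_exact_test(*counts)
        else:
            p_hwe = hwe_chi2_test(*counts)
        allelic_p = None
        if allelic_groups is not None:
            a, b = allelic_groups
            allelic_p = _allelic_p_for_column(dos[:, j], groups, a, b)
        out.append(
            LocusStats(
                locus_id=locus_id,
                call_rate_overall=float(call_rate[j]),
                call_rate_by_group={
                    g: float(group_stats[g][0][j]) for g in group_stats
                },
                alt_freq=float(alt_freq[j]),
                maf_overall=float(maf[j]),
                maf_by_group={
                    g: float(min(f[j], 1 - f[j])) if np.isfinite(f[j]) else float("nan")
                    for g, (_, f) in group_stats.items()
                },
                hwe_p=p_hwe,
                allelic_p=allelic_p,
                undefined_freq=not np.isfinite(alt_freq[j]),
            )
        )
    return out


def _allelic_p_for_column(
    col: np.ndarray, groups: dict[str, np.ndarray], a: str, b: str
) -> float:
    def counts(mask: np.ndarray) -> tuple[int, int]:
        c = col[mask]
        c = c[c != MISSING]
        n_alt = int(c.sum())
        return n_alt, int(2 * len(c) - n_alt)

    if a not in groups or b not in groups:
        return float("nan")
    ca, cb = counts(groups[a]), counts(groups[b])
    if ca[0] + ca[1] == 0 or cb[0] + cb[1] == 0:
        return float("nan")
    _, p = allelic_diff_test(ca, cb)
    return p


def stats_to_frame(stats: Sequence[LocusStats]) -> pd.DataFrame:
    """Flatten LocusStats into a TSV-friendly DataFrame."""
    rows = []
    for s in stats:
        row = {
            "locus_id": s.locus_id,
            "call_rate_overall": s.call_rate_overall,
            "alt_freq": s.alt_freq,
            "maf_overall": s.maf_overall,
            "hwe_p": s.hwe_p,
            "allelic_p": s.allelic_p,
        }
        for g, v in s.call_rate_by_group.items():
            row[f"call_rate_{g}"] = v
        for g, v in s.maf_by_group.items():
            row[f"maf_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg and allelic differentiation tests
# ---------------------------------------------------------------------------


def hwe_exact_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` genotyped diploids carrying ``n_rare`` copies of the rarer
    allele, returns the possible heterozygote counts and their exact
    probabilities under Hardy-Weinberg equilibrium (hypergeometric-type
    conditional distribution).
    """
    n_common = 2 * n - n_rare
    h_min = n_rare % 2
    if n_rare > n:  # cannot happen for the rarer allele, but stay general
        h_min = max(h_min, 2 * n_rare - 2 * n)
    h_values = np.arange(h_min, n_rare + 1, 2)
    probs = np.empty(len(h_values), dtype=float)
    probs[0] = 1.0
    for i in range(1, len(h_values)):
        h = h_values[i - 1]
        hom_rare = (n_rare - h) // 2
        hom_common = (n_common - h) // 2
        probs[i] = probs[i - 1] * 4.0 * hom_rare * hom_common / ((h + 1.0) * (h + 2.0))
    probs /= probs.sum()
    return h_values, probs


def _hwe_exact_integer(n: int, n_rare: int, h_obs: int) -> float:
    """Exact-integer two-sided-by-mass p; ties in probability are exact."""
    from fractions import Fraction
    from math import comb

    weights: dict[int, int] = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        # conditional weight: multinomial(n; hom_rare, h, hom_common) * 2^h
        weights[h] = comb(n, hom_rare) * comb(n - hom_rare, h) * (2**h)
    w_obs = weights[h_obs]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(weights.values())))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test p-value, two-sided by probability mass.

    The p-value is the total probability of heterozygote counts whose
    conditional probability does not exceed that of the observed count.
    Exact integer arithmetic is used up to n = 200 genotypes (tie decisions
    are then exact); beyond that a numerically stable recurrence is used.
    All-zero counts return 1.0 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0
    if n <= 200:
        return _hwe_exact_integer(n, n_rare, n_het)
    h_values, probs = hwe_exact_probs(n, n_rare)
    p_obs = probs[np.searchsorted(h_values, n_het)]
    # small relative slack guards against float round-off in the recurrence
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


def hwe_chi2_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square HWE test (no continuity correction)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(sps.chi2.sf(chi2, df=1))


def allelic_diff_test(
    allele_counts_group1: tuple[int, int],
    allele_counts_group2: tuple[int, int],
    method: Literal["chi2", "fisher"] = "chi2",
) -> tuple[float, float]:
    """Allelic differentiation between two groups on the 2x2 allele table.

    Returns ``(chi2, p)``; for ``method="fisher"`` the first element is the
    odds ratio.  A zero margin (monomorphic overall, or an empty group)
    yields ``(0.0, 1.0)``.
    """
    a, b = allele_counts_group1  # (n_alt, n_ref)
    c, d = allele_counts_group2
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("each group needs at least one allele")
    n = a + b + c + d
    if (a + c) == 0 or (b + d) == 0:
        return 0.0, 1.0
    if method == "fisher":
        odds, p = sps.fisher_exact([[a, b], [c, d]])
        return float(odds), float(p)
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Selection criteria and filters
# ---------------------------------------------------------------------------


@dataclass
class SelectionCriteria:
    """Named thresholds for SNP selection; ``None`` deactivates a rule."""

    min_qual: float | None = None
    max_missing_overall: float | None = None
    min_call_rate_overall: float | None = None
    min_call_rate_per_group: float | None = None
    min_maf_overall: float | None = None
    min_maf_per_group: float | None = None
    min_hwe_p: float | None = None
    excluded_conversion_types: tuple[str, ...] = ()
    require_one_probe_per_strand: bool = False
    require_gatk_qc_pass: bool = False
    max_allelic_p: float | None = None
    min_spacing_bp: int | None = None
    ld_r2_max: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "max_missing_overall",
            "min_call_rate_overall",
            "min_call_rate_per_group",
            "min_hwe_p",
            "max_allelic_p",
            "ld_r2_max",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_maf_overall", "min_maf_per_group"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_conversion_types"] = list(self.excluded_conversion_types)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionCriteria":
        d = dict(d)
        if "excluded_conversion_types" in d:
            d["excluded_conversion_types"] = tuple(d["excluded_conversion_types"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SelectionCriteria":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Array conversion-type categories excluded during array-based screening.
BAD_CONVERSION_TYPES = ("NoMinorHom", "OTV", "MonoHighResolution")

#: Named presets for the two selection stages of each tool.
PRESETS: dict[str, SelectionCriteria] = {
    # sequencing-based discovery screen, parentage candidates
    "stage1-parentage": SelectionCriteria(
        min_qual=10_000,
        max_missing_overall=0.05,
        min_maf_overall=0.45,
        min_hwe_p=1e-4,
        require_one_probe_per_strand=True,
        min_spacing_bp=1_000_000,
    ),
    # sequencing-based discovery screen, composition candidates
    "stage1-composition": SelectionCriteria(
        min_qual=1_000,
        max_missing_overall=0.20,
        min_maf_overall=0.1,
        max_allelic_p=1e-4,
    ),
    # array-based validation screen, parentage
    "stage2-parentage": SelectionCriteria(
        min_call_rate_overall=0.95,
        min_call_rate_per_group=0.90,
        min_maf_overall=0.4,
        min_maf_per_group=0.3,
        min_hwe_p=0.05,
        excluded_conversion_types=BAD_CONVERSION_TYPES,
        ld_r2_max=0.2,
    ),
    # array-based validation screen, composition
    "stage2-composition": SelectionCriteria(
        min_call_rate_overall=0.95,
        min_call_rate_per_group=0.90,
        excluded_conversion_types=BAD_CONVERSION_TYPES,
    ),
}


def flanking_variant_filter(
    loci: Sequence[LocusRecord], flank_bp: int = 36
) -> list[LocusRecord]:
    """Drop every locus with another variant within ``flank_bp`` of it.

    Both members of a close pair are removed (the flanking polymorphism would
    compromise probe design for either).  Distance is in bp on the same
    chromosome; a distance strictly greater than ``flank_bp`` is safe.
    """
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chromosome, loci[i].position))
    doomed = set()
    for k in range(len(order) - 1):
        i, j = order[k], order[k + 1]
        if (
            loci[i].chromosome == loci[j].chromosome
            and abs(loci[j].position - loci[i].position) <= flank_bp
        ):
            doomed.add(i)
            doomed.add(j)
    return [loc for i, loc in enumerate(loci) if i not in doomed]


def select_by_thresholds(
    stats: Sequence[LocusStats],
    loci: Sequence[LocusRecord],
    criteria: SelectionCriteria,
) -> tuple[list[str], dict[str, str]]:
    """Apply threshold criteria; returns (kept ids, first failing rule per locus).

    A criterion whose input is absent for a locus (e.g. ``min_qual`` with no
    QUAL annotation) is skipped for that locus with a single summary warning.
    Spacing and LD rules are not threshold rules and are handled by
    :func:`thin_by_distance` / :func:`ld_prune`.
    """
    by_id = {l.locus_id: l for l in loci}
    kept: list[str] = []
    reasons: dict[str, str] = {}
    skipped_rules: set[str] = set()

    for s in stats:
        loc = by_id.get(s.locus_id)
        reason = _first_failure(s, loc, criteria, skipped_rules)
        if reason is None:
            kept.append(s.locus_id)
        else:
            reasons[s.locus_id] = reason
    if skipped_rules:
        warnings.warn(
            f"criteria skipped for loci lacking the field: {sorted(skipped_rules)}",
            stacklevel=2,
        )
    return kept, reasons


def _first_failure(
    s: LocusStats,
    loc: LocusRecord | None,
    c: SelectionCriteria,
    skipped: set[str],
) -> str | None:
    if c.min_qual is not None:
        if loc is None or loc.qual is None:
            skipped.add("qual")
        elif loc.qual < c.min_qual:
            return "qual"
    if c.max_missing_overall is not None:
        if 1.0 - s.call_rate_overall > c.max_missing_overall:
            return "missing_rate"
    if c.min_call_rate_overall is not None:
        if s.call_rate_overall < c.min_call_rate_overall:
            return "call_rate_overall"
    if c.min_call_rate_per_group is not None:
        rates = [v for v in s.call_rate_by_group.values() if np.isfinite(v)]
        if not s.call_rate_by_group:
            skipped.add("call_rate_group")
        elif any(r < c.min_call_rate_per_group for r in rates):
            return "call_rate_group"
    if c.min_maf_overall is not None:
        if not np.isfinite(s.maf_overall) or s.maf_overall <= c.min_maf_overall:
            return "maf_overall"
    if c.min_maf_per_group is not None:
        mafs = [v for v in s.maf_by_group.values() if np.isfinite(v)]
        if not s.maf_by_group:
            skipped.add("maf_group")
        elif any(m <= c.min_maf_per_group for m in mafs):
            return "maf_group"
    if c.min_hwe_p is not None:
        if s.hwe_p <= c.min_hwe_p:
            return "hwe_p"
    if c.excluded_conversion_types:
        if loc is not None and loc.conversion_type in c.excluded_conversion_types:
            return "conversion_type"
    if c.require_one_probe_per_strand:
        if loc is None or loc.one_probe_per_strand is None:
            skipped.add("probe_per_strand")
        elif not loc.one_probe_per_strand:
            return "probe_per_strand"
    if c.require_gatk_qc_pass:
        if loc is None or loc.gatk_qc_pass is None:
            skipped.add("gatk_qc")
        elif not loc.gatk_qc_pass:
            return "gatk_qc"
    if c.max_allelic_p is not None:
        if s.allelic_p is None or not np.isfinite(s.allelic_p):
            skipped.add("allelic_p")
        elif s.allelic_p >= c.max_allelic_p:
            return "allelic_p"
    return None


def thin_by_distance(
    loci: Sequence[LocusRecord],
    ranked_stats: Sequence[LocusStats] | None = None,
    min_gap_bp: int = 1_000_000,
) -> tuple[list[str], list[str]]:
    """Thin loci so no two kept loci on a chromosome are closer than
    ``min_gap_bp``.

    By default a greedy left-to-right scan keeps the first locus of each
    run; if ``ranked_stats`` is given, loci are instead admitted in
    descending-MAF order (higher-value loci win conflicts).  Removed loci
    are returned second, as "alternative" SNPs.
    """
    if ranked_stats is None:
        kept: list[str] = []
        alternatives: list[str] = []
        by_chrom: dict[str, list[LocusRecord]] = {}
        for loc in loci:
            by_chrom.setdefault(loc.chromosome, []).append(loc)
        for chrom_loci in by_chrom.values():
            chrom_loci.sort(key=lambda l: l.position)
            last = None
            for loc in chrom_loci:
                if last is None or loc.position - last >= min_gap_bp:
                    kept.append(loc.locus_id)
                    last = loc.position
                else:
                    alternatives.append(loc.locus_id)
        return kept, alternatives

    maf = {s.locus_id: s.maf_overall for s in ranked_stats}
    order = sorted(loci, key=lambda l: (-maf.get(l.locus_id, 0.0), l.locus_id))
    taken: dict[str, list[int]] = {}
    kept_set: set[str] = set()
    for loc in order:
        positions = taken.setdefault(loc.chromosome, [])
        if all(abs(loc.position - p) >= min_gap_bp for p in positions):
            positions.append(loc.position)
            kept_set.add(loc.locus_id)
    kept = [l.locus_id for l in loci if l.locus_id in kept_set]
    alternatives = [l.locus_id for l in loci if l.locus_id not in kept_set]
    return kept, alternatives


def pairwise_r2(gm: GenotypeMatrix, locus_a: str, locus_b: str) -> float:
    """Composite LD r-squared: squared Pearson correlation of dosage columns
    over pairwise-complete samples.  Zero variance at either locus returns
    0.0 with a warning (r-squared undefined)."""
    ja = gm.locus_ids.index(locus_a)
    jb = gm.locus_ids.index(locus_b)
    x, y = gm.dosages[:, ja].astype(float), gm.dosages[:, jb].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise ValueError(f"fewer than 2 co-called samples for {locus_a},{locus_b}")
    x, y = x[ok], y[ok]
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        warnings.warn(
            f"r2 undefined (zero variance) for pair ({locus_a},{locus_b}); returning 0",
            stacklevel=2,
        )
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Pairwise composite r^2 for a (samples x loci) block, pairwise-complete."""
    X = dos.astype(float)
    W = (dos != MISSING).astype(float)
    X = np.where(W > 0, X, 0.0)
    n = W.T @ W
    sx = X.T @ W
    sxy = X.T @ X
    sxx = (X * X).T @ W
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_x = sxx / n - (sx / n) ** 2
        denom = var_x * var_x.T
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    stats: Sequence[LocusStats],
    r2_max: float = 0.2,
    window_loci: int = 50,
    step_loci: int = 5,
) -> list[str]:
    """Sliding-window LD pruning.

    Loci must be in genome order (the matrix column order).  Within each
    window of ``window_loci`` surviving loci, while any pair exceeds
    ``r2_max``, the member with the lower MAF is dropped (ties: the later
    locus).  The window advances by ``step_loci`` and whole passes repeat
    until no locus is dropped.
    """
    maf = {s.locus_id: s.maf_overall for s in stats}
    active = list(range(gm.n_loci))
    changed = True
    while changed:
        changed = False
        start = 0
        while start < len(active):
            window = active[start : start + window_loci]
            if len(window) > 1:
                r2 = _r2_matrix(gm.dosages[:, window])
                dropped = _prune_window(window, r2, maf, gm.locus_ids, r2_max)
                if dropped:
                    active = [i for i in active if i not in dropped]
                    changed = True
            start += step_loci
    return [gm.locus_ids[i] for i in active]


def _prune_window(
    window: list[int],
    r2: np.ndarray,
    maf: Mapping[str, float],
    locus_ids: Sequence[str],
    r2_max: float,
) -> set[int]:
    alive = list(range(len(window)))
    dropped: set[int] = set()
    while True:
        worst = None
        for a in range(len(alive)):
            for b in range(a + 1, len(alive)):
                i, j = alive[a], alive[b]
                if r2[i, j] > r2_max:
                    worst = (i, j)
                    break
            if worst:
                break
        if worst is None:
            return dropped
        i, j = worst
        mi = maf.get(locus_ids[window[i]], 0.0)
        mj = maf.get(locus_ids[window[j]], 0.0)
        loser = i if mi < mj else j  # lower MAF loses; tie: later position
        dropped.add(window[loser])
        alive.remove(loser)
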