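"""QC statistics, HWE/allelic tests and the selection filters."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelkit import (
    PRESETS,
    GenotypeMatrix,
    LocusRecord,
    SelectionCriteria,
    allelic_diff_test,
    flanking_variant_filter,
    hwe_chi2_test,
    hwe_exact_test,
    ld_prune,
    locus_stats,
    pairwise_r2,
    select_by_thresholds,
    thin_by_distance,
)


def _gm(columns: list[list[int]], locus_ids=None) -> GenotypeMatrix:
    arr = np.array(columns, dtype=np.int8).T
    ids = locus_ids or [f"l{j}" for j in range(arr.shape[1])]
    return GenotypeMatrix([f"s{i}" for i in range(arr.shape[0])], ids, arr)


class TestLocusStats:
    def test_with_missing(self):
        stats = locus_stats(_gm([[0, 1, 2, -1]]))[0]
        assert stats.call_rate_overall == pytest.approx(0.75)
        assert stats.alt_freq == pytest.approx(0.5)
        assert stats.maf_overall == pytest.approx(0.5)

    def test_monomorphic(self):
        stats = locus_stats(_gm([[0, 0, 0]]))[0]
        assert stats.maf_overall == 0.0 and stats.monomorphic

    def test_hand_count(self):
        stats = locus_stats(_gm([[2, 2, 1]]))[0]
        assert stats.alt_freq == pytest.approx(5 / 6)
        assert stats.maf_overall == pytest.approx(1 / 6)

    def test_zero_call_locus_flagged(self):
        stats = locus_stats(_gm([[-1, -1, -1]]))[0]
        assert stats.call_rate_overall == 0.0 and stats.undefined_freq

    def test_group_stats_and_empty_group(self):
        gm = _gm([[0, 2, 2]])
        stats = locus_stats(gm, group_labels={"s0": "plains", "s1": "plains"})[0]
        assert stats.maf_by_group["plains"] == pytest.approx(0.5)
        # s2 falls in "ungrouped"; groups never raise
        assert "ungrouped" in stats.call_rate_by_group


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Full enumeration of the conditional heterozygote distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    if n == 0 or n_rare == 0:
        return Fraction(1)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = (
            comb(n, hom_rare) * comb(n - hom_rare, h) * 2**h
            if hom_common >= 0
            else 0
        )
    w_obs = weights[n_het]
    return Fraction(
        sum(w for w in weights.values() if w <= w_obs), sum(weights.values())
    )


class TestHWE:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 0, 1), 1 / 3), ((0, 2, 0), 1.0), ((10, 0, 0), 1.0), ((0, 0, 0), 1.0)],
    )
    def test_examples(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n_hom_ref=st.integers(0, 10),
        n_het=st.integers(0, 10),
        n_hom_alt=st.integers(0, 10),
    )
    def test_oracle_equivalence_small_n(self, n_hom_ref, n_het, n_hom_alt):
        """Agrees with full enumeration for all n <= 30."""
        p = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
        assert p == pytest.approx(
            float(hwe_oracle(n_hom_ref, n_het, n_hom_alt)), abs=1e-12
        )

    def test_large_n_recurrence_matches_integer_path(self):
        # same configuration through both code paths (n just beyond cutoff)
        p_big = hwe_exact_test(150, 30, 121)  # n=301, float recurrence
        from panelkit.panel_design import _hwe_exact_integer

        # n=301 genotypes, 272 copies of the rarer allele, 30 heterozygotes
        assert p_big == pytest.approx(_hwe_exact_integer(301, 272, 30), rel=1e-9)

    def test_chi2_variant_sane(self):
        # strong heterozygote deficit is significant under both tests
        assert hwe_chi2_test(50, 0, 50) < 1e-6
        assert hwe_exact_test(50, 0, 50) < 1e-6


class TestAllelicDiff:
    def test_closed_form_value(self):
        chi2, p = allelic_diff_test((30, 10), (10, 30))
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_equal_frequencies(self):
        chi2, p = allelic_diff_test((20, 20), (10, 10))
        assert chi2 == 0.0 and p == 1.0

    def test_second_closed_form_value(self):
        chi2, _ = allelic_diff_test((16, 4), (4, 16))
        assert chi2 == pytest.approx(14.4)

    def test_zero_margin(self):
        assert allelic_diff_test((0, 20), (0, 10)) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            allelic_diff_test((0, 0), (1, 1))

    def test_fisher_option(self):
        _, p = allelic_diff_test((30, 10), (10, 30), method="fisher")
        assert p < 1e-4


class TestFlankingFilter:
    def _loci(self, positions, chrom="1"):
        return [
            LocusRecord(f"v{i}", c if isinstance(c, str) else chrom, p, "A", "C")
            for i, (c, p) in enumerate(
                (x if isinstance(x, tuple) else (chrom, x)) for x in positions
            )
        ]

    def test_close_pair_both_removed(self):
        assert flanking_variant_filter(self._loci([100, 130])) == []

    def test_boundary_kept(self):
        assert len(flanking_variant_filter(self._loci([100, 137]))) == 2

    def test_boundary_removed_at_exact_flank(self):
        assert flanking_variant_filter(self._loci([100, 136])) == []

    def test_different_chromosomes_kept(self):
        loci = self._loci([("1", 100), ("2", 100)])
        assert len(flanking_variant_filter(loci)) == 2


class TestSelectByThresholds:
    def _stats_locus(self, **overrides):
        from panelkit.panel_design import LocusStats

        base = dict(
            locus_id="x",
            call_rate_overall=0.99,
            call_rate_by_group={"plains": 0.95, "wood": 0.96},
            alt_freq=0.45,
            maf_overall=0.45,
            maf_by_group={"plains": 0.44, "wood": 0.40},
            hwe_p=0.4,
        )
        base.update(overrides)
        return LocusStats(**base)

    def _locus(self, **overrides):
        base = dict(
            locus_id="x", chromosome="1", position=100, ref_allele="A", alt_allele="C"
        )
        base.update(overrides)
        return LocusRecord(**base)

    def test_good_locus_kept_under_stage2_parentage(self):
        kept, reasons = select_by_thresholds(
            [self._stats_locus()], [self._locus()], PRESETS["stage2-parentage"]
        )
        assert kept == ["x"] and reasons == {}

    def test_bad_conversion_type_rejected(self):
        _, reasons = select_by_thresholds(
            [self._stats_locus()],
            [self._locus(conversion_type="OTV")],
            PRESETS["stage2-parentage"],
        )
        assert reasons["x"] == "conversion_type"

    def test_low_maf_rejected(self):
        _, reasons = select_by_thresholds(
            [self._stats_locus(maf_overall=0.39)],
            [self._locus()],
            PRESETS["stage2-parentage"],
        )
        assert reasons["x"] == "maf_overall"

    def test_absent_field_criterion_skipped_with_warning(self):
        crit = SelectionCriteria(min_qual=1000)
        with pytest.warns(UserWarning, match="qual"):
            kept, _ = select_by_thresholds([self._stats_locus()], [self._locus()], crit)
        assert kept == ["x"]

    def test_order_invariance(self):
        stats = [
            self._stats_locus(locus_id=f"x{i}", maf_overall=0.3 + 0.02 * i)
            for i in range(8)
        ]
        loci = [self._locus(locus_id=f"x{i}") for i in range(8)]
        kept_fwd, _ = select_by_thresholds(stats, loci, PRESETS["stage2-parentage"])
        kept_rev, _ = select_by_thresholds(
            stats[::-1], loci[::-1], PRESETS["stage2-parentage"]
        )
        assert set(kept_fwd) == set(kept_rev)

    def test_criteria_yaml_round_trip(self, tmp_path):
        crit = PRESETS["stage2-parentage"]
        crit.to_yaml(tmp_path / "c.yaml")
        assert SelectionCriteria.from_yaml(tmp_path / "c.yaml") == crit


class TestThinByDistance:
    def _loci(self, positions, chrom="1"):
        return [
            LocusRecord(f"t{i}", chrom, p, "A", "C") for i, p in enumerate(positions)
        ]

    def test_greedy_scan(self):
        kept, alt = thin_by_distance(self._loci([1, 999_999, 2_000_000]))
        assert kept == ["t0", "t2"] and alt == ["t1"]

    def test_boundary_gap_kept(self):
        kept, alt = thin_by_distance(self._loci([1, 1_000_001]))
        assert kept == ["t0", "t1"] and alt == []

    def test_single_locus(self):
        assert thin_by_distance(self._loci([42])) == (["t0"], [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(1, 10_000_000), min_size=1, max_size=40, unique=True
        )
    )
    def test_min_gap_invariant(self, positions):
        loci = self._loci(positions)
        kept, alternatives = thin_by_distance(loci, min_gap_bp=1_000_000)
        pos = {l.locus_id: l.position for l in loci}
        kept_pos = sorted(pos[k] for k in kept)
        assert all(b - a >= 1_000_000 for a, b in zip(kept_pos, kept_pos[1:]))
        assert sorted(kept + alternatives) == sorted(l.locus_id for l in loci)


class TestPairwiseR2:
    def test_identical_columns(self):
        gm = _gm([[0, 1, 2, 1], [0, 1, 2, 1]])
        assert pairwise_r2(gm, "l0", "l1") == pytest.approx(1.0)

    def test_complement_columns(self):
        gm = _gm([[0, 1, 2, 1], [2, 1, 0, 1]])
        assert pairwise_r2(gm, "l0", "l1") == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        gm = _gm(
            [rng.integers(0, 3, 10_000).tolist(), rng.integers(0, 3, 10_000).tolist()]
        )
        assert pairwise_r2(gm, "l0", "l1") < 0.01

    def test_zero_variance_flagged(self):
        gm = _gm([[1, 1, 1], [0, 1, 2]])
        with pytest.warns(UserWarning, match="zero variance"):
            assert pairwise_r2(gm, "l0", "l1") == 0.0

    def test_too_few_co_called(self):
        gm = _gm([[0, -1, -1], [-1, 1, 2]])
        with pytest.raises(ValueError, match="co-called"):
            pairwise_r2(gm, "l0", "l1")


class TestLdPrune:
    @staticmethod
    def _near_duplicates():
        # a: alt freq 0.45 (maf 0.45); b/c: copies with some hets set to 0,
        # lowering maf to 0.40 / 0.435 while staying in strong LD with a
        a = np.array([0] * 70 + [1] * 80 + [2] * 50, dtype=np.int8)
        b, c = a.copy(), a.copy()
        b[70:90] = 0
        c[70:76] = 0
        return a, b, c

    def test_duplicate_pair_keeps_higher_maf(self):
        a, b, _ = self._near_duplicates()
        gm = _gm([a.tolist(), b.tolist()], locus_ids=["hi", "lo"])
        stats = locus_stats(gm)
        mafs = {s.locus_id: s.maf_overall for s in stats}
        assert mafs["hi"] > mafs["lo"]
        assert ld_prune(gm, stats, r2_max=0.2) == ["hi"]

    def test_all_below_threshold_kept(self):
        rng = np.random.default_rng(5)
        cols = [rng.binomial(2, 0.5, 500).tolist() for _ in range(6)]
        gm = _gm(cols)
        stats = locus_stats(gm)
        assert ld_prune(gm, stats, r2_max=0.5) == gm.locus_ids

    def test_triplicated_column_keeps_exactly_max_maf(self):
        a, b, c = self._near_duplicates()
        gm = _gm([b.tolist(), a.tolist(), c.tolist()], locus_ids=["b", "a", "c"])
        stats = locus_stats(gm)
        kept = ld_prune(gm, stats, r2_max=0.2)
        assert kept == ["a"]  # repeated drop rule leaves only the max-maf locus

    def test_no_pair_above_threshold_after_pruning(self):
        rng = np.random.default_rng(13)
        base = rng.binomial(2, 0.5, 150)
        cols = []
        for j in range(20):
            col = base.copy()
            flip = rng.random(150) < 0.3
            col[flip] = rng.integers(0, 3, flip.sum())
            cols.append(col.tolist())
        gm = _gm(cols)
        stats = locus_stats(gm)
        kept = ld_prune(gm, stats, r2_max=0.3, window_loci=8, step_loci=3)
        from panelkit.panel_design import _r2_matrix

        sub = gm.subset(locus_ids=kept)
        for start in range(0, len(kept), 3):
            window = list(range(start, min(start + 8, len(kept))))
            if len(window) < 2:
                continue
            r2 = _r2_matrix(sub.dosages[:, window])
            off_diag = r2[~np.eye(len(window), dtype=bool)]
            assert (off_diag <= 0.3 + 1e-12).all()
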