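"""Instrument selection, LD clumping and strength statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.instruments import (
    LDTable,
    apply_exclusion_list,
    clump,
    f_statistic,
    find_proxy,
    grade_instruments,
    maf_filter,
    significance_filter,
    variance_explained,
    weak_instrument_filter,
)
from mrkit.simulate import SimulationConfig, simulate_ld_table, simulate_summary_stats
from mrkit.summary_io import AssociationRecord, ReasonCode


def rec(snp="rs1", p=1e-10, eaf=0.3, beta=0.5, se=0.05, chrom="1", pos=1000, n=100_000):
    return AssociationRecord(
        snp_id=snp, effect_allele="C", other_allele="T", eaf=eaf, beta=beta,
        se=se, pval=p, n=n, chrom=chrom, pos=pos,
    )


class TestSignificanceFilter:
    def test_strict_inequality_at_threshold(self):
        records = [rec(snp=f"rs{i}", p=p) for i, p in enumerate([4e-8, 5e-8, 6e-8])]
        kept = significance_filter(records)
        assert [r.snp_id for r in kept] == ["rs0"]

    def test_empty_input(self):
        assert significance_filter([]) == []

    def test_simulated_count_matches_truth_labels(self):
        rng = np.random.default_rng(0)
        ps = np.concatenate([rng.uniform(1e-12, 4.9e-8, 13), rng.uniform(1e-7, 1e-3, 7)])
        records = [rec(snp=f"rs{i}", p=float(p)) for i, p in enumerate(ps)]
        assert len(significance_filter(records)) == 13


def brute_force_clump(records, ld, r2_threshold, window_kb):
    """Independent greedy oracle: literal restatement of the procedure."""
    remaining = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index.snp_id)
        remaining = [
            r for r in remaining
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_kb * 1000
                and ld.r2(index.snp_id, r.snp_id) >= r2_threshold
            )
        ]
    return kept


class TestClump:
    def test_lower_p_snp_retained_in_ld_pair(self):
        a = rec(snp="a", p=1e-10, pos=1000)
        b = rec(snp="b", p=1e-9, pos=2000)
        ld = LDTable.from_pairs([("a", "b", 0.9)])
        ledger = []
        kept = clump([a, b], ld, ledger=ledger)
        assert [r.snp_id for r in kept] == ["a"]
        assert ledger[0].reason is ReasonCode.CLUMPED

    def test_pair_outside_window_both_retained(self):
        a = rec(snp="a", p=1e-10, pos=1000)
        b = rec(snp="b", p=1e-9, pos=1000 + 20_000_000)
        ld = LDTable.from_pairs([("a", "b", 0.9)])
        assert len(clump([a, b], ld)) == 2

    def test_three_block_structure_vs_brute_force(self):
        cfg = SimulationConfig(seed=3, n_snps=12,
                               ld_blocks=((4, 0.8), (4, 0.8), (4, 0.8)))
        ld, positions = simulate_ld_table(cfg)
        exposure, _, _ = simulate_summary_stats(cfg)
        kept = clump(exposure, ld, r2_threshold=0.001, window_kb=10_000)
        expected = brute_force_clump(exposure, ld, 0.001, 10_000)
        assert sorted(r.snp_id for r in kept) == sorted(expected)
        assert len(kept) == 3

    def test_clumped_output_pairwise_independent(self):
        cfg = SimulationConfig(seed=9, n_snps=10, ld_blocks=((5, 0.5), (5, 0.5)))
        ld, _ = simulate_ld_table(cfg)
        exposure, _, _ = simulate_summary_stats(cfg)
        kept = clump(exposure, ld)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                close = a.chrom == b.chrom and abs(a.pos - b.pos) <= 10_000_000
                assert not (close and ld.r2(a.snp_id, b.snp_id) >= 0.001)

    def test_missing_position_names_the_snp(self):
        bad = AssociationRecord(
            snp_id="rsX", effect_allele="C", other_allele="T", eaf=0.3, beta=0.5,
            se=0.05, pval=1e-10, n=1000,
        )
        with pytest.raises(ValueError, match="rsX"):
            clump([bad], LDTable())


class TestMafFilter:
    @pytest.mark.parametrize(
        "eaf,kept", [(0.995, False), (0.05278, True), (0.01, True), (0.005, False)]
    )
    def test_boundaries(self, eaf, kept):
        out = maf_filter([rec(eaf=eaf)])
        assert (len(out) == 1) is kept


class TestFindProxy:
    def make_outcome(self, ids):
        return [rec(snp=s) for s in ids]

    def test_argmax_r2(self):
        ld = LDTable.from_pairs([("t", "a", 0.85), ("t", "b", 0.9)])
        assert find_proxy("t", self.make_outcome(["a", "b"]), ld) == "b"

    def test_strict_inequality_at_08(self):
        ld = LDTable.from_pairs([("t", "a", 0.8)])
        assert find_proxy("t", self.make_outcome(["a"]), ld) is None

    def test_no_ld_entries_means_no_proxy(self):
        assert find_proxy("t", self.make_outcome(["a"]), LDTable()) is None

    def test_tie_broken_by_snp_id(self):
        ld = LDTable.from_pairs([("t", "b", 0.9), ("t", "a", 0.9)])
        assert find_proxy("t", self.make_outcome(["b", "a"]), ld) == "a"


class TestExclusionList:
    def test_confounder_trio_removed(self):
        records = [rec(snp=f"rs{i}") for i in range(7)] + [
            rec(snp=s) for s in ("rs62394289", "rs9378220", "rs112733823")
        ]
        ledger = []
        kept = apply_exclusion_list(
            records,
            [("rs62394289", "bp"), ("rs9378220", "bp"), ("rs112733823", "ra")],
            ledger=ledger,
        )
        assert len(kept) == 7
        assert all(e.reason is ReasonCode.CONFOUNDER for e in ledger)

    def test_empty_list_is_identity(self):
        records = [rec(snp="a")]
        assert apply_exclusion_list(records, []) == records

    def test_absent_snp_warns_not_errors(self):
        with pytest.warns(UserWarning, match="rsGone"):
            kept = apply_exclusion_list([rec(snp="a")], [("rsGone", "x")])
        assert len(kept) == 1


class TestStrength:
    def test_zero_beta_explains_nothing(self):
        assert variance_explained(0.0, 0.1, 0.3, 1000) == 0.0

    def test_forced_simplification_point(self):
        assert variance_explained(1.0, 1.0, 0.5, 1.0) == pytest.approx(0.5)

    def test_formula_on_published_instrument(self):
        # independent arithmetic oracle for the full printed expression
        beta, se, eaf, n = 0.8211, 0.0918, 0.05278, 166_144
        num = 2 * beta**2 * eaf * (1 - eaf)
        den = num + se**2 * 2 * n * eaf * (1 - eaf)
        assert variance_explained(beta, se, eaf, n) == pytest.approx(num / den, rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        beta=st.floats(-5, 5, allow_nan=False),
        se=st.floats(1e-4, 2),
        eaf=st.floats(0.01, 0.99),
        n=st.integers(2, 10_000_000),
    )
    def test_simplified_identity(self, beta, se, eaf, n):
        expected = beta**2 / (beta**2 + se**2 * n)
        assert variance_explained(beta, se, eaf, n) == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= variance_explained(beta, se, eaf, n) < 1.0

    def test_eaf_degenerate_raises(self):
        with pytest.raises(ValueError):
            variance_explained(0.5, 0.05, 1.0, 1000)

    @pytest.mark.parametrize(
        "r2,expected", [(0.000714, 118.7), (0.000912, 151.7), (0.0, 0.0)]
    )
    def test_f_statistic_published_values(self, r2, expected):
        assert f_statistic(r2, 166_144) == pytest.approx(expected, abs=0.1)

    def test_f_monotone_in_r2(self):
        grid = np.linspace(0, 0.9, 50)
        fs = [f_statistic(r, 1000) for r in grid]
        assert np.all(np.diff(fs) > 0)

    def test_f_requires_r2_below_one(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 1000)


class TestWeakFilter:
    def test_boundary_at_ten(self):
        # craft records with F just below / at 10: r2 = F/(N-2+F)
        n = 10_000
        def with_f(f, snp):
            r2 = f / (n - 2 + f)
            beta = 1.0
            se = np.sqrt(beta**2 * (1 - r2) / (r2 * n))
            return rec(snp=snp, beta=beta, se=float(se), n=n)
        weak = with_f(9.99, "weak")
        strong = with_f(10.01, "strong")
        ledger = []
        kept = weak_instrument_filter([weak, strong], ledger=ledger)
        assert [r.snp_id for r in kept] == ["strong"]
        assert ledger[0].reason is ReasonCode.WEAK_INSTRUMENT

    def test_published_instruments_all_strong(self, as_instruments):
        kept = weak_instrument_filter(as_instruments)
        assert len(kept) == 7
        assert all(d.f_stat > 10 for d in grade_instruments(as_instruments))

    def test_empty_input(self):
        assert weak_instrument_filter([]) == []
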