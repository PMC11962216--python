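"""Instrument selection: cis/MAF/p filters, LD clumping, harmonization, Steiger, F."""

import itertools

import numpy as np
import pytest

from targetmr import (
    GeneInfo,
    LDMatrix,
    ThresholdConfig,
    f_filter,
    harmonize,
    ld_clump,
    select_cis_snps,
    select_instruments,
    steiger_filter,
)
from targetmr.instruments import read_ld_matrix, read_sumstats, write_ld_matrix, write_sumstats
from targetmr.simulate import SimConfig, make_truth, simulate_ld, simulate_summary_stats

from conftest import assoc, pair

GENE = GeneInfo("GENE1", "1", 2_000_000, 2_010_000)
CFG = ThresholdConfig()


class TestCisSelection:
    def test_window_boundary_is_inclusive(self):
        at_edge = assoc("rs_edge", pos_bp=GENE.start_bp - 1_000_000)
        outside = assoc("rs_out", pos_bp=GENE.start_bp - 1_000_001)
        kept = select_cis_snps([at_edge, outside], GENE, CFG)
        assert [r.snp_id for r in kept] == ["rs_edge"]

    def test_rare_variant_dropped_by_maf(self):
        rare = assoc("rs_rare", pos_bp=GENE.start_bp, eaf=0.995)  # MAF 0.005
        common = assoc("rs_common", pos_bp=GENE.start_bp, eaf=0.05)
        kept = select_cis_snps([rare, common], GENE, CFG)
        assert [r.snp_id for r in kept] == ["rs_common"]

    def test_pvalue_threshold_is_strict(self):
        at_threshold = assoc("rs_at", pos_bp=GENE.start_bp, pval=1e-5)
        below = assoc("rs_below", pos_bp=GENE.start_bp, pval=9.99e-6)
        kept = select_cis_snps([at_threshold, below], GENE, CFG)
        assert [r.snp_id for r in kept] == ["rs_below"]

    def test_missing_eaf_skips_maf_filter(self):
        rec = assoc("rs_na", pos_bp=GENE.start_bp, eaf=None)
        assert select_cis_snps([rec], GENE, CFG) == [rec]


def _ld_from_corr(snp_ids, r):
    return LDMatrix(snp_ids, np.array(r))


class TestLDClump:
    def test_correlated_weaker_snp_dropped(self):
        recs = [
            assoc("rs1", pos_bp=100, pval=1e-8),
            assoc("rs2", pos_bp=200, pval=1e-6),
        ]
        ld = _ld_from_corr(["rs1", "rs2"], [[1, 0.7], [0.7, 1]])  # r2=0.49
        kept = ld_clump(recs, ld, CFG)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_independent_snps_all_retained(self):
        recs = [assoc(f"rs{i}", pos_bp=100 * i, pval=1e-6 / (i + 1)) for i in range(5)]
        ld = _ld_from_corr([f"rs{i}" for i in range(5)], np.eye(5))
        assert len(ld_clump(recs, ld, CFG)) == 5

    def test_r2_below_threshold_retained(self):
        r = np.sqrt(0.29)
        recs = [assoc("rs1", pos_bp=100, pval=1e-8), assoc("rs2", pos_bp=200, pval=1e-6)]
        ld = _ld_from_corr(["rs1", "rs2"], [[1, r], [r, 1]])
        assert len(ld_clump(recs, ld, CFG)) == 2

    def test_result_independent_of_input_order(self, rng):
        n = 8
        ld = simulate_ld(n, 0.9)
        recs = [
            assoc(f"rs{i + 1}", pos_bp=1000 * i, pval=float(p))
            for i, p in enumerate(rng.uniform(1e-10, 1e-6, n))
        ]
        ref = [r.snp_id for r in ld_clump(recs, ld, CFG)]
        for _ in range(5):
            shuffled = list(rng.permutation(recs))
            assert [r.snp_id for r in ld_clump(shuffled, ld, CFG)] == ref

    def test_missing_snp_raises_naming_it(self):
        recs = [assoc("rs_absent", pos_bp=100)]
        ld = _ld_from_corr(["rs_other"], [[1.0]])
        with pytest.raises(KeyError, match="rs_absent"):
            ld_clump(recs, ld, CFG)

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_equals_exhaustive_oracle(self, seed):
        """Greedy clumping returns the significance-lexicographic-max admissible set."""
        rng = np.random.default_rng(seed)
        n = 8
        ld = simulate_ld(n, float(rng.uniform(0.5, 0.95)))
        recs = [
            assoc(f"rs{i + 1}", pos_bp=1000 * i, pval=float(p))
            for i, p in enumerate(rng.uniform(1e-12, 1e-6, n))
        ]
        rank = {r.snp_id: i for i, r in enumerate(sorted(recs, key=lambda r: (r.pval, r.pos_bp, r.snp_id)))}

        def admissible(subset):
            for a, b in itertools.combinations(subset, 2):
                if abs(a.pos_bp - b.pos_bp) <= CFG.clump_window_kb * 1000:
                    if ld.corr(a.snp_id, b.snp_id) ** 2 >= CFG.clump_r2:
                        return False
            return True

        all_admissible = [
            subset
            for k in range(1, n + 1)
            for subset in itertools.combinations(recs, k)
            if admissible(subset)
        ]
        # the greedy set is the admissible subset whose sorted rank vector is
        # lexicographically smallest among maximal (non-extendable) subsets
        def extendable(subset):
            return any(admissible(tuple(subset) + (r,)) for r in recs if r not in subset)

        maximal = [s for s in all_admissible if not extendable(s)]
        oracle = min(maximal, key=lambda s: tuple(sorted(rank[r.snp_id] for r in s)))
        greedy = ld_clump(recs, ld, CFG)
        assert sorted(r.snp_id for r in greedy) == sorted(r.snp_id for r in oracle)


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = assoc("rs1", effect_allele="A", other_allele="G", beta=0.10)
        out = assoc("rs1", effect_allele="G", other_allele="A", beta=0.05)
        (p,) = harmonize([exp], [out])
        assert p.beta_out == -0.05
        assert p.flipped

    def test_palindromic_snp_dropped(self):
        exp = assoc("rs1", effect_allele="A", other_allele="T")
        out = assoc("rs1", effect_allele="A", other_allele="T")
        assert harmonize([exp], [out]) == []

    def test_allele_mismatch_dropped(self):
        exp = assoc("rs1", effect_allele="A", other_allele="G")
        out = assoc("rs1", effect_allele="A", other_allele="C")
        assert harmonize([exp], [out]) == []

    def test_harmonize_is_idempotent_on_aligned_data(self):
        exp = [assoc(f"rs{i}", beta=0.1 * i + 0.05) for i in range(1, 4)]
        out = [assoc(f"rs{i}", beta=0.02 * i) for i in range(1, 4)]
        once = harmonize(exp, out)
        # re-expressing the harmonized outcome as records and re-harmonizing
        # changes nothing
        out2 = [
            assoc(f"rs{i}", beta=p.beta_out, se=p.se_out, pval=p.pval_out)
            for i, p in zip(range(1, 4), once)
        ]
        twice = harmonize(exp, out2)
        assert [(p.snp_id, p.beta_out, p.flipped) for p in twice] == [
            (p.snp_id, p.beta_out, False) for p in once
        ]

    def test_duplicate_snp_id_raises(self):
        exp = [assoc("rs1"), assoc("rs1")]
        with pytest.raises(ValueError, match="rs1"):
            harmonize(exp, [assoc("rs1")])


class TestSteigerFilter:
    def test_dominant_exposure_signal_kept(self):
        p = pair(beta_exp=0.5, beta_out=0.01, se_exp=0.01, se_out=0.01, n_exp=30000, n_out=30000)
        assert steiger_filter([p]) == [p]

    def test_symmetric_pair_dropped_on_tie(self):
        p = pair(beta_exp=0.1, beta_out=0.1, se_exp=0.01, se_out=0.01, n_exp=30000, n_out=30000)
        assert steiger_filter([p]) == []

    def test_missing_n_passes_with_warning(self):
        # n fields are typed as int, so exercise the eaf-missing fallback path
        p = pair(eaf=None)
        kept = steiger_filter([p])
        assert kept == [p]

    def test_correct_causal_direction_mostly_kept(self):
        """Under a true gene->outcome effect nearly all instruments survive."""
        kept = total = 0
        for s in range(30):
            cfg = SimConfig(n_snps=10, ld_rho=0.0, n_causal_eqtl=10, seed=300 + s)
            truth = make_truth(cfg, theta=0.2)
            e, o, _ = simulate_summary_stats(cfg, truth)
            pairs = harmonize(e, o)
            total += len(pairs)
            kept += len(steiger_filter(pairs))
        assert kept / total >= 0.95


class TestFFilter:
    def test_strong_instrument_kept(self):
        p = pair(beta_exp=0.1, se_exp=0.02)  # F=25
        assert f_filter([p]) == [p]

    def test_weak_instrument_dropped(self):
        p = pair(beta_exp=0.03, se_exp=0.01)  # F=9
        assert f_filter([p]) == []

    def test_retention_is_strict_at_the_boundary(self):
        just_below = pair(beta_exp=0.099999, se_exp=0.099999 / np.sqrt(10) * 1.0000001)
        assert (just_below.beta_exp / just_below.se_exp) ** 2 < 10
        assert f_filter([just_below]) == []

    def test_matches_bruteforce_recomputation(self, rng):
        pairs = [
            pair(f"rs{i}", beta_exp=float(b), se_exp=float(s))
            for i, (b, s) in enumerate(zip(rng.uniform(0.01, 0.2, 30), rng.uniform(0.005, 0.05, 30)))
        ]
        kept = f_filter(pairs)
        expected = [p for p in pairs if (p.beta_exp / p.se_exp) ** 2 > 10]
        assert kept == expected


class TestPipelineAccounting:
    def test_every_snp_in_pairs_or_dropped_exactly_once(self):
        cfg = SimConfig(n_snps=50, ld_rho=0.8, n_causal_eqtl=3, seed=11)
        truth = make_truth(cfg, theta=0.2)
        exposure, outcome, ld = simulate_summary_stats(cfg, truth)
        gene = GeneInfo("GENE1", "1", 1_000_000, 1_010_000)
        iset = select_instruments(exposure, outcome, ld, gene)
        surviving = {p.snp_id for p in iset.pairs}
        dropped = [s for s, _ in iset.dropped]
        assert surviving.isdisjoint(dropped)
        assert sorted(list(surviving) + dropped) == sorted(r.snp_id for r in exposure)
        valid_reasons = {
            "cis_window", "maf", "pval", "ld_clump", "allele_mismatch",
            "palindrome", "missing", "steiger", "weak_f",
        }
        assert {r for _, r in iset.dropped} <= valid_reasons


def test_sumstats_and_ld_round_trip(tmp_path):
    cfg = SimConfig(n_snps=12, ld_rho=0.5, seed=4)
    truth = make_truth(cfg, theta=0.1)
    exposure, _, ld = simulate_summary_stats(cfg, truth)
    write_sumstats(exposure, tmp_path / "exp.tsv")
    back = read_sumstats(tmp_path / "exp.tsv")
    assert [r.snp_id for r in back] == [r.snp_id for r in exposure]
    for a, b in zip(back, exposure):
        assert (a.chrom, a.pos_bp, a.effect_allele, a.other_allele, a.n) == (
            b.chrom, b.pos_bp, b.effect_allele, b.other_allele, b.n,
        )
        for f in ("eaf", "beta", "se", "pval"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)
    write_ld_matrix(ld, tmp_path / "ld.tsv")
    ld2 = read_ld_matrix(tmp_path / "ld.tsv")
    assert ld2.snp_ids == ld.snp_ids
    np.testing.assert_allclose(ld2.r, ld.r, atol=1e-12)
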