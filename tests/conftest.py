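import numpy as np
import pytest

from targetmr import (
    AssocRecord,
    CaseReport,
    HarmonizedPair,
    SimConfig,
    harmonize,
    make_truth,
    simulate_summary_stats,
)


def pair(
    snp_id="rs1",
    beta_exp=0.1,
    se_exp=0.01,
    pval_exp=1e-10,
    n_exp=30000,
    beta_out=0.02,
    se_out=0.01,
    pval_out=0.05,
    n_out=200000,
    eaf=0.3,
    flipped=False,
):
    return HarmonizedPair(
        snp_id, beta_exp, se_exp, pval_exp, n_exp, beta_out, se_out, pval_out, n_out, eaf, flipped
    )


def assoc(
    snp_id="rs1",
    chrom="1",
    pos_bp=1_000_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=1e-6,
    n=30000,
):
    return AssocRecord(snp_id, chrom, pos_bp, effect_allele, other_allele, eaf, beta, se, pval, n)


def report(case_id="C1", version=1, drug="TARGETDRUG", role="suspect", pt="Seizure", **kw):
    kw.setdefault("year", 2020)
    return CaseReport(case_id, version, drug, role, pt, **kw)


def strong_instrument_pairs(seed, theta=0.2, n_snps=20, **cfg_kw):
    """Harmonized pairs from an independent-SNP, all-causal simulation."""
    cfg = SimConfig(n_snps=n_snps, ld_rho=0.0, n_causal_eqtl=n_snps, seed=seed, **cfg_kw)
    truth = make_truth(cfg, theta=theta)
    exposure, outcome, _ = simulate_summary_stats(cfg, truth)
    return harmonize(exposure, outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
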