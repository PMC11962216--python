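"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

SMR estimates the effect of gene expression on an outcome from the single
top cis-eQTL SNP: b_smr = b_GWAS/b_eQTL, tested with

    T_smr = z_x² z_y² / (z_x² + z_y²)  ~  χ²(1)

where z_x and z_y are the eQTL and GWAS z-scores at that SNP.  A small
p_smr is compatible with either a shared causal variant (pleiotropy/
causality) or two distinct variants in LD (linkage).  The HEIDI test
distinguishes the two: under a single shared causal variant the ratio
b_GWAS/b_eQTL is the same at every SNP in the region, so the deviations
d_i = b_smr(i) − b_smr(top) at nearby eQTL SNPs should be pure noise.  HEIDI
refers Σ z_d² to its null distribution — a weighted mixture of χ²(1)
variables whose weights are the eigenvalues of the correlation matrix of d,
obtained from the regional LD structure by the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .instruments import HarmonizedPair, LDMatrix

__all__ = ["SMRResult", "smr_test", "heidi_test", "weighted_chi2_sf"]


@dataclass(frozen=True)
class SMRResult:
    gene_id: str
    outcome_id: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0


def smr_test(
    pairs: Sequence[HarmonizedPair], gene_id: str = "gene", outcome_id: str = "outcome"
) -> SMRResult:
    """SMR estimate at the top eQTL SNP (smallest exposure p-value)."""
    if not pairs:
        raise ValueError("smr_test needs at least one harmonized SNP")
    top = min(pairs, key=lambda p: (p.pval_exp, p.snp_id))
    if top.beta_exp == 0:
        raise ValueError(f"top SNP {top.snp_id}: beta_exp is zero")
    zx = top.beta_exp / top.se_exp
    zy = top.beta_out / top.se_out
    b_smr = top.beta_out / top.beta_exp
    t_smr = (zx**2 * zy**2) / (zx**2 + zy**2)
    p_smr = float(stats.chi2.sf(t_smr, 1))
    se_smr = abs(b_smr) / math.sqrt(t_smr) if t_smr > 0 else float("inf")
    return SMRResult(gene_id, outcome_id, top.snp_id, b_smr, se_smr, p_smr)


def weighted_chi2_sf(q: float, lam: np.ndarray) -> float:
    """P(Σ λ_k χ²₁ > q) by Imhof's numerical inversion of the characteristic
    function; exact up to quadrature error."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1)) if lam[0] > 0 else 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1 + (lam * u) ** 2) ** 0.25)
        return math.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        # the integrand oscillates; quad's subdivision warning is benign here
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, np.inf, limit=500)
    p = 0.5 + val / math.pi
    return float(min(max(p, 0.0), 1.0))


def heidi_test(
    region_pairs: Sequence[HarmonizedPair],
    ld: LDMatrix,
    top_snp: str,
    p_eqtl_max: float = 1.57e-3,
    r2_range: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
    min_snps: int = 3,
) -> tuple[float | None, int]:
    """HEIDI: heterogeneity in dependent instruments around the top eQTL SNP.

    Eligible SNPs have exposure p < ``p_eqtl_max`` and r² with the top SNP
    inside ``r2_range``; the ``max_snps`` most significant are used.  Returns
    ``(p_heidi, n_heidi_snps)``; fewer than ``min_snps`` eligible SNPs yield
    ``(None, count)`` with a warning.  Small p_heidi rejects the single
    shared causal variant null (heterogeneity, i.e. linkage).
    """
    by_id = {p.snp_id: p for p in region_pairs}
    if top_snp not in by_id:
        raise KeyError(f"top SNP {top_snp!r} not among region pairs")
    if top_snp not in ld:
        raise KeyError(f"top SNP {top_snp!r} absent from LD matrix")
    top = by_id[top_snp]
    lo, hi = r2_range
    eligible = []
    for p in region_pairs:
        if p.snp_id == top_snp or p.snp_id not in ld:
            continue
        if not (p.pval_exp < p_eqtl_max):
            continue
        r2 = ld.corr(p.snp_id, top_snp) ** 2
        if lo <= r2 <= hi and p.beta_exp != 0:
            eligible.append(p)
    eligible.sort(key=lambda p: (p.pval_exp, p.snp_id))
    eligible = eligible[:max_snps]
    n = len(eligible)
    if n < min_snps:
        warnings.warn(f"HEIDI: only {n} eligible SNPs (< {min_snps}); test not run")
        return None, n

    snps = [top] + eligible
    bx = np.array([p.beta_exp for p in snps])
    by = np.array([p.beta_out for p in snps])
    sx = np.array([p.se_exp for p in snps])
    sy = np.array([p.se_out for p in snps])
    r = np.array([[ld.corr(a.snp_id, b.snp_id) for b in snps] for a in snps])
    bxy = by / bx

    # delta-method covariance of b_smr across SNPs (two-sample: x and y
    # estimation errors independent, each correlated across SNPs through LD)
    cov_b = (
        r * np.outer(sy, sy) / np.outer(bx, bx)
        + r * np.outer(bxy, bxy) * np.outer(sx, sx) / np.outer(bx, bx)
    )
    # d_i = bxy[i] - bxy[0] for i = 1..n
    d = bxy[1:] - bxy[0]
    cov_d = cov_b[1:, 1:] - cov_b[1:, [0]] - cov_b[[0], 1:] + cov_b[0, 0]
    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    corr_d = cov_d / np.outer(sd, sd)
    t_heidi = float(np.sum(z_d**2))
    lam = np.linalg.eigvalsh(corr_d)
    lam = np.clip(lam, 0.0, None)
    p_heidi = weighted_chi2_sf(t_heidi, lam)
    return max(p_heidi, np.finfo(float).tiny), n
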