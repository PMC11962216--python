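"""Approximate-Bayes-factor colocalization of two association signals.

For each SNP and trait a Wakefield approximate Bayes factor compares
"associated" against "null":

    log ABF = ½ log(1 − r) + ½ z² r,    r = ω²/(ω² + se²)

with ω the prior SD of the true effect.  Assuming at most one causal variant
per trait, summing prior-weighted ABFs over SNP configurations yields
posterior probabilities for five hypotheses: H0 no association, H1/H2 one
trait only, H3 both traits via distinct variants, H4 both traits via a
shared variant.  H4 above 50% is read as possible colocalization and at or
above 80% as highly likely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .instruments import AssocRecord

__all__ = ["ColocResult", "log_abf", "coloc_abf", "classify_coloc"]


@dataclass(frozen=True)
class ColocResult:
    gene_id: str
    outcome_id: str
    n_snps: int
    pp: tuple[float, float, float, float, float]  # H0..H4
    priors: tuple[float, float, float]  # p1, p2, p12
    verdict: str

    @property
    def pp_h4(self) -> float:
        return self.pp[4]


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one SNP-trait association."""
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    return 0.5 * math.log(1 - r) + 0.5 * z**2 * r


def classify_coloc(pp_h4: float) -> str:
    """'highly_likely' at PP.H4 ≥ 0.8, 'possible' above 0.5, else 'none'."""
    if pp_h4 >= 0.8:
        return "highly_likely"
    if pp_h4 > 0.5:
        return "possible"
    return "none"


def coloc_abf(
    trait1: Sequence[AssocRecord],
    trait2: Sequence[AssocRecord],
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.2,
    gene_id: str = "gene",
    outcome_id: str = "outcome",
) -> ColocResult:
    """Colocalize two traits over the SNPs they share.

    ``prior_sd1``/``prior_sd2`` are the effect-size prior SDs (0.15 for a
    quantitative trait, 0.2 for case-control log-odds); ``p1``, ``p2``,
    ``p12`` are per-SNP prior probabilities of trait-1-only, trait-2-only
    and shared causality.  All hypothesis sums are done in log space.
    """
    by_id2 = {r.snp_id: r for r in trait2}
    shared = [(r, by_id2[r.snp_id]) for r in trait1 if r.snp_id in by_id2]
    if not shared:
        raise ValueError("traits share no SNPs")
    l1 = np.array([log_abf(a.beta, a.se, prior_sd1) for a, _ in shared])
    l2 = np.array([log_abf(b.beta, b.se, prior_sd2) for _, b in shared])

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered pairs i != j of exp(l1_i + l2_j)
    both = s1 + s2
    if len(shared) == 1:
        s3 = -np.inf
    else:
        # log( exp(both) - exp(s12) ), guarded against cancellation
        diff = both + np.log1p(-np.exp(min(s12 - both, -1e-300)))
        s3 = diff if np.isfinite(diff) else -np.inf

    lh = np.array(
        [
            0.0,
            math.log(p1) + s1,
            math.log(p2) + s2,
            math.log(p1) + math.log(p2) + s3,
            math.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    verdict = classify_coloc(float(pp[4]))
    return ColocResult(
        gene_id=gene_id,
        outcome_id=outcome_id,
        n_snps=len(shared),
        pp=tuple(float(x) for x in pp),
        priors=(p1, p2, p12),
        verdict=verdict,
    )
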