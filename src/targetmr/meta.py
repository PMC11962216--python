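"""Inverse-variance meta-analysis of MR estimates across GWAS sources.

The same gene-outcome effect estimated against two independent outcome
datasets (e.g. a biobank endpoint and a consortium GWAS) is pooled by
fixed-effect inverse-variance weighting; a DerSimonian-Laird random-effects
model is available when between-study heterogeneity (Cochran's Q, I²)
matters.  Effects are on the log-odds scale and reported as OR with 95% CI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

__all__ = ["MetaInput", "MetaResult", "meta_fixed", "meta_random", "se_from_p"]

Z95 = 1.96


@dataclass(frozen=True)
class MetaInput:
    """Per-study effect estimates: (label, beta, se)."""

    studies: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if any(se <= 0 for _, _, se in self.studies):
            raise ValueError("study standard errors must be positive")

    @classmethod
    def from_studies(cls, studies: Sequence[tuple[str, float, float]]) -> "MetaInput":
        return cls(tuple((str(l), float(b), float(s)) for l, b, s in studies))


@dataclass(frozen=True)
class MetaResult:
    model: str  # 'fixed' or 'random'
    k: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    q: float
    q_pval: float
    i2: float
    tau2: float = 0.0


def se_from_p(beta: float, p: float) -> float:
    """Back-derive a standard error from a two-sided p-value.

    Exact-bound p-values ("<0.01" style, i.e. p at or outside (0,1)) are
    rejected rather than guessed.
    """
    if not (0 < p < 1):
        raise ValueError(f"cannot back-derive se from bound or degenerate p={p!r}")
    z = stats.norm.ppf(1 - p / 2)
    if z <= 0:
        raise ValueError(f"p={p} gives non-positive z")
    return abs(beta) / z


def _finish(model: str, k: int, beta: float, se: float, q: float, df: int, tau2: float) -> MetaResult:
    pval = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 1.0
    q_pval = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        model=model,
        k=k,
        beta=beta,
        se=se,
        pval=float(pval),
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        q=q,
        q_pval=q_pval,
        i2=i2,
        tau2=tau2,
    )


def _q_stat(studies) -> tuple[float, float, float, float]:
    w = [1 / se**2 for _, _, se in studies]
    sw = sum(w)
    beta = sum(wi * b for wi, (_, b, _) in zip(w, studies)) / sw
    q = sum(wi * (b - beta) ** 2 for wi, (_, b, _) in zip(w, studies))
    sw2 = sum(wi**2 for wi in w)
    return beta, sw, q, sw2


def meta_fixed(inp: MetaInput) -> MetaResult:
    """Fixed-effect inverse-variance pooling; single-study input passes through."""
    studies = inp.studies
    k = len(studies)
    if k < 2:
        warnings.warn("meta_fixed: fewer than 2 studies; returning the single study unchanged")
        _, b, se = studies[0]
        return _finish("fixed", 1, b, se, 0.0, 0, 0.0)
    beta, sw, q, _ = _q_stat(studies)
    return _finish("fixed", k, beta, 1 / math.sqrt(sw), q, k - 1, 0.0)


def meta_random(inp: MetaInput) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau² = max(0, (Q − df)/(Σw − Σw²/Σw)) from the fixed-effect weights;
    when Q ≤ df this reduces to the fixed-effect result (tau² = 0).
    """
    studies = inp.studies
    k = len(studies)
    if k < 2:
        warnings.warn("meta_random: fewer than 2 studies; returning the single study unchanged")
        _, b, se = studies[0]
        return _finish("random", 1, b, se, 0.0, 0, 0.0)
    _, sw, q, sw2 = _q_stat(studies)
    df = k - 1
    tau2 = max(0.0, (q - df) / (sw - sw2 / sw))
    w = [1 / (se**2 + tau2) for _, _, se in studies]
    swr = sum(w)
    beta = sum(wi * b for wi, (_, b, _) in zip(w, studies)) / swr
    return _finish("random", k, beta, 1 / math.sqrt(swr), q, df, tau2)
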