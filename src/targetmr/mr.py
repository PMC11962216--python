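"""Two-sample Mendelian randomization estimators and sensitivity analyses.

Given harmonized per-SNP exposure and outcome effects, the causal effect of
the exposure (gene expression) on the outcome (disease liability, log-odds)
is estimated by:

* Wald ratio — β_out/β_exp for a single instrument;
* inverse-variance weighting (IVW) — the primary estimator, a weighted
  regression of outcome on exposure effects through the origin;
* MR-Egger — the same regression with an intercept absorbing directional
  pleiotropy;
* weighted median — consistent when ≥50% of instrument weight is valid;
* weighted mode — consistent when the largest cluster of instruments is valid.

Sensitivity diagnostics cover Cochran's Q heterogeneity, the Egger
intercept, and leave-one-out re-estimation.  The module exposes both plain
functions per estimator and a Model/Results pair (:class:`MRModel`,
:class:`MRResults`) for the fit-then-inspect workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .instruments import HarmonizedPair

__all__ = [
    "MREstimate",
    "SensitivityReport",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "sensitivity",
    "MRModel",
    "MRResults",
]

Z95 = 1.96


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds scale with OR and 95% CI."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "or_", math.exp(self.beta))
        object.__setattr__(self, "ci_low", math.exp(self.beta - Z95 * self.se))
        object.__setattr__(self, "ci_high", math.exp(self.beta + Z95 * self.se))


@dataclass(frozen=True)
class SensitivityReport:
    q: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    loo: list[tuple[str, MREstimate]]


def _norm_p(beta: float, se: float) -> float:
    return 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    return bx, by, sx, sy


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate β_out/β_exp.

    SE is the first-order delta approximation se_out/|β_exp|; with
    ``second_order`` the exposure uncertainty is propagated as well.
    """
    if pair.beta_exp == 0:
        raise ValueError(f"{pair.snp_id}: beta_exp is zero, Wald ratio undefined")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    if second_order:
        se = math.sqrt(
            pair.se_out**2 / pair.beta_exp**2
            + pair.beta_out**2 * pair.se_exp**2 / pair.beta_exp**4
        )
    return MREstimate("wald_ratio", beta, se, _norm_p(beta, se), 1)


def ivw(pairs: Sequence[HarmonizedPair], random_effects: bool = False) -> MREstimate:
    """Inverse-variance-weighted estimate (fixed-effect by default).

    β = Σ(βx·βy/se_y²)/Σ(βx²/se_y²), se = 1/√Σ(βx²/se_y²); with
    ``random_effects`` the SE is inflated by max(1, √(Q/(n−1)))
    (multiplicative random effects).
    """
    if len(pairs) < 2:
        raise ValueError("ivw needs >= 2 instruments; use wald_ratio for a single SNP")
    bx, by, _, sy = _arrays(pairs)
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1 / np.sqrt(np.sum(w)))
    if random_effects:
        q = float(np.sum(w * (by / bx - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (len(pairs) - 1)))
    return MREstimate("ivw", beta, se, _norm_p(beta, se), len(pairs))


def mr_egger(pairs: Sequence[HarmonizedPair]):
    """Egger regression: WLS of β_out on β_exp with intercept, weights 1/se_out².

    Pairs are oriented so β_exp > 0 before fitting.  Returns
    ``(slope_estimate, intercept, intercept_se, intercept_pval)``; slope and
    intercept are tested on t(nsnp−2).
    """
    if len(pairs) < 3:
        raise ValueError("mr_egger needs >= 3 instruments")
    bx, by, _, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1 / sy**2).fit()
    df = len(pairs) - 2
    slope, slope_se = float(fit.params[1]), float(fit.bse[1])
    icpt, icpt_se = float(fit.params[0]), float(fit.bse[0])
    slope_p = 2 * stats.t.sf(abs(slope / slope_se), df)
    icpt_p = 2 * stats.t.sf(abs(icpt / icpt_se), df)
    est = MREstimate("egger", slope, slope_se, float(slope_p), len(pairs))
    return est, icpt, icpt_se, float(icpt_p)


def _ratio_weights(pairs: Sequence[HarmonizedPair]):
    bx, by, _, sy = _arrays(pairs)
    ratio = by / bx
    w = bx**2 / sy**2  # 1/var of the first-order ratio SE
    return ratio, w


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    """Weighted median with linear interpolation at the 50% weight point."""
    order = np.argsort(ratio)
    r, ww = ratio[order], w[order]
    cum = np.cumsum(ww) - 0.5 * ww
    cum /= np.sum(ww)
    return float(np.interp(0.5, cum, r))


def weighted_median(
    pairs: Sequence[HarmonizedPair], n_boot: int = 1000, seed: int | None = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios (50%-valid-weight robustness).

    SE via seeded parametric bootstrap: β_exp and β_out are redrawn from
    normal distributions centred on the observed values.
    """
    if len(pairs) < 3:
        raise ValueError("weighted_median needs >= 3 instruments")
    ratio, w = _ratio_weights(pairs)
    beta = _weighted_median_point(ratio, w)
    se = _bootstrap_se(_weighted_median_point, pairs, n_boot, seed)
    return MREstimate("weighted_median", beta, se, _norm_p(beta, se), len(pairs))


def _mode_bandwidth(ratio: np.ndarray, se_ratio: np.ndarray, factor: float) -> float:
    # modified Silverman rule on the ratio spread (MAD-based, outlier-robust)
    mad = np.median(np.abs(ratio - np.median(ratio))) / stats.norm.ppf(0.75)
    s = mad if mad > 0 else np.std(ratio)
    if s == 0:
        s = float(np.mean(se_ratio))
    return max(factor * 0.9 * s * len(ratio) ** (-0.2), 1e-8)


def _weighted_mode_point(ratio: np.ndarray, w: np.ndarray, bandwidth: float = 1.0) -> float:
    se_ratio = 1 / np.sqrt(w)
    h = _mode_bandwidth(ratio, se_ratio, bandwidth)
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2)).sum(axis=1)
    mode = float(grid[np.argmax(dens)])
    return min(max(mode, float(ratio.min())), float(ratio.max()))


def weighted_mode(
    pairs: Sequence[HarmonizedPair],
    bandwidth: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Mode of the smoothed weighted density of Wald ratios (plurality-valid).

    Normal kernel with a modified-Silverman bandwidth scaled by
    ``bandwidth``; SE via seeded parametric bootstrap.  The mode is clipped
    to the observed ratio range.
    """
    if len(pairs) < 3:
        raise ValueError("weighted_mode needs >= 3 instruments")
    ratio, w = _ratio_weights(pairs)
    beta = _weighted_mode_point(ratio, w, bandwidth)
    se = _bootstrap_se(lambda r, ww: _weighted_mode_point(r, ww, bandwidth), pairs, n_boot, seed)
    return MREstimate("weighted_mode", beta, se, _norm_p(beta, se), len(pairs))


def _bootstrap_se(point_fn, pairs: Sequence[HarmonizedPair], n_boot: int, seed: int | None) -> float:
    if n_boot < 2:
        # degenerate request: fall back to the IVW-style weight-based SE
        _, w = _ratio_weights(pairs)
        return float(1 / np.sqrt(np.sum(w)))
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = _arrays(pairs)
    ests = np.empty(n_boot)
    bxs = rng.normal(bx, sx, size=(n_boot, len(pairs)))
    bys = rng.normal(by, sy, size=(n_boot, len(pairs)))
    bxs[bxs == 0] = 1e-12
    for i in range(n_boot):
        ratio = bys[i] / bxs[i]
        w = bxs[i] ** 2 / sy**2
        ests[i] = point_fn(ratio, w)
    return float(np.std(ests, ddof=1))


def sensitivity(pairs: Sequence[HarmonizedPair], primary: MREstimate | None = None) -> SensitivityReport:
    """Cochran's Q, Egger intercept and leave-one-out diagnostics.

    Q = Σ wᵢ(ratioᵢ − β_ivw)² with wᵢ = β_expᵢ²/se_outᵢ², referred to
    χ²(nsnp−1).  The Egger intercept is reported only for nsnp ≥ 3.
    Leave-one-out refits IVW (or the Wald ratio at nsnp=2) on each subset.
    """
    if len(pairs) < 2:
        raise ValueError("sensitivity needs >= 2 instruments")
    if primary is None:
        primary = ivw(pairs)
    ratio, w = _ratio_weights(pairs)
    q = float(np.sum(w * (ratio - primary.beta) ** 2))
    q_df = len(pairs) - 1
    q_pval = float(stats.chi2.sf(q, q_df))
    if len(pairs) >= 3:
        _, icpt, icpt_se, icpt_p = mr_egger(pairs)
    else:
        icpt = icpt_se = icpt_p = None
    loo = []
    for i, p in enumerate(pairs):
        rest = [q_ for j, q_ in enumerate(pairs) if j != i]
        est = ivw(rest) if len(rest) >= 2 else wald_ratio(rest[0])
        loo.append((p.snp_id, est))
    return SensitivityReport(q, q_df, q_pval, icpt, icpt_se, icpt_p, loo)


# ---------------------------------------------------------------------------
# Model/Results surface


class MRModel:
    """Two-sample MR model over a set of harmonized instruments.

    Parameters
    ----------
    pairs
        Harmonized exposure/outcome effects, one per instrument SNP.
    exposure, outcome
        Optional labels carried through to results and summaries.
    """

    def __init__(
        self,
        pairs: Sequence[HarmonizedPair],
        exposure: str = "exposure",
        outcome: str = "outcome",
    ):
        if not pairs:
            raise ValueError("MRModel needs at least one instrument")
        self.pairs = list(pairs)
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MRModel":
        """Build from a dataframe with columns snp_id, beta_exp, se_exp,
        pval_exp, n_exp, beta_out, se_out, pval_out, n_out [, eaf, flipped]."""
        pairs = [
            HarmonizedPair(
                snp_id=str(r.snp_id),
                beta_exp=float(r.beta_exp),
                se_exp=float(r.se_exp),
                pval_exp=float(r.pval_exp),
                n_exp=int(r.n_exp),
                beta_out=float(r.beta_out),
                se_out=float(r.se_out),
                pval_out=float(r.pval_out),
                n_out=int(r.n_out),
                eaf=float(r.eaf) if "eaf" in df.columns and not pd.isna(r.eaf) else None,
                flipped=bool(getattr(r, "flipped", False)),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(pairs, **kw)

    @property
    def nsnp(self) -> int:
        return len(self.pairs)

    def fit(
        self,
        methods: Sequence[str] | None = None,
        random_effects: bool = False,
        n_boot: int = 1000,
        seed: int | None = 0,
    ) -> "MRResults":
        """Run the primary estimator and whichever assist methods nsnp permits.

        With one instrument the primary method is the Wald ratio; with two or
        more it is IVW, and Egger/weighted-median/weighted-mode are added for
        nsnp ≥ 3 (or on request via ``methods``).
        """
        if methods is None:
            if self.nsnp == 1:
                methods = ["wald_ratio"]
            elif self.nsnp == 2:
                methods = ["ivw"]
            else:
                methods = ["ivw", "egger", "weighted_median", "weighted_mode"]
        estimates: dict[str, MREstimate] = {}
        egger_extra = None
        for m in methods:
            if m == "wald_ratio":
                estimates[m] = wald_ratio(self.pairs[0])
            elif m == "ivw":
                estimates[m] = ivw(self.pairs, random_effects=random_effects)
            elif m == "egger":
                est, icpt, icpt_se, icpt_p = mr_egger(self.pairs)
                estimates[m] = est
                egger_extra = (icpt, icpt_se, icpt_p)
            elif m == "weighted_median":
                estimates[m] = weighted_median(self.pairs, n_boot=n_boot, seed=seed)
            elif m == "weighted_mode":
                estimates[m] = weighted_mode(self.pairs, n_boot=n_boot, seed=seed)
            else:
                raise ValueError(f"unknown MR method {m!r}")
        primary = estimates.get("ivw") or estimates.get("wald_ratio") or next(iter(estimates.values()))
        sens = sensitivity(self.pairs, primary) if self.nsnp >= 2 else None
        return MRResults(self, estimates, primary, sens, egger_extra)


class MRResults:
    """Estimates, diagnostics and a text summary from :meth:`MRModel.fit`."""

    def __init__(self, model, estimates, primary, sensitivity_report, egger_extra):
        self.model = model
        self.estimates = estimates
        self.primary = primary
        self.sensitivity = sensitivity_report
        self._egger_extra = egger_extra

    @property
    def beta(self) -> float:
        return self.primary.beta

    @property
    def se(self) -> float:
        return self.primary.se

    @property
    def pval(self) -> float:
        return self.primary.pval

    @property
    def egger_intercept(self):
        return self._egger_extra

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": e.method,
                "nsnp": e.nsnp,
                "beta": e.beta,
                "se": e.se,
                "pval": e.pval,
                "or": e.or_,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Two-sample MR: {m.exposure} -> {m.outcome}  (nsnp={m.nsnp})",
            "-" * 64,
            f"{'method':<18}{'beta':>9}{'se':>9}{'OR':>8}{'95% CI':>17}{'p':>10}",
        ]
        for e in self.estimates.values():
            ci = f"({e.ci_low:.2f},{e.ci_high:.2f})"
            lines.append(
                f"{e.method:<18}{e.beta:>9.4f}{e.se:>9.4f}{e.or_:>8.3f}{ci:>17}{e.pval:>10.3g}"
            )
        if self.sensitivity is not None:
            s = self.sensitivity
            lines.append("-" * 64)
            lines.append(f"Cochran Q = {s.q:.3f} on {s.q_df} df, p = {s.q_pval:.3g}")
            if s.egger_intercept is not None:
                lines.append(
                    f"Egger intercept = {s.egger_intercept:.4f} "
                    f"(se {s.egger_intercept_se:.4f}, p = {s.egger_intercept_pval:.3g})"
                )
        return "\n".join(lines)
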