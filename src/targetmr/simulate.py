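"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators mirror the two data arms of the analysis:

* ``simulate_summary_stats`` emulates two-sample summary data — cis-eQTL
  (exposure) and disease GWAS (outcome) statistics over an LD-structured
  region.  Simulation happens at the z-score level: true joint SNP effects
  on the standardized-genotype scale are mapped to marginal effects through
  the LD matrix R, and observed z-scores are drawn from MVN(√n·R·b, R),
  the standard asymptotic model for GWAS summary statistics.  The outcome's
  joint effects are θ·(eQTL effects) + per-allele pleiotropy, so the true
  causal effect, instrument strengths and pleiotropic bias are all known
  exactly.
* ``simulate_reports`` emulates a spontaneous-report extract: case reports
  with a configurable target-drug prevalence, baseline event reporting rate
  and drug-event reporting risk ratio, demographic mixes patterned on
  observed adverse-event report characteristics, plus injected duplicate
  versions to exercise deduplication.

Both are driven by one integer seed, expanded into independent substreams
per component, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .faers import CaseReport, write_reports_csv
from .instruments import AssocRecord, GeneInfo, LDMatrix, write_ld_matrix, write_sumstats

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_ld",
    "make_truth",
    "simulate_summary_stats",
    "simulate_reports",
    "write_dataset",
]

# non-palindromic allele pairs only, unless palindrome testing is requested
_ALLELE_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))

# demographic mixes for report simulation (levels, probabilities); patterned
# on the overall column of a large FAERS antipsychotic extract
_SEX_MIX = ((None, 0.127), ("F", 0.453), ("M", 0.420))
_WEIGHT_MIX = ((None, 0.788), ("<50", 0.018), ("50-100", 0.151), (">100", 0.043))
_AGE_MIX = ((None, 0.481), ("<18", 0.035), ("18-64.9", 0.407), ("65-85", 0.068), (">85", 0.009))
_REPORTER_MIX = (
    (None, 0.064),
    ("CN", 0.341),
    ("HP", 0.061),
    ("LW", 0.024),
    ("MD", 0.281),
    ("OT", 0.143),
    ("PH", 0.086),
)
_COUNTRY_MIX = (
    (None, 0.030),
    ("US", 0.366),
    ("Japan", 0.030),
    ("UK", 0.018),
    ("Germany", 0.008),
    ("France", 0.008),
    ("Other", 0.540),
)
_WEIGHT_RANGES = {"<50": (30.0, 50.0), "50-100": (50.0, 100.0), ">100": (100.0, 160.0)}
_AGE_RANGES = {"<18": (1.0, 18.0), "18-64.9": (18.0, 64.9), "65-85": (65.0, 85.0), ">85": (85.1, 100.0)}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the package's reference study conditions."""

    # genetic arm
    n_snps: int = 200
    ld_rho: float = 0.8  # AR(1) LD decay
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 31684  # blood eQTL meta-analysis scale
    n_out: int = 200000  # biobank GWAS scale
    n_causal_eqtl: int = 3
    pleiotropy_mode: str = "none"  # none | directional | balanced
    pleiotropy_effect: float = 0.02  # per-allele direct outcome effect
    pleiotropy_frac: float = 1.0  # fraction of causal SNPs that are pleiotropic
    include_palindromes: bool = False
    # pharmacovigilance arm
    n_reports: int = 100000
    baseline_event_rate: float = 0.0135
    pr_target_drug: float = 0.3
    concomitant_frac: float = 0.1
    duplicate_frac: float = 0.05
    years: tuple[int, int] = (2004, 2023)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0,1)")
        if self.n_causal_eqtl > self.n_snps:
            raise ValueError("n_causal_eqtl cannot exceed n_snps")
        for rate in (self.baseline_event_rate, self.pr_target_drug):
            if not (0 < rate < 1):
                raise ValueError("rates must be in (0,1)")
        if self.pleiotropy_mode not in {"none", "directional", "balanced"}:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters that acceptance tests try to recover."""

    theta: float  # gene -> outcome causal effect (log-odds per SD expression)
    eqtl_effects: dict  # snp_id -> joint eQTL effect, standardized scale
    pleiotropy: dict  # snp_id -> direct outcome effect, per-allele scale
    rr_report: float  # drug-event reporting risk ratio
    seed: int


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("truth", "maf", "alleles", "z_exp", "z_out", "reports")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_ld(n_snps: int, ld_rho: float) -> LDMatrix:
    """AR(1) LD: r[i,j] = ld_rho^|i-j|; positive definite for ld_rho < 1."""
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0,1)")
    idx = np.arange(n_snps)
    r = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix([f"rs{i + 1}" for i in range(n_snps)], r)


def default_gene(cfg: SimConfig) -> GeneInfo:
    """Gene body placed so all simulated SNPs fall in its cis window."""
    return GeneInfo("GENE1", "1", 1_000_000, 1_010_000)


def _snp_positions(cfg: SimConfig, gene: GeneInfo) -> np.ndarray:
    # SNPs every 1 kb starting just upstream of the gene body
    return gene.start_bp - 100_000 + 1000 * np.arange(cfg.n_snps)


def make_truth(
    cfg: SimConfig,
    theta: float = 0.0,
    eqtl_beta: float = 0.05,
    rr_report: float = 1.672,
) -> SimTruth:
    """Fix the ground truth for a configuration.

    Causal eQTL SNPs are spread evenly across the region with joint effects
    drawn uniformly from [0.5, 1.5] x ``eqtl_beta`` on the standardized
    scale (z ≈ √n_exp · effect at the causal SNP, i.e. strong instruments
    with realistically varied strengths at the default sample size).
    Pleiotropy per ``cfg.pleiotropy_mode``: 'directional' adds
    +pleiotropy_effect to the first ``pleiotropy_frac`` of causal SNPs;
    'balanced' alternates the sign.
    """
    rng = _streams(cfg.seed)["truth"]
    step = max(1, cfg.n_snps // cfg.n_causal_eqtl)
    causal = [min(i * step, cfg.n_snps - 1) for i in range(cfg.n_causal_eqtl)]
    effects = eqtl_beta * rng.uniform(0.5, 1.5, size=len(causal))
    eqtl = {f"rs{i + 1}": float(b) for i, b in zip(causal, effects)}
    pleio: dict[str, float] = {}
    if cfg.pleiotropy_mode != "none":
        n_pleio = int(round(cfg.pleiotropy_frac * len(causal)))
        for j, i in enumerate(causal[:n_pleio]):
            sign = 1.0 if cfg.pleiotropy_mode == "directional" or j % 2 == 0 else -1.0
            pleio[f"rs{i + 1}"] = sign * cfg.pleiotropy_effect
    return SimTruth(theta=theta, eqtl_effects=eqtl, pleiotropy=pleio, rr_report=rr_report, seed=cfg.seed)


def _draw_assoc(
    rng: np.random.Generator,
    snp_ids: list[str],
    positions: np.ndarray,
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    chol: np.ndarray,
    joint_std: np.ndarray,
    n: int,
    ld_r: np.ndarray,
) -> list[AssocRecord]:
    scale = np.sqrt(2 * eaf * (1 - eaf))
    se = 1 / (scale * np.sqrt(n))
    z_mean = np.sqrt(n) * (ld_r @ joint_std)
    z = z_mean + chol @ rng.standard_normal(len(snp_ids))
    beta = z * se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return [
        AssocRecord(
            snp_id=snp_ids[i],
            chrom="1",
            pos_bp=int(positions[i]),
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pval=float(pval[i]),
            n=n,
        )
        for i in range(len(snp_ids))
    ]


def simulate_summary_stats(
    cfg: SimConfig, truth: SimTruth
) -> tuple[list[AssocRecord], list[AssocRecord], LDMatrix]:
    """Draw exposure (eQTL) and outcome (GWAS) summary statistics.

    Returns ``(exposure, outcome, ld)`` sharing SNP ids, positions, alleles
    and EAFs; the two z-score draws are independent (two-sample design) but
    each is MVN with the LD correlation structure.
    """
    rngs = _streams(cfg.seed)
    ld = simulate_ld(cfg.n_snps, cfg.ld_rho)
    snp_ids = ld.snp_ids
    gene = default_gene(cfg)
    positions = _snp_positions(cfg, gene)
    eaf = rngs["maf"].uniform(*cfg.maf_range, size=cfg.n_snps)
    pool = _ALLELE_PAIRS + (_PALINDROMIC_PAIRS if cfg.include_palindromes else ())
    alleles = [pool[i] for i in rngs["alleles"].integers(0, len(pool), size=cfg.n_snps)]
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(cfg.n_snps))

    idx = {s: i for i, s in enumerate(snp_ids)}
    joint_exp = np.zeros(cfg.n_snps)
    for snp, b in truth.eqtl_effects.items():
        joint_exp[idx[snp]] = b
    scale = np.sqrt(2 * eaf * (1 - eaf))
    joint_out = truth.theta * joint_exp
    for snp, c in truth.pleiotropy.items():
        # per-allele direct effect -> standardized scale
        joint_out[idx[snp]] += c * scale[idx[snp]]

    exposure = _draw_assoc(
        rngs["z_exp"], snp_ids, positions, alleles, eaf, chol, joint_exp, cfg.n_exp, ld.r
    )
    outcome = _draw_assoc(
        rngs["z_out"], snp_ids, positions, alleles, eaf, chol, joint_out, cfg.n_out, ld.r
    )
    return exposure, outcome, ld


def _draw_mix(rng: np.random.Generator, mix, size: int) -> np.ndarray:
    levels = [m[0] for m in mix]
    probs = np.array([m[1] for m in mix])
    probs = probs / probs.sum()
    return rng.choice(len(levels), p=probs, size=size)


def simulate_reports(cfg: SimConfig, truth: SimTruth) -> list[CaseReport]:
    """Draw a spontaneous-report table with known reporting risk ratio.

    Target-drug reports occur with probability ``pr_target_drug``; the
    target event is reported at ``baseline_event_rate`` for other drugs and
    ``baseline_event_rate * truth.rr_report`` for the target drug.  A
    ``duplicate_frac`` fraction of cases receives an extra, newer version
    (differing only in version number) to exercise deduplication.
    """
    rng = _streams(cfg.seed)["reports"]
    n = cfg.n_reports
    is_target_drug = rng.random(n) < cfg.pr_target_drug
    p_event = np.where(
        is_target_drug, cfg.baseline_event_rate * truth.rr_report, cfg.baseline_event_rate
    )
    if p_event.max() >= 1:
        raise ValueError("baseline_event_rate * rr_report must stay below 1")
    has_event = rng.random(n) < p_event
    is_suspect = rng.random(n) >= cfg.concomitant_frac
    sex_i = _draw_mix(rng, _SEX_MIX, n)
    wt_i = _draw_mix(rng, _WEIGHT_MIX, n)
    age_i = _draw_mix(rng, _AGE_MIX, n)
    rep_i = _draw_mix(rng, _REPORTER_MIX, n)
    cty_i = _draw_mix(rng, _COUNTRY_MIX, n)
    years = rng.integers(cfg.years[0], cfg.years[1] + 1, size=n)
    wt_u = rng.random(n)
    age_u = rng.random(n)

    reports: list[CaseReport] = []
    for i in range(n):
        wt_level = _WEIGHT_MIX[wt_i[i]][0]
        age_level = _AGE_MIX[age_i[i]][0]
        if wt_level is None:
            weight = None
        else:
            lo, hi = _WEIGHT_RANGES[wt_level]
            weight = round(lo + (hi - lo) * wt_u[i], 1)
        if age_level is None:
            age = None
        else:
            lo, hi = _AGE_RANGES[age_level]
            age = round(lo + (hi - lo) * age_u[i], 1)
        reports.append(
            CaseReport(
                case_id=f"C{i + 1:08d}",
                version=1,
                drug="TARGETDRUG" if is_target_drug[i] else "OTHERDRUG",
                role="suspect" if is_suspect[i] else "concomitant",
                pt="Seizure" if has_event[i] else "Nausea",
                sex=_SEX_MIX[sex_i[i]][0],
                age_years=age,
                weight_kg=weight,
                reporter=_REPORTER_MIX[rep_i[i]][0],
                country=_COUNTRY_MIX[cty_i[i]][0],
                year=int(years[i]),
            )
        )
    # inject newer duplicate versions for a deterministic subset of cases
    n_dup = int(round(cfg.duplicate_frac * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    for i in dup_idx:
        base = reports[int(i)]
        reports.append(
            CaseReport(
                case_id=base.case_id,
                version=base.version + 1,
                drug=base.drug,
                role=base.role,
                pt=base.pt,
                sex=base.sex,
                age_years=base.age_years,
                weight_kg=base.weight_kg,
                reporter=base.reporter,
                country=base.country,
                year=base.year,
            )
        )
    return reports


def write_dataset(cfg: SimConfig, truth: SimTruth, outdir) -> dict[str, Path]:
    """Write all synthetic inputs (summary stats, LD, reports, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, ld = simulate_summary_stats(cfg, truth)
    reports = simulate_reports(cfg, truth)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "reports": outdir / "reports.csv",
        "truth": outdir / "truth.json",
    }
    write_sumstats(exposure, paths["exposure"])
    write_sumstats(outcome, paths["outcome"])
    write_ld_matrix(ld, paths["ld"])
    write_reports_csv(reports, paths["reports"])
    paths["truth"].write_text(json.dumps(asdict(truth), indent=2, sort_keys=True))
    return paths
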