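"""cis-eQTL instrument selection and exposure/outcome harmonization.

Instruments for a gene are chosen from its cis region (±1 Mb around the gene
body), restricted to common variants (MAF > 1%) with association p below the
instrument threshold (1e-5), thinned by greedy LD clumping (r² < 0.3 within
10 Mb by default), aligned to the outcome summary statistics, and finally
screened by Steiger directionality and instrument strength (F = β²/se² > 10).
Every input SNP ends up either in the harmonized instrument set or in a
dropped ledger with the stage that removed it, so filtering is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssocRecord",
    "GeneInfo",
    "LDMatrix",
    "HarmonizedPair",
    "InstrumentSet",
    "ThresholdConfig",
    "select_cis_snps",
    "ld_clump",
    "harmonize",
    "steiger_filter",
    "f_filter",
    "select_instruments",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
]

_ALLELES = frozenset("ACGT")
_PALINDROME = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class AssocRecord:
    """One SNP's summary association: per-allele effect, SE, frequency, p, N."""

    snp_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in _ALLELES or self.other_allele not in _ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0,1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must be in (0,1)")

    @property
    def maf(self) -> float | None:
        return None if self.eaf is None else min(self.eaf, 1 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROME


@dataclass(frozen=True)
class GeneInfo:
    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")


class LDMatrix:
    """SNP-SNP correlation matrix for one region (unit diagonal, symmetric)."""

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.shape != (len(snp_ids), len(snp_ids)):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ValueError("LD matrix must be positive semidefinite")
        self.snp_ids = list(snp_ids)
        self.r = r
        self._idx = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._idx

    def corr(self, snp_a: str, snp_b: str) -> float:
        return float(self.r[self._idx[snp_a], self._idx[snp_b]])

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._idx[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP, aligned to the exposure effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    pval_out: float
    n_out: int
    eaf: float | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")

    @property
    def f_stat(self) -> float:
        return (self.beta_exp / self.se_exp) ** 2

    @property
    def ratio(self) -> float:
        return self.beta_out / self.beta_exp


@dataclass
class InstrumentSet:
    """Surviving instruments plus a ledger of dropped SNPs with reasons."""

    gene_id: str
    pairs: list[HarmonizedPair] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def drop(self, snp_id: str, reason: str) -> None:
        self.dropped.append((snp_id, reason))

    @property
    def n_snps(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ThresholdConfig:
    """Instrument-selection thresholds; defaults follow standard cis-MR practice.

    All comparisons are strict: p < p_instrument, MAF > maf_min, r² < clump_r2,
    F > f_min.
    """

    cis_window_bp: int = 1_000_000
    maf_min: float = 0.01
    p_instrument: float = 1e-5
    clump_r2: float = 0.3
    clump_window_kb: int = 10_000
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.clump_r2 < 1):
            raise ValueError("clump_r2 must be in (0,1)")
        if min(self.cis_window_bp, self.maf_min, self.p_instrument, self.clump_window_kb, self.f_min) <= 0:
            raise ValueError("thresholds must be positive")


def select_cis_snps(
    assoc: Sequence[AssocRecord],
    gene: GeneInfo,
    cfg: ThresholdConfig = ThresholdConfig(),
    ledger: InstrumentSet | None = None,
) -> list[AssocRecord]:
    """Retain cis-region SNPs passing MAF and instrument-p thresholds.

    The window is [start - cis_window, end + cis_window], inclusive at both
    edges.  Records with missing EAF skip the MAF check (filter not
    applicable).  Dropped SNPs are logged to ``ledger`` when given.
    """
    lo = gene.start_bp - cfg.cis_window_bp
    hi = gene.end_bp + cfg.cis_window_bp
    kept = []
    for rec in assoc:
        if rec.chrom != gene.chrom or not (lo <= rec.pos_bp <= hi):
            if ledger is not None:
                ledger.drop(rec.snp_id, "cis_window")
            continue
        if rec.maf is not None and not (rec.maf > cfg.maf_min):
            if ledger is not None:
                ledger.drop(rec.snp_id, "maf")
            continue
        if not (rec.pval < cfg.p_instrument):
            if ledger is not None:
                ledger.drop(rec.snp_id, "pval")
            continue
        kept.append(rec)
    return kept


def ld_clump(
    records: Sequence[AssocRecord],
    ld: LDMatrix,
    cfg: ThresholdConfig = ThresholdConfig(),
    ledger: InstrumentSet | None = None,
) -> list[AssocRecord]:
    """Greedy LD clumping: most significant SNP first, keep if r² < clump_r2
    with every already-kept SNP within clump_window_kb.

    Ties at equal p break on smaller position, then SNP id, so the result is
    independent of input order.  Output preserves the significance ordering.
    """
    for rec in records:
        if rec.snp_id not in ld:
            raise KeyError(f"SNP {rec.snp_id!r} absent from LD matrix")
    order = sorted(records, key=lambda r: (r.pval, r.pos_bp, r.snp_id))
    window_bp = cfg.clump_window_kb * 1000
    kept: list[AssocRecord] = []
    for rec in order:
        ok = True
        for acc in kept:
            if abs(acc.pos_bp - rec.pos_bp) <= window_bp:
                if ld.corr(rec.snp_id, acc.snp_id) ** 2 >= cfg.clump_r2:
                    ok = False
                    break
        if ok:
            kept.append(rec)
        elif ledger is not None:
            ledger.drop(rec.snp_id, "ld_clump")
    return kept


def _aligned(exp: AssocRecord, out: AssocRecord) -> str:
    """'same', 'swapped' or 'mismatch' for the two records' allele coding."""
    if (exp.effect_allele, exp.other_allele) == (out.effect_allele, out.other_allele):
        return "same"
    if (exp.effect_allele, exp.other_allele) == (out.other_allele, out.effect_allele):
        return "swapped"
    return "mismatch"


def harmonize(
    exposure: Sequence[AssocRecord],
    outcome: Sequence[AssocRecord],
    ledger: InstrumentSet | None = None,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Swapped-allele records have the outcome beta negated (flipped=True);
    palindromic (A/T, C/G) SNPs and allele-set mismatches are dropped, as are
    SNPs absent from the outcome or with missing effect estimates.
    """
    for side, recs in (("exposure", exposure), ("outcome", outcome)):
        ids = [r.snp_id for r in recs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id in {side}: {dup}")
    out_by_id = {r.snp_id: r for r in outcome}
    pairs = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            if ledger is not None:
                ledger.drop(exp.snp_id, "missing")
            continue
        if exp.is_palindromic or out.is_palindromic:
            if ledger is not None:
                ledger.drop(exp.snp_id, "palindrome")
            continue
        mode = _aligned(exp, out)
        if mode == "mismatch":
            if ledger is not None:
                ledger.drop(exp.snp_id, "allele_mismatch")
            continue
        if any(np.isnan(v) for v in (exp.beta, exp.se, out.beta, out.se)):
            if ledger is not None:
                ledger.drop(exp.snp_id, "missing")
            continue
        flipped = mode == "swapped"
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                pval_exp=exp.pval,
                n_exp=exp.n,
                beta_out=-out.beta if flipped else out.beta,
                se_out=out.se,
                pval_out=out.pval,
                n_out=out.n,
                eaf=exp.eaf,
                flipped=flipped,
            )
        )
    return pairs


def _r2_explained(beta: float, se: float, eaf: float | None, n: int | None) -> float | None:
    """Variance in the trait explained by the SNP, from summary statistics."""
    if eaf is not None and n is not None:
        v = 2 * eaf * (1 - eaf)
        num = v * beta**2
        return num / (num + se**2 * n * v)
    if n is not None:
        f = (beta / se) ** 2
        return f / (f + n - 2)
    return None


def steiger_filter(
    pairs: Sequence[HarmonizedPair],
    ledger: InstrumentSet | None = None,
) -> list[HarmonizedPair]:
    """Directionality screen: keep SNPs explaining strictly more variance in
    the exposure than in the outcome.

    When EAF is unavailable the variance explained falls back to F/(F+n-2);
    when n is also unavailable the pair passes with a warning rather than
    being silently dropped.
    """
    kept = []
    for p in pairs:
        r2_exp = _r2_explained(p.beta_exp, p.se_exp, p.eaf, p.n_exp)
        r2_out = _r2_explained(p.beta_out, p.se_out, p.eaf, p.n_out)
        if r2_exp is None or r2_out is None:
            warnings.warn(f"{p.snp_id}: cannot compute Steiger r2 (missing n); pair retained")
            kept.append(p)
            continue
        if r2_exp > r2_out:
            kept.append(p)
        elif ledger is not None:
            ledger.drop(p.snp_id, "steiger")
    return kept


def f_filter(
    pairs: Sequence[HarmonizedPair],
    cfg: ThresholdConfig = ThresholdConfig(),
    ledger: InstrumentSet | None = None,
) -> list[HarmonizedPair]:
    """Drop weak instruments: retain only F = beta²/se² strictly above f_min."""
    kept = []
    for p in pairs:
        if p.f_stat > cfg.f_min:
            kept.append(p)
        elif ledger is not None:
            ledger.drop(p.snp_id, "weak_f")
    return kept


def select_instruments(
    exposure: Sequence[AssocRecord],
    outcome: Sequence[AssocRecord],
    ld: LDMatrix,
    gene: GeneInfo,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> InstrumentSet:
    """Full selection pipeline: cis/MAF/p -> LD clump -> harmonize -> Steiger -> F.

    Returns an :class:`InstrumentSet` in which every exposure SNP appears
    exactly once, either as a surviving harmonized pair or in the dropped
    ledger with the stage that removed it.
    """
    iset = InstrumentSet(gene_id=gene.gene_id)
    cis = select_cis_snps(exposure, gene, cfg, ledger=iset)
    clumped = ld_clump(cis, ld, cfg, ledger=iset)
    pairs = harmonize(clumped, outcome, ledger=iset)
    pairs = steiger_filter(pairs, ledger=iset)
    iset.pairs = f_filter(pairs, cfg, ledger=iset)
    return iset


# ---------------------------------------------------------------------------
# I/O — GCTA-COJO-style summary statistics with CHR/BP columns, and a square
# LD matrix with SNP ids as first row and first column.

_SUMSTAT_COLS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]


def read_sumstats(path) -> list[AssocRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    missing = [c for c in _SUMSTAT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file lacks columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssocRecord(
                snp_id=row.SNP,
                chrom=str(row.CHR),
                pos_bp=int(row.BP),
                effect_allele=str(row.A1),
                other_allele=str(row.A2),
                eaf=None if pd.isna(row.EAF) else float(row.EAF),
                beta=float(row.BETA),
                se=float(row.SE),
                pval=float(row.P),
                n=int(row.N),
            )
        )
    return out


def write_sumstats(records: Sequence[AssocRecord], path) -> None:
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "BP": [r.pos_bp for r in records],
            "A1": [r.effect_allele for r in records],
            "A2": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pval for r in records],
            "N": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")
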