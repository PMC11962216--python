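"""End-to-end workflow per gene x outcome.

For each (gene, tissue) exposure dataset and each (outcome, source) GWAS the
pipeline selects cis-eQTL instruments, runs MR with the method dictated by
the surviving instrument count (Wald ratio at one SNP, IVW primary plus
assist methods otherwise), applies the sensitivity suite, and — when the
primary MR p-value passes the significance gate — follows up with SMR+HEIDI
and colocalization.  MR estimates for the same gene-outcome pair from
multiple GWAS sources are pooled by inverse-variance meta-analysis.
Everything is deterministic given the config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .coloc import ColocResult, coloc_abf
from .instruments import (
    AssocRecord,
    GeneInfo,
    InstrumentSet,
    LDMatrix,
    ThresholdConfig,
    harmonize,
    read_ld_matrix,
    read_sumstats,
    select_cis_snps,
    select_instruments,
)
from .meta import MetaInput, MetaResult, meta_fixed, meta_random
from .mr import MRModel, MRResults
from .smr import SMRResult, heidi_test, smr_test

__all__ = [
    "AnalysisConfig",
    "GeneOutcomeResult",
    "run_gene_outcome",
    "consistency_sweep",
    "run_pipeline",
    "PipelineConfig",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Per-analysis settings shared across genes and outcomes."""

    thresholds: ThresholdConfig = ThresholdConfig()
    gate: str = "significant"  # follow-up gate: 'significant' (p < gate_p) or 'all'
    gate_p: float = 0.05
    random_effects: bool = False
    meta_model: str = "fixed"
    n_boot: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gate not in {"significant", "all"}:
            raise ValueError("gate must be 'significant' or 'all'")
        if self.meta_model not in {"fixed", "random"}:
            raise ValueError("meta_model must be 'fixed' or 'random'")


@dataclass
class GeneOutcomeResult:
    """All results for one gene x tissue x outcome x source cell."""

    gene_id: str
    tissue: str
    outcome_id: str
    source: str
    status: str  # 'ok', 'no_instruments', 'not_significant'
    instruments: InstrumentSet | None = None
    mr: MRResults | None = None
    smr: SMRResult | None = None
    coloc: ColocResult | None = None

    @property
    def primary_method(self) -> str | None:
        return self.mr.primary.method if self.mr is not None else None


def run_gene_outcome(
    exposure: Sequence[AssocRecord],
    outcome: Sequence[AssocRecord],
    ld: LDMatrix,
    gene: GeneInfo,
    cfg: AnalysisConfig = AnalysisConfig(),
    tissue: str = "blood",
    outcome_id: str = "outcome",
    source: str = "source",
) -> GeneOutcomeResult:
    """Instruments -> MR (+sensitivity) -> gated SMR/HEIDI and colocalization."""
    iset = select_instruments(exposure, outcome, ld, gene, cfg.thresholds)
    res = GeneOutcomeResult(gene.gene_id, tissue, outcome_id, source, "ok", instruments=iset)
    if iset.n_snps == 0:
        res.status = "no_instruments"
        return res
    model = MRModel(iset.pairs, exposure=gene.gene_id, outcome=outcome_id)
    res.mr = model.fit(random_effects=cfg.random_effects, n_boot=cfg.n_boot, seed=cfg.seed)

    gated_out = cfg.gate == "significant" and res.mr.pval >= cfg.gate_p
    if gated_out:
        res.status = "not_significant"
        return res

    # follow-up analyses use the full cis region, not just clumped instruments
    region_cfg = ThresholdConfig(
        cis_window_bp=cfg.thresholds.cis_window_bp,
        maf_min=cfg.thresholds.maf_min,
        p_instrument=1.0,  # keep the whole region for SMR/HEIDI and coloc
        clump_r2=cfg.thresholds.clump_r2,
        clump_window_kb=cfg.thresholds.clump_window_kb,
        f_min=cfg.thresholds.f_min,
    )
    region = select_cis_snps(exposure, gene, region_cfg)
    region_pairs = harmonize(region, outcome)
    if region_pairs:
        top = min(region_pairs, key=lambda p: (p.pval_exp, p.snp_id))
        smr = smr_test(region_pairs, gene_id=gene.gene_id, outcome_id=outcome_id)
        in_ld = [p for p in region_pairs if p.snp_id in ld]
        if top.snp_id in ld:
            p_heidi, n_heidi = heidi_test(in_ld, ld, top.snp_id)
        else:
            p_heidi, n_heidi = None, 0
        res.smr = SMRResult(
            smr.gene_id, smr.outcome_id, smr.top_snp, smr.b_smr, smr.se_smr, smr.p_smr,
            p_heidi, n_heidi,
        )
    region_ids = {r.snp_id for r in region}
    out_region = [r for r in outcome if r.snp_id in region_ids]
    if region and out_region:
        res.coloc = coloc_abf(region, out_region, gene_id=gene.gene_id, outcome_id=outcome_id)
    return res


def consistency_sweep(
    exposure: Sequence[AssocRecord],
    outcome: Sequence[AssocRecord],
    ld: LDMatrix,
    gene: GeneInfo,
    cfg: AnalysisConfig = AnalysisConfig(),
    r2_grid: Sequence[float] = (0.3, 0.2, 0.05, 0.01),
) -> pd.DataFrame:
    """Re-run clumping + MR across LD-clumping thresholds.

    Returns one row per threshold (nsnp, primary method, beta, se, pval)
    with sign agreement and the largest |Δbeta| across the grid stored in
    ``DataFrame.attrs``.
    """
    rows = []
    for r2 in r2_grid:
        t = cfg.thresholds
        thr = ThresholdConfig(
            cis_window_bp=t.cis_window_bp,
            maf_min=t.maf_min,
            p_instrument=t.p_instrument,
            clump_r2=r2,
            clump_window_kb=t.clump_window_kb,
            f_min=t.f_min,
        )
        iset = select_instruments(exposure, outcome, ld, gene, thr)
        if iset.n_snps == 0:
            rows.append({"clump_r2": r2, "nsnp": 0, "method": None, "beta": None, "se": None, "pval": None})
            continue
        fit = MRModel(iset.pairs, exposure=gene.gene_id).fit(
            methods=["wald_ratio"] if iset.n_snps == 1 else ["ivw"],
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        )
        rows.append(
            {
                "clump_r2": r2,
                "nsnp": iset.n_snps,
                "method": fit.primary.method,
                "beta": fit.beta,
                "se": fit.se,
                "pval": fit.pval,
            }
        )
    df = pd.DataFrame(rows)
    betas = df["beta"].dropna()
    df.attrs["sign_agreement"] = bool(len(set(b > 0 for b in betas)) <= 1) if len(betas) else True
    df.attrs["max_delta_beta"] = float(betas.max() - betas.min()) if len(betas) else 0.0
    return df


# ---------------------------------------------------------------------------
# File-driven pipeline


@dataclass
class PipelineConfig:
    """Declarative run description: gene/outcome datasets, thresholds, seed."""

    genes: list[dict]  # gene_id, tissue, chrom, start_bp, end_bp, exposure, ld
    outcomes: list[dict]  # outcome_id, source, file
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = ThresholdConfig(**raw.get("thresholds", {}))
        analysis = AnalysisConfig(
            thresholds=thr,
            gate=raw.get("gate", "significant"),
            gate_p=float(raw.get("gate_p", 0.05)),
            random_effects=bool(raw.get("random_effects", False)),
            meta_model=raw.get("meta_model", "fixed"),
            n_boot=int(raw.get("n_boot", 200)),
            seed=int(raw.get("seed", 0)),
        )
        return cls(
            genes=raw["genes"],
            outcomes=raw["outcomes"],
            analysis=analysis,
            out_dir=raw.get("out_dir", "."),
        )


def _result_rows(res: GeneOutcomeResult) -> list[dict]:
    base = {
        "gene": res.gene_id,
        "tissue": res.tissue,
        "outcome": res.outcome_id,
        "source": res.source,
        "status": res.status,
    }
    if res.mr is None:
        return [dict(base, method=None, nsnp=0)]
    rows = []
    for est in res.mr.estimates.values():
        row = dict(
            base,
            method=est.method,
            nsnp=est.nsnp,
            beta=est.beta,
            se=est.se,
            pval=est.pval,
            odds_ratio=est.or_,
            ci_low=est.ci_low,
            ci_high=est.ci_high,
        )
        if res.smr is not None and est.method == res.mr.primary.method:
            row.update(
                smr_top_snp=res.smr.top_snp,
                smr_beta=res.smr.b_smr,
                smr_pval=res.smr.p_smr,
                heidi_pval=res.smr.p_heidi,
            )
        if res.coloc is not None and est.method == res.mr.primary.method:
            row.update(pp_h4=res.coloc.pp_h4, coloc_verdict=res.coloc.verdict)
        rows.append(row)
    return rows


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every requested gene x outcome cell and write the results tables.

    Writes ``results.tsv`` (one row per gene/tissue/outcome/source/method),
    ``meta.tsv`` (pooled estimates where both sources produced an MR
    estimate for a gene-outcome pair), ``sensitivity.tsv`` and
    ``dropped_snps.tsv`` under ``config.out_dir``; the same tables are
    returned in memory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result_rows: list[dict] = []
    sens_rows: list[dict] = []
    dropped_rows: list[dict] = []
    primary: dict[tuple, list] = {}

    for g in config.genes:
        gene = GeneInfo(g["gene_id"], str(g["chrom"]), int(g["start_bp"]), int(g["end_bp"]))
        exposure = read_sumstats(g["exposure"])
        ld = read_ld_matrix(g["ld"])
        for o in config.outcomes:
            outcome = read_sumstats(o["file"])
            res = run_gene_outcome(
                exposure,
                outcome,
                ld,
                gene,
                config.analysis,
                tissue=g.get("tissue", "blood"),
                outcome_id=o["outcome_id"],
                source=o["source"],
            )
            result_rows.extend(_result_rows(res))
            if res.instruments is not None:
                for snp, reason in res.instruments.dropped:
                    dropped_rows.append(
                        {
                            "gene": gene.gene_id,
                            "tissue": res.tissue,
                            "outcome": res.outcome_id,
                            "source": res.source,
                            "snp": snp,
                            "reason": reason,
                        }
                    )
            if res.mr is not None and res.mr.sensitivity is not None:
                s = res.mr.sensitivity
                sens_rows.append(
                    {
                        "gene": gene.gene_id,
                        "tissue": res.tissue,
                        "outcome": res.outcome_id,
                        "source": res.source,
                        "q": s.q,
                        "q_df": s.q_df,
                        "q_pval": s.q_pval,
                        "egger_intercept": s.egger_intercept,
                        "egger_intercept_pval": s.egger_intercept_pval,
                    }
                )
            if res.mr is not None:
                key = (gene.gene_id, res.tissue, res.outcome_id)
                primary.setdefault(key, []).append((res.source, res.mr.beta, res.mr.se))

    meta_rows = []
    pool = meta_fixed if config.analysis.meta_model == "fixed" else meta_random
    for (gene_id, tissue, outcome_id), studies in sorted(primary.items()):
        if len(studies) < 2:
            continue
        m: MetaResult = pool(MetaInput.from_studies(studies))
        meta_rows.append(
            {
                "gene": gene_id,
                "tissue": tissue,
                "outcome": outcome_id,
                "model": m.model,
                "k": m.k,
                "beta": m.beta,
                "se": m.se,
                "pval": m.pval,
                "odds_ratio": m.or_,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "q": m.q,
                "q_pval": m.q_pval,
                "i2": m.i2,
            }
        )

    tables = {
        "results": pd.DataFrame(result_rows),
        "meta": pd.DataFrame(meta_rows),
        "sensitivity": pd.DataFrame(sens_rows),
        "dropped_snps": pd.DataFrame(dropped_rows),
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    return tables
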