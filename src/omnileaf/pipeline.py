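"""End-to-end orchestration: simulate -> quantgen -> gwas -> annotate -> gsea
-> degx -> netinfer -> popgen, from one config, with a markdown report."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from omnileaf import annotate, degx, gsea, gwas, netinfer, popgen, quantgen
from omnileaf.synthdata import SimConfig, simulate_cohort, write_bundle

__all__ = ["RunConfig", "run", "overlap_analysis"]


@dataclass
class RunConfig:
    """Stage parameters (defaults as used throughout the pipeline) + inputs."""

    window: int = 2000
    top_k: int = 1000
    exponent: float = 1.0
    n_perm: int = 10000
    alpha: float = 0.05
    sigma: float = 2.32
    n_shuffle: int = 100
    n_pcs: int = 0
    qst_boot: int = 100
    network_methods: tuple[str, ...] = ("pearson", "spearman", "clr", "pcor")
    seed: int = 1
    sim: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "network_methods" in data:
            data["network_methods"] = tuple(data["network_methods"])
        return cls(**data)


def overlap_analysis(
    gene_lists: dict[str, list[str]], universe_size: int
) -> pd.DataFrame:
    """Pairwise/full intersections with hypergeometric enrichment p-values."""

    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    if len(gene_lists) < 2:
        raise ValueError("need at least two gene lists")
    sets = {k: set(v) for k, v in gene_lists.items()}
    rows = []
    for a, b in combinations(sets, 2):
        inter = len(sets[a] & sets[b])
        # P(X >= inter) drawing |b| from universe with |a| successes
        p = stats.hypergeom.sf(inter - 1, universe_size, len(sets[a]), len(sets[b]))
        rows.append(
            {"lists": f"{a}&{b}", "overlap": inter,
             "n_a": len(sets[a]), "n_b": len(sets[b]), "p_hypergeom": float(p)}
        )
    full = set.intersection(*sets.values()) if sets else set()
    rows.append(
        {"lists": "&".join(sets), "overlap": len(full),
         "n_a": np.nan, "n_b": np.nan, "p_hypergeom": np.nan}
    )
    return pd.DataFrame(rows)


def _stage(log: list, name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.append({"stage": name, "seconds": round(t1 - t0, 3)})
    return t1


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic pipeline; writes intermediates + report.

    Returns a result dict with per-stage outputs and the report path.
    """

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    t = time.perf_counter()

    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    cfg = SimConfig(**sim_kwargs)
    geno, pheno, expr, truth = simulate_cohort(cfg)
    write_bundle(out / "inputs", cfg, geno, pheno, expr, truth)
    t = _stage(log, "simulate", t)

    # --- quantitative genetics ------------------------------------------------
    qg_rows = []
    blup_tables = {}
    for trait in cfg.traits:
        sub = pheno[(pheno.garden == cfg.gardens[0]) & (pheno.year == cfg.years[0])]
        h2, h2_ci = quantgen.heritability(sub, trait)
        q, q_ci = quantgen.qst(sub, trait, n_boot=config.qst_boot, seed=config.seed)
        qg_rows.append(
            {"trait": trait, "H2": h2, "H2_lo": h2_ci[0], "H2_hi": h2_ci[1],
             "QST": q, "QST_lo": q_ci[0], "QST_hi": q_ci[1]}
        )
        blup_tables[trait] = quantgen.blup(pheno, trait)
    qg_table = pd.DataFrame(qg_rows)
    qg_table.to_csv(out / "quantgen.tsv", sep="\t", index=False)
    t = _stage(log, "quantgen", t)

    # --- GWAS -----------------------------------------------------------------
    K = gwas.kinship(geno.dosages.astype(float), ids=geno.genotype_ids)
    assoc_by_trait = {}
    lambda_gc = {}
    pve = {}
    for trait in cfg.traits:
        y = blup_tables[trait].random.reindex(geno.genotype_ids).to_numpy()
        assoc = gwas.lmm_assoc(y, geno.dosages.astype(float), K,
                               snp_info=geno.snps)
        assoc_by_trait[trait] = assoc
        lambda_gc[trait] = gwas.genomic_control(assoc)
        pve[trait] = gwas.pve_reml(y, K).pve_reml
        assoc.to_csv(out / f"assoc_{trait}.tsv", sep="\t", index=False)
    t = _stage(log, "gwas", t)

    # --- annotation -----------------------------------------------------------
    trait0 = cfg.traits[0]
    snp_map = annotate.map_snps_to_genes(
        assoc_by_trait[trait0], geno.genes, window=config.window
    )
    top_genes = {
        trait: annotate.top_k_genes(assoc_by_trait[trait], snp_map, k=config.top_k)
        for trait in cfg.traits
    }
    subset_snps = assoc_by_trait[trait0].nsmallest(
        min(500, len(assoc_by_trait[trait0])), "p_lrt"
    )
    ctx = annotate.context_density(
        subset_snps, assoc_by_trait[trait0], geno.genes,
        chrom_lengths=geno.chrom_lengths, window=config.window,
    )
    ctx.to_csv(out / "context_density.tsv", sep="\t", index=False)
    t = _stage(log, "annotate", t)

    # --- GSEA -----------------------------------------------------------------
    ranking = gsea.rank_by_min_p(assoc_by_trait[trait0], snp_map)
    gsea_results = gsea.permutation_test(
        ranking, {k: set(v) for k, v in geno.gene_sets.items()},
        n_perm=config.n_perm, seed=config.seed, exponent=config.exponent,
    )
    gsea_df = pd.DataFrame(
        [
            {"set": r.set_id, "n": r.n_set, "ES": r.es, "p_emp": r.p_emp,
             "q": r.q, "leading_edge": ";".join(r.leading_edge)}
            for r in gsea_results
        ]
    )
    gsea_df.to_csv(out / "gsea.tsv", sep="\t", index=False)
    t = _stage(log, "gsea", t)

    # --- network --------------------------------------------------------------
    adj = netinfer.filter_and_adjust(expr.counts, n_pcs=config.n_pcs)
    score_sets = [netinfer.infer(adj, m) for m in config.network_methods]
    net = netinfer.aggregate_irp(score_sets)
    net = netinfer.backbone(net, sigma=config.sigma)
    clusters = netinfer.partition(net, seed=config.seed)
    cent = netinfer.centralities(net)
    summary = netinfer.summary_stats(net)
    cent.to_csv(out / "centrality.tsv", sep="\t")
    clusters.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
    with open(out / "network_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    t = _stage(log, "netinfer", t)

    # --- differential expression ---------------------------------------------
    groups = degx.select_extremes(
        blup_tables[trait0].random, trait0, sample_map=expr.sample_map
    )
    de = degx.nb_test(expr.counts, groups, alpha=config.alpha)
    de.to_csv(out / "de_results.tsv", sep="\t")
    centrality_series = cent["pagerank"] if len(cent) else pd.Series(dtype=float)
    rand = degx.centrality_randomization(
        expr.counts, groups, centrality_series,
        n_shuffle=config.n_shuffle, seed=config.seed, alpha=config.alpha,
    ) if len(cent) else {}
    with open(out / "centrality_randomization.json", "w") as fh:
        json.dump(rand, fh, indent=1)
    t = _stage(log, "degx", t)

    # --- population genetics --------------------------------------------------
    taj = popgen.tajima_d_per_gene(
        geno.dosages.astype(float), geno.snps, geno.genes, window=config.window
    )
    taj.to_csv(out / "tajima_d.tsv", sep="\t")
    deg_set = set(de.index[de["is_deg"].fillna(False)])
    gwas_set = set(top_genes[trait0]["gene_id"])
    contrast = None
    defined = taj["D"].dropna()
    if len(deg_set & set(defined.index)) >= 10 and \
            len((gwas_set - deg_set) & set(defined.index)) >= 10:
        contrast = popgen.set_contrast(taj["D"], deg_set, gwas_set)
    t = _stage(log, "popgen", t)

    # --- overlap + report -----------------------------------------------------
    overlaps = overlap_analysis(
        {tr: top_genes[tr]["gene_id"].tolist() for tr in cfg.traits},
        universe_size=cfg.n_gene,
    ) if len(cfg.traits) >= 2 else pd.DataFrame()

    report = out / "report.md"
    with open(report, "w") as fh:
        fh.write("# Pipeline report\n\n")
        fh.write(f"Seed: {config.seed}\n\n")
        fh.write("## Heritability and population differentiation\n\n")
        fh.write(qg_table.to_markdown(index=False) + "\n\n")
        fh.write("## Candidate-gene overlap\n\n")
        if len(overlaps):
            fh.write(overlaps.to_markdown(index=False) + "\n\n")
        fh.write("## Genomic context of top SNPs\n\n")
        fh.write(ctx.to_markdown(index=False) + "\n\n")
        fh.write("## Network summary\n\n")
        fh.write(
            pd.Series(summary).rename("value").to_markdown() + "\n\n"
        )
        fh.write("## Top central genes\n\n")
        if len(cent):
            tops = netinfer.top_central_genes(cent, k=5)
            fh.write(
                pd.DataFrame({k: v for k, v in tops.items()}).to_markdown()
                + "\n\n"
            )
        fh.write("## Gene-set enrichment\n\n")
        fh.write(gsea_df.sort_values("p_emp").head(20).to_markdown(index=False)
                 + "\n\n")
        fh.write("## Stage timings\n\n")
        fh.write(pd.DataFrame(log).to_markdown(index=False) + "\n")

    return {
        "config": config,
        "sim_config": cfg,
        "truth": truth,
        "quantgen": qg_table,
        "lambda_gc": lambda_gc,
        "pve": pve,
        "assoc": assoc_by_trait,
        "snp_map": snp_map,
        "top_genes": top_genes,
        "context": ctx,
        "gsea": gsea_df,
        "network_summary": summary,
        "centrality": cent,
        "clusters": clusters,
        "de": de,
        "randomization": rand,
        "tajima": taj,
        "tajima_contrast": contrast,
        "overlaps": overlaps,
        "timings": log,
        "report": str(report),
    }
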