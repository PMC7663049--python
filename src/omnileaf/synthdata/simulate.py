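"""Cohort simulators: genome, genotypes, phenotypes, expression."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from omnileaf.annotate import GeneModel
from omnileaf.synthdata.config import ExprConfig, GroundTruth, SimConfig

__all__ = [
    "GenotypeData",
    "ExpressionData",
    "simulate_genome",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_cohort",
]

_UTR5, _EXON, _INTRON, _UTR3 = 200, 300, 200, 300
_N_EXON = 3
_GENE_SPAN = _UTR5 + _N_EXON * _EXON + (_N_EXON - 1) * _INTRON + _UTR3
_GAP = 6000


@dataclass
class GenotypeData:
    """Individuals x SNP dosages plus coordinates and population labels."""

    dosages: np.ndarray  # n_geno x n_snp, values in {0,1,2}
    snps: pd.DataFrame  # chrom, pos, ref, alt
    genotype_ids: list[str]
    populations: pd.Series  # genotype id -> population label
    ancestral_freq: np.ndarray
    pop_freq: np.ndarray  # n_pop x n_snp
    genes: list[GeneModel] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    enriched_sets: list[str] = field(default_factory=list)

    @property
    def n_geno(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class ExpressionData:
    """Raw NB counts (genes x samples) plus the sample-to-genotype map."""

    counts: pd.DataFrame
    sample_map: pd.Series  # sample id -> genotype id
    dispersion: float


def simulate_genome(cfg: SimConfig, rng: np.random.Generator):
    """Toy multi-chromosome genome with UTR/CDS/intron gene structure.

    Genes are laid out sequentially with fixed intergenic gaps; strands
    alternate at random. Returns (gene models, chromosome lengths).
    """

    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_gene / cfg.n_chrom))
    chrom_lengths = {}
    gi = 0
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        cursor = 5001
        for _ in range(per_chrom):
            if gi >= cfg.n_gene:
                break
            start = cursor
            end = start + _GENE_SPAN - 1
            strand = "+" if rng.random() < 0.5 else "-"
            blocks = []
            p = start
            blocks.append(("utr_a", p, p + _UTR5 - 1))
            p += _UTR5
            for e in range(_N_EXON):
                blocks.append(("CDS", p, p + _EXON - 1))
                p += _EXON
                if e < _N_EXON - 1:
                    p += _INTRON
            blocks.append(("utr_b", p, p + _UTR3 - 1))
            feats: dict[str, list[tuple[int, int]]] = {}
            for kind, s, e in blocks:
                if kind == "CDS":
                    feats.setdefault("CDS", []).append((s, e))
                elif kind == "utr_a":
                    key = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
                    feats.setdefault(key, []).append((s, e))
                else:
                    key = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
                    feats.setdefault(key, []).append((s, e))
            genes.append(
                GeneModel(f"G{gi + 1:05d}", chrom, strand, start, end, feats)
            )
            cursor = end + 1 + _GAP
            gi += 1
        chrom_lengths[chrom] = cursor + 5000
    return genes, chrom_lengths


def simulate_genotypes(cfg: SimConfig) -> GenotypeData:
    """Balding-Nichols structured dosages on a toy annotated genome.

    Subpopulation allele frequencies are drawn Beta around uniform ancestral
    frequencies with differentiation ``fst``; dosages are binomial(2, p_pop).
    SNP positions are uniform over the genome, so known fractions land in
    each genomic context of the paired gene models.
    """

    rng = np.random.default_rng(cfg.seed)
    genes, chrom_lengths = simulate_genome(cfg, rng)

    n_snp = cfg.n_snp
    p_anc = rng.uniform(0.1, 0.9, size=n_snp)
    if cfg.fst > 0:
        a = p_anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
        pop_freq = rng.beta(a, b, size=(cfg.n_pop, n_snp)) if n_snp else \
            np.empty((cfg.n_pop, 0))
    else:
        pop_freq = np.tile(p_anc, (cfg.n_pop, 1))

    pops = np.arange(cfg.n_geno) % cfg.n_pop
    dosages = rng.binomial(2, pop_freq[pops, :], size=(cfg.n_geno, n_snp)) \
        if n_snp else np.empty((cfg.n_geno, 0), dtype=int)

    # SNP coordinates: uniform across chromosomes, unique per chromosome
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum() if lens.sum() else None
    snp_chrom_idx = rng.choice(len(chroms), size=n_snp, p=probs) if n_snp else \
        np.array([], dtype=int)
    rows = []
    used: dict[int, set[int]] = {i: set() for i in range(len(chroms))}
    bases = np.array(list("ACGT"))
    for ci in snp_chrom_idx:
        while True:
            pos = int(rng.integers(1, chrom_lengths[chroms[ci]] + 1))
            if pos not in used[ci]:
                used[ci].add(pos)
                break
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append((chroms[ci], pos, bases[ref], bases[alt]))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    if n_snp:
        order = snps.sort_values(["chrom", "pos"]).index.to_numpy()
        snps = snps.iloc[order].reset_index(drop=True)
        dosages = dosages[:, order]
        pop_freq = pop_freq[:, order]
        p_anc = p_anc[order]

    genotype_ids = [f"geno{i + 1:04d}" for i in range(cfg.n_geno)]
    populations = pd.Series(
        [f"pop{p + 1}" for p in pops], index=genotype_ids, name="population"
    )

    gene_ids = [g.gene_id for g in genes]
    gene_sets = {}
    for si in range(cfg.n_sets):
        size = min(cfg.set_size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        gene_sets[f"set{si + 1:03d}"] = sorted(members.tolist())
    enriched = [f"set{si + 1:03d}" for si in range(cfg.n_enriched_sets)]

    return GenotypeData(
        dosages=dosages.astype(np.int8),
        snps=snps,
        genotype_ids=genotype_ids,
        populations=populations,
        ancestral_freq=p_anc,
        pop_freq=pop_freq,
        genes=genes,
        chrom_lengths=chrom_lengths,
        gene_sets=gene_sets,
        enriched_sets=enriched,
    )


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


def _snps_in_genes(geno: GenotypeData, gene_ids: set[str]) -> np.ndarray:
    spans = [
        (g.chrom, g.start, g.end) for g in geno.genes if g.gene_id in gene_ids
    ]
    mask = np.zeros(geno.n_snp, dtype=bool)
    chrom_arr = geno.snps["chrom"].to_numpy()
    pos_arr = geno.snps["pos"].to_numpy()
    for chrom, s, e in spans:
        mask |= (chrom_arr == chrom) & (pos_arr >= s) & (pos_arr <= e)
    return mask


def simulate_phenotypes(
    cfg: SimConfig, geno: GenotypeData
) -> tuple[pd.DataFrame, GroundTruth]:
    """Clonal trait records with configurable variance components.

    Per record: ``value = mu + garden + year + block + g_i + gxe_ij +
    plant_ik + eps``. Genotype effects are multivariate across traits with
    covariance implied by the target rG matrix; population shifts have
    variance V_pop so that the realised Q_ST targets
    ``V_pop / (V_pop + 2 V_geno)``.

    When ``enrichment_effect > 0`` (or ``omnigenic=True``) the first trait's
    genotype effect is built from per-SNP effects concentrated in the
    enriched gene sets, creating true gene-level association signal; rG
    ground truth then describes the SNP-free component only.
    """

    rng = np.random.default_rng(cfg.seed + 1)
    traits = cfg.traits
    k = len(traits)
    vgeno = np.array([cfg.variance_components[t]["V_geno"] for t in traits])
    Sigma = _psd_sqrt(np.outer(np.sqrt(vgeno), np.sqrt(vgeno)) * cfg.rG_matrix)
    G = rng.standard_normal((cfg.n_geno, k)) @ Sigma.T

    if (cfg.enrichment_effect > 0 and cfg.n_enriched_sets > 0) or cfg.omnigenic:
        enriched_genes = set()
        for name in geno.enriched_sets:
            enriched_genes.update(geno.gene_sets.get(name, []))
        beta = np.zeros(geno.n_snp)
        if cfg.omnigenic:
            beta = rng.standard_normal(geno.n_snp) * 0.05
        if enriched_genes and cfg.enrichment_effect > 0:
            mask = _snps_in_genes(geno, enriched_genes)
            beta[mask] = rng.standard_normal(mask.sum()) * cfg.enrichment_effect
        X = geno.dosages.astype(float)
        Xc = X - X.mean(axis=0, keepdims=True)
        g_raw = Xc @ beta
        sd = g_raw.std()
        if sd > 0 and vgeno[0] > 0:
            w = 0.8
            G[:, 0] = (
                np.sqrt(vgeno[0]) * (
                    w * g_raw / sd
                    + np.sqrt(1 - w**2) * rng.standard_normal(cfg.n_geno)
                )
            )

    pop_labels = geno.populations.to_numpy()
    pop_names = sorted(set(pop_labels))
    pop_eff = {
        t: dict(zip(pop_names, rng.normal(
            0.0, np.sqrt(cfg.variance_components[t]["V_pop"]), len(pop_names)
        )))
        for t in traits
    }

    garden_eff = {g: rng.normal(0, cfg.garden_effect_sd) for g in cfg.gardens}
    year_eff = {y: rng.normal(0, cfg.year_effect_sd) for y in cfg.years}
    block_eff = {
        b: rng.normal(0, cfg.block_effect_sd) for b in range(1, cfg.n_block + 1)
    }

    envs = [(g, y) for g in cfg.gardens for y in cfg.years]
    gxe = {
        t: rng.normal(
            0.0, np.sqrt(cfg.variance_components[t]["V_gxe"]),
            (cfg.n_geno, len(envs)),
        )
        for t in traits
    }

    rows = []
    for i, gid in enumerate(geno.genotype_ids):
        for garden in cfg.gardens:
            for rep in range(cfg.n_rep):
                plant = f"{gid}_{garden}_r{rep + 1}"
                block = int(rng.integers(1, cfg.n_block + 1))
                plant_shift = {
                    t: rng.normal(
                        0.0, np.sqrt(cfg.variance_components[t]["V_plant"])
                    )
                    for t in traits
                }
                for year in cfg.years:
                    ei = envs.index((garden, year))
                    rec = {
                        "genotype": gid,
                        "plant": plant,
                        "garden": garden,
                        "year": year,
                        "block": block,
                        "population": pop_labels[i],
                    }
                    for ti, t in enumerate(traits):
                        eps = rng.normal(
                            0.0, np.sqrt(cfg.variance_components[t]["V_res"])
                        )
                        rec[t] = (
                            10.0
                            + garden_eff[garden]
                            + year_eff[year]
                            + block_eff[block]
                            + pop_eff[t][pop_labels[i]]
                            + G[i, ti]
                            + gxe[t][i, ei]
                            + plant_shift[t]
                            + eps
                        )
                    rows.append(rec)
    pheno = pd.DataFrame(rows)

    truth = GroundTruth(seed=cfg.seed, trait_names=traits)
    for ti, t in enumerate(traits):
        c = cfg.variance_components[t]
        denom = c["V_geno"] + c["V_plant"] + c["V_res"]
        truth.true_h2[t] = c["V_geno"] / denom if denom > 0 else 0.0
        qden = c["V_pop"] + 2.0 * c["V_geno"]
        truth.true_qst[t] = c["V_pop"] / qden if qden > 0 else 0.0
        truth.genotype_effects[t] = dict(
            zip(geno.genotype_ids, G[:, ti].tolist())
        )
    truth.true_rg = cfg.rG_matrix.tolist()
    truth.gene_sets = geno.gene_sets
    truth.enriched_sets = geno.enriched_sets
    return pheno, truth


def simulate_expression(
    cfg: SimConfig,
    pheno: pd.DataFrame,
    geno: GenotypeData,
    truth: GroundTruth | None = None,
) -> ExpressionData:
    """NB counts with modular co-expression and phenotype-linked DE genes.

    Gene means combine a log-normal baseline, module latent factors (block
    co-expression), a DE shift proportional to the standardised genotype
    effect of the first trait, and optional cis-SNP effects (eGene
    analogues). Counts are gamma-Poisson with the configured dispersion.
    """

    rng = np.random.default_rng(cfg.seed + 2)
    ex: ExprConfig = cfg.expr
    gene_ids = [g.gene_id for g in geno.genes]
    n_gene = len(gene_ids)

    samples, sample_geno = [], []
    for gid in geno.genotype_ids:
        for r in range(ex.samples_per_genotype):
            samples.append(f"{gid}_s{r + 1}")
            sample_geno.append(gid)
    n_samp = len(samples)
    sample_map = pd.Series(sample_geno, index=samples, name="genotype")

    # standardised genotype effect of the first trait drives DE genes
    trait0 = cfg.traits[0]
    if truth is not None and truth.genotype_effects.get(trait0):
        eff = pd.Series(truth.genotype_effects[trait0])
    else:
        eff = pheno.groupby("genotype")[trait0].mean()
    z = eff.reindex(sample_map.to_numpy()).to_numpy(dtype=float)
    zsd = z.std()
    z = (z - z.mean()) / zsd if zsd > 0 else np.zeros_like(z)

    module_of: dict[str, int] = {}
    mi = 0
    for m in range(ex.n_modules):
        for _ in range(ex.module_size):
            if mi >= n_gene:
                break
            module_of[gene_ids[mi]] = m + 1
            mi += 1
    non_module = [g for g in gene_ids if g not in module_of]
    pool = non_module if len(non_module) >= ex.n_deg else gene_ids
    deg_genes = sorted(
        rng.choice(pool, size=min(ex.n_deg, len(pool)), replace=False).tolist()
    )
    egene_pool = [g for g in gene_ids if g not in deg_genes]
    egenes = sorted(
        rng.choice(
            egene_pool, size=min(ex.n_egenes, len(egene_pool)), replace=False
        ).tolist()
    ) if ex.n_egenes else []

    base = rng.lognormal(ex.base_mean_log, ex.base_mean_sd, size=n_gene)
    factors = rng.standard_normal((ex.n_modules, n_samp))
    log2mult = np.zeros((n_gene, n_samp))
    for gi, gid in enumerate(gene_ids):
        m = module_of.get(gid)
        if m is not None:
            log2mult[gi] += ex.module_loading * factors[m - 1]
    deg_idx = [gene_ids.index(g) for g in deg_genes]
    for gi in deg_idx:
        log2mult[gi] += ex.deg_log2fc * z / 2.0

    if egenes:
        chrom_arr = geno.snps["chrom"].to_numpy()
        pos_arr = geno.snps["pos"].to_numpy()
        gmap = {g.gene_id: g for g in geno.genes}
        dos_by_sample = geno.dosages[
            [geno.genotype_ids.index(g) for g in sample_geno], :
        ].astype(float)
        for gid in egenes:
            g = gmap[gid]
            inside = np.nonzero(
                (chrom_arr == g.chrom) & (pos_arr >= g.start) & (pos_arr <= g.end)
            )[0]
            if inside.size == 0:
                continue
            j = int(rng.choice(inside))
            log2mult[gene_ids.index(gid)] += (
                ex.egene_log2fc_per_allele * (dos_by_sample[:, j] - 1.0)
            )

    mu = base[:, None] * np.exp2(log2mult)
    alpha = ex.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)
    expr = ExpressionData(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        sample_map=sample_map,
        dispersion=alpha,
    )
    if truth is not None:
        truth.deg_genes = deg_genes
        truth.egenes = egenes
        truth.module_of = module_of
    return expr


def simulate_cohort(cfg: SimConfig):
    """Run the full simulator chain; returns (geno, pheno, expr, truth)."""

    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(cfg, geno)
    expr = simulate_expression(cfg, pheno, geno, truth=truth)
    return geno, pheno, expr, truth
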