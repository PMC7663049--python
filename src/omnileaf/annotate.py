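"""SNP-to-gene association by distance and genomic-context analysis.

Genes are treated as genomic intervals: a SNP is associated with every gene
whose span lies within ``window`` (default 2000 bp) of the SNP position.
Context classification uses the feature precedence

    conflict (5'UTR and 3'UTR simultaneously) > UTR > exon > intron
    > upstream > downstream > intergenic

where upstream/downstream are the ``window``-bp flanks oriented by strand,
and "conflict" may arise within one gene model or between adjacent genes.

Coordinates are handled 1-based inclusive at the interfaces (VCF/GFF3
convention); all reported positions are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneModel",
    "read_gff3",
    "map_snps_to_genes",
    "top_k_genes",
    "classify_context",
    "context_density",
    "gene_length_pvalue_confound",
    "CONTEXTS",
]

CONTEXTS = [
    "5'UTR", "exon", "intron", "3'UTR",
    "upstream", "downstream", "conflict", "intergenic",
]

_BODY_PRECEDENCE = {"5'UTR": 0, "3'UTR": 0, "exon": 1, "intron": 2}


@dataclass
class GeneModel:
    """A gene span plus its per-context feature intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    features: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def introns(self) -> list[tuple[int, int]]:
        """Span minus every exonic feature."""

        exonic = sorted(
            self.features.get("exon", [])
            + self.features.get("CDS", [])
            + self.features.get("five_prime_UTR", [])
            + self.features.get("three_prime_UTR", [])
        )
        out, cur = [], self.start
        for s, e in exonic:
            if s > cur:
                out.append((cur, s - 1))
            cur = max(cur, e + 1)
        if cur <= self.end:
            out.append((cur, self.end))
        return out

    def body_context(self, pos: int) -> str | None:
        """Feature label for a position inside the span, else None."""

        if pos < self.start or pos > self.end:
            return None
        for ftype, label in (
            ("five_prime_UTR", "5'UTR"),
            ("three_prime_UTR", "3'UTR"),
            ("CDS", "exon"),
            ("exon", "exon"),
        ):
            for s, e in self.features.get(ftype, []):
                if s <= pos <= e:
                    return label
        return "intron"


def read_gff3(path: str) -> list[GeneModel]:
    """Load gene models (gene spans + feature intervals) from a GFF3 file."""

    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        feats: dict[str, list[tuple[int, int]]] = {}
        for child in db.children(g):
            if child.featuretype in (
                "CDS", "exon", "five_prime_UTR", "three_prime_UTR"
            ):
                feats.setdefault(child.featuretype, []).append(
                    (child.start, child.end)
                )
        genes.append(
            GeneModel(g.id, g.seqid, g.strand or "+", g.start, g.end, feats)
        )
    return genes


def _snp_frame(assoc: pd.DataFrame) -> pd.DataFrame:
    need = {"chrom", "pos"}
    if not need.issubset(assoc.columns):
        raise ValueError("SNP table needs 'chrom' and 'pos' columns")
    return assoc


def map_snps_to_genes(
    assoc: pd.DataFrame, genes: list[GeneModel], window: int = 2000
) -> pd.DataFrame:
    """Associate each SNP with every gene within ``window`` bp of its span.

    Returns a long table (chrom, pos, gene_id, distance, context); a SNP may
    map to multiple genes. Distance is 0 inside the span.
    """

    snps = _snp_frame(assoc)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gl in by_chrom.items():
        gl.sort(key=lambda g: g.start)
        arrays[chrom] = (
            np.array([g.start for g in gl]),
            np.array([g.end for g in gl]),
        )

    rows = []
    unknown = set()
    for chrom, pos in zip(snps["chrom"], snps["pos"]):
        if chrom not in arrays:
            unknown.add(chrom)
            continue
        starts, ends = arrays[chrom]
        hit = np.nonzero((starts <= pos + window) & (ends >= pos - window))[0]
        for idx in hit:
            g = by_chrom[chrom][idx]
            dist = 0 if g.start <= pos <= g.end else min(
                abs(pos - g.start), abs(pos - g.end)
            )
            ctx = g.body_context(pos)
            if ctx is None:
                left = pos < g.start
                if g.strand == "+":
                    ctx = "upstream" if left else "downstream"
                else:
                    ctx = "downstream" if left else "upstream"
            rows.append((chrom, pos, g.gene_id, dist, ctx))
    if unknown:
        warnings.warn(
            f"SNPs on unknown chromosome(s) left intergenic: {sorted(unknown)}"
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "distance", "context"])


def top_k_genes(
    assoc: pd.DataFrame, snp_gene_map: pd.DataFrame, k: int = 1000
) -> pd.DataFrame:
    """Walk SNPs by ascending p-value, collecting unique mapped genes.

    Stops once ``k`` unique genes are collected. Returns (gene_id,
    trigger_chrom, trigger_pos, trigger_p) in collection order.
    """

    snps = assoc.sort_values(
        ["p_lrt", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    lookup: dict[tuple, list[str]] = {}
    for chrom, pos, gid in zip(
        snp_gene_map["chrom"], snp_gene_map["pos"], snp_gene_map["gene_id"]
    ):
        lookup.setdefault((chrom, pos), []).append(gid)
    seen: dict[str, tuple] = {}
    for chrom, pos, p in zip(snps["chrom"], snps["pos"], snps["p_lrt"]):
        for gid in lookup.get((chrom, pos), []):
            if gid not in seen:
                seen[gid] = (chrom, pos, p)
                if len(seen) >= k:
                    break
        if len(seen) >= k:
            break
    if len(seen) < k:
        warnings.warn(
            f"only {len(seen)} genes reachable from the SNP map (requested {k})"
        )
    return pd.DataFrame(
        [
            {"gene_id": gid, "trigger_chrom": c, "trigger_pos": pos, "trigger_p": p}
            for gid, (c, pos, p) in seen.items()
        ]
    )


def classify_context(
    chrom: str, pos: int, genes: list[GeneModel], window: int = 2000
) -> str:
    """Single precedence-resolved context label for one SNP position."""

    labels = []
    for g in genes:
        if g.chrom != chrom:
            continue
        body = g.body_context(pos)
        if body is not None:
            labels.append(body)
        elif g.start - window <= pos < g.start:
            labels.append("upstream" if g.strand == "+" else "downstream")
        elif g.end < pos <= g.end + window:
            labels.append("downstream" if g.strand == "+" else "upstream")
    if not labels:
        return "intergenic"
    if "5'UTR" in labels and "3'UTR" in labels:
        return "conflict"
    for lab in ("5'UTR", "3'UTR", "exon", "intron", "upstream", "downstream"):
        if lab in labels:
            return lab
    return "intergenic"


def context_lengths(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int] | None = None,
    window: int = 2000,
) -> dict[str, int]:
    """Total genomic length per context (flank length = window per gene side)."""

    out = {c: 0 for c in CONTEXTS}
    for g in genes:
        out["5'UTR"] += sum(e - s + 1 for s, e in g.features.get("five_prime_UTR", []))
        out["3'UTR"] += sum(e - s + 1 for s, e in g.features.get("three_prime_UTR", []))
        out["exon"] += sum(
            e - s + 1
            for s, e in g.features.get("CDS", []) + g.features.get("exon", [])
        )
        out["intron"] += sum(e - s + 1 for s, e in g.introns())
        out["upstream"] += window
        out["downstream"] += window
    if chrom_lengths:
        total = sum(chrom_lengths.values())
        used = sum(v for c, v in out.items() if c != "intergenic")
        out["intergenic"] = max(0, total - used)
    return out


def context_density(
    snps_subset: pd.DataFrame,
    snps_all: pd.DataFrame,
    genes: list[GeneModel],
    chrom_lengths: dict[str, int] | None = None,
    window: int = 2000,
) -> pd.DataFrame:
    """Length-normalised context densities plus subset-vs-all proportion tests.

    Returns one row per context: count, density (count / total context
    length), proportion, delta vs the genome-wide proportion, two-proportion
    z, p, and significance stars (* p<0.05, ** p<0.01).
    """

    def classify_all(snps):
        return pd.Series(
            [
                classify_context(c, p, genes, window=window)
                for c, p in zip(snps["chrom"], snps["pos"])
            ]
        )

    lab_sub = classify_all(_snp_frame(snps_subset))
    lab_all = classify_all(_snp_frame(snps_all))
    n1, n2 = len(lab_sub), len(lab_all)
    lengths = context_lengths(genes, chrom_lengths, window=window)
    rows = []
    for ctx in CONTEXTS:
        c1 = int((lab_sub == ctx).sum())
        c2 = int((lab_all == ctx).sum())
        length = lengths.get(ctx, 0)
        density = c1 / length if length > 0 else np.nan
        p1 = c1 / n1 if n1 else np.nan
        p2 = c2 / n2 if n2 else np.nan
        pooled = (c1 + c2) / (n1 + n2) if n1 + n2 else np.nan
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2)) if n1 and n2 else np.nan
        if se and se > 0:
            z = (p1 - p2) / se
            p = 2 * stats.norm.sf(abs(z))
        else:
            z, p = 0.0, 1.0
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append(
            {
                "context": ctx, "count": c1, "length": length,
                "density": density, "proportion": p1,
                "delta_proportion": p1 - p2, "z": z, "p": p, "stars": stars,
                "length_defined": length > 0,
            }
        )
    return pd.DataFrame(rows)


def gene_length_pvalue_confound(
    assoc: pd.DataFrame, snp_gene_map: pd.DataFrame, genes: list[GeneModel]
) -> dict[str, float]:
    """Spearman relation between gene length and per-gene minimum p-value.

    Longer genes harbour more SNPs and thus smaller minima under the null;
    the relationship is reported (rho, r2) but deliberately not corrected for.
    """

    merged = snp_gene_map.merge(assoc[["chrom", "pos", "p_lrt"]], on=["chrom", "pos"])
    min_p = merged.groupby("gene_id")["p_lrt"].min()
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    common = min_p.index.intersection(lengths.index)
    rho, p = stats.spearmanr(lengths[common], min_p[common])
    return {"spearman_rho": float(rho), "r2": float(rho**2), "p": float(p),
            "n_genes": int(len(common))}
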