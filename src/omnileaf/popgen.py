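"""Per-gene Tajima's D and distributional contrasts between gene sets.

D is computed from unphased biallelic dosages assuming Hardy-Weinberg random
pairing of alleles (the standard genotype-based approximation): with
``n = 2 * individuals`` sequences, per-site diversity is
``pi_site = n/(n-1) * 2 p q``, Watterson's estimator is ``S / a1``, and
``D = (pi - theta_W) / sqrt(e1 S + e2 S (S - 1))`` with the standard
constant set a1, a2, b1, b2, c1, c2, e1, e2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TajimaResult",
    "tajima_constants",
    "tajima_d",
    "tajima_d_per_gene",
    "set_contrast",
    "maf_spectrum",
]


@dataclass
class TajimaResult:
    gene_id: str
    n: int
    S: int
    pi: float
    theta_w: float
    D: float  # NaN when S == 0


def tajima_constants(n: int) -> dict[str, float]:
    """The standard constant set for n sequences."""

    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(dosages: np.ndarray, gene_id: str = "") -> TajimaResult:
    """Tajima's D for one region from an individuals x sites dosage matrix."""

    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2:
        raise ValueError("dosage matrix must be individuals x sites")
    m = X.shape[0]
    n = 2 * m
    if n < 4:
        raise ValueError("need at least 2 individuals")
    p = X.mean(axis=0) / 2.0
    seg = (p > 0) & (p < 1)
    S = int(seg.sum())
    pi = float(np.sum(2.0 * p[seg] * (1.0 - p[seg]) * n / (n - 1)))
    if S == 0:
        return TajimaResult(gene_id, n, 0, 0.0, 0.0, np.nan)
    c = tajima_constants(n)
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    D = (pi - theta_w) / np.sqrt(var) if var > 0 else np.nan
    return TajimaResult(gene_id, n, S, pi, float(theta_w), float(D))


def tajima_d_per_gene(
    dosages: np.ndarray,
    snp_pos: pd.DataFrame,
    genes,
    window: int = 2000,
) -> pd.DataFrame:
    """Tajima's D per gene region (gene span +/- window).

    ``snp_pos`` has chrom/pos columns aligned to dosage columns; ``genes``
    is a list of annotate.GeneModel.
    """

    chroms = snp_pos["chrom"].to_numpy()
    pos = snp_pos["pos"].to_numpy()
    rows = []
    for g in genes:
        mask = (chroms == g.chrom) & (pos >= g.start - window) & (pos <= g.end + window)
        if not mask.any():
            rows.append((g.gene_id, 2 * dosages.shape[0], 0, 0.0, 0.0, np.nan))
            continue
        r = tajima_d(dosages[:, mask], gene_id=g.gene_id)
        rows.append((r.gene_id, r.n, r.S, r.pi, r.theta_w, r.D))
    return pd.DataFrame(
        rows, columns=["gene_id", "n", "S", "pi", "theta_w", "D"]
    ).set_index("gene_id")


def set_contrast(
    stat_per_gene: pd.Series, set_a: set[str], set_b: set[str]
) -> dict:
    """Two-sided Wilcoxon rank-sum contrast of a per-gene statistic.

    Genes shared by both sets are removed from ``set_b`` (with a warning).
    Reports medians and the Hodges-Lehmann shift (median pairwise
    difference, a - b).
    """

    overlap = set_a & set_b
    if overlap:
        warnings.warn(f"removing {len(overlap)} overlapping genes from set_b")
        set_b = set_b - overlap
    vals = stat_per_gene.dropna()
    a = vals[vals.index.isin(set_a)].to_numpy()
    b = vals[vals.index.isin(set_b)].to_numpy()
    if len(a) < 10 or len(b) < 10:
        raise ValueError("each set needs >= 10 genes with a defined statistic")
    stat, p = stats.ranksums(a, b)
    hl = float(np.median(a[:, None] - b[None, :]))
    return {
        "n_a": int(len(a)), "n_b": int(len(b)),
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
        "hodges_lehmann": hl,
        "direction": "a>b" if hl > 0 else ("a<b" if hl < 0 else "a=b"),
        "wilcoxon_stat": float(stat), "p": float(p),
    }


def maf_spectrum(
    maf: pd.Series, snp_sets: dict[str, np.ndarray], n_bins: int = 20
) -> dict[str, dict]:
    """Per-set MAF histograms plus two-sample KS tests against all SNPs.

    ``maf`` holds the genome-wide minor-allele frequencies; each entry of
    ``snp_sets`` is an index (positions into ``maf``) defining a SNP subset.
    Empty sets are skipped.
    """

    global_maf = maf.dropna().to_numpy()
    edges = np.linspace(0, 0.5, n_bins + 1)
    out = {}
    for name, idx in snp_sets.items():
        sub = maf.iloc[np.asarray(idx)].dropna().to_numpy() if len(idx) else np.array([])
        if sub.size == 0:
            continue
        hist, _ = np.histogram(sub, bins=edges)
        ks_stat, ks_p = stats.ks_2samp(sub, global_maf)
        out[name] = {
            "n": int(sub.size),
            "bin_edges": edges.tolist(),
            "hist": hist.tolist(),
            "median_maf": float(np.median(sub)),
            "ks_stat": float(ks_stat),
            "ks_p": float(ks_p),
        }
    return out
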