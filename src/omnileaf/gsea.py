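"""Weighted running-sum gene-set enrichment with a gene-ranking permutation null.

Walking a descending-score gene ranking, the running sum is incremented by
``s_i**exponent / sum_set(s_j**exponent)`` for set members and decremented by
``1 / (N - m)`` otherwise. The *maximum* of the trace is the enrichment score
(no negative-enrichment branch); set members ranked at or before the first
argmax form the leading edge. The null permutes the gene ordering uniformly
(scores stay attached to rank positions, set membership travels with genes),
and empirical p-values carry a +1 pseudocount.

Scores default to ``-log10(p_min)``: incrementing "proportionally to the
p-value" is read as proportional to significance, since raw p-values would
up-weight the *least* significant genes. ``score="one_minus_p"`` gives the
alternative reading.

Gene sets with five or fewer members present in the ranking are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RankedGeneList",
    "GseaResult",
    "rank_by_min_p",
    "running_sum",
    "permutation_test",
    "leading_edge",
    "qvalues",
    "MIN_SET_SIZE",
]

#: only sets with strictly more members than this are tested
MIN_SET_SIZE = 5


@dataclass
class RankedGeneList:
    """Descending-score gene ranking; ties broken by gene id (stable)."""

    genes: list[str]
    scores: np.ndarray
    tie_policy: str = "gene-id lexicographic"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores differ in length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    set_id: str
    n_set: int
    es: float
    p_emp: float
    q: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    degenerate: bool = False


def rank_by_min_p(assoc: pd.DataFrame, snp_gene_map: pd.DataFrame) -> RankedGeneList:
    """Rank genes by the most significant associated SNP.

    Per-gene score is ``-log10(min p over mapped SNPs)``; genes without any
    mapped SNP are excluded (their count is reported via a warning).
    """

    merged = snp_gene_map.merge(assoc[["chrom", "pos", "p_lrt"]], on=["chrom", "pos"])
    min_p = merged.groupby("gene_id")["p_lrt"].min()
    if min_p.empty:
        raise ValueError("no gene has a mapped SNP")
    scores = -np.log10(np.clip(min_p.to_numpy(), np.finfo(float).tiny, 1.0))
    order = sorted(
        range(len(min_p)), key=lambda i: (-scores[i], min_p.index[i])
    )
    return RankedGeneList(
        [min_p.index[i] for i in order], scores[order]
    )


def running_sum(
    ranked: RankedGeneList, gene_set: set[str], exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Running-sum trace and its maximum (the enrichment score).

    The trace ends at exactly 0 by construction (increments and decrements
    each sum to 1). If every member score is 0 the statistic is degenerate
    and ES is defined as 0.
    """

    member = np.fromiter(
        (g in gene_set for g in ranked.genes), dtype=bool, count=len(ranked)
    )
    m = int(member.sum())
    N = len(ranked)
    if m == 0 or m == N:
        # all-gene set: trace is the normalised cumulative score
        if m == N:
            w = ranked.scores**exponent
            tot = w.sum()
            trace = np.cumsum(w / tot) if tot > 0 else np.zeros(N)
            return float(trace.max()) if tot > 0 else 0.0, trace
        raise ValueError("gene set has no member in the ranking")
    w = np.where(member, ranked.scores**exponent, 0.0)
    tot = w.sum()
    if tot == 0:
        return 0.0, np.zeros(N)
    steps = np.where(member, w / tot, -1.0 / (N - m))
    trace = np.cumsum(steps)
    return float(trace.max()), trace


def leading_edge(
    trace: np.ndarray, ranked: RankedGeneList, gene_set: set[str]
) -> list[str]:
    """Set members ranked at or before the first argmax of the trace."""

    cut = int(np.argmax(trace))  # first argmax on ties
    return [g for g in ranked.genes[: cut + 1] if g in gene_set]


def _es_from_positions(
    pos_sorted: np.ndarray, w_members: np.ndarray, N: int
) -> float:
    """ES given sorted member rank positions and their (unnormalised) weights.

    Between member positions the trace only decreases, so the maximum lies at
    a member position or at the final position (where the trace is 0).
    """

    m = pos_sorted.size
    tot = w_members.sum()
    if tot == 0:
        return 0.0
    inc = np.cumsum(w_members) / tot
    dec = (pos_sorted + 1 - np.arange(1, m + 1)) / (N - m)
    return float(max(0.0, np.max(inc - dec)))


def permutation_test(
    ranked: RankedGeneList,
    sets: dict[str, set[str]],
    n_perm: int = 10000,
    seed: int = 0,
    exponent: float = 1.0,
    with_qvalues: bool = True,
) -> list[GseaResult]:
    """Empirical enrichment p-values from uniform permutations of the ranking.

    One shared permutation stream serves every set;
    ``p_emp = (1 + #{perm ES >= observed ES}) / (1 + n_perm)``.
    """

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; empirical p-values are coarse")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    gene_idx = {g: i for i, g in enumerate(ranked.genes)}
    weights = ranked.scores**exponent

    tested = {}
    for sid, members in sets.items():
        idx = np.array(sorted(gene_idx[g] for g in members if g in gene_idx))
        if idx.size > MIN_SET_SIZE:
            tested[sid] = idx

    observed, traces = {}, {}
    for sid, idx in tested.items():
        gene_set = {ranked.genes[i] for i in idx}
        es, trace = running_sum(ranked, gene_set, exponent=exponent)
        observed[sid] = es
        traces[sid] = trace

    exceed = {sid: 0 for sid in tested}
    for _ in range(n_perm):
        perm = rng.permutation(N)  # perm[i] = new rank position of gene i
        for sid, idx in tested.items():
            pos = perm[idx]
            order = np.argsort(pos)
            es = _es_from_positions(pos[order], weights[pos[order]], N)
            if es >= observed[sid]:
                exceed[sid] += 1

    results = []
    for sid, idx in tested.items():
        gene_set = {ranked.genes[i] for i in idx}
        p = (1 + exceed[sid]) / (1 + n_perm)
        results.append(
            GseaResult(
                set_id=sid,
                n_set=int(idx.size),
                es=observed[sid],
                p_emp=float(p),
                leading_edge=leading_edge(traces[sid], ranked, gene_set),
                degenerate=observed[sid] == 0.0 and weights[idx].sum() == 0.0,
            )
        )
    if with_qvalues and results:
        qs = qvalues(np.array([r.p_emp for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated by fitting a cubic polynomial smoother to
    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` over the grid
    ``lambda = 0.05, 0.10, ..., 0.95`` and evaluating at the largest lambda.
    With fewer than 100 tests (or an unstable fit) pi0 falls back to 1,
    making the result identical to Benjamini-Hochberg.
    """

    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
            try:
                coef = np.polyfit(lam, pi0_lam, 3)
                pi0 = float(np.polyval(coef, lam[-1]))
            except np.linalg.LinAlgError:
                pi0 = 1.0
            if not np.isfinite(pi0) or pi0 <= 0:
                pi0 = 1.0
            pi0 = min(pi0, 1.0)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    ranked_p = p[order]
    raw = pi0 * m * ranked_p / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(raw[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)
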