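"""Extreme-quartile differential expression with full-data dispersion estimation.

The contrast design: genotypes are ranked by BLUP, the top and bottom
quartiles form the high/low groups, but per-gene negative-binomial
dispersions are estimated on *all* samples (so intermediate-phenotype
samples still inform the dispersion) before the group coefficient is fitted
on the extreme samples only.

This is a deliberately simplified NB engine (method-of-moments dispersions
shrunk toward a robust log-mean trend, Wald test on an NB GLM with log
size-factor offsets, Benjamini-Hochberg adjustment); it is not a bit-exact
re-implementation of any published tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExtremeGroups",
    "select_extremes",
    "size_factors",
    "estimate_dispersions",
    "nb_test",
    "centrality_randomization",
    "expr_pheno_correlation",
]

_MIN_DISP = 1e-8
_SHRINK_WEIGHT = 0.5  # weight of the trend in log-dispersion shrinkage


@dataclass
class ExtremeGroups:
    """Bottom/top BLUP-quartile genotype groups and their sample ids."""

    trait: str
    low_genotypes: list[str]
    high_genotypes: list[str]
    low_samples: list[str] = field(default_factory=list)
    high_samples: list[str] = field(default_factory=list)

    @property
    def extreme_samples(self) -> list[str]:
        return list(self.low_samples) + list(self.high_samples)


def select_extremes(
    blups: pd.Series, trait: str,
    sample_map: pd.Series | None = None,
) -> ExtremeGroups:
    """Bottom/top quartile cut of genotype BLUPs (type-7 quantiles).

    Boundary ties are included on the extreme side; if that inflates a group
    beyond 25% a warning is raised. ``sample_map`` maps sample id -> genotype
    and fills the per-group sample lists.
    """

    vals = blups.dropna()
    if len(vals) < 8:
        raise ValueError("need at least 8 genotypes for a quartile contrast")
    if vals.nunique() == 1:
        raise ValueError("constant BLUPs: no phenotypic extremes exist")
    q25, q75 = np.quantile(vals.to_numpy(), [0.25, 0.75])  # type-7 (linear)
    low = vals.index[vals <= q25].tolist()
    high = vals.index[vals >= q75].tolist()
    if len(low) > 0.25 * len(vals) + 1 or len(high) > 0.25 * len(vals) + 1:
        warnings.warn("boundary ties inflate an extreme group beyond 25%")
    groups = ExtremeGroups(trait, low, high)
    if sample_map is not None:
        groups.low_samples = sample_map.index[sample_map.isin(low)].tolist()
        groups.high_samples = sample_map.index[sample_map.isin(high)].tolist()
    return groups


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Only genes with no zero count contribute to the reference; the factors
    are rescaled so their median is 1 (the overall scale is arbitrary for a
    group contrast).
    """

    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter low-count genes first"
        )
    logref = np.log(mat[nonzero]).mean(axis=1)
    ratios = np.log(mat[nonzero]) - logref[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.median(sf)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame, sf: pd.Series
) -> pd.Series:
    """Per-gene NB dispersions: method-of-moments shrunk toward a trend.

    The raw estimate solves ``Var(q) = mu * mean(1/sf) + alpha * mu^2`` on
    size-factor-normalised counts q; a robust (Huber) regression of
    log(alpha) on log(mu) supplies the trend, and the final dispersion is the
    geometric interpolation between raw and trend values.
    """

    mat = counts.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    q = mat / s[None, :]
    mu = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    xi = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - mu * xi) / mu**2
    raw = np.where(np.isfinite(raw), raw, _MIN_DISP)

    ok = (raw > _MIN_DISP) & (mu > 0)
    if ok.sum() >= 10:
        X = sm.add_constant(np.log(mu[ok]))
        fit = sm.RLM(np.log(raw[ok]), X, M=sm.robust.norms.HuberT()).fit()
        trend = np.full(mu.size, np.nan)
        pos = mu > 0
        trend[pos] = np.exp(
            fit.params[0] + fit.params[1] * np.log(mu[pos])
        )
    else:
        trend = np.full(mu.size, np.exp(np.nanmean(np.log(np.clip(raw, _MIN_DISP, None)))))

    final = np.empty(mu.size)
    for i in range(mu.size):
        t = trend[i] if np.isfinite(trend[i]) else _MIN_DISP
        r = raw[i] if raw[i] > _MIN_DISP else t
        final[i] = np.exp(
            (1 - _SHRINK_WEIGHT) * np.log(max(r, _MIN_DISP))
            + _SHRINK_WEIGHT * np.log(max(t, _MIN_DISP))
        )
    return pd.Series(np.clip(final, _MIN_DISP, None), index=counts.index,
                     name="dispersion")


def _nb_group_mean(Y: np.ndarray, sf: np.ndarray, alpha: np.ndarray):
    """Vectorised per-gene NB MLE of one group's mean (log link, sf offsets).

    Solves the score equation ``sum_s (y_s - m sf_s) / (1 + alpha m sf_s) = 0``
    by Newton iteration on log m. Returns (m, fisher_info) per gene; genes
    whose group counts are all zero get (nan, nan).
    """

    tot = Y.sum(axis=1)
    m = np.where(tot > 0, tot / sf.sum(), np.nan)
    a = alpha[:, None]
    for _ in range(50):
        mu = m[:, None] * sf[None, :]
        denom = 1.0 + a * mu
        score = ((Y - mu) / denom).sum(axis=1)
        fisher = (mu * (1.0 + a * Y) / denom**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(fisher > 0, score / fisher, 0.0)
        step = np.clip(step, -5.0, 5.0)
        m = m * np.exp(step)
        if np.nanmax(np.abs(step), initial=0.0) < 1e-12:
            break
    mu = m[:, None] * sf[None, :]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return m, info


def nb_test(
    counts: pd.DataFrame,
    groups: ExtremeGroups,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wald test of the high-vs-low group coefficient per gene.

    Size factors and dispersions are computed on ALL samples of ``counts``;
    the NB GLM (log link, log size-factor offset) is then fitted on the
    extreme samples only. Positive log2FC means higher expression in the top
    quartile. Genes with all-zero counts in either extreme group get NA
    p-values and are excluded from the BH adjustment.
    """

    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, sf)

    missing = [s for s in groups.extreme_samples if s not in counts.columns]
    if missing:
        raise ValueError(f"extreme samples absent from counts: {missing[:5]}")
    disp = np.clip(dispersions.to_numpy(dtype=float), _MIN_DISP, None)
    Y_lo = counts[groups.low_samples].to_numpy(dtype=float)
    Y_hi = counts[groups.high_samples].to_numpy(dtype=float)
    sf_lo = sf[groups.low_samples].to_numpy(dtype=float)
    sf_hi = sf[groups.high_samples].to_numpy(dtype=float)

    m_lo, info_lo = _nb_group_mean(Y_lo, sf_lo, disp)
    m_hi, info_hi = _nb_group_mean(Y_hi, sf_hi, disp)

    n_genes = len(counts.index)
    base_mean = (counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]).mean(axis=1)
    ln2 = np.log(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.log(m_hi) - np.log(m_lo)
        se_ln = np.sqrt(1.0 / info_lo + 1.0 / info_hi)
        wald = beta / se_ln
    l2fc = beta / ln2
    se = se_ln / ln2
    pval = np.where(np.isfinite(wald), 2 * stats.norm.sf(np.abs(wald)), np.nan)

    p_adj = np.full(n_genes, np.nan)
    ok = np.isfinite(pval)
    if ok.any():
        _, adj, _, _ = multipletests(pval[ok], method="fdr_bh")
        p_adj[ok] = adj
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": l2fc,
            "se": se,
            "wald": wald,
            "p": pval,
            "p_adj": p_adj,
            "is_deg": p_adj < alpha,
        },
        index=counts.index,
    )


def centrality_randomization(
    counts: pd.DataFrame,
    groups: ExtremeGroups,
    centrality: pd.Series,
    n_shuffle: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Does DEG status track network centrality beyond chance?

    Observed statistic: difference in median centrality, DEGs minus
    non-DEGs (a Wilcoxon rank-sum p is also reported). The null shuffles
    sample labels within the pooled extreme samples ``n_shuffle`` times and
    recomputes the statistic; the empirical p is lower-tailed (testing the
    DEGs-less-central direction) with a +1 pseudocount. Dispersions and size
    factors are label-free, so they are computed once and reused.
    """

    sf = size_factors(counts)
    disp = estimate_dispersions(counts, sf)

    def delta_for(g: ExtremeGroups) -> tuple[float, int, bool]:
        de = nb_test(counts, g, sf=sf, dispersions=disp, alpha=alpha)
        flags = de["is_deg"].fillna(False)
        cent = centrality.reindex(de.index)
        ok = cent.notna()
        deg_c = cent[ok & flags]
        non_c = cent[ok & ~flags]
        if len(deg_c) == 0 or len(non_c) == 0:
            return 0.0, int(flags.sum()), True
        return float(deg_c.median() - non_c.median()), int(flags.sum()), False

    obs_delta, n_deg, obs_flag = delta_for(groups)

    # Wilcoxon on the observed split
    de_obs = nb_test(counts, groups, sf=sf, dispersions=disp, alpha=alpha)
    flags = de_obs["is_deg"].fillna(False)
    cent = centrality.reindex(de_obs.index)
    ok = cent.notna()
    if flags[ok].any() and (~flags[ok]).any():
        w_stat, w_p = stats.ranksums(cent[ok & flags], cent[ok & ~flags])
    else:
        w_stat, w_p = np.nan, np.nan

    result = {
        "observed_delta": obs_delta,
        "n_deg": n_deg,
        "wilcoxon_stat": float(w_stat) if np.isfinite(w_stat) else None,
        "wilcoxon_p": float(w_p) if np.isfinite(w_p) else None,
        "n_shuffle": n_shuffle,
        "null_deltas": [],
        "null_flags": [],
        "p_emp": None,
    }
    if n_shuffle <= 0:
        return result

    rng = np.random.default_rng(seed)
    pooled = np.array(groups.extreme_samples)
    n_low = len(groups.low_samples)
    null = np.empty(n_shuffle)
    flags_out = []
    for k in range(n_shuffle):
        perm = rng.permutation(pooled)
        g = ExtremeGroups(
            groups.trait, groups.low_genotypes, groups.high_genotypes,
            low_samples=perm[:n_low].tolist(),
            high_samples=perm[n_low:].tolist(),
        )
        d, _, flagged = delta_for(g)
        null[k] = d
        flags_out.append(flagged)

    p_emp = (1 + int(np.sum(null <= obs_delta))) / (1 + n_shuffle)
    result["null_deltas"] = null.tolist()
    result["null_flags"] = flags_out
    result["p_emp"] = float(p_emp)
    return result


def expr_pheno_correlation(
    expr_by_genotype: pd.DataFrame,
    blups: pd.Series,
    deg_flags: pd.Series,
) -> tuple[pd.Series, float]:
    """Per-gene Pearson r of genotype-mean expression vs trait BLUP.

    Returns the r series and a Wilcoxon rank-sum p comparing |r| of DEGs
    against non-DEGs. Constant-expression genes get NA.
    """

    common = expr_by_genotype.columns.intersection(blups.index)
    E = expr_by_genotype[common].to_numpy(dtype=float)
    b = blups[common].to_numpy(dtype=float)
    bc = b - b.mean()
    denom_b = np.sqrt((bc**2).sum())
    Ec = E - E.mean(axis=1, keepdims=True)
    denom_e = np.sqrt((Ec**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ec @ bc) / (denom_e * denom_b)
    r = pd.Series(np.where(denom_e > 0, r, np.nan),
                  index=expr_by_genotype.index, name="pearson_r")
    flags = deg_flags.reindex(r.index).fillna(False).astype(bool)
    ok = r.notna()
    a = r[ok & flags].abs()
    c = r[ok & ~flags].abs()
    if len(a) == 0 or len(c) == 0:
        return r, np.nan
    _, p = stats.ranksums(a, c)
    return r, float(p)
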