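"""Clonal quantitative genetics: variance components, H2, Q_ST, rG, BLUPs, GxE ANOVA.

All estimators operate on long-format phenotype tables with one row per plant
record (columns ``genotype, plant, garden, year, block, <traits...>``). Trait
values are assumed to already be per-plant medians of leaf-level replicates.

The genetic-correlation estimator uses the variance-of-a-sum identity
``V_GAB = (V_G(A+B) - V_GA - V_GB) / 2`` and returns
``rG = V_GAB / sqrt(V_GA * V_GB)`` (the normalised correlation, clamped to
[-1, 1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "GeneticCorrelation",
    "BlupTable",
    "EstimationError",
    "fit_random_intercept",
    "heritability",
    "qst",
    "genetic_correlation",
    "blup",
    "gxe_anova",
]

_REML_TOL = 1e-8
_REML_MAXIT = 500


class EstimationError(ValueError):
    """Raised when a variance-component model cannot be fitted."""


@dataclass
class VarianceComponents:
    """REML variance-component estimates for a random-intercept model.

    ``components`` maps each random grouping factor name to its variance;
    ``resid`` is the residual variance; ``loglik`` the restricted
    log-likelihood at the optimum.
    """

    components: dict[str, float]
    resid: float
    loglik: float

    @property
    def total(self) -> float:
        return float(sum(self.components.values()) + self.resid)

    def __getitem__(self, key: str) -> float:
        if key in ("resid", "residual"):
            return self.resid
        return self.components[key]


@dataclass
class GeneticCorrelation:
    trait_a: str
    trait_b: str
    V_GA: float
    V_GB: float
    V_GAB: float
    rG: float
    degenerate: bool = False


@dataclass
class BlupTable:
    """Mixed-model solution: genotype random effects and fixed-effect estimates."""

    trait: str
    random: pd.Series  # index: genotype id
    fixed: pd.Series  # index: fixed-effect term name
    variance: VarianceComponents
    dropped_terms: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# REML engines
# ---------------------------------------------------------------------------


def _oneway_profile_reml(y: np.ndarray, groups: np.ndarray):
    """Profile REML for ``y = mu + g + e`` with a single random intercept.

    Uses group sufficient statistics, so each likelihood evaluation is O(G).
    Returns (V_g, V_e, loglik).
    """

    y = np.asarray(y, dtype=float)
    codes, _ = pd.factorize(groups)
    n = y.size
    G = codes.max() + 1
    if G < 2:
        raise EstimationError("need at least 2 groups for a random intercept fit")
    sizes = np.bincount(codes).astype(float)
    sums = np.bincount(codes, weights=y)
    means = sums / sizes
    ssw = float(np.sum((y - means[codes]) ** 2))
    vary = float(np.var(y))
    if vary == 0.0:
        return 0.0, 0.0, np.nan

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = 1.0 + lam * sizes
        w = sizes / d
        mu = np.sum(w * means) / np.sum(w)
        q = ssw + np.sum(sizes * (means - mu) ** 2 / d)
        s2 = q / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(s2)
            + np.sum(np.log(d))
            + np.log(np.sum(w))
            + (n - 1)
            + (n - 1) * np.log(2 * np.pi)
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-10},
    )
    cands = [(res.fun, res.x)]
    # boundary: essentially zero genetic variance
    cands.append((neg_restricted_ll(-25.0), -25.0))
    fun, log_lam = min(cands)
    lam = np.exp(log_lam)
    d = 1.0 + lam * sizes
    w = sizes / d
    mu = np.sum(w * means) / np.sum(w)
    q = ssw + np.sum(sizes * (means - mu) ** 2 / d)
    ve = q / (n - 1)
    vg = lam * ve
    if vg < 1e-10 * vary:
        vg = 0.0
    return float(vg), float(ve), float(-fun)


def _nesting_design(df: pd.DataFrame, grouping: list[str]):
    """Indicator matrices for nested random intercepts, outermost first."""

    Zs, names = [], []
    key = None
    for col in grouping:
        key = df[col].astype(str) if key is None else key + "/" + df[col].astype(str)
        codes, _ = pd.factorize(key)
        q = codes.max() + 1
        Z = np.zeros((len(df), q))
        Z[np.arange(len(df)), codes] = 1.0
        Zs.append(Z)
        names.append(col)
    return Zs, names


def _em_reml(y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray],
             tol: float = _REML_TOL, maxit: int = _REML_MAXIT):
    """EM-REML through Henderson's mixed-model equations.

    Returns (sigma2 per random term, sigma2_e, loglik, beta, u_blocks).
    """

    n = y.size
    p = X.shape[1]
    qs = [Z.shape[1] for Z in Zs]
    Z = np.hstack(Zs)
    q = Z.shape[1]
    vary = float(np.var(y))
    if vary == 0.0:
        return [0.0] * len(Zs), 0.0, np.nan, np.zeros(p), [np.zeros(k) for k in qs]

    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = Z.T @ Z
    Xty = X.T @ y
    Zty = Z.T @ y

    s2 = [vary / (len(Zs) + 1)] * len(Zs)
    se2 = vary / (len(Zs) + 1)
    floor = 1e-12 * vary
    offsets = np.cumsum([0] + qs)

    beta = np.zeros(p)
    u = np.zeros(q)
    for _ in range(maxit):
        dinv = np.concatenate(
            [np.full(k, se2 / max(s, floor)) for k, s in zip(qs, s2)]
        )
        C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(dinv)]])
        rhs = np.concatenate([Xty, Zty])
        Cinv = np.linalg.pinv(C)
        sol = Cinv @ rhs
        beta, u = sol[:p], sol[p:]
        new_s2 = []
        for k, (a, b) in enumerate(zip(offsets[:-1], offsets[1:])):
            tr = np.trace(Cinv[p + a:p + b, p + a:p + b])
            new_s2.append(float((u[a:b] @ u[a:b] + se2 * tr) / qs[k]))
        new_se2 = float((y @ y - beta @ Xty - u @ Zty) / (n - p))
        delta = max(
            max(abs(a - b) for a, b in zip(new_s2, s2)), abs(new_se2 - se2)
        )
        s2, se2 = [max(v, floor) for v in new_s2], max(new_se2, floor)
        if delta < tol * max(vary, 1e-12):
            break

    # restricted log-likelihood at the optimum, via Woodbury
    Gdiag = np.concatenate([np.full(k, max(s, floor)) for k, s in zip(qs, s2)])
    M = np.diag(se2 / Gdiag) + ZtZ
    sign, logdetM = np.linalg.slogdet(M)
    logdetV = (n - q) * np.log(se2) + logdetM + np.sum(np.log(Gdiag))
    Minv = np.linalg.inv(M)

    def vinv(a: np.ndarray) -> np.ndarray:
        return (a - Z @ (Minv @ (Z.T @ a))) / se2

    ViX = vinv(X)
    XtViX = X.T @ ViX
    sign2, logdetXtViX = np.linalg.slogdet(XtViX)
    beta_gls = np.linalg.solve(XtViX, ViX.T @ y)
    r = y - X @ beta_gls
    yPy = float(r @ vinv(y))
    ll = -0.5 * (logdetV + logdetXtViX + yPy + (n - p) * np.log(2 * np.pi))

    s2 = [0.0 if v <= 2 * floor else v for v in s2]
    u_blocks = [u[a:b] for a, b in zip(offsets[:-1], offsets[1:])]
    return s2, se2, float(ll), beta_gls, u_blocks


# ---------------------------------------------------------------------------
# public estimators
# ---------------------------------------------------------------------------


def _fixed_design(df: pd.DataFrame, fixed: list[str]):
    """Full-rank fixed design with intercept; aliased columns dropped."""

    X = np.ones((len(df), 1))
    names = ["(Intercept)"]
    for term in fixed:
        dummies = pd.get_dummies(df[term].astype(str), prefix=term, drop_first=True)
        X = np.hstack([X, dummies.to_numpy(dtype=float)])
        names.extend(dummies.columns.tolist())
    # drop aliased columns via QR pivoting on the gram matrix
    dropped = []
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}")
    return X[:, keep], [names[j] for j in keep], dropped


def fit_random_intercept(
    pheno: pd.DataFrame,
    trait: str,
    grouping: list[str] | str = "genotype",
    fixed: list[str] | None = None,
) -> VarianceComponents:
    """REML variance components for nested random intercepts.

    ``grouping`` lists nesting factors outermost first (e.g.
    ``["genotype", "plant"]`` for plant-within-genotype). Deterministic:
    fixed tolerance 1e-8, at most 500 EM iterations; the single-random-effect
    intercept-only case is solved by exact profile likelihood instead.
    """

    if isinstance(grouping, str):
        grouping = [grouping]
    fixed = list(fixed or [])
    df = pheno.dropna(subset=[trait] + grouping + fixed)
    y = df[trait].to_numpy(dtype=float)
    if df[grouping[0]].nunique() < 2:
        raise EstimationError(
            f"degenerate design: grouping factor {grouping[0]!r} has a single level"
        )
    counts = df.groupby(grouping[0])[trait].count()
    if (counts >= 2).sum() < 2:
        raise EstimationError("need at least 2 groups with at least 2 observations")

    if len(grouping) == 1 and not fixed:
        vg, ve, ll = _oneway_profile_reml(y, df[grouping[0]].to_numpy())
        return VarianceComponents({grouping[0]: vg}, ve, ll)

    X, _, _ = _fixed_design(df, fixed)
    Zs, names = _nesting_design(df, grouping)
    s2, se2, ll, _, _ = _em_reml(y, X, Zs)
    return VarianceComponents(dict(zip(names, s2)), se2, ll)


def _icc_f_ci(vg: float, ve: float, sizes: np.ndarray, alpha: float = 0.05):
    """Exact F-bound CI for the intraclass correlation of a one-way design.

    Uses the ANOVA effective group size n0 for mildly unbalanced data.
    """

    G = sizes.size
    N = float(sizes.sum())
    n0 = (N - np.sum(sizes**2) / N) / (G - 1)
    df1, df2 = G - 1, int(N - G)
    lam = vg / ve if ve > 0 else np.inf
    F = 1.0 + n0 * lam
    fu = stats.f.ppf(1 - alpha / 2, df1, df2)
    fl = stats.f.ppf(alpha / 2, df1, df2)
    lo = (F / fu - 1.0) / (F / fu - 1.0 + n0)
    hi = (F / fl - 1.0) / (F / fl - 1.0 + n0)
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def heritability(
    pheno: pd.DataFrame, trait: str, alpha: float = 0.05,
    n_boot: int = 1000, seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Broad-sense heritability from clonal replicates, with a 95% CI.

    ``H2 = V_geno / (V_geno + V_env)`` where V_env collects every
    non-genotype component (plant-within-genotype plus residual). The CI uses
    exact F-distribution bounds of the one-way ANOVA approximation on (near-)
    balanced designs and a genotype-level bootstrap when group sizes are
    unbalanced by more than 20%.
    """

    nested = pheno.groupby(["genotype", "plant"])[trait].count().max() > 1 \
        if "plant" in pheno.columns else False
    grouping = ["genotype", "plant"] if nested else ["genotype"]
    vc = fit_random_intercept(pheno, trait, grouping=grouping)
    vg = vc.components["genotype"]
    venv = vc.total - vg
    if vc.total == 0:
        raise EstimationError("zero total variance: heritability undefined")
    h2 = vg / (vg + venv)

    sizes = pheno.groupby("genotype")[trait].count().to_numpy(dtype=float)
    unbalance = (sizes.max() - sizes.min()) / sizes.mean()
    if unbalance <= 0.2:
        ci = _icc_f_ci(vg, venv, sizes, alpha=alpha)
    else:
        rng = np.random.default_rng(seed)
        genos = pheno["genotype"].unique()
        by_geno = {g: d for g, d in pheno.groupby("genotype")}
        reps = []
        for _ in range(n_boot):
            pick = rng.choice(genos, size=genos.size, replace=True)
            parts = [
                by_geno[g].assign(genotype=f"bs{i}") for i, g in enumerate(pick)
            ]
            bs = pd.concat(parts, ignore_index=True)
            try:
                v = fit_random_intercept(bs, trait, grouping=grouping)
            except EstimationError:
                continue
            if v.total > 0:
                reps.append(v.components["genotype"] / v.total)
        ci = tuple(np.quantile(reps, [alpha / 2, 1 - alpha / 2]))
    return float(h2), (float(ci[0]), float(ci[1]))


def qst(
    pheno: pd.DataFrame, trait: str, pop_col: str = "population",
    n_boot: int = 1000, seed: int = 0, alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Population differentiation ``Q_ST = V_pop / (V_pop + 2 V_geno)``.

    Components come from the nested population/genotype fit; the CI is a
    seeded nonparametric bootstrap over genotypes within populations.
    """

    if pheno[pop_col].nunique() < 2:
        raise EstimationError("Q_ST requires at least two populations")
    vc = fit_random_intercept(pheno, trait, grouping=[pop_col, "genotype"])
    vpop, vgeno = vc.components[pop_col], vc.components["genotype"]
    denom = vpop + 2.0 * vgeno
    q = 0.0 if denom == 0 else vpop / denom

    if n_boot <= 0:
        return float(q), (float("nan"), float("nan"))

    rng = np.random.default_rng(seed)
    geno_pop = pheno[[pop_col, "genotype"]].drop_duplicates()
    by_geno = {g: d for g, d in pheno.groupby("genotype")}
    reps = []
    for _ in range(n_boot):
        parts = []
        i = 0
        for pop, grp in geno_pop.groupby(pop_col):
            genos = grp["genotype"].to_numpy()
            for g in rng.choice(genos, size=genos.size, replace=True):
                parts.append(by_geno[g].assign(genotype=f"bs{i}", **{pop_col: pop}))
                i += 1
        bs = pd.concat(parts, ignore_index=True)
        try:
            v = fit_random_intercept(bs, trait, grouping=[pop_col, "genotype"])
        except EstimationError:
            continue
        d = v.components[pop_col] + 2.0 * v.components["genotype"]
        reps.append(0.0 if d == 0 else v.components[pop_col] / d)
    if reps:
        ci = tuple(np.quantile(reps, [alpha / 2, 1 - alpha / 2]))
    else:
        ci = (0.0, 1.0)
    return float(q), (float(ci[0]), float(ci[1]))


def genetic_correlation(
    pheno: pd.DataFrame, trait_a: str, trait_b: str
) -> GeneticCorrelation:
    """Genetic correlation via the variance-of-a-sum identity.

    V_G is estimated for each trait and for their per-plant sum; then
    ``V_GAB = (V_G(A+B) - V_GA - V_GB) / 2`` and
    ``rG = V_GAB / sqrt(V_GA * V_GB)`` clamped to [-1, 1].
    """

    df = pheno.dropna(subset=[trait_a, trait_b]).copy()
    df["_sum_ab"] = df[trait_a] + df[trait_b]
    va = fit_random_intercept(df, trait_a).components["genotype"]
    vb = fit_random_intercept(df, trait_b).components["genotype"]
    vab_sum = fit_random_intercept(df, "_sum_ab").components["genotype"]
    cov = (vab_sum - va - vb) / 2.0
    if va <= 0 or vb <= 0:
        return GeneticCorrelation(trait_a, trait_b, va, vb, cov, np.nan, True)
    r = float(np.clip(cov / np.sqrt(va * vb), -1.0, 1.0))
    return GeneticCorrelation(trait_a, trait_b, va, vb, cov, r)


def blup(
    pheno: pd.DataFrame, trait: str,
    fixed: list[str] = ("garden", "year", "block"),
) -> BlupTable:
    """Genotype BLUPs from ``trait ~ fixed + (1 | genotype)``.

    Fixed effects are solved by GLS at the REML variance estimates; genotype
    effects are the Henderson mixed-model-equation solution (equivalently
    ``u = V_geno Z' V^-1 (y - X beta)``).
    """

    fixed = [f for f in fixed if f in pheno.columns]
    df = pheno.dropna(subset=[trait] + fixed)
    y = df[trait].to_numpy(dtype=float)
    X, names, dropped = _fixed_design(df, fixed)
    codes, genos = pd.factorize(df["genotype"])
    Z = np.zeros((len(df), genos.size))
    Z[np.arange(len(df)), codes] = 1.0
    s2, se2, ll, beta, u_blocks = _em_reml(y, X, [Z])
    vc = VarianceComponents({"genotype": s2[0]}, se2, ll)
    return BlupTable(
        trait=trait,
        random=pd.Series(u_blocks[0], index=genos, name=trait),
        fixed=pd.Series(beta, index=names),
        variance=vc,
        dropped_terms=dropped,
    )


def gxe_anova(
    pheno: pd.DataFrame, trait: str,
    site_col: str = "garden", year_col: str = "year",
):
    """Two-way fixed-effects ANOVA with interaction on the range-normalised trait.

    The trait is min-max normalised to [0, 1] before fitting
    ``y ~ site + year + site:year`` with Type I (sequential) sums of squares.
    Returns (F_interaction, p_interaction, anova_table).
    """

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pheno.dropna(subset=[trait, site_col, year_col]).copy()
    for col in (site_col, year_col):
        if df[col].nunique() < 2:
            raise EstimationError(f"factor {col!r} needs at least 2 levels")
    cells = df.groupby([site_col, year_col]).size()
    full = pd.MultiIndex.from_product(
        [df[site_col].unique(), df[year_col].unique()]
    )
    missing = full.difference(cells.index)
    if len(missing):
        raise EstimationError(f"empty design cell(s): {list(missing)}")
    lo, hi = df[trait].min(), df[trait].max()
    if hi == lo:
        raise EstimationError("constant trait: range normalisation undefined")
    df["_y"] = (df[trait] - lo) / (hi - lo)
    df["_site"] = df[site_col].astype(str)
    df["_year"] = df[year_col].astype(str)
    model = ols("_y ~ C(_site) + C(_year) + C(_site):C(_year)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    inter = "C(_site):C(_year)"
    return (
        float(table.loc[inter, "F"]),
        float(table.loc[inter, "PR(>F)"]),
        table,
    )
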