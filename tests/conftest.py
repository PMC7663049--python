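import numpy as np
import pandas as pd
import pytest

from omnileaf.synthdata import SimConfig, simulate_cohort
from omnileaf.synthdata.config import ExprConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A small default cohort shared by read-only tests."""

    cfg = SimConfig(
        n_geno=60, n_snp=300, n_gene=60, n_rep=2, seed=7,
        expr=ExprConfig(n_modules=3, module_size=10, n_deg=10, deg_log2fc=2.0),
    )
    geno, pheno, expr, truth = simulate_cohort(cfg)
    return {"cfg": cfg, "geno": geno, "pheno": pheno, "expr": expr, "truth": truth}


def balanced_oneway(rng, n_groups, n_per, v_between, v_within, mu=0.0):
    """Balanced one-way random-effects draw as a long dataframe."""

    g_eff = rng.normal(0.0, np.sqrt(v_between), n_groups)
    rows = []
    for g in range(n_groups):
        for r in range(n_per):
            rows.append(
                {
                    "genotype": f"g{g:04d}",
                    "plant": f"g{g:04d}p{r}",
                    "y": mu + g_eff[g] + rng.normal(0.0, np.sqrt(v_within)),
                }
            )
    return pd.DataFrame(rows)


def anova_oneway_mom(df, value="y", group="genotype"):
    """Method-of-moments estimates for a balanced one-way design."""

    wide = df.pivot_table(index=group, values=value, aggfunc=list)
    y = np.array(wide[value].tolist(), dtype=float)
    G, n = y.shape
    gm = y.mean()
    gmeans = y.mean(axis=1)
    msb = n * np.sum((gmeans - gm) ** 2) / (G - 1)
    msw = np.sum((y - gmeans[:, None]) ** 2) / (G * (n - 1))
    return max((msb - msw) / n, 0.0), msw
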