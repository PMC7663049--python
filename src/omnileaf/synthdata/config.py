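"""Simulation configuration and recorded ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExprConfig", "SimConfig", "GroundTruth", "DEFAULT_VARIANCES"]

DEFAULT_VARIANCES = {
    "circularity": {"V_pop": 0.02, "V_geno": 0.6, "V_gxe": 0.05,
                    "V_plant": 0.05, "V_res": 0.3},
    "indent_depth": {"V_pop": 0.01, "V_geno": 0.5, "V_gxe": 0.05,
                     "V_plant": 0.05, "V_res": 0.4},
    "area": {"V_pop": 0.02, "V_geno": 0.35, "V_gxe": 0.2,
             "V_plant": 0.05, "V_res": 0.6},
}

_COMPONENT_KEYS = ("V_pop", "V_geno", "V_gxe", "V_plant", "V_res")


@dataclass
class ExprConfig:
    """Expression-simulation parameters."""

    n_modules: int = 4
    module_size: int = 25
    nb_dispersion: float = 0.1
    n_deg: int = 50
    deg_log2fc: float = 1.0
    n_egenes: int = 0
    egene_log2fc_per_allele: float = 0.5
    base_mean_log: float = np.log(100.0)
    base_mean_sd: float = 1.0
    module_loading: float = 0.8
    samples_per_genotype: int = 1


@dataclass
class SimConfig:
    """Full cohort configuration; all randomness flows from ``seed``."""

    n_pop: int = 5
    n_geno: int = 100
    n_rep: int = 3
    gardens: tuple[str, ...] = ("north", "south")
    years: tuple[int, ...] = (2008, 2011)
    n_block: int = 4
    fst: float = 0.01
    n_snp: int = 2000
    n_gene: int = 200
    n_chrom: int = 2
    variance_components: dict = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_VARIANCES.items()}
    )
    rG_matrix: np.ndarray | None = None
    garden_effect_sd: float = 1.0
    year_effect_sd: float = 1.0
    block_effect_sd: float = 0.5
    n_sets: int = 20
    set_size: int = 20
    n_enriched_sets: int = 0
    enrichment_effect: float = 0.0
    omnigenic: bool = False
    expr: ExprConfig = field(default_factory=ExprConfig)
    seed: int = 0

    @property
    def traits(self) -> list[str]:
        return list(self.variance_components)

    def __post_init__(self):
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        for trait, comp in self.variance_components.items():
            for key in _COMPONENT_KEYS:
                comp.setdefault(key, 0.0)
                if comp[key] < 0:
                    raise ValueError(f"negative variance {key} for {trait!r}")
        k = len(self.variance_components)
        if self.rG_matrix is None:
            self.rG_matrix = np.eye(k)
        self.rG_matrix = np.asarray(self.rG_matrix, dtype=float)
        R = self.rG_matrix
        if R.shape != (k, k):
            raise ValueError("rG_matrix shape must match the number of traits")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("rG_matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("rG_matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-8:
            raise ValueError("rG_matrix must be positive semi-definite")


@dataclass
class GroundTruth:
    """True parameter values recorded before observation noise is added."""

    true_h2: dict[str, float] = field(default_factory=dict)
    true_qst: dict[str, float] = field(default_factory=dict)
    true_rg: list[list[float]] = field(default_factory=list)
    trait_names: list[str] = field(default_factory=list)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    enriched_sets: list[str] = field(default_factory=list)
    deg_genes: list[str] = field(default_factory=list)
    egenes: list[str] = field(default_factory=list)
    module_of: dict[str, int] = field(default_factory=dict)
    genotype_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "true_h2": self.true_h2,
            "true_qst": self.true_qst,
            "true_rg": self.true_rg,
            "trait_names": self.trait_names,
            "gene_sets": self.gene_sets,
            "enriched_sets": self.enriched_sets,
            "deg_genes": self.deg_genes,
            "egenes": self.egenes,
            "module_of": self.module_of,
            "seed": self.seed,
        }
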