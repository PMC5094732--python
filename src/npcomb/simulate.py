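"""Synthetic multi-omics studies with known ground truth.

Two named scenarios mirror the simulation designs the integrative methods
are evaluated on:

* ``different_modalities`` — four heterogeneous datasets on the same
  samples: negative-binomial counts (RNA-seq-like), approximately normal
  continuous values (microarray-like), three-level ordinal genotypes and
  uniform reference data, each with its own set of deregulated genes and a
  common block deregulated in every modality.
* ``correlated_modalities`` — two microarray-like datasets whose
  non-deregulated genes carry a controlled per-gene cross-dataset
  correlation (Gaussian convolution, exact population rho).

Every generator is a pure function of (config, seed): identical outputs
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ModalityKind,
    OmicsDataset,
    OutcomeType,
    StudyDesign,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "sim_microarray",
    "sim_rnaseq",
    "sim_snp",
    "sim_uniform",
    "sim_correlated_pair",
    "assemble_scenario",
    "SCENARIOS",
]

SCENARIOS = ("different_modalities", "correlated_modalities")


@dataclass
class SimulationConfig:
    """Study conditions for the simulators.

    Defaults follow the reference simulation design: 2000 genes, per-group
    sample size 10, per-modality deregulation counts (1600, 1200, 800, 400)
    with a common block of 400 deregulated in every modality.  Effect-size
    mechanisms: microarray genes shift their group-2 mean by delta ~
    U(0.5, 2) with random sign; RNA-seq genes multiply the group-2 mean by
    a fold change drawn log-uniformly from {1/3..1/1.5} u {1.5..3}; SNPs
    shift genotype frequencies from (1/3, 1/3, 1/3) to
    (1/3 - eps, 1/3, 1/3 + eps); uniform genes add a location shift delta.
    """

    num_genes: int = 2000
    num_samples_per_group: int = 10
    rnaseq_de: int = 1600
    microarray_de: int = 1200
    snp_de: int = 800
    unif_de: int = 400
    common_de: int = 400
    cor_level: float = 0.0
    microarray_delta_range: tuple = (0.5, 2.0)
    rnaseq_fc_range: tuple = (1.5, 3.0)
    rnaseq_meanlog: float = 5.0
    rnaseq_sdlog: float = 1.5
    rnaseq_dispersion_range: tuple = (0.05, 0.5)
    snp_epsilon: float = 0.25
    unif_delta: float = 0.3
    libsize_cv: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        de_counts = [self.rnaseq_de, self.microarray_de, self.snp_de, self.unif_de]
        if any(c > self.num_genes for c in de_counts) or self.common_de > self.num_genes:
            raise ValidationError("de counts cannot exceed num_genes")
        if not 0.0 <= self.cor_level <= 1.0:
            raise ValidationError("cor_level must lie in [0, 1]")
        if self.snp_epsilon > 1.0 / 3.0:
            raise ValidationError("snp_epsilon must be <= 1/3")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.num_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.num_genes + 1)]

    @property
    def sample_ids(self) -> list[str]:
        n = 2 * self.num_samples_per_group
        width = len(str(n))
        return [f"s{i:0{width}d}" for i in range(1, n + 1)]

    @property
    def group2_mask(self) -> np.ndarray:
        n = self.num_samples_per_group
        return np.array([False] * n + [True] * n)


@dataclass
class SimulatedStudy:
    """Datasets, design and ground-truth deregulation indicators."""

    datasets: list[OmicsDataset]
    design: StudyDesign
    truth: pd.DataFrame  # genes x modalities, boolean
    config: SimulationConfig = None

    @property
    def truth_any(self) -> pd.Series:
        """Deregulated in at least one modality."""
        return self.truth.any(axis=1)

    @property
    def truth_all(self) -> pd.Series:
        """Deregulated in every modality."""
        return self.truth.all(axis=1)

    def same_behavior_mask(self) -> pd.Series:
        """Genes deregulated in all modalities or in none (Fig-3A-style subset)."""
        return self.truth_all | ~self.truth_any


def _make_design(config: SimulationConfig) -> StudyDesign:
    n = config.num_samples_per_group
    outcome = pd.Series(["group1"] * n + ["group2"] * n)
    return StudyDesign(
        sample_ids=config.sample_ids,
        outcome=outcome,
        outcome_type=OutcomeType.DICHOTOMOUS,
    )


def _resolve_de_mask(
    config: SimulationConfig, de_count: int, de_mask, rng: np.random.Generator
) -> np.ndarray:
    if de_mask is not None:
        return np.asarray(de_mask, dtype=bool)
    mask = np.zeros(config.num_genes, dtype=bool)
    mask[rng.choice(config.num_genes, size=de_count, replace=False)] = True
    return mask


def sim_microarray(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    de_mask: Optional[np.ndarray] = None,
    modality_id: str = "microarray",
) -> tuple[OmicsDataset, np.ndarray]:
    """Microarray-like data: iid N(0,1) noise, DE genes mean-shifted in group 2."""
    rng = rng or np.random.default_rng(config.seed)
    de = _resolve_de_mask(config, config.microarray_de, de_mask, rng)
    n_total = 2 * config.num_samples_per_group
    values = rng.standard_normal((config.num_genes, n_total))
    lo, hi = config.microarray_delta_range
    delta = rng.uniform(lo, hi, size=int(de.sum())) * rng.choice(
        [-1.0, 1.0], size=int(de.sum())
    )
    values[np.ix_(de, config.group2_mask)] += delta[:, None]
    ds = OmicsDataset(
        modality_id=modality_id,
        feature_ids=config.gene_ids,
        sample_ids=config.sample_ids,
        values=values,
        kind=ModalityKind.CONTINUOUS,
    )
    return ds, de


def sim_rnaseq(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    de_mask: Optional[np.ndarray] = None,
    modality_id: str = "rnaseq",
) -> tuple[OmicsDataset, np.ndarray]:
    """RNA-seq-like negative-binomial counts with gene-wise baselines and dispersions.

    Baseline means are log-normal, dispersions uniform; DE genes multiply
    the group-2 mean by a fold change drawn log-uniformly from
    ``{1/hi..1/lo} u {lo..hi}`` (default lo=1.5, hi=3).
    """
    rng = rng or np.random.default_rng(config.seed)
    de = _resolve_de_mask(config, config.rnaseq_de, de_mask, rng)
    G, n_total = config.num_genes, 2 * config.num_samples_per_group
    mu0 = rng.lognormal(config.rnaseq_meanlog, config.rnaseq_sdlog, size=G)
    disp = rng.uniform(*config.rnaseq_dispersion_range, size=G)
    lo, hi = config.rnaseq_fc_range
    log_fc = rng.uniform(np.log(lo), np.log(hi), size=int(de.sum()))
    fc = np.exp(log_fc * rng.choice([-1.0, 1.0], size=int(de.sum())))
    mu = np.tile(mu0[:, None], (1, n_total))
    mu[np.ix_(de, config.group2_mask)] *= fc[:, None]
    if config.libsize_cv > 0:
        factors = np.exp(
            rng.normal(0.0, config.libsize_cv, size=n_total)
        )
        mu = mu * factors[None, :]
    size = 1.0 / disp  # NB "number of successes" parameterization
    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p)
    ds = OmicsDataset(
        modality_id=modality_id,
        feature_ids=config.gene_ids,
        sample_ids=config.sample_ids,
        values=counts.astype(float),
        kind=ModalityKind.COUNTS,
    )
    return ds, de


def sim_snp(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    de_mask: Optional[np.ndarray] = None,
    modality_id: str = "snp",
) -> tuple[OmicsDataset, np.ndarray]:
    """Ordinal genotype data: uniform over {0,1,2}; DE SNPs shift group-2 frequencies."""
    rng = rng or np.random.default_rng(config.seed)
    de = _resolve_de_mask(config, config.snp_de, de_mask, rng)
    G, n = config.num_genes, 2 * config.num_samples_per_group
    values = rng.integers(0, 3, size=(G, n)).astype(float)
    eps = config.snp_epsilon
    shifted = rng.choice(
        [0.0, 1.0, 2.0],
        size=(int(de.sum()), config.num_samples_per_group),
        p=[1 / 3 - eps, 1 / 3, 1 / 3 + eps],
    )
    values[np.ix_(de, config.group2_mask)] = shifted
    ds = OmicsDataset(
        modality_id=modality_id,
        feature_ids=config.gene_ids,
        sample_ids=config.sample_ids,
        values=values,
        kind=ModalityKind.GENOTYPE,
    )
    return ds, de


def sim_uniform(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    de_mask: Optional[np.ndarray] = None,
    modality_id: str = "unif",
) -> tuple[OmicsDataset, np.ndarray]:
    """Uniform(0,1) reference data; DE genes add a location shift in group 2."""
    rng = rng or np.random.default_rng(config.seed)
    de = _resolve_de_mask(config, config.unif_de, de_mask, rng)
    G, n = config.num_genes, 2 * config.num_samples_per_group
    values = rng.uniform(0.0, 1.0, size=(G, n))
    values[np.ix_(de, config.group2_mask)] += config.unif_delta
    ds = OmicsDataset(
        modality_id=modality_id,
        feature_ids=config.gene_ids,
        sample_ids=config.sample_ids,
        values=values,
        kind=ModalityKind.UNIFORM_LIKE,
    )
    return ds, de


def sim_correlated_pair(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    de_mask: Optional[np.ndarray] = None,
) -> tuple[OmicsDataset, OmicsDataset, np.ndarray]:
    """Two microarray-like datasets with per-gene correlation among null genes.

    For each non-deregulated gene, dataset 2's row is
    ``rho * X + sqrt(1 - rho^2) * Z`` with X the dataset-1 row and Z fresh
    N(0,1) noise — population Pearson correlation exactly rho.  DE genes are
    drawn independently per dataset but share the same shift (same
    deregulation direction and size, independent noise).
    """
    rng = rng or np.random.default_rng(config.seed)
    rho = config.cor_level
    de = _resolve_de_mask(config, config.microarray_de, de_mask, rng)
    G, n = config.num_genes, 2 * config.num_samples_per_group
    X = rng.standard_normal((G, n))
    Z = rng.standard_normal((G, n))
    Y = rho * X + np.sqrt(1.0 - rho**2) * Z
    lo, hi = config.microarray_delta_range
    n_de = int(de.sum())
    delta = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    # DE rows: independent noise per dataset, shared shift
    X[np.ix_(de, config.group2_mask)] += delta[:, None]
    Y[de] = rng.standard_normal((n_de, n))
    Y[np.ix_(de, config.group2_mask)] += delta[:, None]
    mk = lambda vals, mid: OmicsDataset(
        modality_id=mid,
        feature_ids=config.gene_ids,
        sample_ids=config.sample_ids,
        values=vals,
        kind=ModalityKind.CONTINUOUS,
    )
    return mk(X, "microarray1"), mk(Y, "microarray2"), de


def assemble_scenario(
    name: str, config: Optional[SimulationConfig] = None, **overrides
) -> SimulatedStudy:
    """Build a named simulation scenario with ground-truth bookkeeping.

    ``different_modalities``: four datasets (rnaseq, microarray, snp, unif)
    with a common deregulated block contained in every modality's DE set
    and modality-specific extras drawn from the remaining genes.
    ``correlated_modalities``: two microarray datasets, all DE genes common,
    per-gene correlation ``cor_level`` among the null genes.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}")
    if config is None:
        if name == "correlated_modalities":
            # half the genes deregulated in both datasets, scaling with num_genes
            n_genes = int(overrides.get("num_genes", 2000))
            de = int(overrides.get("microarray_de", n_genes // 2))
            defaults = dict(
                num_samples_per_group=10,
                rnaseq_de=0,
                snp_de=0,
                unif_de=0,
            )
            defaults.update(overrides)
            defaults.update(microarray_de=de, common_de=int(overrides.get("common_de", de)))
            config = SimulationConfig(**defaults)
        else:
            config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    G = config.num_genes

    if name == "correlated_modalities":
        if config.common_de > config.microarray_de:
            raise ValidationError("common_de must be <= microarray_de")
        de = np.zeros(G, dtype=bool)
        de[rng.choice(G, size=config.common_de, replace=False)] = True
        ds1, ds2, _ = sim_correlated_pair(config, rng, de_mask=de)
        truth = pd.DataFrame(
            {"microarray1": de, "microarray2": de}, index=config.gene_ids
        )
        return SimulatedStudy([ds1, ds2], design, truth, config)

    # different_modalities: shuffled gene order; common block first, extras disjoint
    # from the common block but drawn independently per modality
    if config.common_de > min(
        config.rnaseq_de, config.microarray_de, config.snp_de, config.unif_de
    ):
        raise ValidationError("common_de must be <= every per-modality de count")
    order = rng.permutation(G)
    common = np.zeros(G, dtype=bool)
    common[order[: config.common_de]] = True
    pool = order[config.common_de :]
    masks = {}
    for mod, count in (
        ("rnaseq", config.rnaseq_de),
        ("microarray", config.microarray_de),
        ("snp", config.snp_de),
        ("unif", config.unif_de),
    ):
        mask = common.copy()
        extra = count - config.common_de
        if extra > 0:
            mask[rng.choice(pool, size=extra, replace=False)] = True
        masks[mod] = mask
    gens = {
        "rnaseq": sim_rnaseq,
        "microarray": sim_microarray,
        "snp": sim_snp,
        "unif": sim_uniform,
    }
    datasets = [gens[mod](config, rng, de_mask=masks[mod])[0] for mod in gens]
    truth = pd.DataFrame({mod: masks[mod] for mod in gens}, index=config.gene_ids)
    return SimulatedStudy(datasets, design, truth, config)
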