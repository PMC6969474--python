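"""Synthetic two-condition RNA-seq data with planted coexpression modules.

The generator emulates a two-diet testis transcriptome study design: two
conditions of 9 samples each, ~18,000 genes, and a focal "spermatogenesis-like"
gene set of ~145 genes that carries planted coexpression modules. Each module m
has a target within-module correlation rho_m realised by a one-factor Gaussian
latent model: per sample s,

    z_gs = sqrt(rho) * f_ms + sqrt(1 - rho) * eps_gs,   f_ms, eps_gs ~ N(0,1),

so any two module genes have latent correlation rho. Unassigned genes are
independent (z_gs = eps_gs). Condition B applies a disruption delta per module:
rho_B = rho * (1 - delta), attenuating coexpression without touching marginal
expression levels. Counts are negative binomial with mean
exp(mu_g + biological_sd * z_gs) * size_factor_s and variance mu + phi*mu^2;
the per-gene baseline mu_g is shared by both conditions, and per-sample size
factors are log-normal so library-size normalization is non-trivial but mild.

Companion generators produce a per-gene DE p-value table (Beta(a,1)
alternatives among uniforms) and a qPCR Ct table (reference gene plus a shifted
target), so every downstream stage is testable without external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .exprio import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    write_counts,
    write_gene_sets,
    write_pvalue_table,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_de_pvalues",
    "simulate_qpcr",
    "generate_dataset",
]

DEFAULT_MODULES = ((30, 0.8), (25, 0.75), (20, 0.7))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic expression generator.

    Defaults mirror the emulated design: 9 samples per condition, 18,000
    genes, a 145-gene focal set carrying three planted modules with strong
    within-module correlation, and a strong disruption (delta = 0.85) of those
    modules in condition B.
    """

    n_genes: int = 18000
    samples_per_condition: int = 9
    modules: tuple[tuple[int, float], ...] = DEFAULT_MODULES
    disruption: float = 0.85
    gene_set_size: int = 145
    log_mean_range: tuple[float, float] = (2.0, 6.0)
    biological_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.samples_per_condition <= 0:
            raise ConfigurationError("samples_per_condition must be positive")
        total = sum(size for size, _ in self.modules)
        if any(size <= 0 for size, _ in self.modules):
            raise ConfigurationError("module sizes must be positive")
        if total > self.gene_set_size:
            raise ConfigurationError(
                f"module sizes sum to {total} > gene_set_size={self.gene_set_size}"
            )
        if self.gene_set_size > self.n_genes:
            raise ConfigurationError("gene_set_size exceeds n_genes")
        if not (0.0 <= self.disruption <= 1.0):
            raise ConfigurationError(f"disruption must lie in [0, 1], got {self.disruption}")
        for _, rho in self.modules:
            if not (0.0 <= rho < 1.0):
                raise ConfigurationError(f"module rho must lie in [0, 1), got {rho}")
            rho_b = rho * (1.0 - self.disruption)
            if not (0.0 <= rho_b < 1.0):
                raise ConfigurationError(f"disrupted rho = {rho_b} falls outside [0, 1)")
        if self.log_mean_range[0] > self.log_mean_range[1]:
            raise ConfigurationError("log_mean_range must be (low, high) with low <= high")
        if self.biological_sd <= 0:
            raise ConfigurationError("biological_sd must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.library_size_sd < 0:
            raise ConfigurationError("library_size_sd must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted: module membership and per-condition rho."""

    module_assignment: dict[str, str]
    rho_per_condition: dict[str, tuple[float, float]]
    gene_set: tuple[str, ...] = ()
    gene_set_name: str = "FOCAL_SET"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_assignment": self.module_assignment,
            "rho_per_condition": {m: list(v) for m, v in self.rho_per_condition.items()},
            "gene_set": list(self.gene_set),
            "gene_set_name": self.gene_set_name,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # variance = mu + dispersion * mu^2  <=>  NB(size r = 1/dispersion, p = r/(r+mu))
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_expression(
    config: SimulationConfig, return_latent: bool = False
) -> tuple[CountMatrix, CountMatrix, GroundTruth] | tuple[CountMatrix, CountMatrix, GroundTruth, dict]:
    """Draw the two condition count matrices and the planted ground truth.

    Deterministic given ``config.seed``. With ``return_latent=True`` a fourth
    element maps condition label -> latent z matrix (genes x samples), for
    checking the generative model directly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    s_per = config.samples_per_condition

    # module blocks occupy the head of the focal set, which heads the gene list
    assignment: dict[str, str] = {}
    blocks: list[tuple[slice, float]] = []
    start = 0
    for i, (size, rho) in enumerate(config.modules):
        label = f"M{i + 1}"
        blocks.append((slice(start, start + size), rho))
        for g in genes[start : start + size]:
            assignment[g] = label
        start += size
    rho_per_condition = {
        f"M{i + 1}": (rho, rho * (1.0 - config.disruption))
        for i, (_, rho) in enumerate(config.modules)
    }

    mu = rng.uniform(*config.log_mean_range, size=config.n_genes)

    matrices: dict[str, CountMatrix] = {}
    latents: dict[str, np.ndarray] = {}
    for cond_idx, cond in enumerate(("A", "B")):
        eps = rng.standard_normal((config.n_genes, s_per))
        z = eps.copy()
        for (block, rho), _ in zip(blocks, config.modules):
            rho_c = rho if cond == "A" else rho * (1.0 - config.disruption)
            f = rng.standard_normal(s_per)
            z[block] = math.sqrt(rho_c) * f[None, :] + math.sqrt(1.0 - rho_c) * eps[block]
        size_factors = np.exp(rng.normal(0.0, config.library_size_sd, size=s_per))
        mean = np.exp(mu[:, None] + config.biological_sd * z) * size_factors[None, :]
        counts = _nb_counts(rng, mean, config.nb_dispersion)
        sample_ids = [f"{cond}{j + 1:02d}" for j in range(s_per)]
        df = pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene_id"), columns=sample_ids)
        matrices[cond] = CountMatrix(df, {s: cond for s in sample_ids})
        latents[cond] = z

    truth = GroundTruth(
        module_assignment=assignment,
        rho_per_condition=rho_per_condition,
        gene_set=tuple(genes[: config.gene_set_size]),
    )
    if return_latent:
        return matrices["A"], matrices["B"], truth, latents
    return matrices["A"], matrices["B"], truth


def simulate_de_pvalues(
    n_genes: int, n_true: int, alt_beta_a: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Per-gene DE p-value table: Beta(a, 1) alternatives among uniform nulls.

    The first ``n_true`` gene IDs carry the alternatives, so planted DE genes
    coincide with the head of the focal gene set emitted by
    :func:`simulate_expression`. alt_beta_a = 1 makes alternatives
    indistinguishable from the null (Beta(1,1) = U(0,1)).
    """
    if n_true > n_genes:
        raise ConfigurationError(f"n_true={n_true} exceeds n_genes={n_genes}")
    if not (0.0 < alt_beta_a <= 1.0):
        raise ConfigurationError(f"alt_beta_a must lie in (0, 1], got {alt_beta_a}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n_genes)
    if n_true:
        p[:n_true] = rng.beta(alt_beta_a, 1.0, size=n_true)
    return pd.DataFrame({"gene_id": _gene_ids(n_genes), "p_value": p})


def simulate_qpcr(
    n_per_group: int,
    delta_ct_shift: float,
    noise_sd: float,
    seed: int = 0,
    baseline: float = 5.0,
) -> pd.DataFrame:
    """Ct table for one target gene in a control/treated design.

    Reference Ct ~ N(20, noise_sd); target Ct = reference + baseline +
    group shift + N(0, noise_sd), with the treated group shifted by
    ``delta_ct_shift`` cycles (+1 cycle = halved expression). noise_sd = 0
    gives the exact noise-free limit.
    """
    if n_per_group < 2:
        raise ConfigurationError(f"n_per_group must be >= 2, got {n_per_group}")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for group, shift in (("control", 0.0), ("treated", delta_ct_shift)):
        ref = 20.0 + rng.normal(0.0, noise_sd, size=n_per_group) if noise_sd else np.full(n_per_group, 20.0)
        noise = rng.normal(0.0, noise_sd, size=n_per_group) if noise_sd else np.zeros(n_per_group)
        target = ref + baseline + shift + noise
        for j in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{group[0].upper()}{j + 1:02d}",
                    "group": group,
                    "ct_target": target[j],
                    "ct_reference": ref[j],
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    n_true_de: int = 100,
    alt_beta_a: float = 0.05,
    n_decoy_sets: int = 5,
    decoy_set_size: int = 100,
    qpcr_shift: float = 1.0,
    qpcr_noise_sd: float = 0.5,
) -> dict[str, Path]:
    """Write a complete synthetic dataset for the pipeline to ``outdir``.

    Emits counts.tsv + sample_map.tsv (both conditions combined), gene_sets.gmt
    (the focal set plus random decoy sets drawn from the remaining genes),
    de_pvalues.tsv, ct_table.tsv and ground_truth.json. Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm_a, cm_b, truth = simulate_expression(config)
    combined = CountMatrix(
        pd.concat([cm_a.counts, cm_b.counts], axis=1),
        {**cm_a.condition_of, **cm_b.condition_of},
    )
    paths = {
        "counts": outdir / "counts.tsv",
        "sample_map": outdir / "sample_map.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "de_pvalues": outdir / "de_pvalues.tsv",
        "ct_table": outdir / "ct_table.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_counts(combined, paths["counts"], paths["sample_map"])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    sets = {
        truth.gene_set_name: GeneSet(
            truth.gene_set_name, "focal gene set with planted modules", truth.gene_set
        )
    }
    pool = np.array(_gene_ids(config.n_genes)[config.gene_set_size :])
    for i in range(n_decoy_sets):
        size = min(decoy_set_size, pool.size)
        members = tuple(rng.choice(pool, size=size, replace=False)) if size else ()
        if members:
            sets[f"DECOY_{i + 1}"] = GeneSet(f"DECOY_{i + 1}", "random decoy set", members)
    write_gene_sets(GeneSetCollection(sets), paths["gene_sets"])

    de = simulate_de_pvalues(config.n_genes, n_true_de, alt_beta_a, seed=config.seed + 1)
    write_pvalue_table(de, paths["de_pvalues"])

    ct = simulate_qpcr(config.samples_per_condition, qpcr_shift, qpcr_noise_sd, seed=config.seed + 2)
    ct.to_csv(paths["ct_table"], sep="\t", index=False)

    truth.to_json(paths["ground_truth"])
    (outdir / "sim_config.json").write_text(json.dumps(dataclasses.asdict(config), indent=2))
    return paths
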