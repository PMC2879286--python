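"""Synthetic genotype/phenotype generation for testing and benchmarking.

Genotypes are built as a sum of two independent haplotypes. Each haplotype
is a first-order Markov chain over loci: the allele at locus *j* is copied
from locus *j-1* with probability ``ld_rho`` and otherwise drawn fresh as
Bernoulli(MAF_j). Marginally every locus is therefore in Hardy-Weinberg
equilibrium, while adjacent loci carry a tunable amount of linkage
disequilibrium with a closed form for the adjacent-pair correlation.
Missing calls are applied i.i.d. on top. A single integer seed drives one
named generator; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genotype_io import MISSING, GenotypeMatrix, PhenotypeTable, SNPInfo


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic genotype panel.

    ``mafs`` may be a single frequency applied to every SNP or a per-SNP
    sequence of length ``n_snp``; every frequency must lie strictly in
    (0, 1). ``ld_rho`` is the probability that a haplotype allele is
    copied from the previous locus (0 = linkage equilibrium, 1 = every
    locus duplicates the first).
    """

    n_ind: int
    n_snp: int
    mafs: float | Sequence[float] = 0.3
    missing_rate: float = 0.0
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ind < 1 or self.n_snp < 1:
            raise ParameterError("n_ind and n_snp must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not (0.0 <= self.ld_rho <= 1.0):
            raise ParameterError(f"ld_rho must be in [0, 1], got {self.ld_rho}")
        m = self.maf_array()
        if np.any(m <= 0.0) or np.any(m >= 1.0):
            raise ParameterError("every MAF must lie strictly in (0, 1)")

    def maf_array(self) -> np.ndarray:
        m = np.asarray(self.mafs, dtype=np.float64)
        if m.ndim == 0:
            m = np.full(self.n_snp, float(m))
        if m.shape != (self.n_snp,):
            raise ParameterError(
                f"mafs must be scalar or length {self.n_snp}, got shape {m.shape}"
            )
        return m


def uniform_mafs(n_snp: int, low: float, high: float, seed: int) -> np.ndarray:
    """Sample per-SNP allele frequencies uniformly from [low, high]."""
    if not (0.0 < low <= high < 1.0):
        raise ParameterError("need 0 < low <= high < 1")
    return np.random.default_rng(seed).uniform(low, high, size=n_snp)


def _default_snps(n_snp: int, chrom: str = "1", spacing_bp: int = 1000) -> list[SNPInfo]:
    width = len(str(n_snp))
    return [
        SNPInfo(
            name=f"snp{j + 1:0{width}d}",
            chrom=chrom,
            pos=(j + 1) * spacing_bp,
            ref_allele="A",
            alt_allele="G",
        )
        for j in range(n_snp)
    ]


def simulate_haplotypes(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two (n_ind x n_snp) 0/1 haplotype arrays under the copy-chain model.

    Returned separately so tests can compute true haplotypic LD; genotype
    construction sums them.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = spec.maf_array()
    haps = []
    for _ in range(2):
        h = np.empty((spec.n_ind, spec.n_snp), dtype=np.int8)
        fresh = rng.random((spec.n_ind, spec.n_snp)) < mafs[None, :]
        if spec.ld_rho > 0.0 and spec.n_snp > 1:
            copy = rng.random((spec.n_ind, spec.n_snp)) < spec.ld_rho
        else:
            copy = np.zeros((spec.n_ind, spec.n_snp), dtype=bool)
        h[:, 0] = fresh[:, 0]
        for j in range(1, spec.n_snp):
            h[:, j] = np.where(copy[:, j], h[:, j - 1], fresh[:, j])
        haps.append(h)
    return haps[0], haps[1]


def simulate_genotypes(spec: SimSpec) -> GenotypeMatrix:
    """Generate a :class:`GenotypeMatrix` under the spec's copy-chain model."""
    h1, h2 = simulate_haplotypes(spec)
    codes = (h1 + h2).astype(np.int8)
    if spec.missing_rate > 0.0:
        # independent stream for missingness so the genotype draw is
        # unaffected by toggling the missing rate
        rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2**31))
        miss = rng.random(codes.shape) < spec.missing_rate
        codes[miss] = MISSING
    width = len(str(spec.n_ind))
    sample_ids = [f"ind{i + 1:0{width}d}" for i in range(spec.n_ind)]
    return GenotypeMatrix(sample_ids=sample_ids, snps=_default_snps(spec.n_snp), codes=codes)


def simulate_phenotype(
    G: GenotypeMatrix,
    betas: Sequence[float],
    noise_sd: float = 1.0,
    binary: bool = False,
    seed: int = 0,
    trait_name: str = "trait",
) -> PhenotypeTable:
    """Phenotype from a linear predictor over genotype codes.

    Quantitative: ``y = sum_j beta_j g_ij + eps``, ``eps ~ N(0, noise_sd^2)``.
    Binary: Bernoulli with logit equal to the same linear predictor.
    Missing genotypes contribute 0 to the sum.
    """
    betas = np.asarray(betas, dtype=np.float64)
    if betas.shape != (G.n_snps,):
        raise ParameterError(f"betas must have length {G.n_snps}, got {betas.shape}")
    rng = np.random.default_rng(seed)
    g = np.where(G.codes >= 0, G.codes, 0).astype(np.float64)
    eta = g @ betas
    if binary:
        p = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(G.n_samples) < p).astype(np.float64)
    else:
        if noise_sd <= 0:
            raise ParameterError(f"noise_sd must be > 0, got {noise_sd}")
        y = eta + rng.normal(0.0, noise_sd, size=G.n_samples)
    df = pd.DataFrame({trait_name: y}, index=pd.Index(G.sample_ids, name="id"))
    return PhenotypeTable(data=df)


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    n_snp: int = 100,
    mafs: float | Sequence[float] = 0.3,
    missing_rate: float = 0.0,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Unrelated case/control cohort with an exact case count.

    Genotypes follow :func:`simulate_genotypes`; the binary ``status``
    phenotype assigns exactly ``n_cases`` ones at seeded random positions,
    independent of genotype (a null cohort for calibration checks).
    """
    if n_cases < 1 or n_controls < 1:
        raise ParameterError("n_cases and n_controls must be >= 1")
    n = n_cases + n_controls
    spec = SimSpec(
        n_ind=n, n_snp=n_snp, mafs=mafs,
        missing_rate=missing_rate, ld_rho=ld_rho, seed=seed,
    )
    G = simulate_genotypes(spec)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31, size=2)[1])
    status = np.zeros(n, dtype=np.float64)
    status[rng.permutation(n)[:n_cases]] = 1.0
    df = pd.DataFrame({"status": status}, index=pd.Index(G.sample_ids, name="id"))
    return G, PhenotypeTable(data=df)


# kept as an alias of the documented name for the case/control wrapper
simulate_trio_free_cohort = simulate_cohort
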