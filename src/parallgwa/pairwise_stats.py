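"""Pairwise statistics: IBS / genomic kinship between individuals and
two-locus linkage disequilibrium between SNPs.

These are the "type 3" (individual x individual) and "type 4" (SNP x SNP)
computations whose cost grows quadratically and which therefore use the
recursive pairwise grid partitioning.

Identity-by-state between individuals i and k is the average over the
pairwise-complete SNPs of ``1 - |g_i - g_k| / 2``: 1 for identical
genotypes, 1/2 when they differ by one allele, 0 when opposite
homozygotes. The frequency-weighted variant is the genomic-kinship
estimator: the average over polymorphic pairwise-complete SNPs of
``(g_i/2 - p)(g_k/2 - p) / (p (1 - p))`` with p the sample alt-allele
frequency; its diagonal is ``0.5 (1 + F_i)`` with F the per-individual
inbreeding estimate.

LD for a pair of unphased loci is computed from maximum-likelihood
haplotype frequencies obtained with the classical two-locus EM (the
double-heterozygote cell is split between the cis and trans phase
configurations in proportion to the current frequency estimates). From
the converged frequencies: D, D' (D scaled by its admissible bound) and
r^2; rho is the composite LD measure, the plain Pearson correlation of
the two genotype-code vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan
from typing import Sequence

import numpy as np

from .errors import EmptyDataError, ParameterError
from .genotype_io import GenotypeMatrix
from .ind_stats import homozygosity
from .snp_stats import alt_allele_freqs

#: minimum pairwise-complete observations before an LD pair is reported
DEFAULT_MIN_SHARED = 10

LD_STATISTICS = ("D", "dprime", "r2", "rho")


@dataclass
class PairMatrix:
    """Symmetric id x id statistic matrix with companion shared counts."""

    ids: list[str]
    values: np.ndarray
    statistic: str
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.ids)
        if self.values.shape != (k, k) or self.n_shared.shape != (k, k):
            raise ParameterError("PairMatrix arrays must be square over ids")


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (A/a = ref/alt at locus 1, B/b at 2)."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float

    def __post_init__(self) -> None:
        s = self.f_AB + self.f_Ab + self.f_aB + self.f_ab
        if abs(s - 1.0) > 1e-9 or min(self.f_AB, self.f_Ab, self.f_aB, self.f_ab) < -1e-12:
            raise ParameterError(f"haplotype frequencies invalid (sum {s})")


@dataclass(frozen=True)
class LDResult:
    """LD statistics for one locus pair (NaN fields flag a degenerate pair)."""

    D: float
    Dprime: float
    r2: float
    rho: float
    n: int

    @property
    def is_flagged(self) -> bool:
        return isnan(self.D)


_LD_FLAGGED = lambda n: LDResult(np.nan, np.nan, np.nan, np.nan, n)  # noqa: E731


# ---------------------------------------------------------------------------
# IBS / genomic kinship

def ibs_pair(
    g_i: np.ndarray,
    g_k: np.ndarray,
    weight: str = "none",
    freqs: np.ndarray | None = None,
) -> tuple[float, int]:
    """IBS (or genomic kinship, ``weight='freq'``) for one individual pair.

    Returns ``(value, n_shared)``; value is NaN when no SNP is shared.
    """
    gi = np.asarray(g_i)
    gk = np.asarray(g_k)
    if gi.shape != gk.shape:
        raise ParameterError("genotype vectors must have equal length")
    mask = (gi >= 0) & (gk >= 0)
    if weight == "none":
        n = int(mask.sum())
        if n == 0:
            return float("nan"), 0
        val = float(np.mean(1.0 - np.abs(gi[mask] - gk[mask]) / 2.0))
        return val, n
    if weight == "freq":
        if freqs is None:
            raise ParameterError("weight='freq' requires per-SNP allele frequencies")
        p = np.asarray(freqs, dtype=np.float64)
        with np.errstate(invalid="ignore"):
            mask = mask & (p > 0.0) & (p < 1.0)
        n = int(mask.sum())
        if n == 0:
            return float("nan"), 0
        pm = p[mask]
        val = float(
            np.mean((gi[mask] / 2.0 - pm) * (gk[mask] / 2.0 - pm) / (pm * (1.0 - pm)))
        )
        return val, n
    raise ParameterError(f"weight must be 'none' or 'freq', got {weight!r}")


def _ibs_diagonal(G: GenotypeMatrix, weight: str, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal values and shared counts: 1 for plain IBS, 0.5(1+F) for kinship."""
    if weight == "none":
        vals = np.ones(G.n_samples)
        n = (G.codes >= 0).sum(axis=1)
    else:
        F = homozygosity(G)["F"].to_numpy()
        vals = 0.5 * (1.0 + F)
        with np.errstate(invalid="ignore"):
            poly = (freqs > 0.0) & (freqs < 1.0)
        n = ((G.codes >= 0) & poly[None, :]).sum(axis=1)
    return vals, n.astype(np.int64)


def ibs_block(
    G: GenotypeMatrix,
    rows: Sequence[int],
    cols: Sequence[int],
    weight: str = "none",
    freqs: np.ndarray | None = None,
    diag_vals: np.ndarray | None = None,
    diag_n: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """IBS/kinship values for one rows x cols block of the pair grid.

    Used by both the serial matrix builder and the parallel workers, so a
    cell's value never depends on which block computed it.
    """
    if weight == "freq" and freqs is None:
        freqs = alt_allele_freqs(G)
    if diag_vals is None or diag_n is None:
        diag_vals, diag_n = _ibs_diagonal(G, weight, freqs if freqs is not None else np.empty(0))
    vals = np.empty((len(rows), len(cols)))
    ns = np.empty((len(rows), len(cols)), dtype=np.int64)
    for a, i in enumerate(rows):
        gi = G.codes[i]
        for b, k in enumerate(cols):
            if i == k:
                vals[a, b] = diag_vals[i]
                ns[a, b] = diag_n[i]
            else:
                v, n = ibs_pair(gi, G.codes[k], weight=weight, freqs=freqs)
                vals[a, b] = v
                ns[a, b] = n
    return vals, ns


def ibs_matrix(G: GenotypeMatrix, weight: str = "none") -> PairMatrix:
    """Full symmetric IBS (or genomic kinship) matrix over all individuals."""
    if G.n_samples < 2:
        raise ParameterError("ibs_matrix requires at least 2 individuals")
    if weight not in ("none", "freq"):
        raise ParameterError(f"weight must be 'none' or 'freq', got {weight!r}")
    freqs = alt_allele_freqs(G) if weight == "freq" else None
    diag_vals, diag_n = _ibs_diagonal(G, weight, freqs if freqs is not None else np.empty(0))
    n_ind = G.n_samples
    vals = np.empty((n_ind, n_ind))
    ns = np.empty((n_ind, n_ind), dtype=np.int64)
    np.fill_diagonal(vals, 0.0)
    vals[np.diag_indices(n_ind)] = diag_vals
    ns[np.diag_indices(n_ind)] = diag_n
    for i in range(n_ind):
        for k in range(i + 1, n_ind):
            v, n = ibs_pair(G.codes[i], G.codes[k], weight=weight, freqs=freqs)
            vals[i, k] = vals[k, i] = v
            ns[i, k] = ns[k, i] = n
    statistic = "ibs" if weight == "none" else "kinship"
    return PairMatrix(ids=list(G.sample_ids), values=vals, statistic=statistic, n_shared=ns)


# ---------------------------------------------------------------------------
# Two-locus EM and LD

def _genotype_margins(counts: np.ndarray) -> tuple[float, float, float]:
    """(total, alt freq locus 1, alt freq locus 2) from a 3x3 count table."""
    total = float(counts.sum())
    g = np.arange(3, dtype=np.float64)
    p1 = float((counts.sum(axis=1) * g).sum()) / (2.0 * total)
    p2 = float((counts.sum(axis=0) * g).sum()) / (2.0 * total)
    return total, p1, p2


def em_haplotype_freqs(
    joint_counts: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> HaplotypeFreqs:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    ``joint_counts[g1, g2]`` are (possibly fractional) counts of the nine
    unphased genotype combinations. Only the double-heterozygote cell is
    phase-ambiguous; EM splits it between the cis (AB/ab) and trans
    (Ab/aB) resolutions in proportion to the current frequency estimates,
    starting from linkage equilibrium. Iteration stops when the largest
    frequency change is <= ``tol`` or after ``max_iter`` rounds; the tight
    default keeps the likelihood within ~1e-10 of the optimum even when
    the maximum sits on the frequency-simplex boundary, where EM's
    geometric convergence is slowest.
    """
    c = np.asarray(joint_counts, dtype=np.float64)
    if c.shape != (3, 3) or np.any(c < 0):
        raise ParameterError("joint_counts must be a non-negative 3x3 table")
    total, p1, p2 = _genotype_margins(c)
    if total < 2:
        raise ParameterError("need at least 2 observations for EM")
    if not (0.0 < p1 < 1.0) or not (0.0 < p2 < 1.0):
        raise ParameterError("both loci must be polymorphic for EM")

    # fixed haplotype contributions from phase-unambiguous cells
    # (A/a = ref/alt at locus 1, B/b = ref/alt at locus 2)
    base_AB = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    base_Ab = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    base_aB = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    base_ab = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    n_dh = c[1, 1]
    denom = 2.0 * total

    pA, pB = 1.0 - p1, 1.0 - p2
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        share = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = np.array(
            [
                base_AB + share * n_dh,
                base_Ab + (1.0 - share) * n_dh,
                base_aB + (1.0 - share) * n_dh,
                base_ab + share * n_dh,
            ]
        ) / denom
        if np.max(np.abs(new - f)) <= tol:
            f = new
            break
        f = new
    return HaplotypeFreqs(f_AB=float(f[0]), f_Ab=float(f[1]), f_aB=float(f[2]), f_ab=float(f[3]))


def ld_from_freqs(freqs: HaplotypeFreqs) -> tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies.

    D' uses D_max = min(pA*pb, pa*pB) when D > 0 and min(pA*pB, pa*pb)
    when D < 0; a zero bound yields D' = 0 for D = 0 and ±1 otherwise.
    """
    pA = freqs.f_AB + freqs.f_Ab
    pB = freqs.f_AB + freqs.f_aB
    pa, pb = 1.0 - pA, 1.0 - pB
    D = freqs.f_AB - pA * pB
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    else:
        dmax = min(pA * pB, pa * pb)
    if dmax <= 0.0:
        dprime = 0.0 if D == 0.0 else float(np.sign(D))
    else:
        dprime = D / dmax
    denom = pA * pa * pB * pb
    r2 = (D * D / denom) if denom > 0 else (0.0 if D == 0.0 else 1.0)
    return float(D), float(dprime), float(min(r2, 1.0))


def _joint_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    both = (g1 >= 0) & (g2 >= 0)
    idx = 3 * g1[both].astype(np.intp) + g2[both].astype(np.intp)
    return np.bincount(idx, minlength=9).reshape(3, 3).astype(np.float64)


def ld_pair(g1: np.ndarray, g2: np.ndarray) -> LDResult:
    """LD statistics for two genotype-code vectors.

    Pairs with fewer than 2 complete observations or a locus monomorphic
    in the complete subset return a flagged (all-NaN) result.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ParameterError("genotype vectors must have equal length")
    counts = _joint_counts(g1, g2)
    n = int(counts.sum())
    if n < 2:
        return _LD_FLAGGED(n)
    _, p1, p2 = _genotype_margins(counts)
    if not (0.0 < p1 < 1.0) or not (0.0 < p2 < 1.0):
        return _LD_FLAGGED(n)
    freqs = em_haplotype_freqs(counts)
    D, dprime, r2 = ld_from_freqs(freqs)
    # composite LD: correlation of the genotype codes themselves
    both = (g1 >= 0) & (g2 >= 0)
    a = g1[both].astype(np.float64)
    b = g2[both].astype(np.float64)
    va = a - a.mean()
    vb = b - b.mean()
    rho = float((va * vb).sum() / np.sqrt((va * va).sum() * (vb * vb).sum()))
    return LDResult(D=D, Dprime=dprime, r2=r2, rho=rho, n=n)


def ld_cell(
    G: GenotypeMatrix,
    i: int,
    k: int,
    max_bp_window: int | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> LDResult:
    """LD for the SNP pair (i, k) of ``G`` under window/count policies.

    Loci are passed to the estimator in canonical (min, max) index order so
    the (i, k) and (k, i) cells are bit-identical however they are
    computed. Pairs outside the base-pair window (or on different
    chromosomes when a window is set) and pairs with fewer than
    ``min_shared`` complete observations are flagged.
    """
    lo, hi = (i, k) if i <= k else (k, i)
    s1, s2 = G.snps[lo], G.snps[hi]
    if max_bp_window is not None and lo != hi:
        if s1.chrom != s2.chrom or abs(s1.pos - s2.pos) > max_bp_window:
            return _LD_FLAGGED(0)
    res = ld_pair(G.codes[:, lo], G.codes[:, hi])
    if res.n < min_shared:
        return _LD_FLAGGED(res.n)
    return res


def ld_matrix(
    G: GenotypeMatrix,
    snp_subset: Sequence[str] | Sequence[int] | None = None,
    max_bp_window: int | None = None,
    statistics: Sequence[str] = ("r2", "dprime", "rho"),
    min_shared: int = DEFAULT_MIN_SHARED,
) -> dict[str, PairMatrix]:
    """Symmetric LD matrices (one :class:`PairMatrix` per statistic).

    ``snp_subset`` may list SNP names or column indices; all pairs within
    the subset (and within the optional same-chromosome base-pair window)
    are computed, the rest are NaN. Diagonal cells are the self-pair LD
    (1 for polymorphic loci with enough calls, NaN otherwise).
    """
    for s in statistics:
        if s not in LD_STATISTICS:
            raise ParameterError(f"unknown LD statistic {s!r}; choose from {LD_STATISTICS}")
    idx = resolve_snp_subset(G, snp_subset)
    if len(idx) < 2:
        raise EmptyDataError("ld_matrix requires at least 2 SNPs after subsetting")
    sub = G.subset_snps(idx)
    m = sub.n_snps
    mats = {s: np.full((m, m), np.nan) for s in statistics}
    ns = np.zeros((m, m), dtype=np.int64)
    for a in range(m):
        for b in range(a, m):
            res = ld_cell(sub, a, b, max_bp_window=max_bp_window, min_shared=min_shared)
            ns[a, b] = ns[b, a] = res.n
            for s in statistics:
                v = getattr(res, "Dprime" if s == "dprime" else s)
                mats[s][a, b] = mats[s][b, a] = v
    return {
        s: PairMatrix(ids=sub.snp_names, values=mats[s], statistic=s, n_shared=ns.copy())
        for s in statistics
    }


def resolve_snp_subset(
    G: GenotypeMatrix, snp_subset: Sequence[str] | Sequence[int] | None
) -> list[int]:
    """Normalize a subset of SNP names or indices to sorted-unique indices
    in matrix column order (None -> all columns)."""
    if snp_subset is None:
        return list(range(G.n_snps))
    idx: list[int] = []
    name_to_col = {n: j for j, n in enumerate(G.snp_names)}
    for item in snp_subset:
        if isinstance(item, (int, np.integer)):
            j = int(item)
            if not (0 <= j < G.n_snps):
                raise ParameterError(f"SNP index {j} out of range")
        else:
            if item not in name_to_col:
                raise ParameterError(f"unknown SNP name {item!r}")
            j = name_to_col[item]
        idx.append(j)
    return sorted(set(idx))
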