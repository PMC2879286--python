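"""Per-individual statistics: call rate, heterozygosity, homozygosity, inbreeding.

"Type 2" computations — each sample row is processed independently, so the
work partitions over individual ranges. The inbreeding coefficient F is the
method-of-moments excess-homozygosity estimator

    F_i = (o_hom_i - e_hom_i) / (n_called_i - e_hom_i),

with e_hom_i the HWE-expected homozygote count at the sample allele
frequencies, summed over the SNPs called in individual i. Frequencies are
computed once from the full sample (including the focal individual), with
no small-sample correction; monomorphic SNPs contribute 1 to e_hom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .snp_stats import alt_allele_freqs


def _summary_rows(codes: np.ndarray, sample_ids: list[str]) -> pd.DataFrame:
    called = codes >= 0
    n_called = called.sum(axis=1)
    n_het = (codes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        call_rate = n_called / float(codes.shape[1])
        het_frac = np.where(n_called > 0, n_het / np.where(n_called > 0, n_called, 1), np.nan)
    return pd.DataFrame(
        {
            "id": sample_ids,
            "n_called": n_called.astype(np.int64),
            "call_rate": call_rate,
            "het_frac": het_frac,
        }
    )


def per_individual_summary(G: GenotypeMatrix) -> pd.DataFrame:
    """Call rate and heterozygous fraction per sample, in input order."""
    return _summary_rows(G.codes, list(G.sample_ids))


def _homozygosity_rows(
    codes: np.ndarray, sample_ids: list[str], freqs: np.ndarray
) -> pd.DataFrame:
    """Homozygosity rows for a row-slice given full-sample allele freqs.

    Shared by the serial path and the parallel per-block workers so both
    produce bit-identical numbers.
    """
    called = codes >= 0
    n_called = called.sum(axis=1)
    o_hom = (((codes == 0) | (codes == 2))).sum(axis=1)
    # expected homozygote probability per SNP: 1 - 2 p (1 - p)
    with np.errstate(invalid="ignore"):
        e_term = 1.0 - 2.0 * freqs * (1.0 - freqs)
    e_hom = np.where(called, e_term[None, :], 0.0).sum(axis=1)
    denom = n_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(
            (n_called > 0) & (denom != 0.0),
            (o_hom - e_hom) / np.where(denom != 0.0, denom, 1.0),
            np.nan,
        )
    e_hom = np.where(n_called > 0, e_hom, np.nan)
    return pd.DataFrame(
        {
            "id": sample_ids,
            "n_called": n_called.astype(np.int64),
            "o_hom": o_hom.astype(np.int64),
            "e_hom": e_hom,
            "F": F,
        }
    )


def homozygosity(G: GenotypeMatrix) -> pd.DataFrame:
    """Observed/expected homozygosity and inbreeding F per sample.

    Individuals with zero called genotypes get NaN (flagged) statistics.
    """
    return _homozygosity_rows(G.codes, list(G.sample_ids), alt_allele_freqs(G))
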