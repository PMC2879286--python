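"""Genotype, SNP-metadata and phenotype I/O and the shared data model.

Every statistics module in this package operates on one in-memory
representation: a :class:`GenotypeMatrix` holding an N-individual x M-SNP
matrix of alt-allele dosages (0/1/2, ``-1`` for a missing call) together
with ordered sample identifiers and per-SNP metadata. Genotypes are read
either from VCF (biallelic SNP records, GT field) or from a simple
tab-separated matrix with an optional metadata sidecar; phenotypes and
covariates come from a TSV keyed by sample id.

Conventions fixed here and relied on everywhere else:

* genotype code = count of ALT alleles; any half-missing genotype
  (e.g. ``0/.``) is treated as missing;
* phased (``|``) and unphased (``/``) separators are equivalent — phase
  is discarded and never used downstream;
* base-pair coordinates are 1-based as in VCF; all internal index ranges
  are half-open and 0-based;
* on-disk tables are tab-separated UTF-8 with ``NA`` for missing values
  and floats printed with 6 significant digits, so identical inputs
  always produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, EmptyDataError, ParameterError

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in ``GenotypeMatrix.codes``.
MISSING = np.int8(-1)

_VALID_CODES = frozenset({-1, 0, 1, 2})
_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class SNPInfo:
    """Identity and location of one biallelic SNP."""

    name: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataFormatError(f"SNP {self.name!r}: pos must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise DataFormatError(f"SNP {self.name!r}: alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise DataFormatError(f"SNP {self.name!r}: ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """N x M matrix of alt-allele dosage codes with sample and SNP metadata.

    ``codes`` is ``int8`` with entries in {0, 1, 2} and ``-1`` for missing.
    Rows follow ``sample_ids``, columns follow ``snps``; neither order is
    ever changed silently by any operation in the package.
    """

    sample_ids: list[str]
    snps: list[SNPInfo]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.snps)
        if self.codes.shape != (n, m):
            raise DataFormatError(
                f"codes shape {self.codes.shape} does not match "
                f"{n} samples x {m} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("sample ids are not unique")
        names = [s.name for s in self.snps]
        if len(set(names)) != m:
            raise DataFormatError("SNP names are not unique")
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise DataFormatError(f"invalid genotype codes present: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_names(self) -> list[str]:
        return [s.name for s in self.snps]

    def dosage(self) -> np.ndarray:
        """Codes as float64 with missing calls mapped to NaN."""
        x = self.codes.astype(np.float64)
        x[self.codes == MISSING] = np.nan
        return x

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[j] for j in idx],
            codes=self.codes[:, idx],
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            snps=list(self.snps),
            codes=self.codes[idx, :],
        )


@dataclass
class PhenotypeTable:
    """Numeric traits/covariates keyed by sample id (binary traits 0/1)."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DataFormatError("duplicate sample ids in phenotype table")
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def aligned(self, sample_ids: Sequence[str], columns: Sequence[str]) -> np.ndarray:
        """Values for ``columns`` reindexed to ``sample_ids`` (NaN if absent)."""
        for c in columns:
            if c not in self.data.columns:
                raise ParameterError(f"phenotype column {c!r} not found")
        sub = self.data.reindex(list(sample_ids))[list(columns)]
        return sub.to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic, indel and symbolic records are skipped (a count is
    logged). Each GT is coded as its alt-allele dosage; a genotype with any
    missing allele is coded missing. Record order is preserved.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise DataFormatError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise EmptyDataError(f"VCF {path} contains no samples")

    snps: list[SNPInfo] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
            or not var.ALT[0].isalpha()
        ):
            n_skipped += 1
            continue
        name = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        snps.append(
            SNPInfo(
                name=name,
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
            )
        )
        col = np.empty(len(samples), dtype=np.int8)
        for s, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2 or min(alleles) < 0:
                col[s] = MISSING
            else:
                col[s] = alleles[0] + alleles[1]
        cols.append(col)
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, n_skipped)
    if not snps:
        raise EmptyDataError(f"VCF {path} contains no biallelic SNP records")
    codes = np.stack(cols, axis=1)
    return GenotypeMatrix(sample_ids=[str(s) for s in samples], snps=snps, codes=codes)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF (GT only, unphased) for ``G`` via pysam."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    max_pos: dict[str, int] = {}
    for s in G.snps:
        max_pos[s.chrom] = max(max_pos.get(s.chrom, 0), s.pos)
    for chrom, mp in max_pos.items():
        header.contigs.add(chrom, length=mp + 1)
    for sid in G.sample_ids:
        header.add_sample(sid)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, snp in enumerate(G.snps):
            rec = out.new_record(
                contig=snp.chrom,
                start=snp.pos - 1,
                stop=snp.pos,
                alleles=(snp.ref_allele, snp.alt_allele),
                id=snp.name,
            )
            col = G.codes[:, j]
            for i, sid in enumerate(G.sample_ids):
                c = int(col[i])
                if c < 0:
                    rec.samples[sid]["GT"] = (None, None)
                elif c == 0:
                    rec.samples[sid]["GT"] = (0, 0)
                elif c == 1:
                    rec.samples[sid]["GT"] = (0, 1)
                else:
                    rec.samples[sid]["GT"] = (1, 1)
            out.write(rec)


# ---------------------------------------------------------------------------
# Genotype TSV + SNP-metadata sidecar

def default_metadata_path(path: str | Path) -> Path:
    """Sidecar path convention: ``geno.tsv`` -> ``geno.snps.tsv``."""
    p = Path(path)
    return p.with_name(p.stem + ".snps.tsv")


def write_genotype_tsv(G: GenotypeMatrix, path: str | Path, metadata: bool = True) -> None:
    """Write genotype codes as TSV (header = SNP names, body ``NA`` for missing).

    A sidecar TSV with SNP metadata (name/chrom/pos/alleles) is written
    next to the main file unless ``metadata=False``.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\t" + "\t".join(G.snp_names) + "\n")
        for i, sid in enumerate(G.sample_ids):
            row = G.codes[i]
            toks = ["NA" if c < 0 else str(int(c)) for c in row]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")
    if metadata:
        meta = pd.DataFrame(
            {
                "name": [s.name for s in G.snps],
                "chrom": [s.chrom for s in G.snps],
                "pos": [s.pos for s in G.snps],
                "ref_allele": [s.ref_allele for s in G.snps],
                "alt_allele": [s.alt_allele for s in G.snps],
            }
        )
        write_table(meta, default_metadata_path(path))


def read_genotype_tsv(path: str | Path, metadata_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_genotype_tsv`.

    If ``metadata_path`` is None the default sidecar is used when present;
    otherwise placeholder metadata (chrom "0", sequential positions,
    alleles A/B) is synthesized.
    """
    path = Path(path)
    try:
        fh = open(path, encoding="utf-8")
    except OSError as exc:
        raise DataFormatError(f"cannot read genotype TSV {path}: {exc}") from exc
    with fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise EmptyDataError(f"{path}: empty file")
        head = header.split("\t")
        if head[0] != "id":
            raise DataFormatError(f"{path}: first header column must be 'id', got {head[0]!r}")
        snp_names = head[1:]
        if not snp_names:
            raise EmptyDataError(f"{path}: no SNP columns")
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            toks = line.rstrip("\n").split("\t")
            if len(toks) != len(head):
                raise DataFormatError(
                    f"{path}:{lineno}: expected {len(head)} columns, found {len(toks)}"
                )
            sample_ids.append(toks[0])
            row = np.empty(len(snp_names), dtype=np.int8)
            for j, t in enumerate(toks[1:]):
                if t == "NA":
                    row[j] = MISSING
                elif t in ("0", "1", "2"):
                    row[j] = int(t)
                else:
                    raise DataFormatError(
                        f"{path}:{lineno}: invalid genotype token {t!r} "
                        "(expected 0, 1, 2 or NA)"
                    )
            rows.append(row)
    if not rows:
        raise EmptyDataError(f"{path}: no sample rows")

    if metadata_path is None:
        cand = default_metadata_path(path)
        metadata_path = cand if cand.exists() else None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"name": str, "chrom": str})
        required = {"name", "chrom", "pos", "ref_allele", "alt_allele"}
        if not required.issubset(meta.columns):
            raise DataFormatError(
                f"{metadata_path}: metadata must have columns {sorted(required)}"
            )
        by_name = {r["name"]: r for _, r in meta.iterrows()}
        missing = [n for n in snp_names if n not in by_name]
        if missing:
            raise DataFormatError(f"{metadata_path}: no metadata for SNPs {missing[:5]}")
        snps = [
            SNPInfo(
                name=n,
                chrom=str(by_name[n]["chrom"]),
                pos=int(by_name[n]["pos"]),
                ref_allele=str(by_name[n]["ref_allele"]),
                alt_allele=str(by_name[n]["alt_allele"]),
            )
            for n in snp_names
        ]
    else:
        snps = [
            SNPInfo(name=n, chrom="0", pos=j + 1, ref_allele="A", alt_allele="B")
            for j, n in enumerate(snp_names)
        ]
    codes = np.stack(rows, axis=0)
    logger.info("read_genotype_tsv(%s): %d samples x %d SNPs", path, codes.shape[0], codes.shape[1])
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, codes=codes)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` -> VCF, else genotype TSV."""
    p = Path(path)
    if p.name.endswith(".vcf") or p.name.endswith(".vcf.gz"):
        return read_vcf(p)
    return read_genotype_tsv(p)


# ---------------------------------------------------------------------------
# Phenotypes

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype/covariate TSV with an ``id`` column; ``NA`` = missing."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"], keep_default_na=False)
    except OSError as exc:
        raise DataFormatError(f"cannot read phenotype TSV {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise EmptyDataError(f"{path}: empty phenotype file") from exc
    if "id" not in df.columns:
        raise DataFormatError(f"{path}: missing required 'id' column")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DataFormatError(f"{path}: duplicate sample id {dup!r}")
    value_cols = [c for c in df.columns if c != "id"]
    if not value_cols:
        raise DataFormatError(f"{path}: no phenotype columns besides 'id'")
    for c in value_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            val = df.loc[bad, c].iloc[0]
            raise DataFormatError(f"{path}: non-numeric value {val!r} in column {c!r}")
        df[c] = converted.astype(np.float64)
    df = df.set_index("id")
    return PhenotypeTable(data=df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    write_table(table.data.reset_index(), path)


# ---------------------------------------------------------------------------
# Generic result writers (deterministic, byte-stable)

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: fixed column order, ``NA`` missing,
    floats with 6 significant digits. Identical input -> identical bytes."""
    try:
        df.to_csv(path, sep="\t", index=False, na_rep="NA",
                  float_format=_FLOAT_FMT, lineterminator="\n")
    except OSError as exc:
        raise DataFormatError(f"cannot write table to {path}: {exc}") from exc


def write_matrix(values: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    """Write a symmetric id x id matrix as TSV with an id header row/column."""
    values = np.asarray(values)
    if values.shape != (len(ids), len(ids)):
        raise ParameterError(
            f"matrix shape {values.shape} does not match {len(ids)} ids"
        )
    df = pd.DataFrame(values, index=list(ids), columns=list(ids))
    df.index.name = "id"
    try:
        df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT,
                  lineterminator="\n")
    except OSError as exc:
        raise DataFormatError(f"cannot write matrix to {path}: {exc}") from exc


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a matrix written by :func:`write_matrix`; returns (ids, values)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    return [str(i) for i in df.index], df.to_numpy(dtype=np.float64)
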