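"""Readers and writers for feature/trait matrices and scan results.

Conventions: the ordinal feature (genotype) file has features in rows —
first column feature IDs, header row sample IDs — the usual m >> n
layout of GWAS dosage tables.  The trait file is samples x traits
(first column sample ID, one column per trait).  Both are delimited
text with a configurable missing token ("NA" by default).  Genotypes
may alternatively come from a VCF, mapped to alternate-allele dosages.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .kernel import MISSING_CODE, Status
from .scan import OrdinalFeatureMatrix, TraitMatrix

__all__ = [
    "read_feature_matrix",
    "read_trait_matrix",
    "read_vcf_dosage",
    "write_feature_matrix",
    "write_trait_matrix",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)


def read_feature_matrix(
    path,
    delimiter: str = "\t",
    missing_token: str = "NA",
    level_count: Optional[int] = None,
) -> OrdinalFeatureMatrix:
    """Read an ordinal code matrix (features in rows) from delimited text.

    Cells must be small non-negative integers or the missing token; a
    non-integer cell raises with its row/column location.  If
    ``level_count`` is None it is inferred as max(3, max code + 1), so
    plain genotype files keep the declared three dosage levels.
    """
    df = pd.read_csv(
        path, sep=delimiter, index_col=0, header=0, dtype=str,
        keep_default_na=False,
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    codes = np.empty(df.shape, dtype=np.int16)
    for i, (fid, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell == missing_token or cell == "":
                codes[i, j] = MISSING_CODE
                continue
            try:
                val = int(cell)
            except ValueError:
                raise ValueError(
                    f"non-integer code {cell!r} at feature {fid!r}, "
                    f"sample {df.columns[j]!r}"
                ) from None
            if val < 0:
                raise ValueError(
                    f"negative code {val} at feature {fid!r}, "
                    f"sample {df.columns[j]!r}"
                )
            codes[i, j] = val
    observed_max = int(codes.max(initial=-1))
    if level_count is None:
        level_count = max(3, observed_max + 1)
    logger.info(
        "read_feature_matrix: %d features x %d samples from %s",
        codes.shape[0], codes.shape[1], path,
    )
    return OrdinalFeatureMatrix(
        codes=codes,
        feature_ids=df.index.tolist(),
        sample_ids=df.columns.tolist(),
        level_count=level_count,
    )


def read_trait_matrix(
    path,
    delimiter: str = "\t",
    missing_token: str = "NA",
) -> TraitMatrix:
    """Read a samples x traits matrix of reals from delimited text."""
    df = pd.read_csv(
        path, sep=delimiter, index_col=0, header=0, dtype=str,
        keep_default_na=False,
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate trait IDs: {dups}")
    values = np.empty(df.shape, dtype=float)
    for i, (sid, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell == missing_token or cell == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at sample {sid!r}, "
                    f"trait {df.columns[j]!r}"
                ) from None
    logger.info(
        "read_trait_matrix: %d samples x %d traits from %s",
        values.shape[0], values.shape[1], path,
    )
    return TraitMatrix(
        values=values,
        trait_ids=df.columns.tolist(),
        sample_ids=df.index.tolist(),
    )


def read_vcf_dosage(path) -> OrdinalFeatureMatrix:
    """Alternate-allele dosage matrix from the GT fields of a VCF.

    Biallelic records map genotypes to alt-allele counts {0, 1, 2}
    (phased and unphased separators alike); any missing allele makes
    the cell missing.  Multiallelic records are skipped and counted.
    Variant IDs use the ID field, falling back to chrom:pos:ref:alt.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    feature_ids = []
    rows = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        vid = variant.ID
        if vid is None or vid == ".":
            vid = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        row = np.empty(len(samples), dtype=np.int16)
        for j, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last entry is the phasing flag
            if any(a < 0 for a in alleles):
                row[j] = MISSING_CODE
            else:
                row[j] = sum(1 for a in alleles if a > 0)
        feature_ids.append(vid)
        rows.append(row)
    vcf.close()
    if n_multi:
        logger.info("read_vcf_dosage: skipped %d multiallelic records", n_multi)
    codes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int16)
    )
    return OrdinalFeatureMatrix(
        codes=codes,
        feature_ids=feature_ids,
        sample_ids=samples,
        level_count=3,
    )


def write_feature_matrix(
    features: OrdinalFeatureMatrix,
    path,
    delimiter: str = "\t",
    missing_token: str = "NA",
) -> None:
    """Write an ordinal code matrix as delimited text (features in rows)."""
    with open(path, "w") as fh:
        fh.write("feature_id" + delimiter + delimiter.join(features.sample_ids) + "\n")
        for fid, row in zip(features.feature_ids, features.codes):
            cells = [
                missing_token if c == MISSING_CODE else str(int(c)) for c in row
            ]
            fh.write(str(fid) + delimiter + delimiter.join(cells) + "\n")


def write_trait_matrix(
    traits: TraitMatrix,
    path,
    delimiter: str = "\t",
    missing_token: str = "NA",
) -> None:
    """Write a samples x traits matrix as delimited text."""
    with open(path, "w") as fh:
        fh.write("sample_id" + delimiter + delimiter.join(map(str, traits.trait_ids)) + "\n")
        for sid, row in zip(traits.sample_ids, traits.values):
            cells = [
                missing_token if not np.isfinite(v) else repr(float(v))
                for v in row
            ]
            fh.write(str(sid) + delimiter + delimiter.join(cells) + "\n")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a scan result table as TSV.

    J is printed with one decimal (half-integers are exact there); Z and
    p in full double precision; undefined Z/p (non-OK status) as "NA".
    Row order is the table's own (feature-major, trait-minor).
    """
    with open(path, "w") as fh:
        fh.write("feature_id\ttrait_id\tJ\tZ\tp\tn_used\tstatus\n")
        for row in table.itertuples(index=False):
            ok = row.status == Status.OK.value
            z = f"{row.Z:.17e}" if ok and np.isfinite(row.Z) else "NA"
            p = f"{row.p:.17e}" if ok and np.isfinite(row.p) else "NA"
            j = "NA" if not np.isfinite(row.J) else f"{row.J:.1f}"
            fh.write(
                f"{row.feature_id}\t{row.trait_id}\t{j}\t{z}\t{p}\t"
                f"{int(row.n_used)}\t{row.status}\n"
            )


def read_results(path) -> pd.DataFrame:
    """Read back a result TSV written by :func:`write_results`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"feature_id": str, "trait_id": str},
        na_values=["NA"], keep_default_na=False,
    )
    return df
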