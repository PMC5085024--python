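"""Readers and writers for the file formats the pipeline touches.

Supported dialects:

* PLINK text ``.ped``/``.map`` (read and write) — 6 header fields plus two
  allele columns per variant; ``0 0`` allele pairs are missing calls.
* VCF 4.x with hard GT calls (read), via :mod:`cyvcf2`.
* ``.hom`` / ``.hom.indiv`` segment tables (write and re-read), mirroring
  the de-facto dialect emitted by the usual ROH caller.

Coordinates are 1-based inclusive; segment KB = (end - start + 1) / 1000.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    VALID_ALLELES,
    FormatError,
    GenotypeMatrix,
    SampleRecord,
    VariantRecord,
    sort_variants,
)
from .roh import CallingParams, ROHSegment, ROHSet

_PED_PHENOTYPE = {"1": 0, "2": 1}


def read_plink_text(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read a ``.ped``/``.map`` pair into a :class:`GenotypeMatrix`.

    The FID column is taken as the dataset/site label.  Variants are sorted
    by (chromosome, position) with calls permuted consistently; allele codes
    outside {A,C,G,T,1,2,0} are format errors naming the offending line.
    """
    variants: list[VariantRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, vid, _cm, pos = parts
            try:
                pos_bp = int(pos)
            except ValueError:
                raise FormatError(f"{map_path}:{lineno}: non-numeric position {pos!r}") from None
            if pos_bp < 1:
                raise FormatError(f"{map_path}:{lineno}: position must be >= 1")
            variants.append(VariantRecord(chrom=chrom, id=vid, pos_bp=pos_bp))

    n_var = len(variants)
    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    # first observed allele per variant defines a1; second defines a2
    a1 = [None] * n_var
    a2 = [None] * n_var
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_var} fields, got {len(parts)}"
                )
            fid, iid, _pat, _mat, _sex, pheno = parts[:6]
            if pheno not in _PED_PHENOTYPE:
                raise FormatError(
                    f"{ped_path}:{lineno}: phenotype must be 1 (control) or 2 (case), got {pheno!r}"
                )
            row = np.full(n_var, MISSING, dtype=np.int8)
            for j in range(n_var):
                x, y = parts[6 + 2 * j], parts[7 + 2 * j]
                for allele in (x, y):
                    if allele not in VALID_ALLELES:
                        raise FormatError(
                            f"{ped_path}:{lineno}: invalid allele code {allele!r} at variant {j + 1}"
                        )
                if x == "0" or y == "0":
                    if x != y:
                        raise FormatError(
                            f"{ped_path}:{lineno}: half-missing call {x} {y} at variant {j + 1}"
                        )
                    continue
                for allele in (x, y):
                    if a1[j] is None:
                        a1[j] = allele
                    elif allele != a1[j] and a2[j] is None:
                        a2[j] = allele
                    elif allele not in (a1[j], a2[j]):
                        raise FormatError(
                            f"{ped_path}:{lineno}: third allele {allele!r} at variant {j + 1}"
                        )
                row[j] = (x != a1[j]) + (y != a1[j])
            samples.append(SampleRecord(sample_id=iid, dataset_id=fid,
                                        phenotype=_PED_PHENOTYPE[pheno]))
            rows.append(row)

    calls = np.vstack(rows) if rows else np.zeros((0, n_var), dtype=np.int8)
    # canonical orientation: the lexicographically smaller label is a1, so
    # the coding does not depend on row order and round trips are exact
    for j, v in enumerate(variants):
        if a1[j] is not None and a2[j] is not None and a2[j] < a1[j]:
            a1[j], a2[j] = a2[j], a1[j]
            col = calls[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
        elif a1[j] == "2" and a2[j] is None:
            # numeric labels have fixed roles (1 = a1, 2 = a2): a column
            # monomorphic for "2" is an a2 homozygote, not a new a1
            a1[j], a2[j] = "1", "2"
            col = calls[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
        v.a1 = a1[j] or "1"
        v.a2 = a2[j] or "2"
    matrix = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    return sort_variants(matrix).refresh_metadata()


def write_plink_text(matrix: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    """Write a matrix as a ``.ped``/``.map`` pair (inverse of the reader)."""
    with open(map_path, "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(matrix.samples):
            fields = [s.dataset_id, s.sample_id, "0", "0", "0", "2" if s.phenotype else "1"]
            row = matrix.calls[i]
            for j, v in enumerate(matrix.variants):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [v.a1, v.a1]
                elif g == 1:
                    fields += [v.a1, v.a2]
                else:
                    fields += [v.a2, v.a2]
            fh.write(" ".join(fields) + "\n")


def read_vcf(vcf_path: str, sample_table: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read hard diploid GT calls from a VCF.

    Multi-allelic records are rejected.  ``sample_table`` (columns
    ``sample_id``, ``dataset_id``, ``phenotype``) supplies site labels and
    phenotypes, since VCF carries neither; absent samples default to
    dataset "all", phenotype 0.
    """
    from cyvcf2 import VCF

    meta: dict[str, tuple[str, int]] = {}
    if sample_table is not None:
        for rec in sample_table.itertuples(index=False):
            meta[str(rec.sample_id)] = (str(rec.dataset_id), int(rec.phenotype))

    vcf = VCF(vcf_path)
    sample_names = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if rec.ALT and len(rec.ALT) > 1:
            raise FormatError(
                f"{vcf_path}: multi-allelic record at {rec.CHROM}:{rec.POS} not supported"
            )
        col = np.full(len(sample_names), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # trailing element is phasing flag
            if len(alleles) != 2:
                raise FormatError(
                    f"{vcf_path}: non-diploid GT for sample {sample_names[i]} "
                    f"at {rec.CHROM}:{rec.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                continue
            col[i] = int(alleles[0] != 0) + int(alleles[1] != 0)
        ref = rec.REF or "1"
        alt = rec.ALT[0] if rec.ALT else "2"
        variants.append(
            VariantRecord(chrom=str(rec.CHROM), id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                          pos_bp=int(rec.POS), a1=ref, a2=alt)
        )
        cols.append(col)
    vcf.close()

    samples = [
        SampleRecord(sample_id=name, dataset_id=meta.get(name, ("all", 0))[0],
                     phenotype=meta.get(name, ("all", 0))[1])
        for name in sample_names
    ]
    calls = (
        np.column_stack(cols)
        if cols
        else np.zeros((len(sample_names), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    return sort_variants(matrix).refresh_metadata()


_HOM_HEADER = ["FID", "IID", "CHR", "SNP1", "SNP2", "POS1", "POS2", "KB", "NSNP", "DENSITY"]
_HOM_INDIV_HEADER = ["FID", "IID", "NSEG", "KB", "KBAVG"]


def write_hom(
    rohset: ROHSet,
    hom_path: str,
    hom_indiv_path: str | None = None,
    dataset_by_sample: dict[str, str] | None = None,
) -> None:
    """Write segment and per-individual summary tables.

    ``KB`` is (end - start + 1)/1000 and ``DENSITY`` is KB per SNP.  FID is
    looked up in ``dataset_by_sample`` (defaults to the sample id).
    """
    dataset_by_sample = dataset_by_sample or {}
    with open(hom_path, "w") as fh:
        fh.write("\t".join(_HOM_HEADER) + "\n")
        for seg in rohset.segments:
            kb = seg.length_bp / 1000.0
            fid = dataset_by_sample.get(seg.sample_id, seg.sample_id)
            fh.write(
                f"{fid}\t{seg.sample_id}\t{seg.chrom}\t.\t.\t"
                f"{seg.start_bp}\t{seg.end_bp}\t{kb:.3f}\t{seg.n_snps}\t"
                f"{kb / seg.n_snps:.4f}\n"
            )
    if hom_indiv_path is None:
        return
    per: dict[str, list[int]] = {}
    for seg in rohset.segments:
        per.setdefault(seg.sample_id, []).append(seg.length_bp)
    with open(hom_indiv_path, "w") as fh:
        fh.write("\t".join(_HOM_INDIV_HEADER) + "\n")
        for sid in sorted(per):
            lengths = per[sid]
            kb = sum(lengths) / 1000.0
            fid = dataset_by_sample.get(sid, sid)
            fh.write(f"{fid}\t{sid}\t{len(lengths)}\t{kb:.3f}\t{kb / len(lengths):.3f}\n")


def read_hom(hom_path: str, params: CallingParams | None = None) -> ROHSet:
    """Re-parse a ``.hom`` table written by :func:`write_hom`."""
    segments: list[ROHSegment] = []
    with open(hom_path) as fh:
        header = fh.readline().split()
        if header[:3] != ["FID", "IID", "CHR"]:
            raise FormatError(f"{hom_path}: unexpected header {header[:3]}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(_HOM_HEADER):
                raise FormatError(f"{hom_path}:{lineno}: expected {len(_HOM_HEADER)} columns")
            segments.append(
                ROHSegment(
                    sample_id=parts[1],
                    chrom=parts[2],
                    start_bp=int(parts[5]),
                    end_bp=int(parts[6]),
                    n_snps=int(parts[8]),
                )
            )
    return ROHSet(segments=segments, params=params or CallingParams())
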