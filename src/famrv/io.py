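"""Readers and writers for the text formats the toolkit consumes.

Supported formats: PLINK-style PED/MAP and FAM, VCF 4.x (plain or gzip,
read through cyvcf2), refFlat gene annotation (UCSC 11-column), a 1-based
closed interval gene format (``gene chrom start end``), a direct
variant-to-gene mapping (``variant_id gene``), whitespace-delimited
phenotype/covariate tables with an ``FID IID`` key, and a square
tab-delimited relatedness-matrix format.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    GeneSet,
    GenotypeMatrix,
    PedigreeRecord,
    PhenotypeFrame,
    RelMatrix,
    VariantRecord,
)

MISSING_PHENO_TOKENS = {"-9", "NA", "na", "nan", ".", ""}


class FormatError(ValueError):
    """Malformed input file."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# PED / MAP / FAM
# ---------------------------------------------------------------------------

def read_map(map_path) -> list[VariantRecord]:
    variants = []
    with _open_text(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(tok)}")
            chrom, vid, _cm, pos = tok
            variants.append(VariantRecord(chrom, int(pos), vid))
    return variants


def read_ped_map(ped_path, map_path):
    """Read PLINK text PED+MAP into pedigree records and a dosage matrix.

    Allele pairs "0 0" become missing. Dosages count the *minor* allele:
    after reading, allele frequencies are computed per variant and the less
    frequent allele is counted (ties broken by lexicographic allele order).
    Variant ref/alt are set to major/minor allele respectively.
    """
    variants = read_map(map_path)
    m = len(variants)
    records: list[PedigreeRecord] = []
    allele_rows: list[list[str]] = []
    with _open_text(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns "
                    f"(6 + 2x{m} alleles), got {len(tok)}"
                )
            records.append(
                PedigreeRecord(tok[0], tok[1], tok[2], tok[3], int(tok[4]), int(float(tok[5])))
            )
            allele_rows.append(tok[6:])
    n = len(records)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else \
        np.empty((0, m, 2), dtype=object)

    dosage = np.full((n, m), MISSING)
    out_variants = []
    for j, var in enumerate(variants):
        col = alleles[:, j, :]
        typed = (col[:, 0] != "0") & (col[:, 1] != "0")
        obs = np.unique(col[typed])
        if obs.size > 2:
            raise FormatError(
                f"{ped_path}: variant {var.vid} has >2 distinct alleles: {sorted(obs)}"
            )
        if obs.size == 0:
            out_variants.append(var)
            continue
        # count each candidate allele, orient to the minor one
        counts = {a: int(np.sum(col[typed] == a)) for a in obs}
        if obs.size == 1:
            minor, major = obs[0], "N" if obs[0] != "N" else "X"
        else:
            a, b = sorted(obs)  # lexicographic tie-break
            minor, major = (a, b) if counts[a] <= counts[b] else (b, a)
        dosage[typed, j] = np.sum(col[typed] == minor, axis=1)
        out_variants.append(VariantRecord(var.chrom, var.pos, var.vid, str(major), str(minor)))
    geno = GenotypeMatrix(dosage, [r.key for r in records], out_variants)
    return records, geno


def write_ped_map(records, genotypes: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP; dosage counts variant.alt, major allele is variant.ref."""
    with open(map_path, "w") as fh:
        for v in genotypes.variant_order:
            fh.write(f"{v.chrom}\t{v.vid}\t0\t{v.pos}\n")
    rec_by_key = {r.key: r for r in records}
    with open(ped_path, "w") as fh:
        for i, key in enumerate(genotypes.subject_order):
            r = rec_by_key[key]
            row = [r.family_id, r.individual_id, r.father_id, r.mother_id,
                   str(r.sex), str(r.affection)]
            for j, v in enumerate(genotypes.variant_order):
                d = genotypes.dosage[i, j]
                if np.isnan(d):
                    row += ["0", "0"]
                else:
                    k = int(round(d))
                    row += [v.alt] * k + [v.ref] * (2 - k)
            fh.write(" ".join(row) + "\n")


def read_fam(fam_path) -> list[PedigreeRecord]:
    records = []
    with _open_text(fam_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 6:
                raise FormatError(f"{fam_path}:{ln}: expected 6 FAM columns")
            records.append(
                PedigreeRecord(tok[0], tok[1], tok[2], tok[3], int(tok[4]), int(float(tok[5])))
            )
    return records


def write_fam(records, fam_path) -> None:
    with open(fam_path, "w") as fh:
        for r in records:
            fh.write(f"{r.family_id}\t{r.individual_id}\t{r.father_id}\t"
                     f"{r.mother_id}\t{r.sex}\t{r.affection}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, sample_fid_map=None):
    """Read a VCF 4.x (plain or gzip) into sample ids and a dosage matrix.

    Dosage is the ALT-allele count of the GT field; "./." is missing and
    phasing is ignored. Multi-allelic sites are split into one bi-allelic
    record per ALT with genotypes carrying any *other* ALT set missing.

    VCF has no family structure, so subjects are keyed (fid, iid) via
    ``sample_fid_map`` when given, else fid = iid.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for rec in vcf:
        gts = rec.genotype.array()  # (n, ploidy+1); last col = phasing
        if gts is None:
            raise FormatError(f"{vcf_path}: record {rec.CHROM}:{rec.POS} lacks GT")
        a = gts[:, :2].astype(float)
        a[a < 0] = np.nan  # -1 = missing allele
        alts = rec.ALT or []
        for k, alt in enumerate(alts, start=1):
            dos = np.where(np.isnan(a), np.nan, (a == k).astype(float)).sum(axis=1)
            other_alt = np.nansum(np.where(np.isnan(a), 0, (a >= 1) & (a != k)), axis=1) > 0
            dos[other_alt] = np.nan
            vid = rec.ID if rec.ID and len(alts) == 1 else \
                f"{rec.ID or rec.CHROM + ':' + str(rec.POS)}" + (f"_{alt}" if len(alts) > 1 else "")
            variants.append(VariantRecord(str(rec.CHROM), rec.POS, vid, rec.REF, alt))
            cols.append(dos)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    keys = []
    for s in samples:
        if sample_fid_map is not None and s in sample_fid_map:
            keys.append((sample_fid_map[s], s))
        elif ":" in s:
            # "fid:iid" sample names (write_vcf convention) carry family ids
            keys.append(tuple(s.split(":", 1)))
        elif sample_fid_map is not None:
            raise FormatError(f"{vcf_path}: sample {s!r} absent from pedigree")
        else:
            keys.append((s, s))
    return samples, GenotypeMatrix(dosage, keys, variants)


def write_vcf(genotypes: GenotypeMatrix, vcf_path) -> None:
    """Write integer dosages as an unphased GT-only VCF 4.2 text file."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for v in genotypes.variant_order:
            if v.chrom not in seen:
                seen.append(v.chrom)
                fh.write(f"##contig=<ID={v.chrom}>\n")
        ids = "\t".join(f"{fid}:{iid}" for fid, iid in genotypes.subject_order)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(genotypes.variant_order):
            ref = v.ref if v.ref not in ("N", "X") else "A"
            alt = v.alt if v.alt not in ("N", "X") else "T"
            col = genotypes.dosage[:, j]
            gts = "\t".join(
                "./." if np.isnan(d) else gt_code[int(round(d))] for d in col
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path, format_tag: str, variants: list[VariantRecord]) -> GeneSet:
    """Map variants to genes from refFlat, interval, or direct-mapping files.

    refFlat spans follow the UCSC convention (0-based txStart, 1-based
    txEnd): a variant belongs to the gene iff it is on the same chromosome
    and ``txStart < pos <= txEnd``. The interval format ``gene chrom start
    end`` is 1-based closed. The direct format lists ``variant_id gene``
    pairs; unknown variant ids produce a warning and are skipped.
    """
    if format_tag not in ("refflat", "interval", "direct"):
        raise ValueError(f"unknown gene-set format {format_tag!r}")
    genes: dict[str, list[int]] = {}
    if format_tag == "direct":
        vidx = {v.vid: j for j, v in enumerate(variants)}
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                tok = line.split()
                if not tok:
                    continue
                if len(tok) != 2:
                    raise FormatError(f"{path}:{ln}: expected 'variant_id gene'")
                vid, gene = tok
                if vid not in vidx:
                    warnings.warn(f"{path}:{ln}: unknown variant id {vid!r}; skipped")
                    continue
                genes.setdefault(gene, []).append(vidx[vid])
    else:
        spans: list[tuple[str, str, int, int]] = []  # gene, chrom, lo, hi (1-based closed)
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                tok = line.rstrip("\n").split("\t") if format_tag == "refflat" else line.split()
                if not tok or not tok[0]:
                    continue
                if format_tag == "refflat":
                    if len(tok) < 6:
                        raise FormatError(f"{path}:{ln}: short refFlat line")
                    gene, _tx, chrom, _strand, tx_start, tx_end = tok[:6]
                    spans.append((gene, chrom.removeprefix("chr"), int(tx_start) + 1, int(tx_end)))
                else:
                    if len(tok) != 4:
                        raise FormatError(f"{path}:{ln}: expected 'gene chrom start end'")
                    gene, chrom, lo, hi = tok
                    spans.append((gene, chrom.removeprefix("chr"), int(lo), int(hi)))
        for gene, chrom, lo, hi in spans:
            hits = [j for j, v in enumerate(variants)
                    if v.chrom.removeprefix("chr") == chrom and lo <= v.pos <= hi]
            genes.setdefault(gene, []).extend(hits)
    # within-gene order follows genomic position; dedupe preserving first
    for g, ix in genes.items():
        uniq = sorted(set(ix), key=lambda j: (variants[j].chrom, variants[j].pos))
        genes[g] = uniq
    return GeneSet(genes)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, phenotype_name: str, covariate_names=()) -> PhenotypeFrame:
    """Read a whitespace-delimited table with header and FID IID keys.

    A phenotype column whose observed values are a subset of {0,1} or {1,2}
    is treated as binary (the PLINK 1/2 affection convention is recoded to
    0/1); anything else is continuous. "-9" and "NA" are missing.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if not {"FID", "IID"}.issubset(df.columns):
        raise FormatError(f"{path}: header must contain FID and IID")
    wanted = [phenotype_name, *covariate_names]
    missing_cols = [c for c in wanted if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: column(s) {missing_cols} not found; available: "
            f"{[c for c in df.columns if c not in ('FID', 'IID')]}"
        )

    def to_float(col: pd.Series) -> np.ndarray:
        vals = col.astype(str).str.strip()
        out = np.array([np.nan if v in MISSING_PHENO_TOKENS else float(v) for v in vals])
        return out

    y = to_float(df[phenotype_name])
    observed = set(np.unique(y[np.isfinite(y)]))
    kind = "continuous"
    if observed and observed <= {0.0, 1.0}:
        kind = "binary"
    elif observed and observed <= {1.0, 2.0}:
        kind = "binary"
        y = y - 1.0
    cov = np.column_stack([to_float(df[c]) for c in covariate_names]) \
        if covariate_names else np.empty((len(df), 0))
    keys = list(zip(df["FID"].astype(str), df["IID"].astype(str)))
    return PhenotypeFrame(keys, y, phenotype_name, cov, list(covariate_names), kind)


# ---------------------------------------------------------------------------
# Relatedness matrix text format
# ---------------------------------------------------------------------------

def write_relmatrix(rel: RelMatrix, path) -> None:
    """Square tab-delimited matrix; header row of 'fid:iid' subject ids."""
    with open(path, "w") as fh:
        fh.write("#kind=" + rel.kind + "\n")
        fh.write("\t".join(f"{f}:{i}" for f, i in rel.subject_order) + "\n")
        for row in rel.values:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_relmatrix(path) -> RelMatrix:
    with _open_text(path) as fh:
        first = fh.readline().strip()
        kind = "GRM"
        if first.startswith("#kind="):
            kind = first.split("=", 1)[1]
            header = fh.readline().split()
        else:
            header = first.split()
        keys = [tuple(h.split(":", 1)) for h in header]
        values = np.loadtxt(fh)
    if values.ndim == 1:
        values = values.reshape(1, -1)
    return RelMatrix(values, kind, keys)  # type: ignore[arg-type]


def write_dosage_table(genotypes: GenotypeMatrix, path) -> None:
    """FID IID variant_id dosage long-format table (imputation output)."""
    with open(path, "w") as fh:
        fh.write("FID\tIID\tVID\tDOSAGE\n")
        for i, (fid, iid) in enumerate(genotypes.subject_order):
            for j, v in enumerate(genotypes.variant_order):
                d = genotypes.dosage[i, j]
                fh.write(f"{fid}\t{iid}\t{v.vid}\t" + ("NA" if np.isnan(d) else f"{d:.6g}") + "\n")
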