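"""Readers, writers and catalog filters for polymorphic TE variant data.

This module owns the domain types shared across the pipeline (TEV records,
sample metadata, the RPKM expression matrix, gene models, karyotype bands)
and the converters between on-disk conventions and the internal one.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  VCF positions (1-based) and
GTF intervals (1-based closed) are shifted at parse time; BED and UCSC
cytoBand files pass through unchanged.  A point insertion at VCF position
``p`` occupies the interval ``(p-1, p)``; a deletion-coded element spans
``(p-1, p-1+length)``.

Dosage convention
-----------------
Per-sample dosages always count TE-*presence* alleles in {0, 1, 2} with NaN
for a missing genotype.  Records written as ``ALU_DEL``/``LINE1_DEL``/
``SVA_DEL`` describe elements absent from the reference, so their VCF ALT
allele counts the *absence*; they are recoded to ``2 - alt_count`` on read
(and back on write) so that regression effect signs are comparable across
insertion-coded and deletion-coded variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

TE_CLASSES = ("Alu", "L1", "SVA")

#: VCF INFO/SVTYPE vocabulary -> (te_class, deletion_coded)
_SVTYPE_CODES = {
    "ALU": ("Alu", False),
    "LINE1": ("L1", False),
    "SVA": ("SVA", False),
    "ALU_DEL": ("Alu", True),
    "LINE1_DEL": ("L1", True),
    "SVA_DEL": ("SVA", True),
}
_CLASS_TO_SVTYPE = {("Alu", False): "ALU", ("L1", False): "LINE1", ("SVA", False): "SVA",
                    ("Alu", True): "ALU_DEL", ("L1", True): "LINE1_DEL", ("SVA", True): "SVA_DEL"}


class FormatError(ValueError):
    """A file does not follow the dialect its reader expects."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class TevVariant:
    """One polymorphic TE insertion with per-sample presence dosages.

    ``dosages`` is a float array aligned with an externally supplied sample
    order; entries are 0/1/2 presence-allele counts or NaN when the genotype
    is missing.
    """

    variant_id: str
    chrom: str
    pos: int                      # 1-based, VCF convention
    te_class: str                 # Alu | L1 | SVA
    strand: Optional[str]         # '+', '-', or None (unknown)
    deletion_coded: bool
    length: int
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValidationError(f"unknown TE class {self.te_class!r}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError(f"{self.variant_id}: dosages outside {{0,1,2,missing}}")

    @property
    def carrier_count(self) -> int:
        return int(np.nansum(self.dosages >= 1))

    @property
    def interval(self) -> tuple[int, int]:
        """Variant locus as a 0-based half-open interval.

        Deletion-coded elements occupy their full deleted span; insertion
        points are 1 bp.
        """
        start = self.pos - 1
        return (start, start + self.length) if self.deletion_coded else (start, start + 1)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str          # 'male' | 'female'
    population: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.sample_id}: sex {self.sex!r}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample RPKM matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("expression shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicated gene ids")
        if (self.values < 0).any():
            raise ValidationError("negative expression value")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class GeneModel:
    """A gene interval with strand, biotype and exon/intron/UTR substructure.

    ``substructure`` is an ordered list of (feature, start, end) with feature
    in {five_prime_utr, exon, intron, three_prime_utr}; blocks lie inside
    [start, end) and do not overlap.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    substructure: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: empty interval")
        prev_end = self.start
        for feat, s, e in sorted(self.substructure, key=lambda b: b[1]):
            if s < self.start or e > self.end or s >= e:
                raise ValidationError(f"{self.gene_id}: block {feat} outside gene")
            if s < prev_end and prev_end > self.start:
                raise ValidationError(f"{self.gene_id}: overlapping substructure")
            prev_end = e


@dataclass(frozen=True)
class CytoBand:
    chrom: str
    start: int
    end: int
    band_name: str    # e.g. "17q21.31"
    stain: str

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_tev_vcf(path: str, samples: Sequence[str]) -> list[TevVariant]:
    """Read MEI records from a VCF into TevVariants over ``samples``.

    The TE class is taken from INFO/SVTYPE (ALU, LINE1, SVA, or the *_DEL
    deletion-coded forms); records with any other SVTYPE, or none, are
    skipped and counted in the log.  GT maps 0/0->0, 0/1|1/0->1, 1/1->2,
    ./.->NaN; *_DEL dosages are recoded to presence (2 - alt count).
    """
    variants: list[TevVariant] = []
    skipped = 0
    with pysam.VariantFile(path) as vf:
        if not vf.header.formats.keys() or "GT" not in vf.header.formats:
            raise FormatError(f"{path}: no GT FORMAT declared")
        header_samples = set(vf.header.samples)
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise FormatError(f"{path}: samples absent from VCF header: {missing[:5]}")
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in _SVTYPE_CODES:
                skipped += 1
                continue
            te_class, deletion_coded = _SVTYPE_CODES[svtype]
            dosages = np.empty(len(samples))
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    dosages[i] = np.nan
                else:
                    alt = float(sum(1 for a in gt if a != 0))
                    dosages[i] = 2.0 - alt if deletion_coded else alt
            strand = rec.info.get("MESTRAND")
            if strand not in ("+", "-"):
                strand = None
            length = abs(int(rec.info.get("SVLEN", 1))) or 1
            variants.append(TevVariant(
                variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                chrom=rec.chrom, pos=rec.pos, te_class=te_class, strand=strand,
                deletion_coded=deletion_coded, length=length, dosages=dosages))
    if skipped:
        logger.info("read_tev_vcf: skipped %d non-MEI records in %s", skipped, path)
    return variants


def write_tev_vcf(path: str, variants: Iterable[TevVariant], samples: Sequence[str],
                  chrom_sizes: dict[str, int]) -> None:
    """Write TevVariants to an uncompressed VCF (inverse of :func:`read_tev_vcf`)."""
    header = pysam.VariantHeader()
    for chrom, size in chrom_sizes.items():
        header.add_line(f"##contig=<ID={chrom},length={size}>")
    header.info.add("SVTYPE", 1, "String", "MEI class (ALU/LINE1/SVA, *_DEL when reference-absent)")
    header.info.add("SVLEN", 1, "Integer", "Element length in bp")
    header.info.add("MESTRAND", 1, "String", "Element strand")
    header.info.add("END", 1, "Integer", "Stop position of the interval")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.variant_id)):
            alt = f"<DEL:ME:{v.te_class.upper()}>" if v.deletion_coded else f"<INS:ME:{v.te_class.upper()}>"
            rec = vf.new_record(contig=v.chrom, start=v.pos - 1, stop=v.pos,
                                alleles=("N", alt))
            rec.id = v.variant_id
            rec.info["SVTYPE"] = _CLASS_TO_SVTYPE[(v.te_class, v.deletion_coded)]
            rec.info["SVLEN"] = int(v.length)
            if v.strand is not None:
                rec.info["MESTRAND"] = v.strand
            for i, s in enumerate(samples):
                d = v.dosages[i]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    alt_count = int(2 - d) if v.deletion_coded else int(d)
                    rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[alt_count]
            vf.write(rec)


# ---------------------------------------------------------------------------
# Catalog filters
# ---------------------------------------------------------------------------

def min_carrier_frequency(min_carriers: int, n_samples: int) -> float:
    """Carrier frequency implied by an inclusion floor, as a percentage
    rounded to one decimal (3 of 445 -> 0.7)."""
    return round(100.0 * min_carriers / n_samples, 1)


def filter_by_carriers(variants: Sequence[TevVariant], min_carriers: int = 3) -> list[TevVariant]:
    """Keep variants carried by at least ``min_carriers`` individuals.

    A carrier is a sample with presence dosage >= 1.  Input order is
    preserved.  The implied minimum carrier frequency is logged.
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    kept = [v for v in variants if v.carrier_count >= min_carriers]
    if variants:
        n = len(variants[0].dosages)
        logger.info("filter_by_carriers: kept %d/%d (implied min carrier frequency %.1f%%)",
                    len(kept), len(variants), min_carrier_frequency(min_carriers, n))
    return kept


# ---------------------------------------------------------------------------
# Expression and sample metadata
# ---------------------------------------------------------------------------

def read_expression(path: str) -> ExpressionMatrix:
    """Read a Geuvadis-style RPKM TSV (first column gene ids, one column
    per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression value")
    return ExpressionMatrix.from_frame(df)


def write_expression(path: str, matrix: ExpressionMatrix) -> None:
    matrix.to_frame().rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


def read_sample_info(path: str) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [SampleInfo(r.sample_id, r.sex, str(r.population)) for r in df.itertuples()]


def write_sample_info(path: str, cohort: Sequence[SampleInfo]) -> None:
    pd.DataFrame([(s.sample_id, s.sex, s.population) for s in cohort],
                 columns=["sample_id", "sex", "population"]).to_csv(path, sep="\t", index=False)


def align_samples(matrix: ExpressionMatrix, variants: Sequence[TevVariant],
                  genotype_samples: Sequence[str], cohort: Sequence[SampleInfo],
                  ) -> tuple[ExpressionMatrix, list[TevVariant], list[str], list[SampleInfo]]:
    """Restrict all three inputs to their common samples, in one canonical order.

    The canonical order is the genotype sample order restricted to the
    intersection.  Returns the realigned (matrix, variants, sample order,
    cohort); dropped samples are logged.
    """
    expr_set = set(matrix.sample_ids)
    info = {s.sample_id: s for s in cohort}
    common = [s for s in genotype_samples if s in expr_set and s in info]
    if not common:
        raise ValidationError("no samples shared between genotypes, expression and metadata")
    dropped = (set(genotype_samples) | expr_set | set(info)) - set(common)
    if dropped:
        logger.info("align_samples: dropped %d samples absent from some input", len(dropped))
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    expr = ExpressionMatrix(matrix.gene_ids, common,
                            matrix.values[:, [col[s] for s in common]])
    gidx = [genotype_samples.index(s) for s in common]
    new_variants = [
        TevVariant(v.variant_id, v.chrom, v.pos, v.te_class, v.strand,
                   v.deletion_coded, v.length, v.dosages[gidx])
        for v in variants
    ]
    return expr, new_variants, common, [info[s] for s in common]


# ---------------------------------------------------------------------------
# Annotation readers
# ---------------------------------------------------------------------------

def read_cytobands(path: str) -> list[CytoBand]:
    """Read a UCSC cytoBand 5-column TSV.

    Band names are composed as chromosome (without the ``chr`` prefix) plus
    the arm-level name, e.g. ``chr17 q21.31`` -> ``17q21.31``.
    """
    bands: list[CytoBand] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{ln}: expected 5 columns")
            chrom, start, end, name, stain = fields[:5]
            start, end = int(start), int(end)
            if end <= start:
                raise ValidationError(f"{path}:{ln}: end <= start")
            bands.append(CytoBand(chrom, start, end,
                                  chrom.removeprefix("chr") + name, stain))
    by_chrom: dict[str, list[CytoBand]] = {}
    for b in bands:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bl in by_chrom.items():
        bl.sort(key=lambda b: b.start)
        for a, b in zip(bl, bl[1:]):
            if b.start < a.end:
                raise ValidationError(f"{path}: overlapping bands on {chrom}")
    return sorted(bands, key=lambda b: (b.chrom, b.start))


def write_cytobands(path: str, bands: Sequence[CytoBand]) -> None:
    with open(path, "w") as fh:
        for b in sorted(bands, key=lambda b: (b.chrom, b.start)):
            arm = b.band_name.removeprefix(b.chrom.removeprefix("chr"))
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{arm}\t{b.stain}\n")


_GTF_SUBFEATURES = {"five_prime_utr", "exon", "three_prime_utr"}


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_annotation(path: str) -> list[GeneModel]:
    """Read gene models from GTF (1-based closed, shifted on read) or BED6.

    For GTF, ``gene`` rows define the span and exon/UTR rows the
    substructure; exon blocks overlapping a UTR block are trimmed and gaps
    inside the span become introns, so the stored substructure partitions
    the transcribed interval.
    """
    if path.endswith((".bed", ".bed6")):
        genes = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                f = line.rstrip("\n").split("\t")
                start, end = int(f[1]), int(f[2])
                if end <= start:
                    raise ValidationError(f"{path}:{ln}: end <= start")
                genes.append(GeneModel(f[3], f[0], start, end,
                                       f[5] if len(f) > 5 else "+",
                                       f[6] if len(f) > 6 else "other"))
        return genes

    spans: dict[str, GeneModel] = {}
    blocks: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = f
            start, end = int(start1) - 1, int(end1)   # 1-based closed -> half-open
            if end <= start:
                raise ValidationError(f"{path}:{ln}: end <= start after normalization")
            a = _parse_gtf_attributes(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{ln}: no gene_id attribute")
            if feature == "gene":
                spans[gid] = GeneModel(gid, chrom, start, end, strand,
                                       a.get("gene_biotype", "other"))
            elif feature in _GTF_SUBFEATURES:
                blocks.setdefault(gid, []).append((feature, start, end))

    genes = []
    for gid, g in spans.items():
        raw = sorted(blocks.get(gid, []), key=lambda b: b[1])
        utrs = [b for b in raw if b[0] != "exon"]
        sub: list[tuple[str, int, int]] = list(utrs)
        for feat, s, e in (b for b in raw if b[0] == "exon"):
            # trim exon pieces covered by a UTR block
            pieces = [(s, e)]
            for _, us, ue in utrs:
                pieces = [p for seg in pieces for p in _subtract(seg, (us, ue))]
            sub.extend(("exon", ps, pe) for ps, pe in pieces)
        sub.sort(key=lambda b: b[1])
        full = []
        cursor = g.start
        for feat, s, e in sub:
            if s > cursor:
                full.append(("intron", cursor, s))
            full.append((feat, s, e))
            cursor = e
        if cursor < g.end:
            full.append(("intron", cursor, g.end))
        genes.append(GeneModel(gid, g.chrom, g.start, g.end, g.strand, g.biotype,
                               full if raw else []))
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def _subtract(seg: tuple[int, int], cut: tuple[int, int]) -> list[tuple[int, int]]:
    s, e = seg
    cs, ce = cut
    if ce <= s or cs >= e:
        return [(s, e)]
    out = []
    if cs > s:
        out.append((s, cs))
    if ce < e:
        out.append((ce, e))
    return out


def write_gene_annotation(path: str, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GTF (gene rows plus exon/UTR substructure rows;
    introns are implicit)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(f"{g.chrom}\ttevkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for feat, s, e in g.substructure:
                if feat == "intron":
                    continue
                fh.write(f"{g.chrom}\ttevkit\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


def read_regulatory(path: str) -> list[tuple[str, int, int]]:
    """Read regulatory feature intervals from BED (pass-through) or GFF3
    (1-based closed, shifted)."""
    gff = path.endswith((".gff", ".gff3"))
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if gff:
                chrom, start, end = f[0], int(f[3]) - 1, int(f[4])
            else:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                raise ValidationError(f"{path}:{ln}: end <= start after normalization")
            out.append((chrom, start, end))
    return out


def write_bed(path: str, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
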