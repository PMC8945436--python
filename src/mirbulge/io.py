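"""Readers and writers for the external formats the pipeline touches.

Conventions enforced here so downstream modules never worry about them:

* coordinates are 0-based half-open everywhere; VCF's 1-based positions are
  converted at ingestion;
* mature miRNAs are RNA (``U``), genomic sequence is DNA (``T``); use
  :func:`rna_to_dna` / :func:`dna_to_rna` at module boundaries;
* when a gene has several 3'UTR isoforms only the longest is kept, at
  ingestion time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")


class FormatError(ValueError):
    """Malformed or contract-violating input file."""


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement_dna(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR with its genomic placement.

    ``sequence`` is the sense-strand (mRNA-direction) sequence; ``start``/``end``
    are 0-based half-open genomic coordinates on ``chrom``.
    """

    gene_id: str
    transcript_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise FormatError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != span "
                f"{self.end - self.start}"
            )
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(f"{self.gene_id}: non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class MafRow:
    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str  # gapped


@dataclass
class AlignmentBlock:
    """One MAF block: equal-width gapped rows keyed by species."""

    rows: dict[str, MafRow]
    ref_species: str

    def __post_init__(self) -> None:
        widths = {len(r.text) for r in self.rows.values()}
        if len(widths) != 1:
            raise FormatError(f"ragged alignment block: widths {sorted(widths)}")
        if self.ref_species not in self.rows:
            raise FormatError(f"reference species {self.ref_species!r} missing")
        ref = self.rows[self.ref_species]
        ungapped = len(ref.text) - ref.text.count("-")
        if ungapped != ref.size:
            raise FormatError(
                f"reference row ungapped length {ungapped} != declared size {ref.size}"
            )

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())).text)

    @property
    def ref(self) -> MafRow:
        return self.rows[self.ref_species]


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with its minor allele frequency.

    ``pos0`` is 0-based (converted from VCF's 1-based POS at ingestion).
    """

    chrom: str
    pos0: int
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise FormatError(f"{self.chrom}:{self.pos0}: ref == alt")
        if not (0.0 < self.maf <= 0.5):
            raise FormatError(f"{self.chrom}:{self.pos0}: maf {self.maf} outside (0, 0.5]")


def fold_to_maf(freq: float) -> float:
    """Fold an allele frequency onto the minor allele: f > 0.5 becomes 1 - f."""
    return 1.0 - freq if freq > 0.5 else freq


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercased sequence)`` in file order.

    U/T is preserved as read; duplicate ids and empty sequences are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# MAF (Multiple Alignment Format)
# ---------------------------------------------------------------------------


def _species_of(src: str) -> tuple[str, str]:
    """Split a MAF source field ``species.chrom`` into (species, chrom)."""
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, ""


def read_maf(path: str | Path, ref_species: str) -> list[AlignmentBlock]:
    """Read alignment blocks, validating width and the reference row.

    Raises :class:`FormatError` naming the (0-based) block index for a ragged
    block or a block missing the reference species.
    """
    blocks: list[AlignmentBlock] = []
    for i, aln in enumerate(AlignIO.parse(str(path), "maf")):
        rows: dict[str, MafRow] = {}
        for rec in aln:
            sp, chrom = _species_of(rec.id)
            ann = rec.annotations
            rows[sp] = MafRow(
                species=sp,
                chrom=chrom,
                start=int(ann["start"]),
                size=int(ann["size"]),
                strand="+" if ann["strand"] in (1, "+") else "-",
                src_size=int(ann["srcSize"]),
                text=str(rec.seq).upper(),
            )
        try:
            blocks.append(AlignmentBlock(rows=rows, ref_species=ref_species))
        except FormatError as exc:
            raise FormatError(f"block {i}: {exc}") from exc
    return blocks


def write_maf(path: str | Path, blocks: Sequence[AlignmentBlock]) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            for row in block.rows.values():
                src = f"{row.species}.{row.chrom}" if row.chrom else row.species
                fh.write(
                    f"s {src} {row.start} {row.size} {row.strand} "
                    f"{row.src_size} {row.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# VCF (biallelic SNV subset)
# ---------------------------------------------------------------------------


def read_vcf_snvs(
    path: str | Path, maf_field: str = "AF"
) -> tuple[list[VariantRecord], int]:
    """Read biallelic SNVs, folding the INFO frequency field to a MAF.

    Indels and multiallelic records are skipped (the skip count is returned and
    logged, not raised). Records whose folded frequency is 0 carry no
    polymorphism and are skipped too.
    """
    from cyvcf2 import VCF

    variants: list[VariantRecord] = []
    skipped = 0
    for rec in VCF(str(path)):
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        freq = rec.INFO.get(maf_field)
        if freq is None:
            skipped += 1
            continue
        if isinstance(freq, (tuple, list)):
            freq = freq[0]
        maf = fold_to_maf(float(freq))
        if maf <= 0.0:
            skipped += 1
            continue
        variants.append(
            VariantRecord(
                chrom=rec.CHROM, pos0=rec.POS - 1, ref=rec.REF, alt=alts[0], maf=maf
            )
        )
    if skipped:
        log.info("read_vcf_snvs: skipped %d non-SNV/unusable records", skipped)
    return variants, skipped


def write_vcf(
    path: str | Path,
    rows: Iterable[tuple[str, int, str, str, float]],
    maf_field: str = "AF",
    contigs: Sequence[str] = (),
) -> None:
    """Write minimal sites-only VCF from ``(chrom, pos0, ref, alt, af)`` rows."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            f'##INFO=<ID={maf_field},Number=1,Type=Float,'
            f'Description="Allele frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt, af in rows:
            fh.write(
                f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{maf_field}={af:.6g}\n"
            )


# ---------------------------------------------------------------------------
# BED-style regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    name: str
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"{self.name}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise FormatError(f"{self.name}: unknown strand {self.strand!r}")


def _parse_bed6(path: str | Path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected >=6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            regions.append(Region(chrom, int(start), int(end), name, strand))
    return regions


def read_regions(path: str | Path) -> list[Region]:
    """Read BED6 intervals, keeping only the longest interval per gene.

    The name field is ``gene_id`` or ``gene_id|transcript_id``; when a gene has
    multiple intervals (isoforms) only the longest is retained, matching the
    longest-3'UTR isoform rule applied at ingestion. Ties keep the first seen.
    """
    best: dict[str, Region] = {}
    order: list[str] = []
    for region in _parse_bed6(path):
        gene = region.name.split("|", 1)[0]
        if gene not in best:
            best[gene] = region
            order.append(gene)
        elif (region.end - region.start) > (best[gene].end - best[gene].start):
            best[gene] = region
    return [best[g] for g in order]


def region_to_utr(region: Region, sequence: str) -> UTRRecord:
    gene, _, tx = region.name.partition("|")
    return UTRRecord(
        gene_id=gene,
        transcript_id=tx or gene,
        sequence=sequence.upper(),
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        strand=region.strand,
    )


def write_bed6(path: str | Path, regions: Iterable[Region]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
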