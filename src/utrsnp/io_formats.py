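"""On-disk format I/O and coordinate conventions.

All internal coordinates are 0-based half-open.  SAM input is converted on
ingestion (SAM POS is 1-based); every user-facing surface (TSV reports, VCF,
amplicon tables) is 1-based and produced by the :mod:`utrsnp.reports` module.

The central containers are :class:`ContigSet` (assembled consensus
sequences), :class:`AlignedRead` (one read placed on one contig, with the
CIGAR expanded to explicit (read_offset, contig_offset, base) triples) and
:class:`BarcodeTable` (sample <-> MID/barcode mapping used by demultiplexing).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser

#: Placeholder base for alignment gaps (deletions relative to the contig).
GAP = "-"

_ALPHABET = set("ACGTN")

# M, =, X consume read+contig; I consumes read; D, N consume contig;
# S consumes read (soft-clipped bases are real read bases but unaligned);
# H, P consume neither.
_CIG_BOTH = {0, 7, 8}
_CIG_READ = {1}
_CIG_REF = {2, 3}
_CIG_SOFT = 4
_CIG_NONE = {5, 6}


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def _normalize_seq(raw: str, origin: str) -> str:
    """Uppercase, map U->T, collapse non-ACGTN letters (IUPAC codes) to N."""
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise FormatError(f"empty sequence for record {origin!r}")
    if set(seq) - _ALPHABET:
        seq = "".join(c if c in _ALPHABET else "N" for c in seq)
    return seq


class ContigSet:
    """Uppercase consensus sequences keyed by contig id.

    Thin mapping wrapper that enforces unique, non-empty ids and an
    A/C/G/T/N alphabet after normalization.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        self.entries: dict[str, str] = {}
        if entries:
            for cid, seq in entries.items():
                self.add(cid, seq)

    def add(self, contig_id: str, seq: str) -> None:
        if not contig_id:
            raise FormatError("contig id must be non-empty")
        if contig_id in self.entries:
            raise FormatError(f"duplicate contig id {contig_id!r}")
        self.entries[contig_id] = _normalize_seq(seq, contig_id)

    def __getitem__(self, contig_id: str) -> str:
        return self.entries[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.entries.items()}


@dataclass(frozen=True)
class AlignedRead:
    """One read aligned to one contig.

    ``aligned_pairs`` holds (read_offset, contig_offset, base) triples in
    alignment order: insertions have ``contig_offset=None``, deletions have
    ``read_offset=None`` and ``base=GAP``.  Soft-clipped bases do not appear
    as pairs but do count toward ``read_length`` (they are real read bases,
    which matters for distance-from-read-end computations).
    """

    read_id: str
    sample: str
    contig_id: str
    ref_start: int
    aligned_pairs: tuple[tuple[int | None, int | None, str], ...]
    read_length: int

    def contig_offsets(self) -> list[int]:
        return [c for _, c, _ in self.aligned_pairs if c is not None]


@dataclass(frozen=True)
class BarcodeTable:
    """Ordered sample -> barcode rows; order defines demux match priority."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        samples = [s for s, _ in self.rows]
        barcodes = [b for _, b in self.rows]
        if len(set(samples)) != len(samples):
            raise FormatError("duplicate sample names in barcode table")
        if len(set(barcodes)) != len(barcodes):
            raise FormatError("duplicate barcodes in table (demultiplexing would be ambiguous)")
        for s, b in self.rows:
            if not s or not b:
                raise FormatError("empty sample name or barcode")
            if set(b) - set("ACGT"):
                raise FormatError(f"barcode {b!r} contains non-ACGT characters")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.rows)


def read_fasta(path: str | Path) -> ContigSet:
    """Load a FASTA file into a :class:`ContigSet`.

    Record ids are the first whitespace-delimited token of the header;
    sequences are uppercased and U is mapped to T.  Duplicate ids and empty
    records are hard errors.
    """
    contigs = ContigSet()
    with open(path) as fh:
        n = 0
        for header, seq in SimpleFastaParser(fh):
            n += 1
            if not header.strip():
                raise FormatError(f"record {n} in {path} has an empty header")
            contigs.add(header.split()[0], seq)
        if n == 0:
            raise FormatError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: ContigSet | Mapping[str, str], path: str | Path, width: int = 70) -> None:
    entries = contigs.entries if isinstance(contigs, ContigSet) else contigs
    with open(path, "w") as fh:
        for cid, seq in entries.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fasta_records(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (full_header, sequence) pairs without id normalization.

    Used by demultiplexing, which must preserve the original header verbatim.
    """
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            yield header, seq.upper()


def read_barcode_csv(path: str | Path) -> BarcodeTable:
    """Parse the two-column (sample,barcode) CSV, no header row."""
    rows: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise FormatError(f"{path} line {i}: expected 2 comma-separated columns, got {len(row)}")
            sample, barcode = row[0].strip(), row[1].strip().upper()
            rows.append((sample, barcode))
    if not rows:
        raise FormatError(f"no barcode rows in {path}")
    return BarcodeTable(tuple(rows))


def _sample_from_read(name: str, rg: str | None, samples: frozenset[str]) -> str:
    token = name.rsplit("_", 1)[-1]
    if token in samples:
        return token
    if rg:
        return rg
    return ""


def read_alignments(
    sam_path: str | Path,
    contigs: ContigSet,
    samples: Iterable[str] | None = None,
) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM file as :class:`AlignedRead`.

    Unmapped, secondary and supplementary records are skipped.  The sample
    label is taken from the final ``_``-delimited token of the read name when
    it matches a known sample (the convention written by demultiplexing),
    falling back to the read-group tag, else empty.

    Raises :class:`FormatError` when a record references a contig absent from
    ``contigs``, when header lengths disagree with the contig sequences, or
    when the CIGAR is inconsistent with the read sequence.
    """
    known = frozenset(samples) if samples is not None else frozenset()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for name, length in zip(sam.references, sam.lengths):
            if name not in contigs:
                raise FormatError(f"SAM header sequence {name!r} not in contig set")
            if length != len(contigs[name]):
                raise FormatError(
                    f"SAM header length {length} for {name!r} != contig length {len(contigs[name])}"
                )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in contigs:
                raise FormatError(f"read {rec.query_name!r} maps to unknown contig {rec.reference_name!r}")
            seq = rec.query_sequence
            if seq is None:
                raise FormatError(f"read {rec.query_name!r} has no sequence")
            cig = rec.cigartuples
            if not cig:
                raise FormatError(f"mapped read {rec.query_name!r} has no CIGAR")
            pairs: list[tuple[int | None, int | None, str]] = []
            qpos, rpos = 0, rec.reference_start
            for op, ln in cig:
                if op in _CIG_BOTH:
                    for _ in range(ln):
                        pairs.append((qpos, rpos, seq[qpos]))
                        qpos += 1
                        rpos += 1
                elif op in _CIG_READ:
                    for _ in range(ln):
                        pairs.append((qpos, None, seq[qpos]))
                        qpos += 1
                elif op in _CIG_REF:
                    for _ in range(ln):
                        pairs.append((None, rpos, GAP))
                        rpos += 1
                elif op == _CIG_SOFT:
                    qpos += ln
                elif op in _CIG_NONE:
                    pass
                else:
                    raise FormatError(f"read {rec.query_name!r}: unsupported CIGAR op {op}")
            if qpos != len(seq):
                raise FormatError(
                    f"read {rec.query_name!r}: CIGAR consumes {qpos} read bases but sequence has {len(seq)}"
                )
            if rpos > len(contigs[rec.reference_name]):
                raise FormatError(f"read {rec.query_name!r} extends past the end of {rec.reference_name!r}")
            rg = None
            if rec.has_tag("RG"):
                rg = str(rec.get_tag("RG"))
            yield AlignedRead(
                read_id=rec.query_name,
                sample=_sample_from_read(rec.query_name, rg, known),
                contig_id=rec.reference_name,
                ref_start=rec.reference_start,
                aligned_pairs=tuple(pairs),
                read_length=len(seq),
            )
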