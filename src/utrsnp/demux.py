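"""Demultiplex barcoded (MID-tagged) FASTA reads.

Each read is tested against every barcode at a fixed offset from the read
start; on an exact match the prefix up to and including the barcode is
removed and ``_<sample>`` is appended to the read header.  Matching is exact
string comparison in table order (first match wins); barcode uniqueness is
enforced when the table is built, so ties cannot occur.

Reads too short to contain offset+barcode, or matching no barcode, are
unmatched and are kept in an unassigned stream or dropped depending on the
configuration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io_formats import BarcodeTable, iter_fasta_records

KEEP_UNASSIGNED = "keep-unassigned"
DROP = "drop"


@dataclass(frozen=True)
class DemuxConfig:
    #: bases from the read start to the first base of the barcode
    offset: int = 0
    on_unmatched: str = KEEP_UNASSIGNED

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.on_unmatched not in (KEEP_UNASSIGNED, DROP):
            raise ValueError(f"unknown on_unmatched policy {self.on_unmatched!r}")


@dataclass
class DemuxSummary:
    per_sample_counts: Counter = field(default_factory=Counter)
    unmatched_count: int = 0
    total: int = 0


def demultiplex(
    reads: Iterable[tuple[str, str]],
    barcodes: BarcodeTable,
    cfg: DemuxConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], DemuxSummary]:
    """Assign reads to samples by in-line barcode.

    ``reads`` is an iterable of (header, sequence).  Returns
    (labeled, unassigned, summary) where labeled entries have the barcode
    prefix stripped and the sample name appended to the header after ``_``.
    ``unassigned`` is empty when the policy is ``drop``.
    """
    labeled: list[tuple[str, str]] = []
    unassigned: list[tuple[str, str]] = []
    summary = DemuxSummary()
    for header, seq in reads:
        summary.total += 1
        hit = None
        for sample, barcode in barcodes.rows:
            end = cfg.offset + len(barcode)
            if len(seq) >= end and seq[cfg.offset : end] == barcode:
                hit = (sample, end)
                break
        if hit is None:
            summary.unmatched_count += 1
            if cfg.on_unmatched == KEEP_UNASSIGNED:
                unassigned.append((header, seq))
        else:
            sample, end = hit
            summary.per_sample_counts[sample] += 1
            labeled.append((f"{header}_{sample}", seq[end:]))
    return labeled, unassigned, summary


def demultiplex_fasta(
    reads_path: str | Path,
    barcodes: BarcodeTable,
    cfg: DemuxConfig,
    out_dir: str | Path,
) -> DemuxSummary:
    """File-level wrapper: writes ``labeled.fasta``, ``unassigned.fasta``
    (when kept) and ``demux_summary.tsv`` into *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labeled, unassigned, summary = demultiplex(iter_fasta_records(reads_path), barcodes, cfg)
    with open(out_dir / "labeled.fasta", "w") as fh:
        for header, seq in labeled:
            fh.write(f">{header}\n{seq}\n")
    if cfg.on_unmatched == KEEP_UNASSIGNED:
        with open(out_dir / "unassigned.fasta", "w") as fh:
            for header, seq in unassigned:
                fh.write(f">{header}\n{seq}\n")
    with open(out_dir / "demux_summary.tsv", "w") as fh:
        fh.write("sample\treads\n")
        for sample in barcodes.samples:
            fh.write(f"{sample}\t{summary.per_sample_counts.get(sample, 0)}\n")
        fh.write(f"unmatched\t{summary.unmatched_count}\n")
        fh.write(f"total\t{summary.total}\n")
    return summary
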