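"""Readers and writers for the sequence formats the corrector touches.

FASTA and FASTQ go through Biopython, SAM through pysam; this module only
adds the thin conversions into the package's own containers (:class:`Read`,
:class:`GeneReference`, and — for SAM — ``extract.MappedRead``) plus the
tool's truth-log and report TSVs.

Coordinates are 0-based half-open everywhere inside the package; SAM's
1-based POS is converted at this boundary.
"""
from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
GAP = "-"
DEFAULT_QUAL_FILL = "I"

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N,-} (N and the gap map to themselves)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A malformed FASTQ/SAM record; the message names the offending record."""


@dataclass(frozen=True)
class Read:
    """An immutable nucleotide read.

    ``mate`` is one of ``{"first", "second", "unpaired"}``; paired reads
    carry the conventional ``/1`` / ``/2`` id suffix when written to FASTQ.
    """

    read_id: str
    seq: str
    qual: Optional[str] = None
    mate: str = "unpaired"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if not set(self.seq) <= ALPHABET:
            bad = sorted(set(self.seq) - ALPHABET)
            raise ValueError(f"read {self.read_id!r}: invalid characters {bad}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if self.mate not in ("first", "second", "unpaired"):
            raise ValueError(f"read {self.read_id!r}: bad mate {self.mate!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneReference:
    """A target-gene reference sequence I_g.

    ``source_interval`` records where the gene sits on its source contig as
    ``(contig, start, end)`` 0-based half-open, when known; it is what lets
    the extract module cut genomic flanks.
    """

    gene_id: str
    seq: str
    source_interval: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: Union[str, Path], mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _mate_from_id(read_id: str) -> str:
    if read_id.endswith("/1"):
        return "first"
    if read_id.endswith("/2"):
        return "second"
    return "unpaired"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[GeneReference]:
    with _open_text(path) as fh:
        return [GeneReference(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[Union[GeneReference, tuple[str, str]]],
                path: Union[str, Path]) -> None:
    recs = []
    for rec in records:
        if isinstance(rec, GeneReference):
            rid, seq = rec.gene_id, rec.seq
        else:
            rid, seq = rec
        recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: Union[str, Path]) -> Iterator[Read]:
    """Parse a 4-line FASTQ file (optionally gzipped).

    Malformed records (truncated record, seq/qual length mismatch) raise
    :class:`ParseError` naming the 0-based record index.
    """
    index = 0
    with _open_text(path) as fh:
        it = SeqIO.parse(fh, "fastq")
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"FASTQ record {index} in {path}: {exc}") from exc
            phred = rec.letter_annotations["phred_quality"]
            qual = "".join(chr(q + 33) for q in phred)
            yield Read(rec.id, str(rec.seq).upper(), qual, _mate_from_id(rec.id))
            index += 1


def write_fastq(reads: Iterable[Read], path: Union[str, Path],
                qual_fill: str = DEFAULT_QUAL_FILL) -> None:
    """Write reads as 4-line FASTQ; absent qualities get a constant fill."""
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = read.qual if read.qual is not None else qual_fill * len(read.seq)
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")


def write_fastq_paired(pairs: Iterable[tuple[Read, Read]],
                       path1: Union[str, Path], path2: Union[str, Path],
                       qual_fill: str = DEFAULT_QUAL_FILL) -> None:
    """Write mate pairs to two synchronized files with /1 and /2 id suffixes."""
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for r1, r2 in pairs:
            for read, fh, suffix in ((r1, f1, "/1"), (r2, f2, "/2")):
                rid = read.read_id if read.read_id.endswith(suffix) else read.read_id + suffix
                qual = read.qual if read.qual is not None else qual_fill * len(read.seq)
                fh.write(f"@{rid}\n{read.seq}\n+\n{qual}\n")


def read_fastq_paired(path1: Union[str, Path],
                      path2: Union[str, Path]) -> Iterator[tuple[Read, Read]]:
    for r1, r2 in zip(read_fastq(path1), read_fastq(path2)):
        yield r1, r2


# ---------------------------------------------------------------------------
# SAM import
# ---------------------------------------------------------------------------

def read_sam(path: Union[str, Path], ext_ref) -> list:
    """Convert SAM alignments against the extended gene reference to MappedReads.

    CIGAR insertions are stripped from the read (those bases never enter the
    alignment array) and deletions are filled with the gap symbol ``-`` so
    every remaining cell lines up with one reference column.  Unmapped,
    secondary and supplementary records are skipped.  Reverse-strand records
    are used exactly as stored (SAM stores them reference-oriented).
    """
    import numpy as np
    import pysam

    from .extract import MappedRead

    ext_seq = ext_ref.ext_seq
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        it = enumerate(sam)
        while True:
            try:
                i, rec = next(it)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                raise ParseError(f"malformed SAM record in {path}: {exc}") from exc
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            query = (rec.query_sequence or "").upper()
            cells_parts: list[str] = []
            read_pos_parts: list[np.ndarray] = []
            qpos = 0
            for op, length in rec.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    cells_parts.append(query[qpos:qpos + length])
                    read_pos_parts.append(np.arange(qpos, qpos + length, dtype=np.int32))
                    qpos += length
                elif op == 1:  # I: inserted bases are dropped
                    qpos += length
                elif op == 2:  # D: recovered as gap cells
                    cells_parts.append(GAP * length)
                    read_pos_parts.append(np.full(length, -1, dtype=np.int32))
                elif op == 4:  # S
                    qpos += length
                elif op in (3, 5, 6):  # N, H, P consume no query
                    pass
                else:
                    raise ParseError(f"SAM record {i} ({rec.query_name}): CIGAR op {op}")
            if qpos != len(query):
                raise ParseError(
                    f"SAM record {i} ({rec.query_name}): CIGAR consumes {qpos} "
                    f"query bases but sequence has {len(query)}"
                )
            cells = "".join(cells_parts)
            offset = rec.reference_start  # pysam is already 0-based
            if offset < 0 or offset + len(cells) > len(ext_seq):
                raise ParseError(
                    f"SAM record {i} ({rec.query_name}): alignment exceeds the "
                    f"extended reference ({offset}+{len(cells)} > {len(ext_seq)})"
                )
            matches = sum(1 for c, r in zip(cells, ext_seq[offset:offset + len(cells)])
                          if c == r and c != GAP)
            mate = "unpaired"
            rid = rec.query_name
            if rec.is_paired:
                mate = "first" if rec.is_read1 else "second"
                rid = f"{rid}/{1 if rec.is_read1 else 2}"
            qual = None
            if rec.query_qualities is not None:
                qual = "".join(chr(q + 33) for q in rec.query_qualities)
            read = Read(rid, query, qual, mate)
            out.append(MappedRead(
                read=read,
                offset=offset,
                cells=cells,
                mismatches=len(cells) - matches,
                identity_pct=100.0 * matches / len(cells) if cells else 0.0,
                strand="+",
                read_pos=np.concatenate(read_pos_parts) if read_pos_parts
                else np.empty(0, dtype=np.int32),
            ))
    return out


# ---------------------------------------------------------------------------
# Truth log and report TSVs
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ("read_id", "pos_in_read", "true_base", "observed_base")


def write_truth_log(entries: Iterable[tuple[str, int, str, str]],
                    path: Union[str, Path]) -> None:
    """Write injected-error records: read_id, 0-based pos, true base, observed."""
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for row in entries:
            w.writerow(row)


def read_truth_log(path: Union[str, Path]) -> dict[str, dict[int, tuple[str, str]]]:
    """Load a truth log as {read_id: {pos: (true_base, observed_base)}}."""
    truth: dict[str, dict[int, tuple[str, str]]] = {}
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            truth.setdefault(row["read_id"], {})[int(row["pos_in_read"])] = (
                row["true_base"], row["observed_base"])
    return truth


def write_report(rows: Sequence[dict], path: Union[str, Path]) -> None:
    """Write the per-gene evaluation report as TSV (columns from the rows)."""
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    with _open_text(path, "wt") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()),
                           delimiter="\t", lineterminator="\n")
        w.writeheader()
        w.writerows(rows)
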