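"""Extraction of the gene-relevant read subset ``subset(S, I_g)``.

The target gene reference is extended with up to 50 bp of genomic flank on
each side so reads straddling the gene boundary are still captured, and
every read (both orientations) is placed on the extended reference by an
ungapped seed-and-verify mapper: exact k-mer seeds locate candidate
diagonals, each candidate is verified by a full Hamming count, and the read
is kept when its best placement reaches the identity threshold (default
95%, i.e. at most 5 mismatches in a 100 bp read — the tolerance that lets
reads carrying SNP alleles and sequencing errors join the subset).

Seeds use k=16 probed at every read position.  With at most
``floor(0.05*n)`` mismatches in a read of length n >= 96, the longest clean
stretch is at least 16 bases, so an exact seed always exists and extraction
of qualifying reads is deterministic — a guarantee sampled 31-mer seeds
cannot give.  Indels never enter through this mapper; they arrive only via
SAM import (``io.read_sam``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import GAP, GeneReference, Read, revcomp

DEFAULT_FLANK = 50
DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_K = 16

# base encoding shared with the correct module: A C G T N gap
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN-"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN-", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence over {A,C,G,T,N,-} as uint8 codes 0..5."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) == 255:
        raise ValueError("sequence contains characters outside {A,C,G,T,N,-}")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class ExtendedReference:
    """The flank-extended gene reference the subset is built against."""

    gene_id: str
    core_seq: str
    left_flank: int
    right_flank: int
    ext_seq: str

    def __post_init__(self) -> None:
        if len(self.ext_seq) != self.left_flank + len(self.core_seq) + self.right_flank:
            raise ValueError("extended sequence length inconsistent with flanks")

    @property
    def core_start(self) -> int:
        return self.left_flank

    @property
    def core_end(self) -> int:
        return self.left_flank + len(self.core_seq)

    def __len__(self) -> int:
        return len(self.ext_seq)


@dataclass
class MappedRead:
    """A read placed (ungapped, or gap-filled from SAM) on the extended reference.

    ``cells`` is the reference-oriented base string occupying columns
    ``offset .. offset+len(cells)``; ``read_pos[i]`` maps cell i back to a
    position in the original read string (-1 for gap cells), which is how
    corrections are written back in the read's own orientation.
    """

    read: Read
    offset: int
    cells: str
    mismatches: int
    identity_pct: float
    strand: str = "+"
    read_pos: Optional[np.ndarray] = None
    out_flag: bool = False

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("negative mapping offset")
        if self.read_pos is None:
            n = len(self.cells)
            if self.strand == "+":
                self.read_pos = np.arange(n, dtype=np.int32)
            else:
                self.read_pos = np.arange(n - 1, -1, -1, dtype=np.int32)

    @property
    def end(self) -> int:
        return self.offset + len(self.cells)


def extend_reference(gene_ref: GeneReference, flank: int = DEFAULT_FLANK,
                     genome: Optional[str] = None) -> ExtendedReference:
    """Extend I_g with genomic flanks (default 50 bp each side).

    Flanks are cut from ``genome`` at the gene's ``source_interval`` and are
    truncated where the contig ends; with no genome available the flanks are
    empty and the extended sequence equals the gene itself.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    left = right = ""
    if flank > 0 and genome is not None and gene_ref.source_interval is not None:
        _, start, end = gene_ref.source_interval
        left = genome[max(0, start - flank):start]
        right = genome[end:end + flank]
    return ExtendedReference(
        gene_id=gene_ref.gene_id,
        core_seq=gene_ref.seq,
        left_flank=len(left),
        right_flank=len(right),
        ext_seq=left + gene_ref.seq + right,
    )


class KmerIndex:
    """Sorted exact k-mer index of an extended reference sequence."""

    def __init__(self, ext_seq: str, k: int = DEFAULT_K):
        if k < 1 or k > 31:
            raise ValueError("k must be in 1..31")
        self.k = k
        self.codes = encode(ext_seq)
        self.n_cols = len(ext_seq)
        if self.n_cols < k:
            self._sorted = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            return
        kcodes, valid = _kmer_codes(self.codes[None, :], k)
        kcodes, valid = kcodes[0], valid[0]
        pos = np.nonzero(valid)[0]
        kcodes = kcodes[pos]
        order = np.argsort(kcodes, kind="stable")
        self._sorted = kcodes[order]
        self._pos = pos[order]

    def lookup_ranges(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (left, right) occurrence ranges in the sorted position list."""
        left = np.searchsorted(self._sorted, query_codes, side="left")
        right = np.searchsorted(self._sorted, query_codes, side="right")
        return left, right

    def positions(self) -> np.ndarray:
        return self._pos


def _kmer_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes per row of a (n, L) uint8 code matrix.

    Returns (codes, valid) of shape (n, L-k+1); windows containing N (or any
    code >= 4) are flagged invalid and never used as seeds.
    """
    win = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)
    weights = (4 ** np.arange(k, dtype=np.int64))
    codes = win.astype(np.int64) @ weights
    valid = (win < 4).all(axis=2)
    return codes, valid


def _expand_ranges(lefts: np.ndarray, rights: np.ndarray) -> np.ndarray:
    """Concatenate arange(l, r) for each pair, vectorized."""
    counts = rights - lefts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    out[0] = lefts[0]
    cum = np.cumsum(counts)[:-1]
    out[cum] = lefts[1:] - rights[:-1] + 1
    return np.cumsum(out)


class ReadBatch:
    """Reads pre-encoded for mapping, reusable across genes.

    Reads are grouped by length; each group stores forward and
    reverse-complement code matrices.  K-mer seed codes are computed lazily
    per (k, group) and cached.
    """

    def __init__(self, reads: Sequence[Read]):
        self.reads = list(reads)
        by_len: dict[int, list[int]] = {}
        for i, r in enumerate(self.reads):
            by_len.setdefault(len(r.seq), []).append(i)
        self.groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for length, idxs in sorted(by_len.items()):
            idx = np.asarray(idxs, dtype=np.int64)
            buf = "".join(self.reads[i].seq for i in idxs)
            mat = _CODE[np.frombuffer(buf.encode("ascii"), dtype=np.uint8)]
            mat = mat.reshape(len(idxs), length)
            rc = np.where(mat < 4, 3 - mat, mat)[:, ::-1]
            self.groups.append((idx, np.ascontiguousarray(mat), np.ascontiguousarray(rc)))
        self._kmer_cache: dict = {}

    def kmers(self, group_no: int, strand: int, k: int):
        key = (group_no, strand, k)
        if key not in self._kmer_cache:
            mat = self.groups[group_no][1 + strand]
            if mat.shape[1] < k:
                codes = np.empty((mat.shape[0], 0), dtype=np.int64)
                valid = np.empty((mat.shape[0], 0), dtype=bool)
            else:
                codes, valid = _kmer_codes(mat, k)
            self._kmer_cache[key] = (codes, valid)
        return self._kmer_cache[key]


def _best_placements(batch: ReadBatch, index: KmerIndex,
                     min_identity_pct: float,
                     chunk: int = 4096) -> dict[int, tuple[int, int, int]]:
    """Best qualifying placement per read index: {read_idx: (offset, strand, mismatches)}.

    Ties are broken by fewest mismatches, then smallest offset, then forward
    strand — in that order.
    """
    n_cols = index.n_cols
    ext_codes = index.codes
    best: dict[int, tuple[int, int, int]] = {}  # read_idx -> (mism, offset, strand)
    for gno, (idx, fwd, rc) in enumerate(batch.groups):
        length = fwd.shape[1]
        if length > n_cols:
            continue
        max_mism = int(np.floor(length * (100.0 - min_identity_pct) / 100.0 + 1e-9))
        ref_windows = np.lib.stride_tricks.sliding_window_view(ext_codes, length)
        for start in range(0, fwd.shape[0], chunk):
            stop = min(start + chunk, fwd.shape[0])
            cand_rows: list[np.ndarray] = []
            cand_offs: list[np.ndarray] = []
            cand_strand: list[np.ndarray] = []
            for strand, mat in ((0, fwd), (1, rc)):
                codes, valid = batch.kmers(gno, strand, index.k)
                codes, valid = codes[start:stop], valid[start:stop]
                if codes.size == 0:
                    continue
                left, right = index.lookup_ranges(codes)
                hit = valid & (right > left)
                rows, qpos = np.nonzero(hit)
                if rows.size == 0:
                    continue
                expanded = _expand_ranges(left[rows, qpos], right[rows, qpos])
                counts = (right - left)[rows, qpos]
                rep_rows = np.repeat(rows, counts)
                rep_qpos = np.repeat(qpos, counts)
                offs = index.positions()[expanded] - rep_qpos
                ok = (offs >= 0) & (offs + length <= n_cols)
                rep_rows, offs = rep_rows[ok], offs[ok]
                if rep_rows.size == 0:
                    continue
                key = rep_rows * np.int64(n_cols + 1) + offs
                key = np.unique(key)
                cand_rows.append(key // (n_cols + 1))
                cand_offs.append(key % (n_cols + 1))
                cand_strand.append(np.full(key.size, strand, dtype=np.int64))
            if not cand_rows:
                continue
            rows = np.concatenate(cand_rows)
            offs = np.concatenate(cand_offs)
            strands = np.concatenate(cand_strand)
            mats = (fwd[start:stop], rc[start:stop])
            mism = np.empty(rows.size, dtype=np.int64)
            for s in (0, 1):
                sel = strands == s
                if not sel.any():
                    continue
                q = mats[s][rows[sel]]
                r = ref_windows[offs[sel]]
                mism[sel] = (q != r).sum(axis=1)
            ok = mism <= max_mism
            rows, offs, strands, mism = rows[ok], offs[ok], strands[ok], mism[ok]
            if rows.size == 0:
                continue
            order = np.lexsort((strands, offs, mism, rows))
            rows, offs, strands, mism = (a[order] for a in (rows, offs, strands, mism))
            first = np.ones(rows.size, dtype=bool)
            first[1:] = rows[1:] != rows[:-1]
            for r_, o_, s_, m_ in zip(rows[first], offs[first], strands[first], mism[first]):
                ridx = int(idx[start + r_])
                cur = best.get(ridx)
                cand = (int(m_), int(o_), int(s_))
                if cur is None or cand < cur:
                    best[ridx] = cand
    return {ridx: (o, s, m) for ridx, (m, o, s) in best.items()}


def _make_mapped(read: Read, offset: int, strand: int, mismatches: int) -> MappedRead:
    cells = read.seq if strand == 0 else revcomp(read.seq)
    n = len(cells)
    return MappedRead(
        read=read,
        offset=offset,
        cells=cells,
        mismatches=mismatches,
        identity_pct=100.0 * (n - mismatches) / n,
        strand="+" if strand == 0 else "-",
    )


def map_read(read: Read, ext_ref: ExtendedReference,
             min_identity_pct: float = DEFAULT_MIN_IDENTITY,
             k: int = DEFAULT_K,
             index: Optional[KmerIndex] = None) -> Optional[MappedRead]:
    """Best ungapped placement of the read (either orientation), or None.

    The placement must reach ``min_identity_pct`` percent identity; ties are
    broken by fewest mismatches, then smallest offset, then forward strand.
    """
    if index is None:
        index = KmerIndex(ext_ref.ext_seq, k)
    batch = ReadBatch([read])
    best = _best_placements(batch, index, min_identity_pct)
    if 0 not in best:
        return None
    offset, strand, mism = best[0]
    return _make_mapped(read, offset, strand, mism)


def extract_subset(reads: Iterable[Read], ext_ref: ExtendedReference,
                   min_identity_pct: float = DEFAULT_MIN_IDENTITY,
                   k: int = DEFAULT_K,
                   batch: Optional[ReadBatch] = None,
                   index: Optional[KmerIndex] = None) -> list[MappedRead]:
    """Collect every read with a qualifying placement, sorted by offset.

    The result is the input order of the alignment array: ascending offset,
    ties broken by read id.  A pre-built :class:`ReadBatch` can be shared
    across genes to amortize read encoding.
    """
    if batch is None:
        batch = ReadBatch(list(reads))
    if index is None:
        index = KmerIndex(ext_ref.ext_seq, k)
    best = _best_placements(batch, index, min_identity_pct)
    mapped = [_make_mapped(batch.reads[i], o, s, m) for i, (o, s, m) in best.items()]
    mapped.sort(key=lambda mr: (mr.offset, mr.read.read_id))
    return mapped


# ---------------------------------------------------------------------------
# Subset TSV (the extract CLI's output / the correct CLI's input)
# ---------------------------------------------------------------------------

def write_subset_tsv(subset: Sequence[MappedRead], path) -> None:
    import csv
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "offset", "cells", "identity_pct", "strand", "seq", "qual"])
        for mr in subset:
            w.writerow([mr.read.read_id, mr.offset, mr.cells,
                        f"{mr.identity_pct:.4f}", mr.strand,
                        mr.read.seq, mr.read.qual or ""])


def read_subset_tsv(path) -> list[MappedRead]:
    import csv
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            read = Read(row["read_id"], row["seq"], row["qual"] or None,
                        mate="unpaired")
            cells = row["cells"]
            identity = float(row["identity_pct"])
            mism = int(round(len(cells) * (100.0 - identity) / 100.0))
            out.append(MappedRead(
                read=read, offset=int(row["offset"]), cells=cells,
                mismatches=mism, identity_pct=identity,
                strand=row["strand"]))
    out.sort(key=lambda mr: (mr.offset, mr.read.read_id))
    return out
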