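"""Column-dominance error correction over the alignment array.

The extracted subset, sorted by start offset, forms the *alignment array*:
rows are reads, columns are positions of the flank-extended gene reference.
Each column is classified by how many nucleotide types account for
essentially all of its bases:

* one/two/three-type dominance — the smallest number m of (non-N) types
  such that all remaining bases total at most ``minor_count`` (default 3),
  or at most ``minor_frac`` (default 2%) of the column when its depth is at
  least ``min_depth_for_frac`` (default 100);
* four-type dominance — no such m exists; the column is left alone.

Bases of a minor type in a dominance-1/2/3 column are correction
candidates.  Each gets a score ``f + p``: its type frequency in the column
plus a priority 0.1/0.2/0.3 by the column's dominance, so outliers at
simpler columns are corrected first.  Rows are then corrected
conservatively: per row, only the ``ceil(row_error_frac * n)``
lowest-scoring candidates (2 for a 100 bp read) are changed in one pass —
to the dominant base at a one-type column, or to a dominant type chosen by
neighbor-column phasing and largest-remainder proportional assignment at a
two/three-type column.  A row whose candidate set contains more than one
base scoring above ``out_threshold`` looks like consistent disagreement
(a repeat elsewhere in the genome, not sequencing noise): it is labeled
``out`` and removed from the subset.

``correct_rows`` is exactly one such pass.  ``correct_array`` repeats
passes until no cell changes (default cap 8 passes): reads carrying more
errors than one pass's per-row budget are finished by later passes once the
column profiles have been updated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .extract import ExtendedReference, MappedRead, _DECODE, decode, encode
from .io import Read

BASES = "ACGT"
BASES_N = "ACGTN"
PRIORITY = {1: 0.1, 2: 0.2, 3: 0.3}

_COMP_CODE = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)


@dataclass(frozen=True)
class CorrectorParams:
    """Tunable thresholds of the corrector (defaults per the method)."""

    minor_count: int = 3
    minor_frac: float = 0.02
    min_depth_for_frac: int = 100
    row_error_frac: float = 0.02
    out_threshold: float = 0.2
    phasing_window: int = 50
    max_passes: int = 8
    seed: int = 42


@dataclass(frozen=True)
class CorrectionRecord:
    """Audit record of one base change, in the read's own orientation."""

    read_id: str
    pos_in_read: int
    old_base: str
    new_base: str
    col: int
    dominance_at_col: int


@dataclass(frozen=True)
class ColumnProfile:
    col: int
    counts: dict
    depth: int
    freqs: dict
    dominance: int
    dominant_types: tuple
    minor_types: tuple


@dataclass(frozen=True)
class BaseAnnotation:
    row: int
    col: int
    base: str
    f: float
    p: float
    score: float


@dataclass
class AlignmentArray:
    """Reads sorted by start offset over the extended reference columns."""

    ext_ref: ExtendedReference
    rows: list
    n_cols: int

    @classmethod
    def build(cls, subset: Sequence[MappedRead], ext_ref: ExtendedReference):
        rows = sorted(subset, key=lambda mr: mr.offset)  # stable
        n_cols = len(ext_ref.ext_seq)
        for mr in rows:
            if mr.offset + len(mr.cells) > n_cols:
                raise ValueError(
                    f"read {mr.read.read_id!r} overruns the alignment array "
                    f"({mr.offset}+{len(mr.cells)} > {n_cols})")
        return cls(ext_ref=ext_ref, rows=rows, n_cols=n_cols)


def build_alignment_array(subset: Sequence[MappedRead],
                          ext_ref: ExtendedReference) -> AlignmentArray:
    return AlignmentArray.build(subset, ext_ref)


# ---------------------------------------------------------------------------
# Dominance classification
# ---------------------------------------------------------------------------

def classify_dominance(counts: Union[Mapping[str, int], Sequence[int]],
                       depth: int,
                       minor_count: int = 3,
                       minor_frac: float = 0.02,
                       min_depth_for_frac: int = 100):
    """Classify one column; returns (dominance, dominant_types, minor_types).

    The dominance is the smallest m in {1,2,3} such that, taking the m most
    frequent non-N types as dominant (frequency ties broken A<C<G<T), the
    remaining bases (including N) number at most ``minor_count``, or at most
    a ``minor_frac`` fraction when the depth is ``min_depth_for_frac`` or
    more.  N is never dominant.  If no m qualifies the column is four-type
    dominant and receives no correction.
    """
    if depth <= 0:
        raise ValueError("undefined column: depth must be >= 1")
    if isinstance(counts, Mapping):
        cnt = {b: int(counts.get(b, 0)) for b in BASES_N}
    else:
        vals = list(counts) + [0] * (5 - len(list(counts)))
        cnt = dict(zip(BASES_N, (int(v) for v in vals)))
    if sum(cnt.values()) != depth:
        raise ValueError("counts do not sum to depth")
    ranked = sorted(BASES, key=lambda b: (-cnt[b], b))
    if cnt[ranked[0]] == 0:  # only N in the column: nothing to anchor on
        return 4, (), tuple(b for b in BASES_N if cnt[b] > 0)
    cum = 0
    for m in (1, 2, 3):
        cum += cnt[ranked[m - 1]]
        other = depth - cum
        if other <= minor_count or (
                depth >= min_depth_for_frac and other / depth <= minor_frac):
            dominant = tuple(ranked[:m])
            minor = tuple(b for b in BASES_N if b not in dominant and cnt[b] > 0)
            return m, dominant, minor
    dominant = tuple(b for b in ranked if cnt[b] > 0)
    minor = ("N",) if cnt["N"] > 0 else ()
    return 4, dominant, minor


def _classify_columns(counts6: np.ndarray, depth: np.ndarray,
                      params: CorrectorParams):
    """Vectorized dominance over all columns.

    Returns (dominance, order, rank, dom_mask, p_col): ``order[j, c]`` is the
    j-th most frequent non-N base code of column c (ties A<C<G<T),
    ``dom_mask[b, c]`` flags dominant base codes, ``p_col`` is the priority
    added to minor bases (NaN for four-type/empty columns).
    """
    c4 = counts6[:4].astype(np.int64)
    order = np.argsort(-c4, axis=0, kind="stable")
    sorted_c = np.take_along_axis(c4, order, axis=0)
    cum = np.cumsum(sorted_c, axis=0)
    dominance = np.full(depth.shape, 4, dtype=np.int8)
    with np.errstate(divide="ignore", invalid="ignore"):
        for m in (3, 2, 1):
            other = depth - cum[m - 1]
            cond = (other <= params.minor_count) | (
                (depth >= params.min_depth_for_frac)
                & (other <= params.minor_frac * depth))
            dominance[cond] = m
    dominance[sorted_c[0] == 0] = 4  # N-only columns: no anchor type
    dominance[depth == 0] = 0
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(4, dtype=np.int64)[:, None]
                      * np.ones(depth.shape, dtype=np.int64)[None, :], axis=0)
    dom_mask = (rank < dominance[None, :]) & (dominance[None, :] <= 3)
    p_col = np.where((dominance >= 1) & (dominance <= 3),
                     dominance * 0.1, np.nan)
    return dominance, order, rank, dom_mask, p_col


def profile_columns(array: AlignmentArray,
                    params: Optional[CorrectorParams] = None) -> list:
    """Per-column :class:`ColumnProfile` objects (non-empty columns only)."""
    params = params or CorrectorParams()
    eng = _Engine(array, params, np.random.default_rng(params.seed))
    eng.profile()
    profiles = []
    for c in np.nonzero(eng.depth > 0)[0]:
        cnt = {b: int(eng.counts6[i, c]) for i, b in enumerate(BASES_N)}
        depth = int(eng.depth[c])
        dom = int(eng.dominance[c])
        dominant = tuple(BASES[b] for b in eng.order[:dom, c]
                         if eng.counts6[b, c] > 0) if dom <= 3 else tuple(
            BASES[b] for b in eng.order[:, c] if eng.counts6[b, c] > 0)
        minor = tuple(b for b in BASES_N if b not in dominant and cnt[b] > 0)
        freqs = {b: cnt[b] / depth for b in BASES_N}
        profiles.append(ColumnProfile(int(c), cnt, depth, freqs, dom,
                                      dominant, minor))
    return profiles


def annotate_bases(array: AlignmentArray,
                   params: Optional[CorrectorParams] = None) -> list:
    """Score every correction candidate cell (minor type, dominance 1-3).

    Dominant-type cells and cells at four-type columns get no annotation —
    they are never candidates.
    """
    params = params or CorrectorParams()
    eng = _Engine(array, params, np.random.default_rng(params.seed))
    eng.profile()
    scores, is_minor = eng.cell_scores()
    out = []
    for i in np.nonzero(is_minor)[0]:
        col = int(eng.cols[i])
        out.append(BaseAnnotation(
            row=int(eng.rowid[i]), col=col,
            base=BASES_N[eng.cells[i]] if eng.cells[i] < 5 else "-",
            f=float(eng.counts6[eng.cells[i], col] / eng.depth[col]),
            p=float(eng.p_col[col]),
            score=float(scores[i])))
    return out


# ---------------------------------------------------------------------------
# Proportional assignment (two/three-type columns)
# ---------------------------------------------------------------------------

def _largest_remainder(k: int, types: Sequence, freqs: Sequence[float]) -> dict:
    total = float(sum(freqs))
    quotas_f = [k * f / total for f in freqs]
    base_q = [int(math.floor(q)) for q in quotas_f]
    leftover = k - sum(base_q)
    order = sorted(range(len(types)),
                   key=lambda i: (-(quotas_f[i] - base_q[i]), -freqs[i], i))
    for i in order[:leftover]:
        base_q[i] += 1
    return dict(zip(types, base_q))


def proportional_assignment(candidates: Sequence, dominant_types: Sequence,
                            freqs: Union[Mapping, Sequence[float]],
                            seed: Union[int, np.random.Generator] = 0,
                            preferred: Optional[Mapping] = None) -> dict:
    """Partition candidate cells among dominant types by their frequencies.

    Largest-remainder rounding conserves the candidate count exactly (98
    candidates at 40%/58% dominant frequencies become 40 and 58).  A
    candidate with a phasing preference takes its preferred type first while
    that type's quota lasts; the rest are filled in a seeded deterministic
    shuffle so residual ties are reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(freqs, Mapping):
        fvals = [float(freqs[t]) for t in dominant_types]
    else:
        fvals = [float(f) for f in freqs]
    cand = list(candidates)
    quota = _largest_remainder(len(cand), list(dominant_types), fvals)
    result: dict = {}
    pool = []
    for c in cand:
        pref = preferred.get(c) if preferred else None
        if pref is not None and quota.get(pref, 0) > 0:
            result[c] = pref
            quota[pref] -= 1
        else:
            pool.append(c)
    if pool:
        perm = rng.permutation(len(pool))
        shuffled = [pool[i] for i in perm]
        by_freq = sorted(dominant_types,
                         key=lambda t: (-fvals[list(dominant_types).index(t)],))
        pos = 0
        for t in by_freq:
            for _ in range(quota.get(t, 0)):
                if pos >= len(shuffled):
                    break
                result[shuffled[pos]] = t
                pos += 1
    return result


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------

class _Engine:
    """Flat-array workhorse shared by the public correction operations."""

    def __init__(self, array: AlignmentArray, params: CorrectorParams,
                 rng: np.random.Generator):
        self.array = array
        self.params = params
        self.rng = rng
        self.n_cols = array.n_cols
        self.records: list[CorrectionRecord] = []
        self.out_ids: list[str] = []
        self._build_flat()

    def _build_flat(self) -> None:
        rows = self.array.rows
        if rows:
            self.cells = np.concatenate([encode(mr.cells) for mr in rows])
            self.cols = np.concatenate([
                np.arange(mr.offset, mr.offset + len(mr.cells), dtype=np.int64)
                for mr in rows])
            self.rowid = np.repeat(np.arange(len(rows), dtype=np.int64),
                                   [len(mr.cells) for mr in rows])
            self.readpos = np.concatenate([
                np.asarray(mr.read_pos, dtype=np.int64) for mr in rows])
        else:
            self.cells = np.empty(0, dtype=np.uint8)
            self.cols = np.empty(0, dtype=np.int64)
            self.rowid = np.empty(0, dtype=np.int64)
            self.readpos = np.empty(0, dtype=np.int64)
        self.row_sizes = np.asarray([len(mr.cells) for mr in rows], dtype=np.int64)
        self.row_starts = np.concatenate(([0], np.cumsum(self.row_sizes)))
        self.read_len = np.asarray([len(mr.read.seq) for mr in rows], dtype=np.int64)
        self.offsets = np.asarray([mr.offset for mr in rows], dtype=np.int64)

    # -- column statistics ---------------------------------------------------

    def profile(self) -> None:
        counts6 = np.zeros((6, self.n_cols), dtype=np.int64)
        if self.cells.size:
            np.add.at(counts6, (self.cells, self.cols), 1)
        self.counts6 = counts6
        self.depth = counts6[:5].sum(axis=0)  # gaps carry no base evidence
        (self.dominance, self.order, self.rank,
         self.dom_mask, self.p_col) = _classify_columns(counts6, self.depth,
                                                        self.params)

    def cell_scores(self) -> tuple[np.ndarray, np.ndarray]:
        cells, cols = self.cells, self.cols
        dom = self.dominance[cols]
        scorable = (dom >= 1) & (dom <= 3)
        acgt = cells < 4
        minor = np.zeros(cells.shape, dtype=bool)
        minor[acgt] = ~self.dom_mask[cells[acgt], cols[acgt]]
        minor[cells == 4] = True  # N is always a candidate
        minor &= scorable
        minor &= cells != 5  # gaps are never corrected
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.depth[cols] > 0,
                         self.counts6[np.minimum(cells, 4), cols]
                         / np.maximum(self.depth[cols], 1), 0.0)
        scores = np.where(minor, f + self.p_col[cols], np.inf)
        return scores, minor

    # -- helpers -------------------------------------------------------------

    def _cell_index(self, row: int, col: int) -> int:
        """Flat index of row's cell at col, or -1 if the row skips it."""
        lo, hi = self.row_starts[row], self.row_starts[row + 1]
        i = lo + np.searchsorted(self.cols[lo:hi], col)
        if i < hi and self.cols[i] == col:
            return int(i)
        return -1

    def _rows_covering(self, col: int) -> np.ndarray:
        if self.offsets.size == 0:
            return np.empty(0, dtype=np.int64)
        max_span = int(self.row_sizes.max(initial=0))
        hi = np.searchsorted(self.offsets, col, side="right")
        lo = np.searchsorted(self.offsets, col - max_span + 1, side="left")
        rows = np.arange(lo, hi)
        ends = self.offsets[rows] + self.row_sizes[rows]
        return rows[ends > col]

    def _neighbor_preference(self, row: int, col: int,
                             dom_types: Sequence[int],
                             dom23_cols: np.ndarray) -> Optional[int]:
        """Same-read phasing: prefer the dominant type co-occurring with the
        read's own dominant base at the nearest two/three-type neighbor column."""
        w = self.params.phasing_window
        lo = np.searchsorted(dom23_cols, col - w)
        hi = np.searchsorted(dom23_cols, col + w, side="right")
        neighbors = dom23_cols[lo:hi]
        neighbors = neighbors[neighbors != col]
        if neighbors.size == 0:
            return None
        neighbors = neighbors[np.argsort(np.abs(neighbors - col), kind="stable")]
        for nc in neighbors:
            ci = self._cell_index(row, int(nc))
            if ci < 0:
                continue
            b_own = int(self.cells[ci])
            if b_own >= 4 or not self.dom_mask[b_own, nc]:
                continue
            votes = np.zeros(4, dtype=np.int64)
            for r2 in self._rows_covering(int(nc)):
                if r2 == row:
                    continue
                i2 = self._cell_index(int(r2), int(nc))
                j2 = self._cell_index(int(r2), col)
                if i2 < 0 or j2 < 0:
                    continue
                b2, bc = int(self.cells[i2]), int(self.cells[j2])
                if b2 != b_own or bc >= 4:
                    continue
                if self.dom_mask[bc, col]:
                    votes[bc] += 1
            votes_dom = [(votes[t], t) for t in dom_types]
            best = max(votes_dom, key=lambda vt: (vt[0], self.counts6[vt[1], col]))
            if best[0] > 0:
                return best[1]
        return None

    # -- one correction pass ---------------------------------------------------

    def pass_once(self) -> tuple[int, int]:
        """One row-wise conservative correction pass.

        Returns (number of changed cells, number of rows labeled out).  Per
        row at most ``ceil(row_error_frac * n)`` cells change.
        """
        if not self.array.rows:
            return 0, 0
        self.profile()
        scores, _ = self.cell_scores()
        n_rows = len(self.array.rows)
        order = np.lexsort((self.cols, scores, self.rowid))
        rank = np.arange(order.size) - self.row_starts[self.rowid[order]]
        k_row = np.ceil(self.params.row_error_frac * self.read_len).astype(np.int64)
        cand_mask = (rank < k_row[self.rowid[order]]) & np.isfinite(scores[order])
        cand = order[cand_mask]

        # repeat detection: consistent disagreement looks like another locus
        flags = scores[cand] > self.params.out_threshold
        per_row = np.bincount(self.rowid[cand], weights=flags, minlength=n_rows)
        out_rows = np.nonzero(per_row > 1)[0]
        if out_rows.size:
            keep = ~np.isin(self.rowid[cand], out_rows)
            cand = cand[keep]

        n_changes = 0
        dom_at = self.dominance[self.cols[cand]]
        # dominance priority: one-type columns first, then two-, then three-type
        d1 = cand[dom_at == 1]
        if d1.size:
            new1 = self.order[0, self.cols[d1]].astype(np.uint8)
            self._apply(d1, new1)
            n_changes += d1.size
        dom23_cols = np.nonzero((self.dominance == 2) | (self.dominance == 3))[0]
        for dlevel in (2, 3):
            dsel = cand[dom_at == dlevel]
            if not dsel.size:
                continue
            for c in np.unique(self.cols[dsel]):
                in_col = np.sort(dsel[self.cols[dsel] == c])
                dom_types = [int(b) for b in self.order[:self.dominance[c], c]
                             if self.counts6[b, c] > 0]
                fvals = [self.counts6[t, c] / self.depth[c] for t in dom_types]
                if len(dom_types) == 1:
                    assign = {int(i): dom_types[0] for i in in_col}
                else:
                    preferred = {}
                    for i in in_col:
                        pref = self._neighbor_preference(
                            int(self.rowid[i]), int(c), dom_types, dom23_cols)
                        if pref is not None:
                            preferred[int(i)] = pref
                    assign = proportional_assignment(
                        [int(i) for i in in_col], dom_types, fvals,
                        self.rng, preferred)
                idxs = np.asarray(sorted(assign), dtype=np.int64)
                news = np.asarray([assign[int(i)] for i in idxs], dtype=np.uint8)
                self._apply(idxs, news)
                n_changes += idxs.size
        if out_rows.size:
            self._drop_rows(out_rows)
        return n_changes, int(out_rows.size)

    def _apply(self, idxs: np.ndarray, new_codes: np.ndarray) -> None:
        for i, nb in zip(idxs, new_codes):
            mr = self.array.rows[int(self.rowid[i])]
            old_code, new_code = int(self.cells[i]), int(nb)
            if old_code == new_code:
                continue
            rp = int(self.readpos[i])
            if mr.strand == "-":
                old_r, new_r = _COMP_CODE[old_code], _COMP_CODE[new_code]
            else:
                old_r, new_r = old_code, new_code
            self.records.append(CorrectionRecord(
                read_id=mr.read.read_id, pos_in_read=rp,
                old_base=BASES_N[old_r] if old_r < 5 else "-",
                new_base=BASES_N[new_r] if new_r < 5 else "-",
                col=int(self.cols[i]),
                dominance_at_col=int(self.dominance[self.cols[i]])))
        keep = self.cells[idxs] != new_codes
        self.cells[idxs[keep]] = new_codes[keep]

    def _drop_rows(self, out_rows: np.ndarray) -> None:
        out_set = set(int(r) for r in out_rows)
        for r in out_set:
            mr = self.array.rows[r]
            mr.out_flag = True
            self.out_ids.append(mr.read.read_id)
        keep_cells = ~np.isin(self.rowid, out_rows)
        self.cells = self.cells[keep_cells]
        self.cols = self.cols[keep_cells]
        self.readpos = self.readpos[keep_cells]
        old_rowid = self.rowid[keep_cells]
        keep_rows = np.asarray([i for i in range(len(self.array.rows))
                                if i not in out_set], dtype=np.int64)
        remap = np.full(len(self.array.rows), -1, dtype=np.int64)
        remap[keep_rows] = np.arange(keep_rows.size)
        self.rowid = remap[old_rowid]
        self.array.rows = [self.array.rows[int(i)] for i in keep_rows]
        self.row_sizes = self.row_sizes[keep_rows]
        self.row_starts = np.concatenate(([0], np.cumsum(self.row_sizes)))
        self.read_len = self.read_len[keep_rows]
        self.offsets = self.offsets[keep_rows]

    # -- results --------------------------------------------------------------

    def sync_cells(self) -> None:
        for r, mr in enumerate(self.array.rows):
            lo, hi = self.row_starts[r], self.row_starts[r + 1]
            mr.cells = decode(self.cells[lo:hi])

    def corrected_reads(self) -> list[Read]:
        out = []
        for r, mr in enumerate(self.array.rows):
            lo, hi = self.row_starts[r], self.row_starts[r + 1]
            codes = self.cells[lo:hi]
            rp = self.readpos[lo:hi]
            seq = np.frombuffer(mr.read.seq.encode("ascii"), dtype=np.uint8).copy()
            valid = rp >= 0
            rc = _COMP_CODE[codes] if mr.strand == "-" else codes
            seq[rp[valid]] = _DECODE[rc[valid]]
            out.append(_dc_replace(mr.read, seq=seq.tobytes().decode("ascii")))
        return out


# ---------------------------------------------------------------------------
# Public correction operations
# ---------------------------------------------------------------------------

def correct_rows(array: AlignmentArray,
                 row_error_fraction: float = 0.02,
                 out_threshold: float = 0.2,
                 params: Optional[CorrectorParams] = None,
                 rng: Optional[np.random.Generator] = None):
    """One conservative correction pass over the alignment array (in place).

    Returns (corrected reads, correction records, out read ids).  Rows
    labeled ``out`` are removed from the array.
    """
    params = params or CorrectorParams(row_error_frac=row_error_fraction,
                                       out_threshold=out_threshold)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    eng = _Engine(array, params, rng)
    eng.pass_once()
    eng.sync_cells()
    return eng.corrected_reads(), eng.records, eng.out_ids


@dataclass
class CorrectionResult:
    corrected_reads: list
    records: list
    out_read_ids: list
    consensus: str
    n_passes: int
    changes_per_pass: list


def correct_array(array: AlignmentArray,
                  params: Optional[CorrectorParams] = None) -> CorrectionResult:
    """Run correction passes to convergence and build the consensus.

    Each pass changes at most ``ceil(row_error_frac * n)`` cells per row;
    passes repeat (up to ``max_passes``) until a pass changes nothing, so
    reads with more errors than one pass's budget are finished once the
    updated column profiles confirm the remaining outliers.
    """
    params = params or CorrectorParams()
    rng = np.random.default_rng(params.seed)
    eng = _Engine(array, params, rng)
    changes_per_pass = []
    for _ in range(params.max_passes):
        n_changes, n_out = eng.pass_once()
        changes_per_pass.append(n_changes)
        if n_changes == 0 and n_out == 0:
            break
    eng.sync_cells()
    consensus = _consensus_from_engine(eng)
    return CorrectionResult(
        corrected_reads=eng.corrected_reads(),
        records=eng.records,
        out_read_ids=eng.out_ids,
        consensus=consensus,
        n_passes=len(changes_per_pass),
        changes_per_pass=changes_per_pass,
    )


def _consensus_from_engine(eng: _Engine) -> str:
    eng.profile()
    top = eng.order[0]  # most frequent A/C/G/T, ties in fixed base order
    covered = eng.counts6[:4].sum(axis=0) > 0
    ref_codes = encode(eng.array.ext_ref.ext_seq)
    cons = np.where(covered, top.astype(np.uint8), ref_codes)
    ext_ref = eng.array.ext_ref
    core = cons[ext_ref.core_start:ext_ref.core_end]
    return decode(core)


def consensus_sequence(array: AlignmentArray,
                       params: Optional[CorrectorParams] = None) -> str:
    """Per-column majority consensus over retained rows, trimmed to the gene.

    Zero-coverage columns fall back to the reference base; at two/three-type
    columns the highest-frequency dominant type wins (the plain majority).
    """
    params = params or CorrectorParams()
    eng = _Engine(array, params, np.random.default_rng(params.seed))
    return _consensus_from_engine(eng)
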