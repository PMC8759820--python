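"""Pairwise alignment engines.

Two engines live here:

* :func:`semi_global` — the production engine.  It aligns a full query
  against (a region of) a target with edlib in infix mode, then keeps the
  maximal-scoring local segment of the alignment, yielding BLAST-style
  identity (matches / alignment columns, gaps counted against identity)
  and query coverage (aligned query bases / query length).

* :func:`exhaustive_scan` — a reference scanner: a full Smith–Waterman
  dynamic program (linear gap penalty, numba-compiled) over an entire
  contig that tracks, for every cell, the statistics of the best local
  alignment ending there.  It is algorithmically independent of the
  anchored edlib path and serves as the oracle the fast engine is checked
  against.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

import edlib
import numpy as np
from numba import njit

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

# BLAST-like scoring for the reference scanner (blastn defaults, linear gap)
SW_MATCH = 2
SW_MISMATCH = -3
SW_GAP = -4


@dataclass
class AlignmentStats:
    """Statistics of one pairwise alignment.

    Coordinates are 0-based half-open: ``query[q_start:q_end]`` is aligned
    to ``target[t_start:t_end]``.
    """

    identity: float
    query_coverage: float
    matches: int
    columns: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    query_length: int

    @property
    def aligned_query_bases(self) -> int:
        return self.q_end - self.q_start


def _parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def semi_global(
    query: str, target: str, max_edit_fraction: Optional[float] = None
) -> Optional[AlignmentStats]:
    """Align the full query within the target (edlib infix mode) and keep
    the best local sub-alignment, so overhanging or truncated query ends
    reduce coverage rather than diluting identity.

    max_edit_fraction, if given, caps the edit distance at that fraction of
    the query length and returns None beyond it — an early-out for callers
    that only need a pass/fail near high identity.

    Returns None when edlib reports no alignment (empty inputs or cap hit).
    """
    if not query or not target:
        return None
    k = -1 if max_edit_fraction is None else max(1, int(max_edit_fraction * len(query)))
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start = res["locations"][0][0]

    # expand the CIGAR into per-column operations, then keep the
    # maximal-scoring contiguous segment under the local scoring — this
    # turns the semi-global path into its best local sub-alignment, so
    # low-quality tails (truncated copies bleeding into flanking sequence,
    # query overhangs) reduce coverage instead of diluting identity
    ops_expanded: List[str] = []
    for n, op in _parse_cigar(res["cigar"]):
        ops_expanded.extend(op * n)
    col_ops = np.frombuffer("".join(ops_expanded).encode(), dtype=np.uint8)
    scores = np.where(
        col_ops == ord("="), SW_MATCH,
        np.where(col_ops == ord("X"), SW_MISMATCH, SW_GAP),
    ).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(scores)])
    run_min = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - run_min
    c_end = int(np.argmax(gains)) + 1
    if gains[c_end - 1] <= 0:
        return None
    c_start = int(np.argmin(cum[:c_end]))

    seg = col_ops[c_start:c_end]
    is_q = (seg == ord("=")) | (seg == ord("X")) | (seg == ord("I"))
    is_t = (seg == ord("=")) | (seg == ord("X")) | (seg == ord("D"))
    matches = int((seg == ord("=")).sum())
    columns = int(seg.size)
    q_span = int(is_q.sum())
    t_span = int(is_t.sum())
    head = col_ops[:c_start]
    q_start = int(((head == ord("=")) | (head == ord("X")) | (head == ord("I"))).sum())
    t_off = int(((head == ord("=")) | (head == ord("X")) | (head == ord("D"))).sum())

    return AlignmentStats(
        identity=matches / columns,
        query_coverage=q_span / len(query),
        matches=matches,
        columns=columns,
        q_start=q_start,
        q_end=q_start + q_span,
        t_start=t_start + t_off,
        t_end=t_start + t_off + t_span,
        query_length=len(query),
    )


def count_substitutions(a: str, b: str) -> int:
    """Single-base substitutions between two sequences, gaps excluded.

    Equal lengths are compared position-by-position (gap-free); otherwise
    the shorter sequence is aligned within the longer with free end gaps
    and mismatch columns are counted.
    """
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if x != y)
    query, target = (a, b) if len(a) < len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    return sum(n for n, op in _parse_cigar(res["cigar"]) if op == "X")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


@njit(cache=True)
def _sw_scan_kernel(q, t, match, mismatch, gap):
    """Full Smith–Waterman over query q x target t with per-cell tracking of
    (matches, columns, query start, target start).  For every target end
    position j (exclusive) the maximal-scoring cell is recorded, so the
    candidates are the standard maximal local alignments, to be threshold-
    filtered afterwards."""
    m = q.shape[0]
    n = t.shape[0]

    score = np.zeros(n + 1, dtype=np.int32)
    mat = np.zeros(n + 1, dtype=np.int32)
    col = np.zeros(n + 1, dtype=np.int32)
    qs = np.zeros(n + 1, dtype=np.int32)
    ts = np.zeros(n + 1, dtype=np.int32)

    best_score = np.full(n, -1, dtype=np.int32)
    best_mat = np.zeros(n, dtype=np.int32)
    best_col = np.zeros(n, dtype=np.int32)
    best_qs = np.zeros(n, dtype=np.int32)
    best_qe = np.zeros(n, dtype=np.int32)
    best_ts = np.zeros(n, dtype=np.int32)

    for j in range(n + 1):
        ts[j] = j

    for i in range(1, m + 1):
        qi = q[i - 1]
        # diagonals of the previous row, carried through the sweep
        prev_score = score[0]
        prev_mat = mat[0]
        prev_col = col[0]
        prev_qs = qs[0]
        prev_ts = ts[0]
        # column 0 of this row: empty alignment starting at (i, 0)
        score[0] = 0
        mat[0] = 0
        col[0] = 0
        qs[0] = i
        ts[0] = 0
        for j in range(1, n + 1):
            up_score = score[j]
            up_mat = mat[j]
            up_col = col[j]
            up_qs = qs[j]
            up_ts = ts[j]

            eq = 1 if qi == t[j - 1] else 0
            d = prev_score + (match if eq == 1 else mismatch)
            u = up_score + gap
            l = score[j - 1] + gap

            if d >= u and d >= l and d > 0:
                score[j] = d
                mat[j] = prev_mat + eq
                col[j] = prev_col + 1
                qs[j] = prev_qs
                ts[j] = prev_ts
            elif u >= l and u > 0:
                score[j] = u
                mat[j] = up_mat
                col[j] = up_col + 1
                qs[j] = up_qs
                ts[j] = up_ts
            elif l > 0:
                score[j] = l
                mat[j] = mat[j - 1]
                col[j] = col[j - 1] + 1
                qs[j] = qs[j - 1]
                ts[j] = ts[j - 1]
            else:
                score[j] = 0
                mat[j] = 0
                col[j] = 0
                qs[j] = i
                ts[j] = j

            if score[j] > 0 and score[j] > best_score[j - 1]:
                best_score[j - 1] = score[j]
                best_mat[j - 1] = mat[j]
                best_col[j - 1] = col[j]
                best_qs[j - 1] = qs[j]
                best_qe[j - 1] = i
                best_ts[j - 1] = ts[j]

            prev_score = up_score
            prev_mat = up_mat
            prev_col = up_col
            prev_qs = up_qs
            prev_ts = up_ts

    return best_score, best_mat, best_col, best_qs, best_qe, best_ts


def exhaustive_scan(
    query: str,
    target: str,
    min_identity: float,
    min_coverage: float,
) -> List[AlignmentStats]:
    """Exhaustive local-alignment scan of a full query against a target.

    Every target position is considered as an alignment end; the
    maximal-scoring candidates are reduced to non-redundant local optima
    (sorted by score, a candidate is dropped when its target interval
    overlaps an already accepted one by more than 50% of the shorter
    interval) and only then filtered by identity and coverage — mirroring
    how a BLAST-style search reports the peak alignment of a region and
    discards sub-threshold peaks.
    """
    if not query or not target:
        return []
    bs, bm, bc, bqs, bqe, bts = _sw_scan_kernel(
        _encode(query), _encode(target), SW_MATCH, SW_MISMATCH, SW_GAP
    )
    min_score = SW_MATCH * min_coverage * min_identity * len(query) * 0.5
    idx = np.nonzero(bs >= min_score)[0]
    order = idx[np.argsort(bs[idx], kind="stable")[::-1]]
    peaks: List[AlignmentStats] = []
    for j in order:
        start, end = int(bts[j]), int(j + 1)
        redundant = False
        for h in peaks:
            ov = min(end, h.t_end) - max(start, h.t_start)
            shorter = min(end - start, h.t_end - h.t_start)
            if ov > 0.5 * shorter:
                redundant = True
                break
        if not redundant:
            peaks.append(
                AlignmentStats(
                    identity=int(bm[j]) / int(bc[j]),
                    query_coverage=(int(bqe[j]) - int(bqs[j])) / len(query),
                    matches=int(bm[j]),
                    columns=int(bc[j]),
                    q_start=int(bqs[j]),
                    q_end=int(bqe[j]),
                    t_start=start,
                    t_end=end,
                    query_length=len(query),
                )
            )
    hits = [
        h for h in peaks
        if h.identity >= min_identity and h.query_coverage >= min_coverage
    ]
    hits.sort(key=lambda h: h.t_start)
    return hits


def overlap_fraction(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Overlap length divided by the shorter interval length (0 if disjoint)."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return ov / min(a_end - a_start, b_end - b_start)


def kmer_positions(seq: str, k: int) -> dict:
    """Map each k-mer to the list of its start positions in seq."""
    index: dict = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index
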