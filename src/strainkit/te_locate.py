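"""Locating full-length transposable-element copies in assemblies.

A complete family sequence is matched against every contig on both strands;
placements are retained only when the alignment reaches both the identity
threshold (matches / alignment columns) and the query-coverage threshold
(aligned query bases / query length), defaults 95% / 95%.  This mirrors the
BLAST-style "complete element" filter used for yeast Ty annotation: solo
LTRs and fragmented copies fail the coverage filter by construction.

The production engine anchors exact k-mers, groups them by diagonal, and
aligns the full family sequence against the implied region with edlib; an
exhaustive Smith–Waterman scan (:func:`locate_te_exhaustive`) provides the
independent reference the fast path is validated against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .align import (
    AlignmentStats,
    exhaustive_scan,
    kmer_positions,
    overlap_fraction,
    semi_global,
)
from .assembly import Assembly, revcomp

logger = logging.getLogger(__name__)

ANCHOR_K = 15
MAX_CHAIN_GAP = 500  # bp; fragmented copies are not chained into one hit
MIN_ANCHORS = 2
REGION_PAD = 100


@dataclass(frozen=True)
class TELocus:
    """One full-length element placement (0-based, half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    identity: float
    query_coverage: float
    aln_columns: int = 0

    def length(self) -> int:
        return self.end - self.start


def _validate_thresholds(min_identity: float, min_coverage: float) -> None:
    for name, v in (("min_identity", min_identity), ("min_coverage", min_coverage)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {v}")


def _diagonal_groups(
    anchors: List[Tuple[int, int]], qlen: int
) -> Iterable[List[Tuple[int, int]]]:
    """Split (qpos, tpos) anchors into candidate element groups.

    Anchors are grouped by diagonal (tpos - qpos) within a tolerance that
    admits up to ~5% indels, then split where consecutive target positions
    jump by more than MAX_CHAIN_GAP.  Tandem copies land on well-separated
    diagonals and therefore form separate groups.
    """
    tol = max(30, int(0.05 * qlen))
    anchors = sorted(anchors, key=lambda a: (a[1] - a[0], a[1]))
    group: List[Tuple[int, int]] = []
    for a in anchors:
        if group and (
            (a[1] - a[0]) - (group[0][1] - group[0][0]) > tol
            or a[1] - group[-1][1] > MAX_CHAIN_GAP
        ):
            yield group
            group = []
        group.append(a)
    if group:
        yield group


def _resolve_overlaps(hits: List[TELocus]) -> List[TELocus]:
    """Keep one element per location: among hits overlapping by more than
    50% of the shorter interval keep the highest identity; ties broken by
    longer alignment, then lexicographic family name."""
    kept: List[TELocus] = []
    for h in sorted(
        hits, key=lambda h: (-h.identity, -h.aln_columns, h.family, h.contig, h.start)
    ):
        clash = any(
            k.contig == h.contig
            and overlap_fraction(h.start, h.end, k.start, k.end) > 0.5
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start, h.family))
    return kept


def _candidate_hits_anchored(
    contig_name: str,
    contig_seq: str,
    family: str,
    query: str,
    strand: str,
    index: Dict[str, List[int]],
    min_identity: float,
    min_coverage: float,
) -> List[TELocus]:
    qlen = len(query)
    anchors: List[Tuple[int, int]] = []
    for qpos in range(0, qlen - ANCHOR_K + 1):
        for tpos in index.get(query[qpos : qpos + ANCHOR_K], ()):
            anchors.append((qpos, tpos))
    hits: List[TELocus] = []
    for group in _diagonal_groups(anchors, qlen):
        if len(group) < MIN_ANCHORS:
            continue
        r_start = max(0, min(t - q for q, t in group) - REGION_PAD)
        r_end = min(len(contig_seq), max(t - q + qlen for q, t in group) + REGION_PAD)
        stats = semi_global(query, contig_seq[r_start:r_end])
        if stats is None:
            continue
        if stats.identity >= min_identity and stats.query_coverage >= min_coverage:
            hits.append(
                TELocus(
                    contig=contig_name,
                    start=r_start + stats.t_start,
                    end=r_start + stats.t_end,
                    strand=strand,
                    family=family,
                    identity=stats.identity,
                    query_coverage=stats.query_coverage,
                    aln_columns=stats.columns,
                )
            )
    return hits


def _is_degenerate(seq: str) -> bool:
    return len(seq) == 0 or set(seq) <= {"N"}


def locate_te(
    assembly: Assembly,
    library: Dict[str, str],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> List[TELocus]:
    """Find full-length copies of each library family in the assembly.

    Both strands are searched; overlapping candidates (any family) are
    resolved to the single best hit per location.  Returns loci sorted by
    (contig, start).  An assembly with zero contigs yields an empty list;
    all-N contigs are skipped with a logged warning.
    """
    _validate_thresholds(min_identity, min_coverage)
    for fam, seq in library.items():
        if not seq:
            raise ValueError(f"empty library sequence for family {fam!r}")

    hits: List[TELocus] = []
    for contig in assembly:
        if _is_degenerate(contig.sequence):
            logger.warning("skipping degenerate contig %s", contig.name)
            continue
        index = kmer_positions(contig.sequence, ANCHOR_K)
        for family, fseq in library.items():
            fseq = fseq.upper()
            for strand, query in (("+", fseq), ("-", revcomp(fseq))):
                hits.extend(
                    _candidate_hits_anchored(
                        contig.name,
                        contig.sequence,
                        family,
                        query,
                        strand,
                        index,
                        min_identity,
                        min_coverage,
                    )
                )
    return _resolve_overlaps(hits)


def locate_te_exhaustive(
    assembly: Assembly,
    library: Dict[str, str],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> List[TELocus]:
    """Reference locator: full Smith–Waterman scan of every family against
    every contig and strand, with the same thresholds and overlap rule as
    :func:`locate_te`.  Quadratic time; intended for validation at the
    ≤ 100 kb scale."""
    _validate_thresholds(min_identity, min_coverage)
    hits: List[TELocus] = []
    for contig in assembly:
        if _is_degenerate(contig.sequence):
            continue
        for family, fseq in library.items():
            fseq = fseq.upper()
            for strand, query in (("+", fseq), ("-", revcomp(fseq))):
                for st in exhaustive_scan(
                    query, contig.sequence, min_identity, min_coverage
                ):
                    hits.append(
                        TELocus(
                            contig=contig.name,
                            start=st.t_start,
                            end=st.t_end,
                            strand=strand,
                            family=family,
                            identity=st.identity,
                            query_coverage=st.query_coverage,
                            aln_columns=st.columns,
                        )
                    )
    return _resolve_overlaps(hits)


def filter_chromosome_scale(
    loci: List[TELocus], assembly: Assembly, min_contig_length: int
) -> List[TELocus]:
    """Retain loci on contigs of at least min_contig_length bp (order kept)."""
    if min_contig_length < 0:
        raise ValueError("min_contig_length must be >= 0")
    return [l for l in loci if len(assembly[l.contig]) >= min_contig_length]


def write_bed(loci: List[TELocus], path) -> None:
    """BED6: name = family, score = round(identity * 1000)."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.contig}\t{l.start}\t{l.end}\t{l.family}"
                f"\t{round(l.identity * 1000)}\t{l.strand}\n"
            )


def write_tsv(loci: List[TELocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tfamily\tidentity\tquery_coverage\n")
        for l in loci:
            fh.write(
                f"{l.contig}\t{l.start}\t{l.end}\t{l.strand}\t{l.family}"
                f"\t{l.identity:.4f}\t{l.query_coverage:.4f}\n"
            )


def read_loci_tsv(path) -> List[TELocus]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            loci.append(
                TELocus(
                    contig=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    family=row["family"],
                    identity=float(row["identity"]),
                    query_coverage=float(row["query_coverage"]),
                )
            )
    return loci
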