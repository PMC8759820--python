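"""Per-strain-pair conservation of transposable-element locations.

A location is compared between strains by extracting each element together
with 1,500 bp of upstream and downstream genomic context and aligning the
flank-augmented sequences; the location counts as conserved when the
alignment reaches 95% identity and 99% query coverage.  Coverage is
directional, so both query directions are tried and the pair is conserved
if either passes — this restores the symmetry a distance measure needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .align import semi_global
from .assembly import Assembly, revcomp
from .te_locate import TELocus

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 1500


@dataclass
class FlankedLocus:
    """An element plus up/downstream genomic context, in library orientation."""

    locus: TELocus
    flank_length: int
    sequence: str
    left_clamped: bool
    right_clamped: bool


def extract_flanked(
    assembly: Assembly, locus: TELocus, flank_length: int = DEFAULT_FLANK
) -> FlankedLocus:
    """Extract element sequence plus flanks, clamped at contig ends.

    Minus-strand loci are reverse-complemented so the element is always in
    library orientation; after reverse complementation "left" refers to the
    element's 5' side (the downstream side on the contig).
    """
    if locus.contig not in assembly:
        raise KeyError(f"contig {locus.contig!r} not present in assembly")
    contig = assembly[locus.contig]
    lo = max(0, locus.start - flank_length)
    hi = min(len(contig), locus.end + flank_length)
    seq = contig.sequence[lo:hi]
    left_clamped = lo > locus.start - flank_length
    right_clamped = hi < locus.end + flank_length
    if locus.strand == "-":
        seq = revcomp(seq)
        left_clamped, right_clamped = right_clamped, left_clamped
    return FlankedLocus(locus, flank_length, seq, left_clamped, right_clamped)


def is_conserved(
    a: FlankedLocus,
    b: FlankedLocus,
    min_identity: float = 0.95,
    min_query_coverage: float = 0.99,
) -> Tuple[bool, float, float]:
    """Do two flank-augmented loci represent the same genomic location?

    Both query directions (a within b, b within a) are aligned; the pair is
    conserved if either direction meets both thresholds.  Returns
    (conserved, identity, coverage) of the best-coverage direction.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("flanked sequences must be non-empty")
    best: Optional[Tuple[float, float]] = None
    conserved = False
    # identity >= 0.95 bounds the achievable edit distance; cap a little
    # above it so hopeless pairs abort early
    cap = max(0.08, 1.06 - min_identity)
    for query, target in ((a.sequence, b.sequence), (b.sequence, a.sequence)):
        stats = semi_global(query, target, max_edit_fraction=cap)
        if stats is None:
            continue
        if best is None or stats.query_coverage > best[1]:
            best = (stats.identity, stats.query_coverage)
        if stats.identity >= min_identity and stats.query_coverage >= min_query_coverage:
            conserved = True
    if best is None:
        return False, 0.0, 0.0
    if (
        not conserved
        and (a.left_clamped or a.right_clamped or b.left_clamped or b.right_clamped)
        and best[0] >= min_identity - 0.02
        and best[1] >= min_query_coverage - 0.02
    ):
        logger.warning(
            "clamped-flank locus pair narrowly failed conservation "
            "(identity %.3f, coverage %.3f)", best[0], best[1],
        )
    return conserved, best[0], best[1]


@dataclass
class PairConservation:
    """One-to-one matching of conserved locations between two strains."""

    strain_a: str
    strain_b: str
    matches: List[Tuple[int, int, float, float]]  # (idx_a, idx_b, identity, coverage)
    n_a: int
    n_b: int

    @property
    def n_shared(self) -> int:
        return len(self.matches)

    @property
    def n_distinct(self) -> int:
        return self.n_a + self.n_b - 2 * self.n_shared


def pair_conservation(
    loci_a: List[TELocus],
    assembly_a: Assembly,
    loci_b: List[TELocus],
    assembly_b: Assembly,
    strain_a: str = "A",
    strain_b: str = "B",
    flank_length: int = DEFAULT_FLANK,
    min_identity: float = 0.95,
    min_query_coverage: float = 0.99,
) -> PairConservation:
    """Greedy one-to-one matching of conserved locations between strains.

    Only same-family locus pairs are compared (cross-family flank matches
    cannot reach the coverage threshold over a full-length element).
    Candidate conserved pairs are accepted in order of descending identity,
    each locus used at most once; ties break on the smaller index pair.
    """
    flanked_a = [extract_flanked(assembly_a, l, flank_length) for l in loci_a]
    flanked_b = [extract_flanked(assembly_b, l, flank_length) for l in loci_b]

    candidates: List[Tuple[float, float, int, int]] = []
    for i, fa in enumerate(flanked_a):
        for j, fb in enumerate(flanked_b):
            if fa.locus.family != fb.locus.family:
                continue
            ok, ident, cov = is_conserved(fa, fb, min_identity, min_query_coverage)
            if ok:
                candidates.append((ident, cov, i, j))

    candidates.sort(key=lambda c: (-c[0], c[2], c[3]))
    used_a: set = set()
    used_b: set = set()
    matches: List[Tuple[int, int, float, float]] = []
    for ident, cov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j, ident, cov))
    matches.sort()
    return PairConservation(strain_a, strain_b, matches, len(loci_a), len(loci_b))


def all_pair_conservation(
    loci: Dict[str, List[TELocus]],
    assemblies: Dict[str, Assembly],
    flank_length: int = DEFAULT_FLANK,
    min_identity: float = 0.95,
    min_query_coverage: float = 0.99,
) -> Dict[Tuple[str, str], PairConservation]:
    """pair_conservation over every unordered strain pair."""
    out: Dict[Tuple[str, str], PairConservation] = {}
    names = list(loci)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = pair_conservation(
                loci[a], assemblies[a], loci[b], assemblies[b],
                strain_a=a, strain_b=b, flank_length=flank_length,
                min_identity=min_identity, min_query_coverage=min_query_coverage,
            )
    return out


def write_summary_tsv(pairs: Dict[Tuple[str, str], PairConservation], path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_a\tstrain_b\tn_a\tn_b\tn_shared\tn_distinct\n")
        for (a, b), pc in pairs.items():
            fh.write(f"{a}\t{b}\t{pc.n_a}\t{pc.n_b}\t{pc.n_shared}\t{pc.n_distinct}\n")
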