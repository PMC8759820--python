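"""Circular-sequence canonicalization and inversion-isoform interconversion.

Assemblers start circular molecules (mtDNA, plasmids) at arbitrary points
and strands; these utilities rotate them to a shared anchor (or to the
lexicographically minimal rotation when no anchor is available) so that
different assemblies can be compared base-by-base.  Plasmids that exist as
two inversion isoforms differing by one large inversion between a pair of
inverted repeats — the classic A/B-form dimorphism of the yeast 2-micron
circle — are interconverted by reverse-complementing the segment between
the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .assembly import revcomp


@dataclass
class CircularSeq:
    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("circular sequence must be non-empty")
        self.sequence = self.sequence.upper()

    def rotated(self, offset: int) -> "CircularSeq":
        offset %= len(self.sequence)
        return CircularSeq(
            self.id, self.sequence[offset:] + self.sequence[:offset], self.circular
        )


def _best_circular_match(anchor: str, seq: str) -> tuple[int, int]:
    """(edit distance, start) of the best anchor match in the doubled
    sequence, i.e. allowing matches that wrap the origin."""
    doubled = seq + seq[: len(anchor)]
    res = edlib.align(anchor, doubled, mode="HW", task="locations")
    start = min(loc[0] for loc in res["locations"])
    return res["editDistance"], start % len(seq)


def rotate_to_anchor(
    s: CircularSeq, anchor: str, max_mismatch_fraction: float = 0.05
) -> CircularSeq:
    """Rotate so the sequence starts at the best anchor match.

    Both strands are searched (wrapping the origin); if the best match lies
    on the minus strand the sequence is reverse-complemented first.  An
    anchor whose best match exceeds the mismatch budget raises ValueError.
    """
    anchor = anchor.upper()
    if not anchor or len(anchor) >= len(s.sequence):
        raise ValueError("anchor must be non-empty and shorter than the sequence")
    fwd_dist, fwd_start = _best_circular_match(anchor, s.sequence)
    rc_seq = revcomp(s.sequence)
    rev_dist, rev_start = _best_circular_match(anchor, rc_seq)
    budget = max_mismatch_fraction * len(anchor)
    best = min(fwd_dist, rev_dist)
    if best > budget:
        raise ValueError(
            f"no anchor match within mismatch budget "
            f"(best edit distance {best}, budget {budget:.1f})"
        )
    if fwd_dist <= rev_dist:
        return s.rotated(fwd_start)
    return CircularSeq(s.id, rc_seq, s.circular).rotated(rev_start)


def canonical_rotation(s: CircularSeq) -> CircularSeq:
    """Lexicographically minimal rotation (Booth's algorithm); idempotent."""
    seq = s.sequence
    doubled = seq + seq
    n = len(seq)
    f = [-1] * (2 * n)
    start = 0
    for j in range(1, 2 * n):
        i = f[j - start - 1]
        while i != -1 and doubled[j] != doubled[start + i + 1]:
            if doubled[j] < doubled[start + i + 1]:
                start = j - i - 1
            i = f[i]
        if doubled[j] != doubled[start + i + 1]:
            if doubled[j] < doubled[start + i + 1]:  # i == -1 here
                start = j
            f[j - start] = -1
        else:
            f[j - start] = i + 1
    return s.rotated(start)


def invert_between_repeats(
    s: CircularSeq, repeat: str, invert_longer: bool = False
) -> CircularSeq:
    """Interconvert inversion isoforms defined by a pair of inverted repeats.

    The repeat must occur exactly twice, once per orientation.  The shorter
    of the two inter-repeat segments (the other, with invert_longer=True)
    is reverse-complemented in place, repeats included — because the two
    repeat copies are inverted images of each other this leaves the repeat
    content unchanged, and applying the operation twice restores the input.
    """
    repeat = repeat.upper()
    if not repeat:
        raise ValueError("repeat must be non-empty")
    seq = s.sequence
    rc = revcomp(repeat)

    def find_all(pattern: str) -> list[int]:
        hits, start = [], 0
        while True:
            i = seq.find(pattern, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1

    fwd = find_all(repeat)
    rev = find_all(rc) if rc != repeat else []
    total = len(fwd) + len(rev)
    if total != 2 or not fwd or not rev:
        raise ValueError(
            f"repeat must occur exactly twice in inverted orientation; "
            f"found {len(fwd)} forward and {len(rev)} reverse occurrences"
        )
    p = min(fwd[0], rev[0])
    q = max(fwd[0], rev[0])
    # two candidate segments on the circle, both bounded by the repeats
    inner = (p, q + len(repeat))  # p .. end of second repeat
    inner_len = inner[1] - inner[0]
    outer_len = len(seq) - (q - p - len(repeat))
    use_inner = (inner_len <= outer_len) != invert_longer
    if use_inner:
        a, b = inner
        out = seq[:a] + revcomp(seq[a:b]) + seq[b:]
    else:
        # invert the wrap-around segment: rotate it to be contiguous first
        rot = s.rotated(q)
        seq_r = rot.sequence
        seg_end = len(repeat) + (len(seq) - (q + len(repeat))) + p + len(repeat)
        out_r = revcomp(seq_r[:seg_end]) + seq_r[seg_end:]
        out = out_r[-q:] + out_r[:-q]
    return CircularSeq(s.id, out, s.circular)
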