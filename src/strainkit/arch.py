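"""Cumulative beta-arch amyloidogenicity profiles.

An external arch predictor emits, per protein sequence, a set of beta
arches (start, end, score).  The cumulative arch score of a residue is the
sum of the scores of all arches covering it — the per-residue measure of
amyloidogenic potential.  Allele profiles are compared on a shared
coordinate frame by projecting each profile onto a multiple sequence
alignment, with gap columns scored exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .assembly import read_fasta_sequences

GAP_CHARS = set("-.")


@dataclass
class Arch:
    """One beta arch; 1-based inclusive residue coordinates."""

    start: int
    end: int
    score: float


@dataclass
class ArchSet:
    seq_id: str
    length: int
    arches: List[Arch] = field(default_factory=list)

    def validate(self) -> None:
        for a in self.arches:
            if not (1 <= a.start <= a.end <= self.length):
                raise ValueError(
                    f"arch {a.start}-{a.end} outside sequence "
                    f"{self.seq_id!r} of length {self.length}"
                )
            if not np.isfinite(a.score):
                raise ValueError(f"non-finite arch score in {self.seq_id!r}")


def read_arches(path, lengths: Dict[str, int]) -> Dict[str, ArchSet]:
    """Permissive TSV reader: header (id, start, end, score); comment lines
    (#) skipped.  `lengths` supplies the sequence length per id."""
    sets: Dict[str, ArchSet] = {
        sid: ArchSet(sid, n) for sid, n in lengths.items()
    }
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.lower() for f in fields]
                continue
            row = dict(zip(header, fields))
            sid = row["id"]
            if sid not in sets:
                raise KeyError(f"arch for unknown sequence id {sid!r}")
            sets[sid].arches.append(
                Arch(int(row["start"]), int(row["end"]), float(row["score"]))
            )
    return sets


def cumulative_arch_score(arches: ArchSet) -> np.ndarray:
    """Per-residue cumulative score: profile[i] = sum of scores of arches
    covering residue i (0-based output over 1-based inclusive arches)."""
    arches.validate()
    profile = np.zeros(arches.length)
    for a in arches.arches:
        profile[a.start - 1 : a.end] += a.score
    return profile


def project_profiles(
    profiles: Dict[str, np.ndarray], msa: Dict[str, str]
) -> Tuple[List[str], np.ndarray]:
    """Place per-residue scores at their alignment columns; gap columns 0.

    `msa` maps id -> aligned sequence (all equal length).  Returns
    (row ids in MSA order, matrix rows x alignment columns).
    """
    ids = list(msa)
    ncol = {len(s) for s in msa.values()}
    if len(ncol) != 1:
        raise ValueError("MSA rows have unequal lengths")
    ncol = ncol.pop()
    out = np.zeros((len(ids), ncol))
    for r, sid in enumerate(ids):
        if sid not in profiles:
            raise KeyError(f"no profile for MSA sequence {sid!r}")
        row = msa[sid]
        residues = [c for c in range(ncol) if row[c] not in GAP_CHARS]
        prof = profiles[sid]
        if len(residues) != len(prof):
            raise ValueError(
                f"profile length {len(prof)} does not match ungapped MSA row "
                f"length {len(residues)} for sequence {sid!r}"
            )
        out[r, residues] = prof
    return ids, out


def project_from_fasta(profiles: Dict[str, np.ndarray], msa_path):
    return project_profiles(profiles, read_fasta_sequences(msa_path))


@dataclass
class ProfileDelta:
    delta: np.ndarray
    max_abs: float
    argmax: int
    exceeding: np.ndarray  # column indices with |delta| > threshold


def profile_delta(
    p1: np.ndarray, p2: np.ndarray, threshold: float = 0.0
) -> ProfileDelta:
    """Column-wise p1 - p2 with summary statistics (magnitudes only; no
    significance classification is attached)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"profile lengths differ: {p1.shape} vs {p2.shape}")
    d = p1 - p2
    absd = np.abs(d)
    return ProfileDelta(
        delta=d,
        max_abs=float(absd.max(initial=0.0)),
        argmax=int(absd.argmax()) if d.size else 0,
        exceeding=np.nonzero(absd > threshold)[0],
    )


def write_profile_tsv(ids: List[str], matrix: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\t" + "\t".join(ids) + "\n")
        for c in range(matrix.shape[1]):
            fh.write(
                f"{c + 1}\t" + "\t".join(f"{matrix[r, c]:.4f}"
                                         for r in range(matrix.shape[0])) + "\n"
            )
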