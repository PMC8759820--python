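"""Tandem copy-number estimation and qPCR relative quantification.

Assembly-based counting finds non-overlapping full-length marker matches
(both strands) genome-wide; qPCR quantitation-cycle tables are reduced with
the comparative-Ct method (fold = 2^-ddCt, perfect doubling assumed); the
two combine into a copy estimate for the calibrator strain:
calibrator copies = assembly copies / relative fold.  A multi-copy locus
can additionally be laid out gene-by-gene with per-copy substitution
counts, which is how tandem paralog arrays (one ancestral copy plus
duplicates sharing derived mutations) are dissected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .align import count_substitutions
from .assembly import Assembly
from .te_locate import locate_te

QPCR_COLUMNS = ["sample", "target", "reference", "replicate", "cq_target", "cq_reference"]


def count_tandem_copies(
    assembly: Assembly,
    marker: str,
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> int:
    """Number of non-overlapping full-length marker occurrences (both
    strands) at >= min_identity, genome-wide.  Zero is a valid answer."""
    if not marker:
        raise ValueError("marker must be non-empty")
    loci = locate_te(
        assembly, {"marker": marker},
        min_identity=min_identity, min_coverage=min_coverage,
    )
    return len(loci)


@dataclass
class FoldResult:
    """ddCt relative quantification of one sample against the calibrator."""

    sample: str
    calibrator: str
    target: str
    dct_sample: float
    dct_calibrator: float
    ddct: float
    fold: float
    sd_ddct: float  # replicate SD of ddCt, propagated from the four means

    @property
    def fold_low(self) -> float:
        return 2.0 ** (-(self.ddct + self.sd_ddct))

    @property
    def fold_high(self) -> float:
        return 2.0 ** (-(self.ddct - self.sd_ddct))


def read_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df


def _validate_qpcr(df: pd.DataFrame) -> None:
    cq = df[["cq_target", "cq_reference"]].to_numpy(dtype=float)
    if not np.isfinite(cq).all() or (cq <= 0).any():
        raise ValueError("Cq values must be finite and > 0")


def ddct_fold(
    table: pd.DataFrame, sample: str, calibrator: str, target: str
) -> FoldResult:
    """Comparative-Ct fold change of `sample` relative to `calibrator`.

    dCt = mean(Cq_target) - mean(Cq_reference) per sample;
    ddCt = dCt_sample - dCt_calibrator; fold = 2^-ddCt.  Replicate
    variation is propagated as the root sum of squared standard errors of
    the four Cq means.
    """
    _validate_qpcr(table)

    def dct(sample_id: str) -> Tuple[float, float]:
        rows = table[(table["sample"] == sample_id) & (table["target"] == target)]
        if rows.empty:
            raise ValueError(
                f"no rows for sample {sample_id!r}, target {target!r}"
            )
        if rows["cq_reference"].isna().any():
            raise ValueError(f"missing reference-gene Cq for sample {sample_id!r}")
        t = rows["cq_target"].to_numpy(dtype=float)
        r = rows["cq_reference"].to_numpy(dtype=float)
        var = 0.0
        for v in (t, r):
            if len(v) > 1:
                var += v.var(ddof=1) / len(v)
        return float(t.mean() - r.mean()), var

    dct_s, var_s = dct(sample)
    dct_c, var_c = dct(calibrator)
    ddct = dct_s - dct_c
    return FoldResult(
        sample=sample,
        calibrator=calibrator,
        target=target,
        dct_sample=dct_s,
        dct_calibrator=dct_c,
        ddct=ddct,
        fold=2.0 ** (-ddct),
        sd_ddct=math.sqrt(var_s + var_c),
    )


@dataclass
class CopyEstimate:
    assembly_copies: int
    relative_fold: float
    inferred_calibrator_copies: float


def infer_calibrator_copies(assembly_copies: int, relative_fold: float) -> CopyEstimate:
    """Copy number of the calibrator strain implied by the assembly count of
    the sample and the sample-vs-calibrator fold change."""
    if assembly_copies < 0:
        raise ValueError("assembly_copies must be >= 0")
    if relative_fold <= 0:
        raise ValueError("relative_fold must be > 0")
    return CopyEstimate(
        assembly_copies=assembly_copies,
        relative_fold=relative_fold,
        inferred_calibrator_copies=assembly_copies / relative_fold,
    )


@dataclass
class GeneCopy:
    name: str
    contig: str
    start: int
    end: int
    strand: str
    identity: float
    sequence: str


@dataclass
class LocusStructure:
    """Ordered gene copies at a locus plus their pairwise substitution counts."""

    copies: List[GeneCopy]
    labels: List[str]
    substitutions: np.ndarray  # square, order matches `copies`

    def ordered_names(self) -> List[str]:
        return [c.name for c in self.copies]


def locus_gene_structure(
    assembly: Assembly,
    gene_queries: Dict[str, str],
    region: Optional[Tuple[str, int, int]] = None,
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> LocusStructure:
    """Lay out full-length copies of each gene query along the assembly
    (optionally restricted to region=(contig, start, end)) and count
    substitutions between every pair of found copies.

    Substitution counts come from gap-free comparison of equal-length
    copies (free-end-gap alignment otherwise); gaps are excluded from the
    count.  Copies of the same gene are numbered in coordinate order
    (name-1, name-2, ...).
    """
    if not gene_queries:
        raise ValueError("gene_queries must be non-empty")
    target = assembly
    offset = 0
    if region is not None:
        contig, start, end = region
        sub = Assembly()
        sub.add(contig, assembly[contig].sequence[start:end])
        target = sub
        offset = start

    loci = locate_te(
        target, gene_queries, min_identity=min_identity, min_coverage=min_coverage
    )
    copies: List[GeneCopy] = []
    for l in loci:
        seq = target[l.contig].sequence[l.start : l.end]
        copies.append(
            GeneCopy(
                name=l.family,
                contig=l.contig,
                start=l.start + offset,
                end=l.end + offset,
                strand=l.strand,
                identity=l.identity,
                sequence=seq,
            )
        )
    # number copies of the same gene by coordinate order
    counts: Dict[str, int] = {}
    labels: List[str] = []
    for c in copies:
        counts[c.name] = counts.get(c.name, 0) + 1
        labels.append(
            f"{c.name}-{counts[c.name]}" if list(
                x.name for x in copies).count(c.name) > 1 else c.name
        )

    n = len(copies)
    subs = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            a = copies[i].sequence
            b = copies[j].sequence
            if copies[i].strand != copies[j].strand:
                from .assembly import revcomp

                b = revcomp(b)
            subs[i, j] = subs[j, i] = count_substitutions(a, b)
    return LocusStructure(copies=copies, labels=labels, substitutions=subs)
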