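"""Synthetic strain-evolution simulator.

Generates a set of strain genomes evolved along a known rooted tree:

* a random ancestral background sequence carrying full-length transposable
  elements at well-separated positions;
* along each branch, per-site substitutions (probability proportional to
  branch length, uniform over the three alternative bases, applied
  uniformly across background and element sequence alike), element gains
  (Poisson in branch length, inserted at uniformly chosen positions between
  existing elements) and element losses (per-copy Bernoulli, clean excision
  with no scar);
* no background indels, so true SNP counts between any two leaves are
  well defined position-by-position.

Every emitted genome comes with ground truth: element loci labelled by an
ancestral locus id shared exactly by orthologous placements, per-branch
gain/loss event log, and true pairwise SNP counts.  Elements keep at least
two flank lengths of clearance from contig ends and from each other, so
flank extraction downstream is never clamped or contaminated by a
neighbouring element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .assembly import Assembly, iter_pairs, revcomp
from .trees import Tree, TreeNode

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

DEFAULT_FLANK = 1500
END_CLEARANCE = 2 * DEFAULT_FLANK
MIN_TE_SPACING = 2 * DEFAULT_FLANK + 200
CONTIG_NAME = "chr1"


def encode_seq(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr.copy()


def decode_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode_seq(rng.integers(0, 4, size=length, dtype=np.uint8))


def random_te_library(
    n_families: int = 2, length: int = 1000, seed: int = 0
) -> Dict[str, str]:
    """Synthetic element family sequences (random, hence repeat-free)."""
    rng = np.random.default_rng(seed)
    return {f"TY{i + 1}": random_sequence(length, rng) for i in range(n_families)}


@dataclass
class SimParams:
    """Simulation conditions.

    tree
        Rooted binary tree (``Tree`` or Newick string); branch lengths in
        substitutions per site.
    genome_length
        Background (element-free) genome length in bp.
    te_library
        family name -> full-length element sequence.
    n_ancestral_te
        Element copies placed in the ancestor.
    te_gain_rate
        Expected insertions per unit branch length.
    te_loss_rate
        Expected excisions per existing copy per unit branch length.
    mutation_rate
        Scale factor on the per-site substitution probability
        (probability = mutation_rate x branch length); 1.0 means branch
        lengths are literal substitutions/site.
    """

    tree: Union[Tree, str]
    genome_length: int = 100_000
    te_library: Dict[str, str] = field(default_factory=random_te_library)
    n_ancestral_te: int = 8
    te_gain_rate: float = 100.0
    te_loss_rate: float = 10.0
    mutation_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.tree, str):
            self.tree = Tree.from_newick(self.tree)
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        for name in ("te_gain_rate", "te_loss_rate", "mutation_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for _, child in self.tree.edges():
            if child.length < 0:
                raise ValueError("branch lengths must be >= 0")


@dataclass(frozen=True)
class TruthLocus:
    """Ground-truth element placement in final genome coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    locus_id: int


@dataclass(frozen=True)
class SimEvent:
    branch: str  # label of the child node of the branch
    kind: str  # "gain" | "loss"
    locus_id: int
    family: str
    position: int  # background coordinate of the insertion point


@dataclass
class SimTruth:
    true_tree: Tree
    te_loci_by_strain: Dict[str, List[TruthLocus]]
    snp_counts: Dict[Tuple[str, str], int]
    events: List[SimEvent]


@dataclass
class _TECopy:
    locus_id: int
    position: int  # background insertion point
    strand: str
    family: str
    seq: np.ndarray  # genome-strand sequence of this copy (mutable)


class _Lineage:
    def __init__(self, background: np.ndarray, tes: List[_TECopy]):
        self.background = background
        self.tes = tes

    def copy(self) -> "_Lineage":
        return _Lineage(
            self.background.copy(),
            [
                _TECopy(t.locus_id, t.position, t.strand, t.family, t.seq.copy())
                for t in self.tes
            ],
        )

    def total_sites(self) -> int:
        return len(self.background) + sum(len(t.seq) for t in self.tes)


def _mutate(lineage: _Lineage, p: float, rng: np.random.Generator) -> int:
    """Apply per-site substitutions uniformly over background + elements."""
    if p <= 0:
        return 0
    total = lineage.total_sites()
    n_mut = rng.binomial(total, min(p, 1.0))
    if n_mut == 0:
        return 0
    sites = rng.choice(total, size=n_mut, replace=False)
    shifts = rng.integers(1, 4, size=n_mut, dtype=np.uint8)
    bg_len = len(lineage.background)
    for site, shift in zip(sites, shifts):
        if site < bg_len:
            arr, off = lineage.background, site
        else:
            off = site - bg_len
            for te in lineage.tes:
                if off < len(te.seq):
                    arr = te.seq
                    break
                off -= len(te.seq)
        arr[off] = (arr[off] + shift) % 4
    return int(n_mut)


def _valid_insertion_point(
    pos: int, lineage: _Lineage, genome_length: int
) -> bool:
    if pos < END_CLEARANCE or pos > genome_length - END_CLEARANCE:
        return False
    return all(abs(pos - te.position) >= MIN_TE_SPACING for te in lineage.tes)


def _place_te(
    lineage: _Lineage,
    genome_length: int,
    library: Dict[str, str],
    locus_id: int,
    rng: np.random.Generator,
) -> Optional[_TECopy]:
    family = list(library)[rng.integers(len(library))]
    strand = "+" if rng.random() < 0.5 else "-"
    for _ in range(200):
        pos = int(rng.integers(END_CLEARANCE, genome_length - END_CLEARANCE + 1))
        if _valid_insertion_point(pos, lineage, genome_length):
            seq = library[family] if strand == "+" else revcomp(library[family])
            te = _TECopy(locus_id, pos, strand, family, encode_seq(seq))
            lineage.tes.append(te)
            lineage.tes.sort(key=lambda t: t.position)
            return te
    return None  # genome saturated; skip this insertion


def _splice(lineage: _Lineage) -> Tuple[str, List[TruthLocus]]:
    parts: List[np.ndarray] = []
    loci: List[TruthLocus] = []
    prev = 0
    offset = 0
    for te in sorted(lineage.tes, key=lambda t: t.position):
        parts.append(lineage.background[prev : te.position])
        start = te.position + offset
        parts.append(te.seq)
        loci.append(
            TruthLocus(
                CONTIG_NAME, start, start + len(te.seq), te.strand, te.family,
                te.locus_id,
            )
        )
        offset += len(te.seq)
        prev = te.position
    parts.append(lineage.background[prev:])
    return decode_seq(np.concatenate(parts)), loci


def simulate_strains(params: SimParams) -> Tuple[Dict[str, Assembly], SimTruth]:
    """Evolve one genome per tree leaf; return assemblies plus ground truth.

    Deterministic: identical params (including seed) give byte-identical
    genomes and truth tables.
    """
    tree: Tree = params.tree  # type: ignore[assignment]
    leaves = tree.leaf_names()
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    if any(name is None for name in leaves):
        raise ValueError("all leaves must be named")
    if len(set(leaves)) != len(leaves):
        raise ValueError("leaf names must be unique")
    if not params.te_library:
        raise ValueError("te_library must be non-empty")
    for fam, seq in params.te_library.items():
        if not seq:
            raise ValueError(f"empty sequence for family {fam!r}")

    rng = np.random.default_rng(params.seed)
    events: List[SimEvent] = []
    next_locus = [0]

    # ancestor
    root_lineage = _Lineage(
        encode_seq(random_sequence(params.genome_length, rng)), []
    )
    for _ in range(params.n_ancestral_te):
        te = _place_te(
            root_lineage, params.genome_length, params.te_library,
            next_locus[0], rng,
        )
        if te is not None:
            next_locus[0] += 1

    # label internal nodes for the event log
    counter = [0]
    for node in tree.root.walk():
        if node.name is None:
            counter[0] += 1
            node.name = f"node{counter[0]}"

    leaf_lineages: Dict[str, _Lineage] = {}

    def evolve(node: TreeNode, lineage: _Lineage) -> None:
        for child in node.children:
            sub = lineage.copy()
            b = child.length
            # losses
            if params.te_loss_rate > 0 and b > 0:
                p_loss = 1.0 - np.exp(-params.te_loss_rate * b)
                survivors = []
                for te in sub.tes:
                    if rng.random() < p_loss:
                        events.append(
                            SimEvent(child.name, "loss", te.locus_id,
                                     te.family, te.position)
                        )
                    else:
                        survivors.append(te)
                sub.tes = survivors
            # gains
            if params.te_gain_rate > 0 and b > 0:
                for _ in range(rng.poisson(params.te_gain_rate * b)):
                    te = _place_te(
                        sub, params.genome_length, params.te_library,
                        next_locus[0], rng,
                    )
                    if te is not None:
                        next_locus[0] += 1
                        events.append(
                            SimEvent(child.name, "gain", te.locus_id,
                                     te.family, te.position)
                        )
            # substitutions
            _mutate(sub, params.mutation_rate * b, rng)
            if child.is_leaf:
                leaf_lineages[child.name] = sub
            else:
                evolve(child, sub)

    evolve(tree.root, root_lineage)

    assemblies: Dict[str, Assembly] = {}
    loci_by_strain: Dict[str, List[TruthLocus]] = {}
    for name in leaves:
        seq, loci = _splice(leaf_lineages[name])
        asm = Assembly()
        asm.add(CONTIG_NAME, seq)
        assemblies[name] = asm
        loci_by_strain[name] = loci

    snp_counts: Dict[Tuple[str, str], int] = {}
    for a, b in iter_pairs(leaves):
        la, lb = leaf_lineages[a], leaf_lineages[b]
        n = int(np.count_nonzero(la.background != lb.background))
        tes_b = {t.locus_id: t for t in lb.tes}
        for te in la.tes:
            other = tes_b.get(te.locus_id)
            if other is not None:
                n += int(np.count_nonzero(te.seq != other.seq))
        snp_counts[(a, b)] = n

    return assemblies, SimTruth(tree, loci_by_strain, snp_counts, events)


def make_tandem_array(
    marker: str,
    n_copies: int,
    spacer_length: int = 500,
    seed: int = 0,
    divergence: float = 0.0,
) -> Assembly:
    """Single-contig assembly with exactly n_copies occurrences of the
    marker separated (and bounded) by random spacers.

    divergence, if nonzero, plants exactly round(divergence * len(marker))
    substitutions (uniform alternative base, random positions) in each
    copy independently, emulating diverged tandem repeats with a hard
    per-copy divergence bound.
    """
    if not marker:
        raise ValueError("marker must be non-empty")
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    if spacer_length < 0:
        raise ValueError("spacer_length must be >= 0")
    rng = np.random.default_rng(seed)
    parts = [random_sequence(spacer_length, rng)]
    for _ in range(n_copies):
        copy = encode_seq(marker)
        if divergence > 0:
            n_mut = round(len(copy) * divergence)
            if n_mut:
                sites = rng.choice(len(copy), size=n_mut, replace=False)
                copy[sites] = (copy[sites] + rng.integers(
                    1, 4, size=n_mut, dtype=np.uint8)) % 4
        parts.append(decode_seq(copy))
        parts.append(random_sequence(spacer_length, rng))
    asm = Assembly()
    asm.add("tandem", "".join(parts))
    return asm


def plant_copies(
    background_length: int,
    copies: List[Tuple[str, str, str]],
    seed: int = 0,
    min_gap: int = 200,
) -> Tuple[Assembly, List[TruthLocus]]:
    """Random background with the given sequences planted at random,
    non-overlapping positions: copies = [(name, sequence, strand), ...].

    A direct fixture builder for locator tests: the returned truth loci are
    exact by construction.  Sequences are inserted in random order at
    positions keeping min_gap bp between copies and from the ends.
    """
    rng = np.random.default_rng(seed)
    total_insert = sum(len(seq) for _, seq, _ in copies)
    if background_length <= total_insert + (len(copies) + 1) * min_gap:
        raise ValueError("background too short for the requested copies")
    # choose background insertion points, then splice in position order
    while True:
        points = sorted(
            int(rng.integers(min_gap, background_length - min_gap))
            for _ in copies
        )
        if all(b - a >= min_gap for a, b in zip(points, points[1:])):
            break
    order = rng.permutation(len(copies))
    bg = random_sequence(background_length, rng)
    out: List[str] = []
    loci: List[TruthLocus] = []
    prev = 0
    offset = 0
    for point, idx in zip(points, order):
        name, seq, strand = copies[idx]
        placed = seq if strand == "+" else revcomp(seq)
        out.append(bg[prev:point])
        start = point + offset
        out.append(placed)
        loci.append(
            TruthLocus("contig", start, start + len(placed), strand, name, int(idx))
        )
        offset += len(placed)
        prev = point
    out.append(bg[prev:])
    asm = Assembly()
    asm.add("contig", "".join(out))
    return asm, loci


def mutate_sequence(seq: str, n_substitutions: int, seed: int = 0) -> str:
    """Plant exactly n substitutions (uniform alternative base) at distinct
    random positions."""
    if n_substitutions > len(seq):
        raise ValueError("more substitutions than positions")
    rng = np.random.default_rng(seed)
    arr = encode_seq(seq)
    sites = rng.choice(len(arr), size=n_substitutions, replace=False)
    arr[sites] = (arr[sites] + rng.integers(1, 4, size=n_substitutions,
                                            dtype=np.uint8)) % 4
    return decode_seq(arr)


# -- truth writers (plain-text outputs for the CLI) -----------------------


def write_truth_bed(loci_by_strain: Dict[str, List[TruthLocus]], directory) -> None:
    import os

    for strain, loci in loci_by_strain.items():
        with open(os.path.join(str(directory), f"{strain}.truth.bed"), "w") as fh:
            for l in loci:
                fh.write(
                    f"{l.contig}\t{l.start}\t{l.end}"
                    f"\t{l.family}:{l.locus_id}\t0\t{l.strand}\n"
                )


def write_events_tsv(events: List[SimEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tkind\tlocus_id\tfamily\tposition\n")
        for e in events:
            fh.write(f"{e.branch}\t{e.kind}\t{e.locus_id}\t{e.family}\t{e.position}\n")


def write_snp_tsv(snp_counts: Dict[Tuple[str, str], int], path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_a\tstrain_b\tsnp_count\n")
        for (a, b), n in snp_counts.items():
            fh.write(f"{a}\t{b}\t{n}\n")
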