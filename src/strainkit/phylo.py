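"""Distance matrices and neighbor-joining strain trees.

The distance between two strains is the fraction of their element
locations that are not shared: d(A,B) = n_distinct / (n_a + n_b - n_shared)
— the Jaccard distance over location sets (a true metric).  The averaged
alternative 1 - 2*n_shared/(n_a+n_b) is available behind a flag.  Trees
are inferred with classic neighbor joining (Q-criterion agglomeration),
which is exact on additive matrices.  Assembly-to-assembly substitution
counts come from unique k-mer anchor chains with mismatches counted inside
gap-free blocks, and the agreement between the two signals is quantified
by the correlation of shared-location fraction with SNP count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import stats as sps

from .assembly import Assembly
from .conservation import PairConservation
from .simulate import encode_seq
from .trees import Tree, TreeNode, robinson_foulds  # noqa: F401 (re-export)

logger = logging.getLogger(__name__)

SNP_ANCHOR_K = 21


@dataclass
class DistanceMatrix:
    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distance matrix must be non-negative")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def write_tsv(self, path, phylip: bool = False) -> None:
        with open(path, "w") as fh:
            if phylip:
                fh.write(f"{len(self.labels)}\n")
                for lab, row in zip(self.labels, self.values):
                    fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
            else:
                fh.write("strain\t" + "\t".join(self.labels) + "\n")
                for lab, row in zip(self.labels, self.values):
                    fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _normalize_pair(pair: Tuple[str, str]) -> Tuple[str, str]:
    return (pair[0], pair[1]) if pair[0] <= pair[1] else (pair[1], pair[0])


def te_distance(
    pairs: Dict[Tuple[str, str], PairConservation],
    method: str = "union",
) -> DistanceMatrix:
    """Distance matrix from per-pair shared/distinct location counts.

    method="union": d = n_distinct / (n_a + n_b - n_shared)   (Jaccard)
    method="average": d = 1 - 2*n_shared / (n_a + n_b)
    """
    if method not in ("union", "average"):
        raise ValueError(f"unknown method {method!r}")
    labels = sorted({s for p in pairs for s in p})
    index = {s: i for i, s in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))
    seen = set()
    for key, pc in pairs.items():
        i, j = index[pc.strain_a], index[pc.strain_b]
        union = pc.n_a + pc.n_b - pc.n_shared
        if union == 0:
            raise ValueError(
                f"distance undefined for pair ({pc.strain_a}, {pc.strain_b}): "
                "no element locations in either strain"
            )
        if method == "union":
            d = pc.n_distinct / union
        else:
            d = 1.0 - 2.0 * pc.n_shared / (pc.n_a + pc.n_b)
        values[i, j] = values[j, i] = d
        seen.add(_normalize_pair((pc.strain_a, pc.strain_b)))
    missing = [
        (a, b)
        for ai, a in enumerate(labels)
        for b in labels[ai + 1 :]
        if (a, b) not in seen
    ]
    if missing:
        raise ValueError(f"missing conservation results for pairs: {missing}")
    return DistanceMatrix(labels, values)


def shared_fractions(
    pairs: Dict[Tuple[str, str], PairConservation]
) -> Dict[Tuple[str, str], float]:
    """Per-pair fraction of shared locations (union-normalized)."""
    out = {}
    for pc in pairs.values():
        union = pc.n_a + pc.n_b - pc.n_shared
        out[_normalize_pair((pc.strain_a, pc.strain_b))] = (
            pc.n_shared / union if union else 0.0
        )
    return out


def nj_tree(d: DistanceMatrix) -> Tree:
    """Classic neighbor joining.

    Ties on the Q criterion break to the lowest index pair; negative branch
    lengths are clamped to 0 with a log note.  The returned tree is rooted
    at the final join purely for representation; interpret it as unrooted.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = d.values.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in d.labels]

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("clamping negative NJ branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.children = [nodes[i], nodes[j]]
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = D2

    u, v = nodes
    edge = max(D[0, 1], 0.0)
    if u.is_leaf and not v.is_leaf:
        u, v = v, u
    v.length = edge
    u.children.append(v)
    return Tree(u)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Patristic (leaf-to-leaf path length) distances of a tree."""
    labels = sorted(tree.leaf_names())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))

    def below(node: TreeNode) -> Dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        merged: Dict[str, float] = {}
        child_maps = []
        for child in node.children:
            cm = {k: v + child.length for k, v in below(child).items()}
            child_maps.append(cm)
        for a_i, cm_a in enumerate(child_maps):
            for cm_b in child_maps[a_i + 1 :]:
                for la, da in cm_a.items():
                    for lb, db in cm_b.items():
                        i, j = index[la], index[lb]
                        values[i, j] = values[j, i] = da + db
            merged.update(cm_a)
        merged.update(child_maps[-1])
        return merged

    below(tree.root)
    return DistanceMatrix(labels, values)


def snp_distance(a: Assembly, b: Assembly, k: int = SNP_ANCHOR_K) -> int:
    """Single-base mismatches inside gap-free blocks anchored by k-mers that
    are unique in, and shared by, both assemblies.

    Anchors are chained colinearly per contig pair; maximal runs of anchors
    on a common diagonal delimit gap-free blocks whose positions are
    compared directly.  The chain's terminal blocks are extended to the
    sequence boundaries along their diagonal; regions where the diagonal
    changes (indels) are skipped and contribute no mismatches.
    """

    def unique_kmers(asm: Assembly) -> Dict[str, Tuple[str, int]]:
        counts: Dict[str, int] = {}
        pos: Dict[str, Tuple[str, int]] = {}
        for contig in asm:
            s = contig.sequence
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                counts[km] = counts.get(km, 0) + 1
                pos[km] = (contig.name, i)
        return {km: p for km, p in pos.items() if counts[km] == 1}

    ua, ub = unique_kmers(a), unique_kmers(b)
    shared = set(ua) & set(ub)
    if not shared:
        raise ValueError("no homologous sequence (no shared unique anchors)")

    groups: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for km in shared:
        ca, pa = ua[km]
        cb, pb = ub[km]
        groups.setdefault((ca, cb), []).append((pa, pb))

    enc_a = {c.name: encode_seq(c.sequence) for c in a}
    enc_b = {c.name: encode_seq(c.sequence) for c in b}

    total = 0
    for (ca, cb), anchors in groups.items():
        anchors.sort()
        # longest chain with strictly increasing target positions
        import bisect

        tails: List[int] = []
        tails_idx: List[int] = []
        back = [-1] * len(anchors)
        for idx, (_, pb) in enumerate(anchors):
            pos = bisect.bisect_left(tails, pb)
            if pos == len(tails):
                tails.append(pb)
                tails_idx.append(idx)
            else:
                tails[pos] = pb
                tails_idx[pos] = idx
            back[idx] = tails_idx[pos - 1] if pos > 0 else -1
        chain = []
        cur = tails_idx[-1]
        while cur != -1:
            chain.append(anchors[cur])
            cur = back[cur]
        chain.reverse()

        sa, sb = enc_a[ca], enc_b[cb]
        # split the chain into maximal same-diagonal runs
        runs: List[Tuple[int, int, int]] = []  # (a_start, a_end_exclusive, diag)
        run_start = chain[0]
        prev = chain[0]
        for pa, pb in chain[1:]:
            if pb - pa != run_start[1] - run_start[0]:
                runs.append((run_start[0], prev[0] + k, run_start[1] - run_start[0]))
                run_start = (pa, pb)
            prev = (pa, pb)
        runs.append((run_start[0], prev[0] + k, run_start[1] - run_start[0]))

        for ri, (astart, aend, diag) in enumerate(runs):
            if ri == 0:
                ext = min(astart, astart + diag)
                astart -= ext
            if ri == len(runs) - 1:
                aend += min(len(sa) - aend, len(sb) - (aend + diag))
            total += int(
                np.count_nonzero(sa[astart:aend] != sb[astart + diag : aend + diag])
            )
    return total


def distance_concordance(
    te_shared: Dict[Tuple[str, str], float],
    snp_counts: Dict[Tuple[str, str], int],
    method: str = "pearson",
) -> Tuple[float, int]:
    """Correlation of shared-location fraction with SNP count across pairs.

    Returns (r, n).  Expected strongly negative when location turnover
    accumulates with sequence divergence.
    """
    keys = sorted(
        set(map(_normalize_pair, te_shared)) & set(map(_normalize_pair, snp_counts))
    )
    te_norm = {_normalize_pair(p): v for p, v in te_shared.items()}
    snp_norm = {_normalize_pair(p): v for p, v in snp_counts.items()}
    if len(keys) < 3:
        raise ValueError("need at least 3 strain pairs")
    x = np.array([te_norm[p] for p in keys], dtype=float)
    y = np.array([snp_norm[p] for p in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in shared fractions or SNP counts")
    if method == "pearson":
        r = sps.pearsonr(x, y).statistic
    elif method == "spearman":
        r = sps.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), len(keys)
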