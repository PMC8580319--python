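"""Neighbor-joining phylogenetics with bootstrap supports.

Pipeline: progressive multiple alignment (UPGMA guide tree over pairwise
alignment distances, then profile-profile global alignment up the tree),
pairwise-deletion distances (p-distance or Poisson-corrected), Saitou-Nei
neighbor joining with a deterministic tie-break, and column-resampling
bootstrap with a counter-based generator so replicate r is reproducible
independently of execution order.  Branch-length claims are deliberately
modest — the aligner is a documented simple progressive aligner — so tree
results should be read as topological statements (e.g. monophyly of the
classifier-positive set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage

from acsarch.mapping import global_align, _load_matrix
from acsarch.motifs import AA_ALPHABET


class PhyloError(ValueError):
    pass


class DistanceSaturationError(PhyloError):
    """A pairwise p-distance reached 1 under the Poisson correction."""


@dataclass(frozen=True)
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise PhyloError("ids and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise PhyloError("alignment rows must all have equal length")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.ids)
        if m.shape != (n, n):
            raise PhyloError(f"matrix shape {m.shape} != ({n}, {n})")
        if np.any(np.abs(m - m.T) > 1e-12):
            raise PhyloError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise PhyloError("distance matrix diagonal must be exactly 0")
        if np.any(m < 0):
            raise PhyloError("distances must be non-negative")


@dataclass
class PhyloTree:
    """Unrooted tree (dendropy-backed) with supports and clamp diagnostics."""

    tree: dendropy.Tree
    clamped_edges: list[tuple[str, float]] = field(default_factory=list)
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()

    def bipartitions(self) -> list[frozenset]:
        """Non-trivial leaf bipartitions, one canonical side per internal edge."""
        all_leaves = frozenset(self.leaf_labels)
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(all_leaves) - 1:
                out.append(_canonical_split(side, all_leaves))
        return out


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Represent a bipartition by the side not containing the smallest label."""
    anchor = min(all_leaves)
    return frozenset(all_leaves - side) if anchor in side else side


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile_from_rows(rows: list[str], index: dict[str, int]) -> np.ndarray:
    """(L, 21) column frequency profile; slot 20 is the gap character."""
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for r in rows:
        for j, c in enumerate(r):
            prof[j, index.get(c, 20) if c != "-" else 20] += 1
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str], smat: np.ndarray,
                    index: dict[str, int], gap_open: float,
                    gap_extend: float) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) global alignment of two profiles, expected score.

    Deterministic traceback preference: diagonal, then gap-in-B (up), then
    gap-in-A (left).
    """
    pa = _profile_from_rows(rows_a, index)
    pb = _profile_from_rows(rows_b, index)
    # expected substitution score between columns; gap slots contribute 0
    S = pa[:, :20] @ smat @ pb[:, :20].T
    La, Lb = S.shape
    NEG = -1e18
    go, ge = gap_open + gap_extend, gap_extend

    M = np.full((La + 1, Lb + 1), NEG)
    Ix = np.full((La + 1, Lb + 1), NEG)   # gap in B (consume A row)
    Iy = np.full((La + 1, Lb + 1), NEG)   # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        Ix[i, 0] = -go - (i - 1) * ge
    for j in range(1, Lb + 1):
        Iy[0, j] = -go - (j - 1) * ge

    for i in range(1, La + 1):
        Mi1, Mi = M[i - 1], M[i]
        Ixi1, Ixi = Ix[i - 1], Ix[i]
        Iyi1, Iyi = Iy[i - 1], Iy[i]
        Si = S[i - 1]
        for j in range(1, Lb + 1):
            best_prev = max(Mi1[j - 1], Ixi1[j - 1], Iyi1[j - 1])
            Mi[j] = best_prev + Si[j - 1]
            Ixi[j] = max(Mi1[j] - go, Ixi1[j] - ge)
            Iyi[j] = max(Mi[j - 1] - go, Iyi[j - 1] - ge)

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = La, Lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prevs = [M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]]
            nstate = int(np.argmax(prevs))
            out_a.append("COL")
            out_b.append("COL")
            i -= 1
            j -= 1
            state = nstate
        elif state == 1 and i > 0:
            # entered by opening from M or extending Ix
            nstate = 0 if M[i - 1][j] - gap_open - gap_extend >= \
                Ix[i - 1][j] - gap_extend else 1
            out_a.append("COL")
            out_b.append("GAP")
            i -= 1
            state = nstate
        elif state == 2 and j > 0:
            nstate = 0 if M[i][j - 1] - gap_open - gap_extend >= \
                Iy[i][j - 1] - gap_extend else 2
            out_a.append("GAP")
            out_b.append("COL")
            j -= 1
            state = nstate
        elif i > 0:
            out_a.append("COL")
            out_b.append("GAP")
            i -= 1
        else:
            out_a.append("GAP")
            out_b.append("COL")
            j -= 1
    out_a.reverse()
    out_b.reverse()

    def emit(rows: list[str], ops: list[str]) -> list[str]:
        merged = []
        for r in rows:
            chars = []
            k = 0
            for op in ops:
                if op == "COL":
                    chars.append(r[k])
                    k += 1
                else:
                    chars.append("-")
            merged.append("".join(chars))
        return merged

    return emit(rows_a, out_a), emit(rows_b, out_b)


def progressive_msa(records, matrix="BLOSUM62", gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> MultipleAlignment:
    """Progressive multiple alignment with a UPGMA guide tree.

    ``records`` is an iterable of (id, sequence) pairs.  Pairs of single
    sequences are merged with the exact pairwise aligner; profile merges use
    an affine-gap expected-score DP.  Fully deterministic.
    """
    records = list(records)
    if not records:
        raise PhyloError("no sequences to align")
    ids = [r[0] for r in records]
    seqs = [r[1].upper() for r in records]
    n = len(seqs)
    if n == 1:
        return MultipleAlignment(ids, [seqs[0]])

    mat = _load_matrix(matrix)
    index = {a: i for i, a in enumerate(AA_ALPHABET)}
    smat = np.zeros((20, 20))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            smat[i, j] = mat[a, b]

    # guide distances: p-distance over pairwise global alignments
    pairwise: dict[tuple[int, int], object] = {}
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], mat, gap_open, gap_extend,
                               query_id=ids[i], reference_id=ids[j])
            pairwise[(i, j)] = aln
            same = compared = 0
            for a, b in zip(aln.aligned_query, aln.aligned_reference):
                if a != "-" and b != "-":
                    compared += 1
                    same += a == b
            cond.append(1.0 - same / compared if compared else 1.0)
    Z = linkage(np.asarray(cond), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        if len(rows_a) == 1 and len(rows_b) == 1 and \
                "-" not in rows_a[0] and "-" not in rows_b[0]:
            ia, ib = ids.index(ids_a[0]), ids.index(ids_b[0])
            key = (min(ia, ib), max(ia, ib))
            aln = pairwise[key]
            if ia < ib:
                merged_a, merged_b = [aln.aligned_query], [aln.aligned_reference]
            else:
                merged_a, merged_b = [aln.aligned_reference], [aln.aligned_query]
        else:
            merged_a, merged_b = _align_profiles(rows_a, rows_b, smat, index,
                                                 gap_open, gap_extend)
        clusters[n + k] = (ids_a + ids_b, merged_a + merged_b)

    final_ids, final_rows = clusters.popitem()[1]
    order = [final_ids.index(i) for i in ids]
    return MultipleAlignment(ids, [final_rows[k] for k in order])


# ---------------------------------------------------------------------------
# distances


def distance_matrix(msa: MultipleAlignment, model: str = "poisson",
                    saturation: str = "error") -> DistanceMatrix:
    """Pairwise-deletion distances: p-distance or Poisson correction.

    p = mismatches / compared columns over columns where neither row is
    gapped; Poisson d = -ln(1 - p).  A pair with zero comparable columns is
    an error naming the pair.  A saturated pair (p -> 1) raises
    :class:`DistanceSaturationError` unless ``saturation='clamp'``.
    """
    if msa.n_taxa < 2:
        raise PhyloError("need at least two rows")
    if model not in ("p", "poisson"):
        raise PhyloError(f"unknown distance model {model!r}")
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != "-"
    n = msa.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            compared = int(both.sum())
            if compared == 0:
                raise PhyloError(
                    f"no comparable columns for pair "
                    f"({msa.ids[i]!r}, {msa.ids[j]!r})")
            p = float((arr[i, both] != arr[j, both]).sum() / compared)
            if model == "p":
                d = p
            else:
                if p >= 1.0:
                    if saturation == "clamp":
                        p = 1.0 - 1e-6
                    else:
                        raise DistanceSaturationError(
                            f"Poisson distance undefined at p={p} for pair "
                            f"({msa.ids[i]!r}, {msa.ids[j]!r})")
                d = -np.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(msa.ids), D)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ with the standard Q-criterion.

    Ties in Q are broken toward the lexicographically smallest label pair.
    Negative branch-length estimates are clamped to zero and recorded in
    ``clamped_edges``.
    """
    n = len(D.ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(D.ids)
    nodes: list[dendropy.Node] = []
    labels = list(D.ids)
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    d = D.matrix.astype(float).copy()
    active = list(range(n))
    clamped: list[tuple[str, float]] = []
    next_label = 0

    def clamp(length: float, name: str) -> float:
        if length < 0:
            clamped.append((name, float(length)))
            return 0.0
        return float(length)

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        nlab = f"internal{next_label}"
        next_label += 1
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(li, f"{labels[i]}")
        nodes[j].edge.length = clamp(lj, f"{labels[j]}")
        # new distances
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(parent)
        labels.append(nlab)
        active = [x for x in active if x not in (i, j)] + [k]

    # final star join of the remaining three
    i, j, k = active
    a = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    b = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    c = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = dendropy.Node()
    for idx, length in ((i, a), (j, b), (k, c)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(length, labels[idx])

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, clamped_edges=clamped)


def path_length_matrix(ptree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths; on additive inputs NJ reproduces them."""
    pdm = ptree.tree.phylogenetic_distance_matrix()
    labels = sorted(ptree.leaf_labels)
    n = len(labels)
    taxa = {t.label: t for t in ptree.tree.taxon_namespace}
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, M)


# ---------------------------------------------------------------------------
# bootstrap and monophyly


def _pair_masks(msa: MultipleAlignment):
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != "-"
    n = msa.n_taxa
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    comparable = np.array([nongap[i] & nongap[j] for i, j in pairs])
    mismatch = np.array([(arr[i] != arr[j]) & comparable[k]
                         for k, (i, j) in enumerate(pairs)])
    return pairs, comparable, mismatch


def _nj_from_column_sample(msa, cols, pairs, comparable, mismatch, model):
    n = msa.n_taxa
    comp = comparable[:, cols].sum(axis=1)
    mis = mismatch[:, cols].sum(axis=1)
    D = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        if comp[k] == 0:
            p = 1.0 - 1e-6
        else:
            p = mis[k] / comp[k]
        if model == "poisson":
            p = min(p, 1.0 - 1e-6)
            dist = -np.log(1.0 - p)
        else:
            dist = p
        D[i, j] = D[j, i] = dist
    return neighbor_joining(DistanceMatrix(list(msa.ids), D))


def bootstrap_support(msa: MultipleAlignment, n_replicates: int = 1000,
                      model: str = "poisson", seed: int = 0) -> PhyloTree:
    """Column-resampling bootstrap supports on the full-data NJ tree.

    Replicate r draws its columns from a Philox stream keyed by (seed, r),
    so each replicate is reproducible in isolation.  Support is the
    percentage of replicate trees containing each internal bipartition of
    the full-data tree, attached as internal node labels.
    """
    if msa.n_columns < 2:
        raise PhyloError("bootstrap needs an alignment with >= 2 columns")
    full = neighbor_joining(distance_matrix(msa, model, saturation="clamp"))
    target_splits = full.bipartitions()
    counts = {s: 0 for s in target_splits}
    pairs, comparable, mismatch = _pair_masks(msa)
    L = msa.n_columns
    for r in range(n_replicates):
        rng = np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, r]))
        cols = rng.integers(0, L, size=L)
        rep = _nj_from_column_sample(msa, cols, pairs, comparable, mismatch,
                                     model)
        rep_splits = set(rep.bipartitions())
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1

    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    all_leaves = frozenset(full.leaf_labels)
    for node in full.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            sup = supports[_canonical_split(side, all_leaves)]
            node.label = f"{sup:g}"
    full.supports = supports
    return full


def is_monophyletic(ptree: PhyloTree, labels) -> bool:
    """True iff removing one edge separates exactly ``labels`` from the rest."""
    subset = frozenset(labels)
    all_leaves = frozenset(ptree.leaf_labels)
    unknown = subset - all_leaves
    if unknown:
        raise PhyloError(f"labels not in tree: {sorted(unknown)}")
    if len(subset) in (1, len(all_leaves)):
        return True
    target = _canonical_split(subset, all_leaves)
    # leaf edges cover size-1 splits; internal edges the rest
    if len(subset) == len(all_leaves) - 1:
        return True  # complement is a single leaf's pendant edge
    return target in set(ptree.bipartitions())
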