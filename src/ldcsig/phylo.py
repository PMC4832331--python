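"""Distance-based phylogenetics: WAG/Poisson/p distances, NJ, bootstrap.

The tree is built by neighbor joining (Saitou–Nei Q-criterion) on
pairwise distances; under the WAG-ML mode each pairwise distance is the
branch length maximising the two-sequence likelihood under the WAG
model. Bootstrap supports come from column resampling. Trees are
dendropy objects so Newick IO and rerooting come for free.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import GAP, MultipleAlignment
from .substitution_models import PAML_ORDER, WAG_FREQS, wag_transition_probs

#: Poisson distances are capped here once the mismatch fraction
#: saturates (p >= SATURATION_P); capped pairs are flagged.
SATURATION_P = 0.85
MAX_DISTANCE = 5.0

_PAML_INDEX = {a: i for i, a in enumerate(PAML_ORDER)}


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise PhyloError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise PhyloError("distances must be finite and non-negative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{name:<12s} {row}\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(ids, np.array(rows))


_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _aa, _idx in _PAML_INDEX.items():
    _ENCODE_LUT[ord(_aa)] = _idx


def _encode(aln: MultipleAlignment) -> np.ndarray:
    """Rows as int8 in PAML order; gaps/X/unknown become -1."""
    flat = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[flat].reshape(aln.n_rows, aln.column_count)


def _wag_ml_distance(counts: np.ndarray) -> float:
    """Branch length maximising the two-sequence WAG likelihood.

    counts is the 20x20 matrix of aligned residue-pair counts; the
    likelihood of a pair (a, b) at time t is pi_a * P_ab(t).
    """
    logpi = np.log(WAG_FREQS)

    def nll(t):
        p = wag_transition_probs(t)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(p, 1e-300))
        return -float(np.sum(counts * (logpi[:, None] + lp)))

    res = minimize_scalar(nll, bounds=(1e-8, MAX_DISTANCE), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def pairwise_distance(
    aln: MultipleAlignment, model: str = "wag-ml"
) -> DistanceMatrix:
    """Pairwise distance matrix; gap-containing columns excluded pairwise.

    model: "wag-ml" | "poisson" | "p-distance".
    """
    return _distance_from_encoded(_encode(aln), list(aln.ids), model)


def _distance_from_encoded(
    enc: np.ndarray, ids: list[str], model: str
) -> DistanceMatrix:
    if model not in {"wag-ml", "poisson", "p-distance"}:
        raise PhyloError(f"unknown distance model {model!r}")
    n = len(ids)
    saturated: list[tuple[str, str]] = []
    if model in {"p-distance", "poisson"}:
        valid = enc >= 0
        # pairwise ungapped-overlap counts and mismatch counts, vectorised
        overlap = valid.astype(np.float64) @ valid.astype(np.float64).T
        diff = (enc[:, None, :] != enc[None, :, :]) & valid[:, None, :] & valid[None, :, :]
        mism = diff.sum(axis=2, dtype=np.float64)
        if np.any(overlap[~np.eye(n, dtype=bool)] == 0):
            i, j = np.argwhere((overlap == 0) & ~np.eye(n, dtype=bool))[0]
            raise PhyloError(
                f"no ungapped overlap between {ids[i]!r} and {ids[j]!r}"
            )
        with np.errstate(invalid="ignore"):
            p = np.where(overlap > 0, mism / np.maximum(overlap, 1), 0.0)
        np.fill_diagonal(p, 0.0)
        if model == "p-distance":
            d = p.astype(float)
        else:
            sat = p >= SATURATION_P
            d = np.where(sat, MAX_DISTANCE, -np.log(np.maximum(1.0 - p, 1e-12)))
            np.fill_diagonal(d, 0.0)
            for i, j in zip(*np.nonzero(np.triu(sat, 1))):
                saturated.append((ids[i], ids[j]))
        d = 0.5 * (d + d.T)
        return DistanceMatrix(ids, d, saturated)

    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = enc[i], enc[j]
        mask = (a >= 0) & (b >= 0)
        if not mask.any():
            raise PhyloError(f"no ungapped overlap between {ids[i]!r} and {ids[j]!r}")
        counts = np.zeros((20, 20))
        np.add.at(counts, (a[mask], b[mask]), 1.0)
        dist = _wag_ml_distance(counts)
        if dist >= MAX_DISTANCE - 1e-6:
            saturated.append((ids[i], ids[j]))
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids, d, saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree.

    Q-matrix ties are broken by the lexicographically smallest pair of
    current node indices; negative branch lengths are clamped to zero
    with a warning.
    """
    n = len(dm.ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    d = dm.values.copy()
    active = list(range(n))
    clamped = False

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first occurrence of the minimum = lowest (i, j) index pair
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i], active[j]
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        nodes[gi].edge.length = li
        nodes[gj].edge.length = lj
        # distances from the new node to the remaining ones
        new_index = len(nodes)
        nodes.append(parent)
        newrow = np.zeros(new_index)
        for k_pos, gk in enumerate(active):
            if k_pos in (i, j):
                continue
            newrow[gk] = 0.5 * (d[gi, gk] + d[gj, gk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_index, : new_index] = newrow
        d[: new_index, new_index] = newrow
        active = [g for g in active if g not in (gi, gj)] + [new_index]

    ga, gb = active
    last = d[ga, gb]
    if last < 0:
        clamped = True
        last = 0.0
    # join the final two lineages through an unrooted "seed" of degree >= 3
    if nodes[gb].is_leaf() and not nodes[ga].is_leaf():
        ga, gb = gb, ga
    root = nodes[gb] if not nodes[gb].is_leaf() else dendropy.Node()
    if root is nodes[gb]:
        root.add_child(nodes[ga])
        nodes[ga].edge.length = last
    else:  # both leaves: 2-taxon remainder cannot happen for n >= 3
        root.add_child(nodes[ga])
        root.add_child(nodes[gb])
        nodes[ga].edge.length = last / 2
        nodes[gb].edge.length = last / 2
    tree.seed_node = root
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as normalised leaf-name sets.

    Each internal edge splits the leaves in two; the side not containing
    the alphabetically first leaf is the canonical representative.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = labels[0]
    all_set = frozenset(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_set - below if anchor in below else below
        if 1 < len(side) < len(all_set) - 1:
            splits.add(side)
    return splits


def bipartition_separates(
    tree: dendropy.Tree, group_a: set[str], group_b: set[str]
) -> bool:
    """True iff an internal edge induces exactly the {A | B} leaf split."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if group_a & group_b:
        raise PhyloError("groups overlap")
    if group_a | group_b != leaves:
        raise PhyloError("groups do not partition the leaf set")
    labels = sorted(leaves)
    anchor = labels[0]
    target = frozenset(group_b if anchor in group_a else group_a)
    if len(target) < 2 or len(target) > len(leaves) - 2:
        # a trivial (single-leaf) split is always present in a binary tree
        return True
    return target in leaf_bipartitions(tree)


def bootstrap_supports(
    aln: MultipleAlignment,
    model: str = "wag-ml",
    n_reps: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with internal-node bootstrap supports (percent).

    Columns are resampled with replacement n_reps times; support of an
    internal edge is the percentage of replicate NJ trees containing
    its bipartition.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    point = nj_tree(pairwise_distance(aln, model))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    ncol = aln.column_count
    enc = _encode(aln)
    ids = list(aln.ids)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_tree(_distance_from_encoded(enc[:, cols], ids, model))
        for split in leaf_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    labels = sorted(lf.taxon.label for lf in point.leaf_node_iter())
    anchor = labels[0]
    all_set = frozenset(labels)
    for node in point.preorder_node_iter():
        if node.is_leaf() or node is point.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_set - below if anchor in below else below
        if 1 < len(side) < len(all_set) - 1:
            support = 100.0 * counts.get(side, 0) / n_reps
            node.label = f"{support:g}"
    return point


def edge_support(tree: dendropy.Tree, group_a: set[str], group_b: set[str]) -> float | None:
    """Bootstrap support (percent) of the edge separating A from B, if any."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    labels = sorted(leaves)
    anchor = labels[0]
    all_set = frozenset(labels)
    target = frozenset(group_b if anchor in group_a else group_a)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_set - below if anchor in below else below
        if side == target and node.label is not None:
            return float(node.label)
    return None


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(labels)
    taxa = {t.label: t for t in tree.taxon_namespace}
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, out)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
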