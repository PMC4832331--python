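"""Synthetic fixtures: tree-evolved families, context tables, toy decamers.

Generates the three kinds of input the downstream stages consume,
with planted ground truth so every stage is testable end to end:

* two sequence groups evolved on a shared tree, with group-specific
  conserved residues planted in the two C-terminal signature regions
  (the Y697-vs-K697 dimorphism is in the defaults);
* gene-neighborhood tables matching each group's genetic environment
  (cadB operon vs accA/yaeR flanks), with optional injected
  annotation mislabels and the injection log returned for audits;
* D5-symmetric toy decamers of five Gaussian-cloud domains, whose
  C-terminal domain is displaced by a known rigid swing/stretch.

All outputs are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment import AMINO_ACIDS, GAP, MultipleAlignment
from .genome_context import Neighbor, NeighborhoodRecord
from .structcompare import DomainPartition, StructureModel
from .substitution_models import (
    WAG_FREQS,
    uniform_transition_probs,
    wag_transition_probs,
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trees


def sample_tree(n_taxa: int, height: float, seed: int,
                prefix: str = "t") -> dendropy.Tree:
    """Random rooted binary tree with positive branch lengths.

    Topology by random sequential joins; edge lengths exponential with
    mean height / log2(n), so root-to-tip paths average ~`height`
    expected substitutions per site.
    """
    if n_taxa < 3:
        raise SyntheticError("sample_tree needs n_taxa >= 3")
    if height <= 0:
        raise SyntheticError("tree height must be positive")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1:03d}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    pool = []
    scale = height / max(np.log2(n_taxa), 1.0)
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.edge.length = float(rng.exponential(scale))
        pool.append(node)
    while len(pool) > 1:
        i = int(rng.integers(len(pool)))
        a = pool.pop(i)
        j = int(rng.integers(len(pool)))
        b = pool.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.exponential(scale))
        pool.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = pool[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def sample_two_group_tree(
    n_per_group: int, height: float, separation: float, seed: int
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Two clades (taxa A*/B*) joined by an internal branch.

    `separation` is the expected substitutions/site between the two
    group ancestors. Returns (tree, taxon -> group label in {A, B}).
    """
    sub_a = sample_tree(n_per_group, height, seed * 2 + 1, prefix="A")
    sub_b = sample_tree(n_per_group, height, seed * 2 + 2, prefix="B")
    labels = [t.label for t in sub_a.taxon_namespace] + [
        t.label for t in sub_b.taxon_namespace
    ]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def _clone(node, tns):
        new = dendropy.Node()
        if node.taxon is not None:
            new.taxon = tns.get_taxon(node.taxon.label)
        new.edge.length = node.edge.length
        for child in node.child_nodes():
            new.add_child(_clone(child, tns))
        return new

    root = dendropy.Node()
    ra = _clone(sub_a.seed_node, taxa)
    rb = _clone(sub_b.seed_node, taxa)
    root.add_child(ra)
    root.add_child(rb)
    ra.edge.length = separation / 2.0
    rb.edge.length = separation / 2.0
    tree.seed_node = root
    tree.is_rooted = True
    groups = {lab: lab[0] for lab in labels}
    return tree, groups


# ---------------------------------------------------------------------------
# sequence evolution with planted signatures

#: Disjoint (group A, group B) residue pairs cycled over signature
#: positions; position 697 is pinned to (Y, K), mirroring the strict
#: tyrosine/lysine dimorphism of the two natural groups.
_SIGNATURE_PAIR_CYCLE = [
    ("F", "L"), ("D", "K"), ("S", "A"), ("R", "E"), ("N", "G"),
    ("W", "M"), ("T", "V"), ("Q", "I"), ("H", "P"), ("C", "Y"),
]


def default_signature_residues(
    regions: tuple[tuple[int, int], ...],
) -> dict[int, tuple[frozenset, frozenset]]:
    out: dict[int, tuple[frozenset, frozenset]] = {}
    k = 0
    for start, end in regions:
        for pos in range(start, end + 1):
            if pos == 697:
                out[pos] = (frozenset("Y"), frozenset("K"))
            else:
                a, b = _SIGNATURE_PAIR_CYCLE[k % len(_SIGNATURE_PAIR_CYCLE)]
                out[pos] = (frozenset(a), frozenset(b))
                k += 1
    return out


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the two-group family simulation.

    Defaults mirror the natural dataset: 11 taxa per group (22 in
    all), full-length 715-residue proteins, signature regions 631–640
    and 697–715 with disjoint group-specific residues (Y/K at 697).
    """

    n_taxa_per_group: int = 11
    tree_height: float = 0.5
    group_separation: float = 0.5
    sequence_length: int = 715
    signature_regions: tuple[tuple[int, int], ...] = ((631, 640), (697, 715))
    group_signature_residues: dict[int, tuple[frozenset, frozenset]] | None = None
    background_model: str = "uniform"  # "uniform" | "wag"
    indel_rate: float = 0.0
    seed: int = 0

    def resolved_signature(self) -> dict[int, tuple[frozenset, frozenset]]:
        table = self.group_signature_residues or default_signature_residues(
            self.signature_regions
        )
        for pos, (sa, sb) in table.items():
            if sa & sb:
                raise SyntheticError(
                    f"signature residue sets overlap at position {pos}"
                )
            if pos < 1 or pos > self.sequence_length:
                raise SyntheticError(
                    f"signature position {pos} outside sequence length"
                )
        return table

    def validate(self) -> None:
        if self.n_taxa_per_group < 2:
            raise SyntheticError("need at least 2 taxa per group")
        if not 0.0 <= self.indel_rate < 1.0:
            raise SyntheticError("indel_rate must be in [0, 1)")
        if self.background_model not in {"uniform", "wag"}:
            raise SyntheticError(f"unknown background model {self.background_model!r}")
        for start, end in self.signature_regions:
            if start < 1 or end > self.sequence_length or end < start:
                raise SyntheticError(
                    f"signature region ({start}, {end}) outside sequence"
                )
        self.resolved_signature()


def _transition(model: str, t: float) -> np.ndarray:
    # PAML-order matrices re-indexed to the alphabetical AA order
    if model == "wag":
        p = wag_transition_probs(t)
    else:
        p = uniform_transition_probs(t)
    from .substitution_models import PAML_ORDER

    perm = [PAML_ORDER.index(a) for a in AMINO_ACIDS]
    return p[np.ix_(perm, perm)]


def _stationary(model: str) -> np.ndarray:
    if model == "wag":
        from .substitution_models import PAML_ORDER

        perm = [PAML_ORDER.index(a) for a in AMINO_ACIDS]
        return WAG_FREQS[perm]
    return np.full(20, 1.0 / 20.0)


def evolve_alignment(
    tree: dendropy.Tree,
    params: SimulationParams,
    group_labels: dict[str, str] | None = None,
) -> MultipleAlignment:
    """Evolve one sequence per leaf; plant group signatures at leaves.

    Non-signature columns evolve under the background model along the
    tree; signature columns are drawn per leaf from the leaf group's
    residue set (group A = label "A", group B = label "B"). With
    indel_rate > 0, non-signature columns are deleted per leaf at that
    rate (gaps in the returned true alignment).
    """
    params.validate()
    length = params.sequence_length
    signature = params.resolved_signature()
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if group_labels is None:
        group_labels = {lab: lab[0] for lab in leaves}
    for lab in leaves:
        if group_labels.get(lab) not in {"A", "B"}:
            raise SyntheticError(f"leaf {lab!r} lacks an A/B group label")

    rng = np.random.default_rng(params.seed)
    stationary = _stationary(params.background_model)
    root_seq = rng.choice(20, size=length, p=stationary)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        if t <= 0:
            child = parent_seq.copy()
        else:
            p = _transition(params.background_model, t)
            cum = p.cumsum(axis=1)[parent_seq]
            u = rng.random(length)
            child = np.minimum(
                (u[:, None] > cum).sum(axis=1), 19
            ).astype(root_seq.dtype)
        seqs[id(node)] = child

    sig_positions = sorted(signature)
    rows, ids = [], []
    for lf in tree.leaf_node_iter():
        lab = lf.taxon.label
        arr = seqs[id(lf)].copy()
        chars = [AMINO_ACIDS[k] for k in arr]
        gi = 0 if group_labels[lab] == "A" else 1
        for pos in sig_positions:
            allowed = sorted(signature[pos][gi])
            chars[pos - 1] = allowed[int(rng.integers(len(allowed)))]
        if params.indel_rate > 0:
            sigset = set(sig_positions)
            drop = rng.random(length) < params.indel_rate
            for j in range(length):
                if drop[j] and (j + 1) not in sigset:
                    chars[j] = GAP
        ids.append(lab)
        rows.append("".join(chars))
    return MultipleAlignment(ids, rows)


def simulate_family(
    params: SimulationParams,
) -> tuple[dendropy.Tree, dict[str, str], MultipleAlignment]:
    """Two-group tree + labels + evolved alignment, in one call."""
    tree, groups = sample_two_group_tree(
        params.n_taxa_per_group, params.tree_height,
        params.group_separation, params.seed,
    )
    aln = evolve_alignment(tree, params, groups)
    return tree, groups, aln


# ---------------------------------------------------------------------------
# neighborhood tables


def gen_neighborhood_table(
    leaves: list[str],
    group_labels: dict[str, str],
    seed: int,
    mislabel_rate: float = 0.0,
) -> tuple[list[NeighborhoodRecord], list[str]]:
    """Context records consistent with each leaf's group.

    Group A gets a same-strand operonic cadB partner (ldcI-like
    environment); group B gets accA/yaeR flanks (ldcC-like). With
    mislabel_rate > 0, stated annotations are flipped at that rate;
    the flipped gene_ids are returned as the injection log.
    """
    missing = [lab for lab in leaves if lab not in group_labels]
    if missing:
        raise SyntheticError(f"leaves without group label: {missing}")
    rng = np.random.default_rng(seed)
    records, injected = [], []
    for lab in leaves:
        gid = f"ldc_{lab}"
        group = group_labels[lab]
        strand = "+" if rng.random() < 0.5 else "-"
        if group == "A":
            neighbors = [
                Neighbor("cadB", strand, True),
                Neighbor("yjdC", "+" if rng.random() < 0.5 else "-", False),
            ]
            stated = "ldcI"
        else:
            flip = rng.random() < 0.5
            up, down = ("accA", "yaeR") if not flip else ("yaeR", "accA")
            neighbors = [
                Neighbor(up, "+" if rng.random() < 0.5 else "-", False),
                Neighbor(down, "+" if rng.random() < 0.5 else "-", False),
            ]
            stated = "ldcC"
        if mislabel_rate > 0 and rng.random() < mislabel_rate:
            stated = "ldcC" if stated == "ldcI" else "ldcI"
            injected.append(gid)
        records.append(NeighborhoodRecord(gid, lab, strand, neighbors, stated))
    return records, injected


# ---------------------------------------------------------------------------
# toy decamers


@dataclass(frozen=True)
class ToyDecamerSpec:
    """A D5 decamer of five Gaussian-cloud domains with a known CTD move."""

    points_per_domain: int = 8
    ctd_swing_angle: float = 0.0  # degrees, about swing_axis through CTD centroid
    ctd_stretch: float = 0.0  # Å, radial (local +x) translation
    swing_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    ring_radius: float = 40.0
    domain_spread: float = 3.0
    seed: int = 0
    domain_layout: dict[str, np.ndarray] | None = None

    def partition(self) -> DomainPartition:
        p = self.points_per_domain
        names = ["wing", "linker", "plp_sd", "subdomain4", "ctd"]
        intervals = tuple(
            (name, i * p + 1, (i + 1) * p) for i, name in enumerate(names)
        )
        return DomainPartition(intervals)


_DOMAIN_CENTROIDS = {
    "wing": np.array([-12.0, 0.0, 6.0]),
    "linker": np.array([-6.0, 3.0, 2.0]),
    "plp_sd": np.array([0.0, -2.0, 0.0]),
    "subdomain4": np.array([7.0, 2.0, -3.0]),
    "ctd": np.array([15.0, -1.0, -6.0]),
}


def _rotation_about(axis: np.ndarray, degrees: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(degrees) * axis).as_matrix()


def gen_toy_decamer(spec: ToyDecamerSpec) -> tuple[StructureModel, StructureModel]:
    """(reference, moved) toy decamers differing by a rigid CTD move.

    The monomer is five Gaussian point clouds; ten copies are placed
    with exact D5 symmetry (5-fold about z, flip about x). The moved
    copy applies, in each monomer's local frame, a rotation of
    ctd_swing_angle degrees about swing_axis through the CTD centroid
    followed by a ctd_stretch translation along local +x (radially
    outward), to CTD points only.
    """
    if spec.points_per_domain < 3:
        raise SyntheticError("points_per_domain must be >= 3")
    rng = np.random.default_rng(spec.seed)
    names = ["wing", "linker", "plp_sd", "subdomain4", "ctd"]
    clouds = {}
    for name in names:
        if spec.domain_layout and name in spec.domain_layout:
            pts = np.asarray(spec.domain_layout[name], float)
            if pts.shape != (spec.points_per_domain, 3):
                raise SyntheticError(f"domain_layout[{name!r}] has wrong shape")
        else:
            pts = _DOMAIN_CENTROIDS[name] + rng.normal(
                0.0, spec.domain_spread, size=(spec.points_per_domain, 3)
            )
        sing = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sing[1] < 1e-8:
            raise SyntheticError(f"degenerate (collinear) domain template {name!r}")
        clouds[name] = pts

    monomer_ref = np.concatenate([clouds[n] for n in names])
    ctd = clouds["ctd"]
    ctd_centroid = ctd.mean(axis=0)
    rot = _rotation_about(np.asarray(spec.swing_axis), spec.ctd_swing_angle)
    ctd_moved = (ctd - ctd_centroid) @ rot.T + ctd_centroid
    ctd_moved = ctd_moved + np.array([spec.ctd_stretch, 0.0, 0.0])
    monomer_moved = np.concatenate(
        [clouds[n] if n != "ctd" else ctd_moved for n in names]
    )

    chains = "ABCDEFGHIJ"
    flip = _rotation_about(np.array([1.0, 0.0, 0.0]), 180.0)
    offset = np.array([spec.ring_radius, 0.0, 0.0])

    def place(monomer: np.ndarray) -> dict[str, dict[int, np.ndarray]]:
        out = {}
        for k in range(10):
            ring, pos = divmod(k, 5)
            rz = _rotation_about(np.array([0.0, 0.0, 1.0]), 72.0 * pos)
            local = monomer + offset
            if ring == 1:
                local = local @ flip.T
            placed = local @ rz.T
            out[chains[k]] = {i + 1: placed[i] for i in range(len(placed))}
        return out

    ref = StructureModel("toy-reference", place(monomer_ref))
    moved = StructureModel("toy-moved", place(monomer_moved))
    return ref, moved


def expected_ctd_in_context_rmsd(spec: ToyDecamerSpec) -> float:
    """Brute-force oracle: RMS displacement of the CTD template points
    under the stated swing+stretch, computed by explicit point
    arithmetic (no superposition code involved)."""
    ref, moved = gen_toy_decamer(spec)
    part = spec.partition()
    (_, start, end) = next(iv for iv in part.intervals if iv[0] == "ctd")
    disp = []
    for c in ref.chains:
        for n in range(start, end + 1):
            disp.append(np.sum((ref.chains[c][n] - moved.chains[c][n]) ** 2))
    return float(np.sqrt(np.mean(disp)))


# ---------------------------------------------------------------------------
# bundle writer


def write_family(
    out_dir,
    params: SimulationParams,
    mislabel_rate: float = 0.0,
) -> dict[str, str]:
    """Simulate a family and write FASTA/TSV/Newick (+ injection log)."""
    import json
    from pathlib import Path

    from . import genome_context
    from .alignment import write_alignment_fasta, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, groups, aln = simulate_family(params)
    records, injected = gen_neighborhood_table(
        list(aln.ids), groups, params.seed + 1, mislabel_rate
    )
    write_fasta(aln.to_records(), out / "sequences.fasta")
    write_alignment_fasta(aln, out / "true_alignment.fasta")
    genome_context.write_tsv(records, out / "neighborhoods.tsv")
    tree.write(path=str(out / "true_tree.nwk"), schema="newick")
    (out / "truth.json").write_text(
        json.dumps({"groups": groups, "mislabelled": injected}, indent=2)
    )
    return {
        "sequences": str(out / "sequences.fasta"),
        "alignment": str(out / "true_alignment.fasta"),
        "neighborhoods": str(out / "neighborhoods.tsv"),
        "tree": str(out / "true_tree.nwk"),
        "truth": str(out / "truth.json"),
    }
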