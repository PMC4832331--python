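"""Cα-level structural comparison of decamer models by domain.

Two RMSD flavours are distinguished: the in-context RMSD of a domain
after ONE global superposition (whole decamer by default, per monomer
optionally) with no per-domain refit, and RMSD_min, the RMSD after an
optimal rigid-body superposition of the domain itself. Rigid-body
domain motions therefore show up as in-context RMSD >> RMSD_min ≈ 0.
The five-domain partition follows E. coli LdcI numbering: wing 1–129,
linker 130–183, PLP-binding subdomain 184–417, subdomain 4 418–563,
C-terminal domain 564–715.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import alignment as _aln

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    pass


@dataclass
class StructureModel:
    """Per-residue Cα coordinates keyed by (chain id, residue number)."""

    model_id: str
    chains: dict[str, dict[int, np.ndarray]]
    residue_names: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self):
        for cid, residues in self.chains.items():
            for num, xyz in residues.items():
                xyz = np.asarray(xyz, dtype=float)
                if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                    raise StructureError(
                        f"bad coordinate for {cid}/{num} in {self.model_id!r}"
                    )
                residues[num] = xyz

    @property
    def chain_ids(self) -> list[str]:
        return sorted(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def coords(self) -> np.ndarray:
        return np.array(
            [
                self.chains[c][n]
                for c in self.chain_ids
                for n in sorted(self.chains[c])
            ]
        )

    def sequence(self, chain_id: str) -> str:
        names = self.residue_names.get(chain_id, {})
        return "".join(
            names.get(n, "X") for n in sorted(self.chains[chain_id])
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        new = {
            c: {n: rotation @ xyz + translation for n, xyz in res.items()}
            for c, res in self.chains.items()
        }
        return StructureModel(self.model_id, new, self.residue_names)


@dataclass(frozen=True)
class DomainPartition:
    """Named, disjoint, contiguous residue-number intervals."""

    intervals: tuple[tuple[str, int, int], ...] = (
        ("wing", 1, 129),
        ("linker", 130, 183),
        ("plp_sd", 184, 417),
        ("subdomain4", 418, 563),
        ("ctd", 564, 715),
    )

    def __post_init__(self):
        prev_end = 0
        for name, start, end in self.intervals:
            if start != prev_end + 1 or end < start:
                raise StructureError(
                    f"domain intervals must be ordered and contiguous ({name})"
                )
            prev_end = end

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.intervals]

    def domain_of(self, residue_number: int) -> str | None:
        for name, start, end in self.intervals:
            if start <= residue_number <= end:
                return name
        return None

    @property
    def core_domains(self) -> tuple[str, ...]:
        """The core = linker + PLP-SD + subdomain 4."""
        return ("linker", "plp_sd", "subdomain4")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# IO


def read_structure(path, model_id: str | None = None) -> StructureModel:
    """Read Cα coordinates from a PDB or mmCIF file.

    Altlocs resolve to the highest-occupancy conformer (ties to 'A');
    insertion codes are rejected.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    chains: dict[str, dict[int, np.ndarray]] = {}
    names: dict[str, dict[int, str]] = {}
    for chain in model:
        cdict: dict[int, np.ndarray] = {}
        ndict: dict[int, str] = {}
        best_occ: dict[int, float] = {}
        for residue in chain:
            if residue.seqid.icode not in ("", " "):
                raise StructureError(
                    f"insertion code {residue.seqid.icode!r} at "
                    f"{chain.name}/{residue.seqid.num} not supported"
                )
            num = residue.seqid.num
            for atom in residue:
                if atom.name != "CA" or atom.element.name not in ("C", ""):
                    continue
                occ = atom.occ
                key = (occ, -ord(atom.altloc or "A"))
                prev = best_occ.get(num)
                if prev is None or key > prev:
                    best_occ[num] = key
                    cdict[num] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    ndict[num] = _THREE_TO_ONE.get(residue.name, "X")
        if cdict:
            chains[chain.name] = cdict
            names[chain.name] = ndict
    if not chains:
        raise StructureError(f"no Cα atoms found in {path}")
    return StructureModel(model_id or st.name or str(path), chains, names)


def write_ca_pdb(model: StructureModel, path) -> None:
    """Write a Cα-only PDB file (plain text, one ATOM record per residue)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    serial = 1
    with open(path, "w") as fh:
        for cid in model.chain_ids:
            names = model.residue_names.get(cid, {})
            for num in sorted(model.chains[cid]):
                x, y, z = model.chains[cid][num]
                res3 = one_to_three.get(names.get(num, "G"), "GLY")
                fh.write(
                    f"ATOM  {serial:5d}  CA  {res3} {cid[:1]}{num:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def write_ca_mmcif(model: StructureModel, path) -> None:
    """Write the same Cα-only model in mmCIF format via gemmi."""
    st = gemmi.Structure()
    st.name = model.model_id
    md = gemmi.Model("1")
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    for cid in model.chain_ids:
        ch = gemmi.Chain(cid)
        names = model.residue_names.get(cid, {})
        for num in sorted(model.chains[cid]):
            res = gemmi.Residue()
            res.name = one_to_three.get(names.get(num, "G"), "GLY")
            res.seqid = gemmi.SeqId(num, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = model.chains[cid][num]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            res.add_atom(atom)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto target.

    Proper rotation only (no reflection). Raises on size mismatch or
    (near-)collinear point sets, where the optimal rotation about the
    common axis is undefined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise StructureError("coordinate sets must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise StructureError("superposition needs at least 3 points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    m0, t0 = mobile - mc, target - tc
    sing_m = np.linalg.svd(m0, compute_uv=False)
    sing_t = np.linalg.svd(t0, compute_uv=False)
    scale = max(sing_m[0], sing_t[0], 1e-12)
    if sing_m[1] / scale < 1e-8 and sing_t[1] / scale < 1e-8:
        raise StructureError("degenerate (collinear) point sets")
    rot, rssd = Rotation.align_vectors(t0, m0)
    rmat = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(n)
    translation = tc - rmat @ mc
    return SuperpositionResult(rmat, translation, rmsd, n)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between matched coordinate rows."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# residue pairing


def pair_residues(
    a: StructureModel,
    b: StructureModel,
    mode: str = "same-numbering",
) -> list[tuple[str, str, int, int]]:
    """Matched Cα list [(chain_a, chain_b, resnum_a, resnum_b), ...].

    same-numbering pairs equal residue numbers in order-matched chains;
    sequence-aligned pairs chains via global sequence alignment and
    drops gapped columns.
    """
    if not a.chains or not b.chains:
        raise StructureError("empty structure model")
    if len(a.chain_ids) != len(b.chain_ids):
        raise StructureError("models have different numbers of chains")
    pairs: list[tuple[str, str, int, int]] = []
    for ca, cb in zip(a.chain_ids, b.chain_ids):
        if mode == "same-numbering":
            shared = sorted(set(a.chains[ca]) & set(b.chains[cb]))
            pairs.extend((ca, cb, n, n) for n in shared)
        elif mode == "sequence-aligned":
            nums_a, nums_b = sorted(a.chains[ca]), sorted(b.chains[cb])
            ra = _aln.SequenceRecord(f"a:{ca}", a.sequence(ca))
            rb = _aln.SequenceRecord(f"b:{cb}", b.sequence(cb))
            pw = _aln.global_align(ra, rb)
            ia = ib = 0
            for x, y in pw.columns:
                if x != _aln.GAP and y != _aln.GAP:
                    pairs.append((ca, cb, nums_a[ia], nums_b[ib]))
                if x != _aln.GAP:
                    ia += 1
                if y != _aln.GAP:
                    ib += 1
        else:
            raise StructureError(f"unknown pairing mode {mode!r}")
    if len(pairs) < 3:
        raise StructureError("insufficient residue overlap between models")
    return pairs


def _pair_coords(a, b, pairs):
    xa = np.array([a.chains[ca][na] for ca, cb, na, nb in pairs])
    xb = np.array([b.chains[cb][nb] for ca, cb, na, nb in pairs])
    return xa, xb


# ---------------------------------------------------------------------------
# the domain RMSD report


@dataclass
class DomainRMSDReport:
    pair_id: str
    table: pd.DataFrame  # monomer, domain, in_context_rmsd, rmsd_min, n_residues
    global_fit_scope: str

    def summary(self) -> pd.DataFrame:
        """Min/max over monomers per domain (the range phrasing of results)."""
        g = self.table.groupby("domain", sort=False)
        out = g.agg(
            in_context_min=("in_context_rmsd", "min"),
            in_context_max=("in_context_rmsd", "max"),
            rmsd_min_min=("rmsd_min", "min"),
            rmsd_min_max=("rmsd_min", "max"),
        )
        return out.reset_index()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def text_summary(self) -> str:
        lines = [f"Domain RMSD report: {self.pair_id} (scope={self.global_fit_scope})"]
        for row in self.summary().itertuples(index=False):
            lines.append(
                f"  {row.domain:<11s} in-context {row.in_context_min:.2f}–"
                f"{row.in_context_max:.2f} Å, min {row.rmsd_min_min:.2f}–"
                f"{row.rmsd_min_max:.2f} Å"
            )
        return "\n".join(lines)


def domain_rmsd_report(
    a: StructureModel,
    b: StructureModel,
    partition: DomainPartition = DomainPartition(),
    global_fit_scope: str = "decamer",
    pairing_mode: str = "same-numbering",
) -> DomainRMSDReport:
    """Per-monomer, per-domain in-context RMSD and RMSD_min of b vs a.

    in-context: one global superposition at the stated scope (decamer =
    all paired Cα of the assembly; monomer = each chain pair fitted
    separately), then plain RMSD per domain with no refit. RMSD_min:
    per-domain optimal superposition.
    """
    if global_fit_scope not in {"decamer", "monomer"}:
        raise StructureError(f"unknown global fit scope {global_fit_scope!r}")
    pairs = pair_residues(a, b, pairing_mode)
    rows = []
    if global_fit_scope == "decamer":
        xa, xb = _pair_coords(a, b, pairs)
        fit = kabsch_superpose(xb, xa)
        xb_fit = fit.apply(xb)
        coords_fit = dict(zip(pairs, xb_fit))
    chain_pairs = sorted({(ca, cb) for ca, cb, _, _ in pairs})
    for ca, cb in chain_pairs:
        mono = [p for p in pairs if p[0] == ca and p[1] == cb]
        xa_m, xb_m = _pair_coords(a, b, mono)
        if global_fit_scope == "monomer":
            fit_m = kabsch_superpose(xb_m, xa_m)
            xb_m_fit = fit_m.apply(xb_m)
        else:
            xb_m_fit = np.array([coords_fit[p] for p in mono])
        domain_keys = np.array([partition.domain_of(na) or "" for _, _, na, _ in mono])
        for name in partition.names:
            sel = domain_keys == name
            n_dom = int(sel.sum())
            if n_dom == 0:
                continue
            in_context = rmsd_between(xa_m[sel], xb_m_fit[sel])
            if n_dom >= 3:
                try:
                    rmin = kabsch_superpose(xb_m[sel], xa_m[sel]).rmsd
                except StructureError:
                    rmin = in_context
            else:
                rmin = in_context
            rmin = min(rmin, in_context)
            rows.append(
                dict(
                    monomer=f"{ca}/{cb}", domain=name,
                    in_context_rmsd=in_context, rmsd_min=rmin,
                    n_residues=n_dom,
                )
            )
    table = pd.DataFrame(rows)
    report = DomainRMSDReport(f"{a.model_id} vs {b.model_id}", table, global_fit_scope)
    bad = table[table.rmsd_min > table.in_context_rmsd + 1e-9]
    if len(bad):  # pragma: no cover - defensive
        raise StructureError("rmsd_min exceeded in-context RMSD")
    return report


def principal_axis(model: StructureModel) -> np.ndarray:
    """Unit symmetry axis estimate: principal inertia axis of all Cα."""
    x = model.coords()
    x0 = x - x.mean(axis=0)
    cov = x0.T @ x0
    w, v = np.linalg.eigh(cov)
    # the 5-fold axis is the unique inertia direction: the eigenvalue
    # farthest from the (degenerate) pair of in-plane ones
    axis = v[:, np.argmax(np.abs(w - np.median(w)))]
    return axis / np.linalg.norm(axis)


def segment_centroid_shift(
    a: StructureModel,
    b: StructureModel,
    segment: tuple[int, int],
    global_fit_scope: str = "decamer",
    axis: np.ndarray | None = None,
    pairing_mode: str = "same-numbering",
) -> pd.DataFrame:
    """Per-monomer centroid displacement of a residue segment.

    After the global superposition (scope "decamer", "monomer" or
    "none" for pre-superposed models), reports the Euclidean centroid
    shift of the segment and, given (or estimating) the D5 axis, the
    radial component (change of distance from the axis; positive =
    away from the axis).
    """
    if global_fit_scope not in {"decamer", "monomer", "none"}:
        raise StructureError(f"unknown global fit scope {global_fit_scope!r}")
    start, end = segment
    pairs = pair_residues(a, b, pairing_mode)
    xa, xb = _pair_coords(a, b, pairs)
    if global_fit_scope == "decamer":
        fit = kabsch_superpose(xb, xa)
        xb = fit.apply(xb)
    if axis is None:
        axis = principal_axis(a)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    center = np.array([a.chains[c][n] for c, _, n, _ in pairs]).mean(axis=0)
    rows = []
    chain_pairs = sorted({(ca, cb) for ca, cb, _, _ in pairs})
    for ca, cb in chain_pairs:
        idx = [
            k
            for k, (pca, pcb, na, nb) in enumerate(pairs)
            if pca == ca and pcb == cb and start <= na <= end
        ]
        if not idx:
            raise StructureError(
                f"segment {segment} not paired on monomer {ca}/{cb}"
            )
        sub_a, sub_b = xa[idx], xb[idx]
        if global_fit_scope == "monomer":
            mono = [k for k, (pca, pcb, _, _) in enumerate(pairs) if pca == ca and pcb == cb]
            fit_m = kabsch_superpose(xb[mono], xa[mono])
            sub_b = fit_m.apply(xb[idx])
        cen_a, cen_b = sub_a.mean(axis=0), sub_b.mean(axis=0)
        shift = float(np.linalg.norm(cen_b - cen_a))

        def radial_dist(p):
            rel = p - center
            return float(np.linalg.norm(rel - np.dot(rel, axis) * axis))

        rows.append(
            dict(
                monomer=f"{ca}/{cb}",
                centroid_shift=shift,
                radial_shift=radial_dist(cen_b) - radial_dist(cen_a),
                n_residues=len(idx),
            )
        )
    return pd.DataFrame(rows)
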