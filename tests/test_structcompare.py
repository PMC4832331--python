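"""Structure IO, Kabsch superposition, residue pairing, domain RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ldcsig.structcompare import (
    DomainPartition,
    StructureError,
    StructureModel,
    domain_rmsd_report,
    kabsch_superpose,
    pair_residues,
    principal_axis,
    read_structure,
    segment_centroid_shift,
    write_ca_mmcif,
    write_ca_pdb,
)
from ldcsig.synthetic import ToyDecamerSpec, gen_toy_decamer

from .oracles import horn_superpose


def _random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(0, 20, 3)


class TestIO:
    def test_pdb_roundtrip(self, tmp_path):
        spec = ToyDecamerSpec(points_per_domain=4, seed=5)
        ref, _ = gen_toy_decamer(spec)
        # quantise to the PDB 3-decimal grid so the round trip is exact
        quant = StructureModel(
            "q",
            {
                c: {n: np.round(xyz, 3) for n, xyz in res.items()}
                for c, res in ref.chains.items()
            },
        )
        path = tmp_path / "toy.pdb"
        write_ca_pdb(quant, path)
        back = read_structure(path)
        assert back.chain_ids == quant.chain_ids
        for c in quant.chains:
            for n, xyz in quant.chains[c].items():
                assert np.array_equal(back.chains[c][n], xyz)

    def test_mmcif_and_pdb_agree(self, tmp_path):
        spec = ToyDecamerSpec(points_per_domain=3, seed=2)
        ref, _ = gen_toy_decamer(spec)
        quant = StructureModel(
            "q",
            {
                c: {n: np.round(xyz, 3) for n, xyz in res.items()}
                for c, res in ref.chains.items()
            },
        )
        pdb, cif = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_ca_pdb(quant, pdb)
        write_ca_mmcif(quant, cif)
        from_pdb, from_cif = read_structure(pdb), read_structure(cif)
        assert from_pdb.chain_ids == from_cif.chain_ids
        for c in from_pdb.chains:
            assert from_pdb.chains[c].keys() == from_cif.chains[c].keys()
            for n in from_pdb.chains[c]:
                assert np.allclose(from_pdb.chains[c][n], from_cif.chains[c][n])

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "altloc.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  GLY A   2       1.000   1.000   1.000  1.00  0.00           C\n"
            "ATOM      4  CA  VAL A   3       2.000   1.000   1.000  1.00  0.00           C\n"
            "END\n"
        )
        model = read_structure(pdb)
        assert len(model.chains["A"]) == 3
        assert model.chains["A"][1][0] == pytest.approx(9.0)

    def test_insertion_code_rejected(self, tmp_path):
        pdb = tmp_path / "icode.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   1A      1.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(StructureError, match="insertion"):
            read_structure(pdb)

    def test_no_ca_atoms_rejected(self, tmp_path):
        pdb = tmp_path / "noca.pdb"
        pdb.write_text(
            "ATOM      1  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        with pytest.raises(StructureError, match="Cα|Ca|CA|atoms"):
            read_structure(pdb)


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        x = rng.normal(0, 5, (12, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_recovers_applied_transform(self, rng):
        x = rng.normal(0, 5, (15, 3))
        rot, trans = _random_rigid(rng)
        y = x @ rot.T + trans
        res = kabsch_superpose(x, y)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.rotation, rot, atol=1e-8)
        assert np.allclose(res.apply(x), y, atol=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(0, 5, (10, 3))
            y = rng.normal(0, 5, (10, 3))
            res = kabsch_superpose(x, y)
            _, rmsd_oracle = horn_superpose(x, y)
            assert res.rmsd == pytest.approx(rmsd_oracle, abs=1e-8)

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(StructureError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        with pytest.raises(StructureError, match="degenerate|collinear"):
            kabsch_superpose(line, line * 2.0)


class TestPairResidues:
    def test_identical_models_fully_paired(self):
        spec = ToyDecamerSpec(points_per_domain=4, seed=3)
        ref, _ = gen_toy_decamer(spec)
        pairs = pair_residues(ref, ref)
        assert len(pairs) == ref.n_residues

    def test_offset_numbering_overlap(self):
        coords_a = {i: np.array([i, 0.0, 0.0]) for i in range(1, 101)}
        coords_b = {i: np.array([i, 0.0, 0.0]) for i in range(51, 151)}
        a = StructureModel("a", {"A": coords_a})
        b = StructureModel("b", {"A": coords_b})
        pairs = pair_residues(a, b, "same-numbering")
        assert len(pairs) == 50
        assert {p[2] for p in pairs} == set(range(51, 101))

    def test_sequence_aligned_pairing_skips_indel(self):
        seq_a = "MKTAYIAKQRQISFVKSHFSRQ"
        seq_b = seq_a[:10] + seq_a[11:]  # one deletion
        a = StructureModel(
            "a",
            {"A": {i + 1: np.array([i, 0.0, 0.0]) for i in range(len(seq_a))}},
            {"A": {i + 1: c for i, c in enumerate(seq_a)}},
        )
        b = StructureModel(
            "b",
            {"A": {i + 1: np.array([i, 0.0, 0.0]) for i in range(len(seq_b))}},
            {"A": {i + 1: c for i, c in enumerate(seq_b)}},
        )
        pairs = pair_residues(a, b, "sequence-aligned")
        assert len(pairs) == len(seq_b)
        assert all(na != 11 for _, _, na, _ in pairs)


class TestDomainPartition:
    def test_default_matches_monomer_span(self):
        part = DomainPartition()
        assert part.names == ["wing", "linker", "plp_sd", "subdomain4", "ctd"]
        assert part.domain_of(1) == "wing"
        assert part.domain_of(129) == "wing"
        assert part.domain_of(130) == "linker"
        assert part.domain_of(417) == "plp_sd"
        assert part.domain_of(563) == "subdomain4"
        assert part.domain_of(715) == "ctd"
        assert part.domain_of(716) is None
        assert part.core_domains == ("linker", "plp_sd", "subdomain4")

    def test_non_contiguous_rejected(self):
        with pytest.raises(StructureError):
            DomainPartition((("a", 1, 10), ("b", 12, 20)))


class TestDomainRMSDReport:
    def test_self_comparison_all_zero(self, toy_decamer_pair):
        spec, ref, _ = toy_decamer_pair
        report = domain_rmsd_report(ref, ref, spec.partition())
        assert report.table.in_context_rmsd.max() < 1e-6
        assert report.table.rmsd_min.max() < 1e-6

    def test_ctd_translation_recovered(self, toy_decamer_pair):
        spec, ref, moved = toy_decamer_pair
        report = domain_rmsd_report(ref, moved, spec.partition(), "decamer")
        tab = report.table.set_index(["monomer", "domain"])
        ctd = report.table[report.table.domain == "ctd"]
        other = report.table[report.table.domain != "ctd"]
        assert ctd.in_context_rmsd.values == pytest.approx(4.0, abs=1e-6)
        assert ctd.rmsd_min.max() < 1e-6
        assert other.in_context_rmsd.max() < 1e-6

    def test_rmsd_min_never_exceeds_in_context(self, rng):
        spec = ToyDecamerSpec(points_per_domain=5, ctd_swing_angle=7.0,
                              ctd_stretch=2.0, seed=17)
        ref, moved = gen_toy_decamer(spec)
        # add noise so nothing is exactly rigid
        noisy = StructureModel(
            "noisy",
            {
                c: {n: xyz + rng.normal(0, 0.5, 3) for n, xyz in res.items()}
                for c, res in moved.chains.items()
            },
        )
        report = domain_rmsd_report(ref, noisy, spec.partition())
        assert (report.table.rmsd_min <= report.table.in_context_rmsd + 1e-9).all()

    def test_rigid_motion_nullity(self, toy_decamer_pair, rng):
        """Rigidly moving one whole model changes neither in-context nor
        minimum RMSDs."""
        spec, ref, moved = toy_decamer_pair
        rot, trans = _random_rigid(rng)
        moved2 = moved.transformed(rot, trans)
        r1 = domain_rmsd_report(ref, moved, spec.partition())
        r2 = domain_rmsd_report(ref, moved2, spec.partition())
        assert np.allclose(
            r1.table.in_context_rmsd, r2.table.in_context_rmsd, atol=1e-8
        )
        assert np.allclose(r1.table.rmsd_min, r2.table.rmsd_min, atol=1e-6)

    def test_monomer_scope_also_recovers_translation(self, toy_decamer_pair):
        spec, ref, moved = toy_decamer_pair
        report = domain_rmsd_report(ref, moved, spec.partition(), "monomer")
        ctd = report.table[report.table.domain == "ctd"]
        assert (ctd.rmsd_min < 1e-6).all()

    def test_summary_ranges(self, toy_decamer_pair):
        spec, ref, moved = toy_decamer_pair
        summary = domain_rmsd_report(ref, moved, spec.partition()).summary()
        row = summary[summary.domain == "ctd"].iloc[0]
        assert row.in_context_min == pytest.approx(4.0, abs=1e-6)
        assert row.in_context_max == pytest.approx(4.0, abs=1e-6)


class TestSegmentShift:
    def test_self_shift_zero(self, toy_decamer_pair):
        spec, ref, _ = toy_decamer_pair
        part = spec.partition()
        (_, start, end) = part.intervals[0]
        frame = segment_centroid_shift(ref, ref, (start, end))
        assert frame.centroid_shift.max() < 1e-6

    def test_three_four_five_translation(self):
        coords = {i: np.random.default_rng(1).normal(0, 5, 3) for i in range(1, 13)}
        a = StructureModel("a", {"A": dict(coords)})
        shifted = {
            i: (xyz + np.array([3.0, 4.0, 0.0]) if i <= 4 else xyz)
            for i, xyz in coords.items()
        }
        b = StructureModel("b", {"A": shifted})
        frame = segment_centroid_shift(a, b, (1, 4), global_fit_scope="none")
        assert frame.centroid_shift.iloc[0] == pytest.approx(5.0)

    def test_planted_radial_shift_recovered(self):
        spec = ToyDecamerSpec(points_per_domain=6, seed=23)
        ref, _ = gen_toy_decamer(spec)
        part = spec.partition()
        (_, start, end) = next(iv for iv in part.intervals if iv[0] == "plp_sd")
        axis = np.array([0.0, 0.0, 1.0])
        center = ref.coords().mean(axis=0)
        moved_chains = {}
        for c, res in ref.chains.items():
            seg = [res[n] for n in range(start, end + 1)]
            centroid = np.mean(seg, axis=0)
            radial = centroid - center
            radial -= np.dot(radial, axis) * axis
            radial /= np.linalg.norm(radial)
            moved_chains[c] = {
                n: (xyz + 3.5 * radial if start <= n <= end else xyz)
                for n, xyz in res.items()
            }
        moved = StructureModel("planted", moved_chains)
        frame = segment_centroid_shift(
            ref, moved, (start, end), global_fit_scope="none", axis=axis
        )
        assert frame.radial_shift.values == pytest.approx(3.5, abs=0.01)

    def test_principal_axis_of_ring(self):
        spec = ToyDecamerSpec(points_per_domain=6, seed=29)
        ref, _ = gen_toy_decamer(spec)
        axis = principal_axis(ref)
        assert abs(abs(axis[2]) - 1.0) < 0.05
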