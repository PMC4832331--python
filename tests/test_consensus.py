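"""Consensus profiles, signature extraction/classification, chimeras."""

import math

import numpy as np
import pytest

from ldcsig.alignment import (
    AMINO_ACIDS,
    MultipleAlignment,
    SequenceRecord,
    global_align,
    map_to_reference,
)
from ldcsig.consensus import (
    POLARITY_SCHEME,
    SignatureDefinition,
    SignatureError,
    SignatureString,
    build_consensus,
    build_signature_profiles,
    classify_by_signature,
    design_chimera,
    discriminating_positions,
    extract_signature,
)


@pytest.fixture()
def toy_alignment():
    rows = ["MYKA", "MYKC", "MKKA", "MKKC"]
    return MultipleAlignment([f"s{i}" for i in range(4)], rows)


class TestBuildConsensus:
    def test_hand_counted_frequencies(self, toy_alignment):
        prof = build_consensus(toy_alignment)["family"]
        y = AMINO_ACIDS.index("Y")
        k = AMINO_ACIDS.index("K")
        m = AMINO_ACIDS.index("M")
        assert prof.frequencies[0, m] == 1.0
        assert prof.frequencies[1, y] == pytest.approx(0.5)
        assert prof.frequencies[1, k] == pytest.approx(0.5)
        assert prof.frequencies[2, k] == 1.0
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_conservation_fully_conserved_column(self, toy_alignment):
        prof = build_consensus(toy_alignment)["family"]
        assert prof.conservation[0] == 1.0
        assert prof.conservation[1] == pytest.approx(0.5)

    def test_information_mode_max_bits(self):
        aln = MultipleAlignment(["a", "b"], ["YY", "YA"])
        prof = build_consensus(aln, mode="information")["family"]
        assert prof.conservation[0] == pytest.approx(math.log2(20))
        assert prof.conservation[1] < math.log2(20)

    def test_per_group_profiles(self, toy_alignment):
        labels = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        profs = build_consensus(toy_alignment, labels)
        assert set(profs) == {"family", "A", "B"}
        y = AMINO_ACIDS.index("Y")
        assert profs["A"].frequencies[1, y] == 1.0
        assert profs["B"].frequencies[1, y] == 0.0

    def test_conservation_monotone_in_max_frequency(self, rng):
        rows = ["".join(rng.choice(list(AMINO_ACIDS), 30)) for _ in range(12)]
        prof = build_consensus(MultipleAlignment([f"r{i}" for i in range(12)], rows))[
            "family"
        ]
        maxfreq = prof.frequencies[:, :20].max(axis=1)
        order = np.argsort(maxfreq)
        assert np.all(np.diff(prof.conservation[order]) >= -1e-12)

    def test_unlabelled_record_rejected(self, toy_alignment):
        with pytest.raises(SignatureError):
            build_consensus(toy_alignment, {"s0": "A"})


def test_polarity_scheme_total_and_disjoint():
    assert sorted(POLARITY_SCHEME) == sorted(AMINO_ACIDS)
    assert set(POLARITY_SCHEME.values()) == {
        "acidic", "basic", "hydrophilic", "hydrophobic",
    }


class TestExtractSignature:
    def test_reference_literal_residues(self, small_family):
        params, _, _, aln = small_family
        ref = aln.ids[0]
        refmap = map_to_reference(aln, ref)
        sigdef = SignatureDefinition(params.signature_regions)
        sig = extract_signature(aln.row(ref), refmap, sigdef)
        expected = "".join(
            aln.degapped(ref)[p - 1] for p in sigdef.positions
        )
        assert sig.residues == expected
        assert sig.positions == sigdef.positions

    def test_planted_group_residues(self, small_family):
        params, _, groups, aln = small_family
        refmap = map_to_reference(aln, aln.ids[0])
        sigdef = SignatureDefinition(params.signature_regions)
        table = params.resolved_signature()
        for rid, row in zip(aln.ids, aln.rows):
            sig = extract_signature(row, refmap, sigdef)
            gi = 0 if groups[rid] == "A" else 1
            for pos, c in zip(sig.positions, sig.residues):
                assert c in table[pos][gi]

    def test_gap_flagged(self):
        aln = MultipleAlignment(["r", "s"], ["MK-A", "MKCA"])
        refmap = map_to_reference(aln, "s")
        sig = extract_signature(aln.row("r"), refmap, SignatureDefinition(((3, 3),)))
        assert sig.residues == "-"
        assert sig.gapped_positions == [3]

    def test_unmapped_region_raises(self):
        aln = MultipleAlignment(["r"], ["MKA"])
        refmap = map_to_reference(aln, "r")
        with pytest.raises(SignatureError):
            extract_signature(aln.row("r"), refmap, SignatureDefinition(((10, 12),)))

    def test_overlapping_regions_rejected(self):
        with pytest.raises(SignatureError):
            SignatureDefinition(((631, 700), (697, 715)))


class TestClassifyBySignature:
    @pytest.fixture(scope="class")
    def trained(self):
        from ldcsig.synthetic import SimulationParams, simulate_family

        params = SimulationParams(
            n_taxa_per_group=8, sequence_length=120,
            signature_regions=((80, 85), (100, 110)), seed=21,
        )
        _, groups, aln = simulate_family(params)
        refmap = map_to_reference(aln, aln.ids[0])
        sigdef = SignatureDefinition(params.signature_regions)
        profiles = build_signature_profiles(aln, groups, refmap, sigdef)
        return params, groups, aln, refmap, sigdef, profiles

    def test_y697_vs_k697_rule(self):
        """A tyrosine at the dimorphic position calls the inducible-like
        group; a lysine calls the constitutive-like group."""
        from ldcsig.consensus import SignatureProfile

        freqs_y = np.zeros((1, 21)); freqs_y[0, AMINO_ACIDS.index("Y")] = 1.0
        freqs_k = np.zeros((1, 21)); freqs_k[0, AMINO_ACIDS.index("K")] = 1.0
        profiles = {
            "A": SignatureProfile("A", [697], freqs_y),
            "B": SignatureProfile("B", [697], freqs_k),
        }
        label_y, score_y = classify_by_signature(SignatureString([697], "Y"), profiles)
        label_k, score_k = classify_by_signature(SignatureString([697], "K"), profiles)
        assert label_y == "A" and score_y > 0
        assert label_k == "B" and score_k < 0

    def test_all_gap_signature_unknown(self, trained):
        *_, profiles = trained
        positions = profiles["A"].positions
        sig = SignatureString(positions, "-" * len(positions))
        label, score = classify_by_signature(sig, profiles)
        assert label == "unknown" and score == 0.0

    def test_group_swap_symmetry(self, trained):
        _, groups, aln, refmap, sigdef, profiles = trained
        from ldcsig.consensus import SignatureProfile

        swapped = {
            "A": SignatureProfile("A", profiles["B"].positions, profiles["B"].frequencies),
            "B": SignatureProfile("B", profiles["A"].positions, profiles["A"].frequencies),
        }
        sig = extract_signature(aln.rows[0], refmap, sigdef)
        label1, score1 = classify_by_signature(sig, profiles)
        label2, score2 = classify_by_signature(sig, swapped)
        assert {label1, label2} == {"A", "B"}
        assert score2 == pytest.approx(-score1)

    def test_leave_one_out_is_perfect(self, trained):
        params, groups, aln, refmap, sigdef, _ = trained
        for rid in aln.ids:
            train = {u: g for u, g in groups.items() if u != rid}
            rows = [aln.row(u) for u in aln.ids if u != rid]
            sub = MultipleAlignment([u for u in aln.ids if u != rid], rows)
            profiles = build_signature_profiles(sub, train, refmap, sigdef)
            sig = extract_signature(aln.row(rid), refmap, sigdef)
            label, _ = classify_by_signature(sig, profiles)
            assert label == groups[rid]

    def test_discriminating_positions_subset(self, trained):
        params, _, _, _, sigdef, profiles = trained
        disc = discriminating_positions(profiles)
        assert set(disc) <= set(sigdef.positions)
        assert disc  # planted disjoint sets must discriminate

    def test_length_mismatch_vs_missing_positions(self, trained):
        *_, profiles = trained
        # unknown positions are simply skipped -> unknown when nothing scores
        sig = SignatureString([9999], "Y")
        label, _ = classify_by_signature(sig, profiles)
        assert label == "unknown"


class TestDesignChimera:
    def test_self_swap_is_identity(self):
        s = SequenceRecord("s", "".join(AMINO_ACIDS) * 3)
        aln = global_align(s, s)
        result = design_chimera(s, s, aln, SignatureDefinition(((10, 20), (40, 50))))
        assert result.record.residues == s.residues

    def test_swap_changes_only_regions(self, rng):
        base = "".join(rng.choice(list(AMINO_ACIDS), 80))
        # donor differs by scattered substitutions, keeping the pairwise
        # alignment gap-free so positions map one to one
        donor = list(base)
        for pos in rng.choice(80, size=20, replace=False):
            donor[pos] = AMINO_ACIDS[(AMINO_ACIDS.index(donor[pos]) + 1) % 20]
        donor_seq = "".join(donor)
        a = SequenceRecord("a", base)
        b = SequenceRecord("b", donor_seq)
        sigdef = SignatureDefinition(((20, 30), (60, 70)))
        aln = global_align(a, b)
        assert "-" not in aln.aligned_a and "-" not in aln.aligned_b
        result = design_chimera(a, b, aln, sigdef)
        chim = result.record.residues
        for pos in range(1, 81):
            inside = any(s <= pos <= e for s, e in sigdef.regions)
            assert chim[pos - 1] == (donor_seq if inside else base)[pos - 1]

    def test_double_swap_restores_backbone_on_gap_free_regions(self):
        a = SequenceRecord("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        b = SequenceRecord("b", "MKTWYIGKQRNISFVESHFSRQLAERLGLIEVQ")
        sigdef = SignatureDefinition(((4, 8), (20, 25)))
        first = design_chimera(a, b, global_align(a, b), sigdef).record
        second = design_chimera(
            SequenceRecord("ab", first.residues), a,
            global_align(SequenceRecord("ab", first.residues), a), sigdef,
        ).record
        assert second.residues == a.residues

    def test_junction_report(self):
        a = SequenceRecord("a", "MKTAYIAKQRQISFVKSHFSRQ")
        b = SequenceRecord("b", "MKTWYIGKQRNISFVESHFSRQ")
        sigdef = SignatureDefinition(((4, 8),))
        result = design_chimera(a, b, global_align(a, b), sigdef)
        frame = result.junction_frame()
        assert frame.backbone_start.iloc[0] == 4
        assert frame.backbone_end.iloc[0] == 8

    def test_chimera_flips_signature_classification(self, trained_family_pair):
        """Swapping the β-sheet regions between a group-A and a group-B
        member flips the signature call, mirroring the RavA-binding
        phenotype swap of the chimeric constructs."""
        aln, groups, refmap, sigdef, profiles, rec_a, rec_b = trained_family_pair
        chim_ab = design_chimera(rec_a, rec_b, global_align(rec_a, rec_b), sigdef)
        chim_ba = design_chimera(rec_b, rec_a, global_align(rec_b, rec_a), sigdef)
        for chim, expected in ((chim_ab, "B"), (chim_ba, "A")):
            rec = chim.record
            pseudo = MultipleAlignment([rec.id], [rec.residues])
            sigmap = map_to_reference(pseudo, rec.id)
            sig = extract_signature(pseudo.rows[0], sigmap, sigdef)
            label, _ = classify_by_signature(sig, profiles)
            assert label == expected

    def test_donor_gap_region_fails(self):
        a = SequenceRecord("a", "MKTAYIAKQRQISFVKSHFSRQ")
        b = SequenceRecord("b", "MKTAYIAK")
        sigdef = SignatureDefinition(((15, 20),))
        with pytest.raises(SignatureError):
            design_chimera(a, b, global_align(a, b), sigdef)


@pytest.fixture(scope="module")
def trained_family_pair():
    from ldcsig.synthetic import SimulationParams, simulate_family

    # mild divergence so the pairwise alignment is gap-free, as for the
    # natural ~69%-identical protein pair the construct emulates
    params = SimulationParams(
        n_taxa_per_group=6, sequence_length=120, tree_height=0.15,
        group_separation=0.2, signature_regions=((80, 85), (100, 110)),
        seed=33,
    )
    _, groups, aln = simulate_family(params)
    refmap = map_to_reference(aln, aln.ids[0])
    sigdef = SignatureDefinition(params.signature_regions)
    profiles = build_signature_profiles(aln, groups, refmap, sigdef)
    recs = {r.id: r for r in aln.to_records()}
    rec_a = next(recs[i] for i in aln.ids if groups[i] == "A")
    rec_b = next(recs[i] for i in aln.ids if groups[i] == "B")
    return aln, groups, refmap, sigdef, profiles, rec_a, rec_b
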