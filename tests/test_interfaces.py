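import numpy as np
import pytest

from conftest import random_rotation
from ringscan import synthetic_data as synth
from ringscan.interfaces import (
    ContactParams,
    Selection,
    assign_contacts_to_regions,
    count_close_e3_residues,
    detect_backbone_hbonds,
    extract_contacts,
)
from ringscan.io_model import Alignment, Atom, Chain, Residue, Structure
from ringscan.structure_compare import SCRSegment


def brute_force_contacts(structure, e3_sel, e2_sel, params):
    """Independent all-atom-pair scan over the two selections."""
    pairs = set()
    for r3 in e3_sel.residues(structure):
        for r2 in e2_sel.residues(structure):
            best = min(
                (float(np.linalg.norm(a.xyz - b.xyz))
                 for a in r3.atoms if a.is_heavy
                 for b in r2.atoms if b.is_heavy),
                default=float("inf"),
            )
            if best <= params.contact_cutoff:
                tier = "close" if best <= params.close_cutoff else "contact"
                pairs.add((r3.label, r2.label, round(best, 9), tier))
    return pairs


def rigid_copy(structure, R, t):
    chains = []
    for ch in structure.chains:
        residues = [
            Residue(r.chain_id, r.seq_num, r.name3, [
                Atom(a.name, a.element, tuple(R @ a.xyz + t)) for a in r.atoms
            ], r.icode)
            for r in ch.residues
        ]
        chains.append(Chain(id=ch.id, residues=residues))
    return Structure(id=structure.id, chains=chains)


PLAN_10 = (
    (2.8, "CA", "CA"), (3.0, "CA", "CA"), (3.2, "CA", "CA"),
    (3.4, "CA", "CA"), (3.5, "CA", "CA"),                      # 5 close
    (3.6, "CA", "CA"), (3.8, "CA", "CA"), (4.0, "CA", "CA"),   # 3 contact
    (4.3, "CA", "CA"), (6.0, "CA", "CA"),                      # 2 beyond
)


class TestExtractContacts:
    def test_distant_chains_empty(self):
        st, _ = synth.gen_complex(
            synth.ComplexSpec(seed=1, pair_plan=((25.0, "CA", "CA"),),
                              spacing=60.0)
        )
        assert extract_contacts(st, Selection("E"), Selection("F")) == []

    def test_planted_tiers_recovered(self):
        st, truth = synth.gen_complex(synth.ComplexSpec(seed=2, pair_plan=PLAN_10))
        synth.check_complex_truth(st, truth)
        records = extract_contacts(st, Selection("E"), Selection("F"))
        assert len(records) == 8
        assert sum(r.tier == "close" for r in records) == 5
        assert count_close_e3_residues(records) == 5

    def test_boundary_exactly_four_is_contact_not_close(self):
        st, _ = synth.gen_complex(
            synth.ComplexSpec(seed=3, pair_plan=((4.0, "CA", "CA"),))
        )
        records = extract_contacts(st, Selection("E"), Selection("F"))
        assert len(records) == 1 and records[0].tier == "contact"

    def test_swapped_selections_mirror(self):
        st, _ = synth.gen_complex(synth.ComplexSpec(seed=4, pair_plan=PLAN_10))
        fwd = extract_contacts(st, Selection("E"), Selection("F"))
        rev = extract_contacts(st, Selection("F"), Selection("E"))
        fwd_pairs = {(r.e3_residue.label, r.e2_residue.label,
                      round(r.min_distance, 9)) for r in fwd}
        rev_pairs = {(r.e2_residue.label, r.e3_residue.label,
                      round(r.min_distance, 9)) for r in rev}
        assert fwd_pairs == rev_pairs

    def test_close_records_subset_of_contact_records(self):
        st, _ = synth.gen_complex(synth.ComplexSpec(seed=5, pair_plan=PLAN_10))
        strict = ContactParams(contact_cutoff=3.5, close_cutoff=3.5)
        loose = ContactParams()
        close_set = {(r.e3_residue.label, r.e2_residue.label)
                     for r in extract_contacts(st, Selection("E"), Selection("F"),
                                               strict)}
        all_set = {(r.e3_residue.label, r.e2_residue.label)
                   for r in extract_contacts(st, Selection("E"), Selection("F"),
                                             loose)}
        assert close_set <= all_set

    def test_matches_brute_force_on_random_systems(self):
        rng = np.random.default_rng(44)
        params = ContactParams()
        for _ in range(200):
            chains = []
            for cid in ("E", "F"):
                n = int(rng.integers(3, 10))
                residues = [
                    Residue(cid, k + 1, "GLY", [
                        Atom("CA", "C", tuple(rng.uniform(-7, 7, 3))),
                        Atom("CB", "C", tuple(rng.uniform(-7, 7, 3))),
                    ])
                    for k in range(n)
                ]
                chains.append(Chain(id=cid, residues=residues))
            st = Structure(id="rnd", chains=chains)
            got = {
                (r.e3_residue.label, r.e2_residue.label,
                 round(r.min_distance, 9), r.tier)
                for r in extract_contacts(st, Selection("E"), Selection("F"),
                                          params)
            }
            assert got == brute_force_contacts(st, Selection("E"),
                                               Selection("F"), params)

    def test_counts_invariant_under_rigid_motion(self):
        # distances kept off the exact cutoffs: a pair at exactly 4.0 A is
        # not float-stable under rotation
        rng = np.random.default_rng(45)
        plan = tuple((d, a, b) for d, a, b in PLAN_10
                     if abs(d - 4.0) > 0.05 and abs(d - 3.5) > 0.05)
        st, _ = synth.gen_complex(synth.ComplexSpec(seed=6, pair_plan=plan))
        moved = rigid_copy(st, random_rotation(rng), rng.normal(size=3) * 30)
        a = extract_contacts(st, Selection("E"), Selection("F"))
        b = extract_contacts(moved, Selection("E"), Selection("F"))
        assert len(a) == len(b)
        assert count_close_e3_residues(a) == count_close_e3_residues(b)
        for ra, rb in zip(a, b):
            assert ra.min_distance == pytest.approx(rb.min_distance, abs=1e-6)

    def test_errors_on_empty_or_overlapping_selections(self):
        st, _ = synth.gen_complex(synth.ComplexSpec(seed=7))
        with pytest.raises(ValueError):
            extract_contacts(st, Selection("E"), Selection("E"))
        with pytest.raises(KeyError):
            extract_contacts(st, Selection("Z"), Selection("F"))
        with pytest.raises(ValueError):
            extract_contacts(st, Selection("E", 100, 200), Selection("F"))


class TestSelections:
    def test_parse_specs(self):
        assert Selection.parse("A") == Selection("A")
        assert Selection.parse("A:381-420") == Selection("A", 381, 420)
        with pytest.raises(ValueError):
            Selection.parse("A:nonsense")

    def test_residue_range_filter(self):
        st, _ = synth.gen_complex(synth.ComplexSpec(seed=8, pair_plan=PLAN_10))
        subset = Selection("E", 2, 4).residues(st)
        assert [r.seq_num for r in subset] == [2, 3, 4]


class TestHydrogenBonds:
    def test_planted_no_pair_detected_and_cutoff_enforced(self):
        st, _ = synth.gen_complex(
            synth.ComplexSpec(seed=9, pair_plan=((2.9, "O", "N"),
                                                 (3.6, "O", "N")))
        )
        bonds = detect_backbone_hbonds(st, Selection("E"), Selection("F"))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-3)
        # donor is the backbone N side (chain F), acceptor carries the O
        assert bonds[0].donor_residue.chain_id == "F"
        assert bonds[0].acceptor_residue.chain_id == "E"

    def test_distant_chains_no_bonds(self):
        st, _ = synth.gen_complex(
            synth.ComplexSpec(seed=10, pair_plan=((20.0, "O", "N"),),
                              spacing=60.0)
        )
        assert detect_backbone_hbonds(st, Selection("E"), Selection("F")) == []


class TestRegionAssignment:
    def test_planted_residues_labelled_by_region(self):
        st, _ = synth.gen_complex(synth.ComplexSpec(seed=11, pair_plan=PLAN_10))
        records = extract_contacts(st, Selection("E"), Selection("F"))
        ncol = 13
        aln = Alignment(row_ids=["e3"], rows=["A" * ncol])
        segments = [
            SCRSegment(1, 3, 0.5, region_label="N-loop"),
            SCRSegment(5, 7, 0.5, region_label="beta-alpha"),
            SCRSegment(9, 11, 0.5, region_label="C-loop"),
        ]
        summary = assign_contacts_to_regions(records, segments, aln, "e3")
        # contacting E3 residues are seq 1..8 -> columns 1..8
        expected = {1: "I", 2: "I", 3: "I", 4: "none", 5: "II", 6: "II",
                    7: "II", 8: "none"}
        for res_label, region in summary.region_assignment.items():
            seq_num = int("".join(filter(str.isdigit, res_label)))
            assert region == expected[seq_num]
        assert summary.n_contact_residues_e3 == 8
        assert summary.n_close_residues_e3 == 5

    def test_unmappable_residue_diagnosed(self):
        st, _ = synth.gen_complex(
            synth.ComplexSpec(seed=12, pair_plan=((3.0, "CA", "CA"),) * 2)
        )
        records = extract_contacts(st, Selection("E"), Selection("F"))
        aln = Alignment(row_ids=["e3"], rows=["A"])  # too short to map seq 2
        summary = assign_contacts_to_regions(records, [], aln, "e3")
        assert summary.region_assignment["E:" + records[-1].e3_residue.name3
                                         + "2"] == "none"
        assert summary.diagnostics
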