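"""Cross-link filtering, distance mapping, contacts, transfer, export."""

import numpy as np
import pandas as pd
import pytest

from polterm.simulate import simulate_structure_fixture
from polterm.xl_structure import (
    XLError,
    align_residue_map,
    extract_contacts,
    export_links,
    filter_links,
    load_structure,
    map_distances,
    transfer_by_alignment,
)


def make_pdb(tmp_path, atoms, name="toy.pdb"):
    """atoms: list of (chain, resnum, x, y, z) -> CA-only PDB file path."""
    lines = []
    for serial, (chain, resnum, x, y, z) in enumerate(atoms, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return str(p)


def links_table(rows):
    return pd.DataFrame(
        rows, columns=["protein_a", "residue_a", "protein_b", "residue_b", "e_value"]
    )


class TestFilterLinks:
    def test_threshold_is_strict(self):
        t = links_table(
            [
                ("p1", 1, "p2", 2, 1.0e-6),  # kept
                ("p1", 3, "p2", 4, 1.0e-4),  # removed
                ("p1", 5, "p2", 6, 1.0e-5),  # boundary: removed (strict <)
            ]
        )
        kept = filter_links(t)
        assert len(kept) == 1
        assert kept["residue_a"].iloc[0] == 1

    def test_duplicate_pairs_collapse_with_summed_counts(self):
        rows = [
            ("p1", 1, "p2", 2, 1e-6),
            ("p2", 2, "p1", 1, 1e-7),  # same unordered pair
            ("p1", 3, "p2", 4, 1e-6),
            ("p1", 3, "p2", 4, 1e-8),
            ("p1", 5, "p2", 6, 1e-6),
        ]
        kept = filter_links(links_table(rows))
        assert len(kept) == 3
        counts = dict(zip(zip(kept["residue_a"], kept["residue_b"]), kept["count"]))
        assert counts[(1, 2)] == 2 and counts[(3, 4)] == 2 and counts[(5, 6)] == 1

    def test_missing_e_value_column_rejected(self):
        with pytest.raises(XLError, match="e_value"):
            filter_links(pd.DataFrame({"protein_a": ["p"]}))


class TestMapDistances:
    def test_hand_euclidean_distance(self, tmp_path):
        path = make_pdb(
            tmp_path, [("A", 1, 0.0, 0.0, 0.0), ("B", 1, 3.0, 4.0, 0.0)]
        )
        st = load_structure(path)
        out = map_distances(
            links_table([("pA", 1, "pB", 1, 1e-6)]), st, {"pA": "A", "pB": "B"}
        )
        assert out["ca_distance"].iloc[0] == pytest.approx(5.0)
        assert out["status"].iloc[0] == "satisfied"

    def test_self_link_zero_distance(self, tmp_path):
        path = make_pdb(tmp_path, [("A", 7, 1.0, 2.0, 3.0)])
        st = load_structure(path)
        out = map_distances(
            links_table([("pA", 7, "pA", 7, 1e-6)]), st, {"pA": "A"}
        )
        assert out["ca_distance"].iloc[0] == 0.0
        assert out["status"].iloc[0] == "satisfied"

    def test_unresolved_residue_flagged_not_dropped(self, tmp_path):
        path = make_pdb(tmp_path, [("A", 1, 0.0, 0.0, 0.0)])
        st = load_structure(path)
        out = map_distances(
            links_table([("pA", 1, "pA", 99, 1e-6)]), st, {"pA": "A"}
        )
        assert len(out) == 1
        assert out["status"].iloc[0] == "unmapped"
        assert out.attrs["summary"]["unmapped"] == 1

    def test_absent_chain_named_in_error(self, tmp_path):
        path = make_pdb(tmp_path, [("A", 1, 0.0, 0.0, 0.0)])
        st = load_structure(path)
        with pytest.raises(XLError, match="'Z'"):
            map_distances(links_table([("pZ", 1, "pZ", 2, 1e-6)]), st, {"pZ": "Z"})

    def test_planted_fixture_links_all_satisfied(self, tmp_path):
        pdb, links, _ = simulate_structure_fixture(
            11, n_residues=50, n_links=10, max_planted_distance=30.0, n_decoys=6
        )
        p = tmp_path / "fix.pdb"
        p.write_text(pdb)
        st = load_structure(str(p))
        kept = filter_links(links)  # retains exactly the planted links
        out = map_distances(kept, st, {"protA": "A", "protB": "B"}, cutoff=30.0)
        assert (out["status"] == "satisfied").all()


class TestExtractContacts:
    def test_threshold_at_15_angstroms(self, tmp_path):
        st = load_structure(
            make_pdb(
                tmp_path,
                [("A", 1, 0.0, 0.0, 0.0), ("B", 1, 14.9, 0.0, 0.0),
                 ("B", 2, 15.1, 0.0, 0.0)],
            )
        )
        contacts = extract_contacts(st, ["A"], ["B"], cutoff=15.0)
        assert [(c.residue_b, round(c.distance, 1)) for c in contacts] == [(1, 14.9)]

    def test_zero_cutoff_keeps_only_coincident_atoms(self, tmp_path):
        st = load_structure(
            make_pdb(
                tmp_path,
                [("A", 1, 1.0, 1.0, 1.0), ("B", 1, 1.0, 1.0, 1.0),
                 ("B", 2, 1.0, 1.0, 2.0)],
            )
        )
        contacts = extract_contacts(st, ["A"], ["B"], cutoff=0.0)
        assert len(contacts) == 1 and contacts[0].residue_b == 1

    def test_empty_chain_set_rejected(self, tmp_path):
        st = load_structure(make_pdb(tmp_path, [("A", 1, 0.0, 0.0, 0.0)]))
        with pytest.raises(XLError):
            extract_contacts(st, [], ["A"])

    def test_matches_all_pairs_brute_force(self, tmp_path):
        pdb, _, _ = simulate_structure_fixture(17, n_residues=200, n_links=0)
        p = tmp_path / "big.pdb"
        p.write_text(pdb)
        st = load_structure(str(p))
        from polterm.xl_structure import ca_coordinates

        coords = ca_coordinates(st)
        expected = set()
        for (ca, ra), xa in coords.items():
            for (cb, rb), xb in coords.items():
                if ca == "A" and cb == "B":
                    if np.linalg.norm(xa - xb) <= 15.0:
                        expected.add((ra, rb))
        contacts = extract_contacts(st, ["A"], ["B"], cutoff=15.0)
        assert {(c.residue_a, c.residue_b) for c in contacts} == expected

    def test_distance_symmetry(self, tmp_path):
        pdb, _, _ = simulate_structure_fixture(19, n_residues=60, n_links=0)
        p = tmp_path / "s.pdb"
        p.write_text(pdb)
        st = load_structure(str(p))
        ab = {(c.residue_a, c.residue_b, round(c.distance, 6))
              for c in extract_contacts(st, ["A"], ["B"], cutoff=20.0)}
        ba = {(c.residue_b, c.residue_a, round(c.distance, 6))
              for c in extract_contacts(st, ["B"], ["A"], cutoff=20.0)}
        assert ab == ba


class TestTransfer:
    def test_identical_sequences_identity_map(self):
        mapping, identity = align_residue_map("MKTAYIAKQR", "MKTAYIAKQR")
        assert identity == 1.0
        assert mapping == {i: i for i in range(1, 11)}

    def test_single_n_terminal_insertion_shifts_by_one(self):
        mapping, _ = align_residue_map("MKTAYIAKQR", "GMKTAYIAKQR")
        assert all(mapping[i] == i + 1 for i in range(1, 11))

    def test_gap_positions_reported_untransferable(self):
        # target lacks the middle segment of the source
        src = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        tgt = "MKTAYIAKQRQISFVKSGLIEVQ"
        table = links_table([("p", 2, "p", 25, 1e-6)])
        out, report = transfer_by_alignment(
            table, {"p": src}, {"p": tgt}
        )
        assert out["transfer_status"].iloc[0] == "untransferable"
        assert out["residue_a_target"].iloc[0] == 2

    def test_low_identity_raises(self):
        with pytest.raises(XLError, match="identity"):
            align_residue_map("MKTAYIAKQRMKTAYIAKQR", "WWPGCNDHEEWWPGCNDHEE")

    def test_transfer_is_functional(self):
        mapping, _ = align_residue_map("MKTAYIAKQRQISFVK", "MKTAYIKQRQISFVK")
        targets = list(mapping.values())
        assert len(targets) == len(set(targets))


class TestExport:
    def test_xinet_round_trip(self, tmp_path):
        _, links, _ = simulate_structure_fixture(23, n_residues=30, n_links=7)
        kept = filter_links(links)
        path = str(tmp_path / "links.csv")
        export_links(kept, path, "xinet_csv")
        back = pd.read_csv(path)
        assert len(back) == len(kept)
        orig = {
            (r.protein_a, r.residue_a, r.protein_b, r.residue_b)
            for r in kept.itertuples(index=False)
        }
        round_tripped = {
            (r.Protein1, r.PepPos1, r.Protein2, r.PepPos2)
            for r in back.itertuples(index=False)
        }
        assert round_tripped == orig

    def test_pseudobond_lines_reference_chain_and_residue(self, tmp_path):
        table = links_table([("pA", 12, "pB", 34, 1e-6)])
        path = str(tmp_path / "pb.txt")
        export_links(table, path, "chimera_pseudobond", {"pA": "A", "pB": "B"})
        lines = open(path).read().splitlines()
        assert lines == ["#0:12.A@CA #0:34.B@CA"]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(XLError):
            export_links(links_table([("a", 1, "b", 2, 1e-6)]),
                         str(tmp_path / "x"), "nope")
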