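import gemmi
import numpy as np
import pytest

from foldswitch_bench.structio import (
    RegionSpec,
    StructureError,
    add_glycine_cb,
    extract_region,
    plddt_profile,
    read_structure,
    region_gap_report,
    standardize_residues,
    strip_sidechains,
    structures_allclose,
    truncate_to_common,
    write_structure,
)
from foldswitch_bench.synthetic import build_helix

from conftest import make_structure


class TestReadStructure:
    def test_three_residue_fixture(self, three_residue_pdb):
        s = read_structure(three_residue_pdb, "A")
        assert len(s) == 3
        assert s.sequence == "AGS"
        assert [r.name for r in s.residues] == ["ALA", "GLY", "SER"]

    def test_pdb_mmcif_equivalence(self, three_residue_pdb, tmp_path):
        st = gemmi.read_structure(str(three_residue_pdb))
        st.setup_entities()
        cif_path = tmp_path / "three.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        from_pdb = read_structure(three_residue_pdb, "A")
        from_cif = read_structure(cif_path, "A")
        assert structures_allclose(from_pdb, from_cif)

    def test_altloc_highest_occupancy_wins(self, altloc_pdb):
        s = read_structure(altloc_pdb, "A")
        ca = s.residues[0].atom("CA")
        # conformer A (occ 0.60) sits at x=1.458; B (occ 0.40) at 1.500
        assert ca.xyz[0] == pytest.approx(1.458, abs=1e-3)
        assert len([a for a in s.residues[0].atoms if a.name == "CA"]) == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb", "A")

    def test_unknown_chain(self, three_residue_pdb):
        with pytest.raises(StructureError, match="chain"):
            read_structure(three_residue_pdb, "Z")


class TestExtractRegion:
    def test_full_span_is_identity(self, helix20):
        sub = extract_region(helix20, RegionSpec(1, 20))
        assert structures_allclose(sub, helix20)

    def test_single_residue(self, helix20):
        sub = extract_region(helix20, RegionSpec(5, 5))
        assert len(sub) == 1
        assert sub.residues[0].number == 5

    def test_internal_gap_shortens_and_is_reported(self, helix20):
        # drop residue 10 to fake an unresolved residue
        from dataclasses import replace

        gapped = replace(
            helix20, residues=tuple(r for r in helix20.residues if r.number != 10)
        )
        region = RegionSpec(5, 15)
        sub = extract_region(gapped, region)
        assert len(sub) == region.length - 1
        assert region_gap_report(gapped, region) == [(10, "unresolved")]

    def test_region_outside_structure_lists_missing(self, helix20):
        with pytest.raises(StructureError, match="25"):
            extract_region(helix20, RegionSpec(18, 25))


class TestPlddtProfile:
    def test_uniform_bfactor(self, helix20):
        from foldswitch_bench.synthetic import set_bfactors

        s = set_bfactors(helix20, [88.5] * 20)
        assert plddt_profile(s) == [88.5] * 20

    def test_ca_convention(self):
        s = make_structure(
            {1: {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2, 1.4, 0), "CB": (2, -1, -1)}}
        )
        from dataclasses import replace

        # CA carries 70, sidechain CB carries 10: the residue value is CA's
        res = s.residues[0]
        atoms = tuple(
            replace(a, bfactor=70.0 if a.name == "CA" else 10.0) for a in res.atoms
        )
        s = replace(s, residues=(replace(res, atoms=atoms),))
        assert plddt_profile(s) == [70.0]

    def test_out_of_range_value_rejected(self, helix20):
        from foldswitch_bench.synthetic import set_bfactors

        s = set_bfactors(helix20, [88.5] * 19 + [250.0])
        with pytest.raises(StructureError, match="outside"):
            plddt_profile(s)

    def test_length_equals_residue_count(self, helix20):
        assert len(plddt_profile(helix20)) == len(helix20)


class TestResidueEdits:
    def test_strip_keeps_backbone_plus_cb(self):
        s = make_structure(
            {
                1: {
                    "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2, 1.4, 0),
                    "O": (1.3, 2.4, 0), "CB": (2, -1, -1), "CG": (3, -1.5, -1),
                    "CD": (3.5, -2.5, -2),
                }
            },
            names={1: "LYS"},
        )
        stripped = strip_sidechains(s)
        assert {a.name for a in stripped.residues[0].atoms} == {"N", "CA", "C", "O", "CB"}

    def test_strip_glycine_unchanged(self, helix20):
        gly_idx = helix20.sequence.index("G")
        stripped = strip_sidechains(helix20)
        assert stripped.residues[gly_idx].atoms == helix20.residues[gly_idx].atoms

    def test_strip_idempotent(self, helix20):
        once = strip_sidechains(helix20)
        assert structures_allclose(strip_sidechains(once), once)

    def test_glycine_cb_geometry(self, helix20):
        s = add_glycine_cb(helix20)
        gly = next(r for r in s.residues if r.name == "GLY")
        cb, ca = gly.atom("CB"), gly.atom("CA")
        assert cb is not None
        assert np.linalg.norm(cb.xyz - ca.xyz) == pytest.approx(1.521, abs=1e-3)
        n = gly.atom("N")
        u = (n.xyz - ca.xyz) / np.linalg.norm(n.xyz - ca.xyz)
        w = (cb.xyz - ca.xyz) / np.linalg.norm(cb.xyz - ca.xyz)
        assert np.degrees(np.arccos(u @ w)) == pytest.approx(110.4, abs=0.1)

    def test_glycine_cb_chirality_is_l(self, helix20):
        # improper dihedral N-CA-C-CB of an L-amino acid is near -122 degrees
        s = add_glycine_cb(helix20)
        gly = next(r for r in s.residues if r.name == "GLY")
        p = [gly.atom(x).xyz for x in ("N", "CA", "C", "CB")]
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        improper = np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
        assert improper == pytest.approx(-122.6, abs=2.0)

    def test_non_glycine_untouched_and_idempotent(self, helix20):
        once = add_glycine_cb(helix20)
        ala_idx = helix20.sequence.index("A")
        assert once.residues[ala_idx].atoms == helix20.residues[ala_idx].atoms
        assert structures_allclose(add_glycine_cb(once), once)

    def test_glycine_missing_backbone_errors(self):
        s = make_structure({1: {"N": (0, 0, 0), "CA": (1.5, 0, 0)}}, names={1: "GLY"})
        with pytest.raises(StructureError, match="glycine 1"):
            add_glycine_cb(s)

    def test_strip_and_cb_commute_without_glycine(self):
        s = build_helix("ACDEFHIKLM")
        a = add_glycine_cb(strip_sidechains(s))
        b = strip_sidechains(add_glycine_cb(s))
        assert structures_allclose(a, b)


class TestStandardize:
    def test_mse_to_met(self):
        s = make_structure(
            {1: {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2, 1.4, 0), "SE": (3, -1, 0)}},
            names={1: "MSE"},
        )
        out = standardize_residues(s)
        res = out.residues[0]
        assert res.name == "MET"
        assert res.atom("SD") is not None and res.atom("SE") is None
        assert res.atom("SD").element == "S"

    def test_no_seleno_identity(self, helix20):
        assert structures_allclose(standardize_residues(helix20), helix20)

    def test_mixed_chain_only_mse_converted(self):
        s = make_structure(
            {
                1: {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2, 1.4, 0), "SD": (3, 0, 0)},
                2: {"N": (4, 0, 0), "CA": (5.5, 0, 0), "C": (6, 1.4, 0), "SE": (7, 0, 0)},
            },
            names={1: "MET", 2: "MSE"},
        )
        out = standardize_residues(s)
        assert [r.name for r in out.residues] == ["MET", "MET"]
        assert out.residues[0].atoms == s.residues[0].atoms


class TestTruncateToCommon:
    def test_identical_sequences_unchanged(self, helix20):
        a, b, report = truncate_to_common(helix20, helix20)
        assert structures_allclose(a, helix20) and structures_allclose(b, helix20)
        assert report["trimmed_a"] == report["trimmed_b"] == 0

    def test_purification_tag_removed(self):
        core = "ACDEFGHIKLMNPQRSTVWY"
        a = build_helix(core)
        b = build_helix("HHHHHH" + core)
        ta, tb, report = truncate_to_common(a, b)
        assert ta.sequence == tb.sequence == core
        assert report["trimmed_b"] == 6

    def test_shared_core_with_different_flanks(self):
        # brute-force longest-common-substring oracle over all substrings
        core = "MNPQRSTVWYACDEFGHIKLMNPQRSTVWY"  # 30-mer
        seq_a = "AAAA" + core + "CCC"
        seq_b = "WWW" + core + "DDDDD"
        best = 0
        for i in range(len(seq_a)):
            for j in range(i + 1, len(seq_a) + 1):
                if seq_a[i:j] in seq_b:
                    best = max(best, j - i)
        assert best == 30
        ta, tb, report = truncate_to_common(build_helix(seq_a), build_helix(seq_b))
        assert len(ta) == len(tb) == 30
        assert ta.sequence == tb.sequence == core

    def test_no_common_block_errors(self):
        with pytest.raises(StructureError, match="common sequence block"):
            truncate_to_common(build_helix("ACDEFGHIKLAC"), build_helix("WYWYWYWYWYWY"))


class TestWriteStructure:
    def test_round_trip(self, helix20, tmp_path):
        path = write_structure(helix20, tmp_path / "out.pdb")
        back = read_structure(path, "A")
        assert structures_allclose(back, helix20, atol=1e-3)

    def test_coordinates_rounded_to_three_decimals(self, tmp_path):
        s = make_structure(
            {1: {"N": (0, 0, 0), "CA": (1.23456, 0, 0), "C": (2, 1.4, 0)}}
        )
        path = write_structure(s, tmp_path / "r.pdb")
        assert " 1.235" in path.read_text()

    def test_empty_structure_rejected(self, tmp_path):
        from foldswitch_bench.structio import Structure

        with pytest.raises(StructureError):
            write_structure(Structure(id="x", chain="A"), tmp_path / "x.pdb")
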