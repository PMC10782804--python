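"""Feature blocks: one-hots, charge, buried surface area, PSSM, embeddings."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockgraph.errors import (
    MalformedProfileError,
    MissingFeatureError,
    ProfileMisalignedError,
    UnencodableResidueError,
)
from dockgraph.node_features import (
    AA_ALPHABET,
    FeatureConfig,
    FeatureSources,
    SyntheticEmbeddingProvider,
    assemble_node_features,
    compute_bsa,
    embed_chain,
    one_hot_type,
    parse_pssm,
    polarity_feature,
    residue_charge,
    shrake_rupley_sasa,
)
from dockgraph.structure_io import ONE_TO_THREE, Complex
from dockgraph.graph_builder import select_interface_nodes
from dockgraph.synthetic_data import generate_complex

from conftest import make_residue


class TestResidueTables:
    def test_alanine_first_tyrosine_last(self):
        assert one_hot_type("ALA")[0] == 1 and one_hot_type("ALA").sum() == 1
        assert one_hot_type("TYR")[19] == 1

    def test_every_standard_residue_encodes_once(self):
        for aa in AA_ALPHABET:
            assert one_hot_type(ONE_TO_THREE[aa]).sum() == 1
            assert polarity_feature(ONE_TO_THREE[aa]).sum() == 1

    def test_polarity_classes(self):
        assert polarity_feature("GLU")[3] == 1   # negative
        assert polarity_feature("LEU")[0] == 1   # apolar
        assert polarity_feature("LYS")[2] == 1   # positive
        assert polarity_feature("SER")[1] == 1   # polar

    def test_charges(self):
        assert residue_charge("ARG") == 1.0
        assert residue_charge("ASP") == -1.0
        assert residue_charge("HIS") == pytest.approx(0.1)
        assert residue_charge("ALA") == 0.0
        assert sum(residue_charge("GLY") for _ in range(5)) == 0.0

    def test_selenomethionine_normalizes(self):
        assert np.array_equal(one_hot_type("MSE"), one_hot_type("MET"))

    def test_unknown_residue_rejected(self):
        with pytest.raises(UnencodableResidueError, match="unencodable residue"):
            one_hot_type("XYZ")


class TestBuriedSurfaceArea:
    def test_remote_residue_buries_nothing(self):
        a = make_residue("A", 1, "GLY", [[0, 0, 0]])
        b = make_residue("B", 1, "GLY", [[40, 0, 0]])
        cplx = Complex("t", {"A": [a], "B": [b]})
        assert compute_bsa(cplx, a) == pytest.approx(0.0, abs=1e-6)

    def test_fully_enclosed_residue_buries_its_isolated_sasa(self):
        # octahedral cage of partner atoms around a single-atom residue
        center = make_residue("A", 1, "GLY", [[0, 0, 0]])
        cage_pos = 3.2 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                                   [0, -1, 0], [0, 0, 1], [0, 0, -1],
                                   [.577, .577, .577], [-.577, .577, .577],
                                   [.577, -.577, .577], [.577, .577, -.577],
                                   [-.577, -.577, .577], [-.577, .577, -.577],
                                   [.577, -.577, -.577], [-.577, -.577, -.577]])
        cage = [make_residue("B", i + 1, "GLY", [p]) for i, p in enumerate(cage_pos)]
        cplx = Complex("t", {"A": [center], "B": cage})
        isolated = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]))[0]
        assert compute_bsa(cplx, center) == pytest.approx(isolated, rel=0.05)

    def test_quadrature_refinement_agrees_within_5_percent(self):
        _, cplx, _ = generate_complex(8, seed=3)
        res = select_interface_nodes(cplx)[0]
        coarse = compute_bsa(cplx, res, n_points=100)
        fine = compute_bsa(cplx, res, n_points=1000)
        assert coarse == pytest.approx(fine, rel=0.05, abs=1.0)

    def test_invariant_under_rigid_motion(self):
        _, cplx, _ = generate_complex(8, seed=4)
        res_index = 2
        rot = Rotation.from_rotvec([0.5, 0.5, -0.2]).as_matrix()
        moved = cplx.transformed(rot, np.array([10.0, -4.0, 3.0]))
        before = compute_bsa(cplx, cplx.chains["A"][res_index])
        after = compute_bsa(moved, moved.chains["A"][res_index])
        assert before == pytest.approx(after, abs=1e-3)

    def test_against_independent_sasa_implementation(self, tmp_path):
        """Total chain SASA cross-checked against Bio.PDB's Shrake-Rupley."""
        biopdb = pytest.importorskip("Bio.PDB")
        from Bio.PDB.SASA import ShrakeRupley
        from dockgraph.node_features import _atom_radii

        pdb_text, cplx, _ = generate_complex(8, seed=5)
        path = tmp_path / "synthetic_complex.pdb"
        path.write_text(pdb_text)
        parser = biopdb.PDBParser(QUIET=True)
        structure = parser.get_structure("s", str(path))
        ShrakeRupley(probe_radius=1.4, n_points=100).compute(structure[0], level="A")
        ref_total = sum(a.sasa for a in structure[0].get_atoms())

        atoms = [a for r in cplx.residues() for a in r.atoms]
        coords = np.array([a.position for a in atoms])
        radii = _atom_radii(atoms)
        mine = shrake_rupley_sasa(coords, radii, n_points=100).sum()
        assert mine == pytest.approx(ref_total, rel=0.05)


PSSM_TEXT = """\
# pos wt scores... ic
1 G 0 -3 -1 -2 -3 6 -2 -4 -2 -4 -3 0 -2 -2 -2 0 -2 -3 -2 -3 0.8
2 A 4 0 -2 -1 -2 0 -2 -1 -1 -1 -1 -2 -1 -1 -1 1 0 0 -3 -2 0.5
3 K -1 -3 -1 1 -3 -2 -1 -3 5 -2 -1 0 -1 1 2 0 -1 -2 -3 -2 1.2
"""


class TestPssm:
    def test_parse_dimensions(self):
        prof = parse_pssm(PSSM_TEXT)
        assert len(prof) == 3
        assert prof.scores.shape == (3, 20)
        assert prof.information_content[2] == pytest.approx(1.2)

    def test_conservation_is_wild_type_score(self):
        prof = parse_pssm(PSSM_TEXT)
        # row 3: wild type K, K column (index 8 in A,C,D,...) scores 5
        assert prof.conservation(2) == 5.0

    def test_misaligned_profile_rejected(self):
        from dockgraph.node_features import align_profile
        prof = parse_pssm(PSSM_TEXT)
        with pytest.raises(ProfileMisalignedError, match="profile misaligned"):
            align_profile(prof, 4)

    @pytest.mark.parametrize("bad", [
        "1 G 0 1 2 0.5",                       # too few fields
        PSSM_TEXT.replace(" 6 ", " six ", 1),  # non-numeric score
    ])
    def test_malformed_rows_rejected(self, bad):
        with pytest.raises(MalformedProfileError, match="malformed profile"):
            parse_pssm(bad)


class TestEmbeddings:
    def test_deterministic_and_shaped(self):
        provider = SyntheticEmbeddingProvider(embedding_dim=1280, seed=0)
        m1 = embed_chain(provider, "GAK")
        m2 = embed_chain(provider, "GAK")
        assert m1.shape == (3, 1280)
        assert np.array_equal(m1, m2)

    def test_seed_sensitivity(self):
        a = embed_chain(SyntheticEmbeddingProvider(16, seed=0), "GAK")
        b = embed_chain(SyntheticEmbeddingProvider(16, seed=1), "GAK")
        assert not np.array_equal(a, b)

    def test_dimension_contract(self):
        assert embed_chain(SyntheticEmbeddingProvider(8, seed=0), "GAK").shape == (3, 8)

    def test_values_standard_normal_like(self):
        m = embed_chain(SyntheticEmbeddingProvider(1280, seed=2), "ACDEFGHIKL")
        assert abs(m.mean()) < 0.05 and abs(m.std() - 1.0) < 0.05


class TestFeatureConfig:
    @pytest.mark.parametrize("preset,dim", [
        ("esm-pssm", 1328), ("esm", 1306), ("pssm-only", 48), ("minimal", 26),
    ])
    def test_preset_dimensions(self, preset, dim):
        assert FeatureConfig.preset(preset).dim == dim

    def test_dimension_identity_for_all_flag_combinations(self):
        for flags in itertools.product([False, True], repeat=5):
            t, p, b, c, e = flags
            cfg = FeatureConfig(use_type=t, use_polarity=p, use_bsa=b,
                                use_charge=c, use_pssm_block=False,
                                use_embedding=e, embedding_dim=32)
            assert cfg.dim == 20 * t + 4 * p + b + c + 32 * e
            cfg2 = FeatureConfig(use_type=t, use_polarity=p, use_bsa=b,
                                 use_charge=c, use_pssm_block=True,
                                 use_embedding=e, embedding_dim=32)
            assert cfg2.dim == cfg.dim + 22

    def test_json_round_trip(self):
        cfg = FeatureConfig.preset("esm", embedding_dim=16)
        assert FeatureConfig.from_json(cfg.to_json()) == cfg


class TestAssembly:
    def test_assembled_matrix_is_finite_with_documented_layout(self):
        _, cplx, seqs = generate_complex(8, seed=6)
        nodes = select_interface_nodes(cplx)
        cfg = FeatureConfig.preset("esm", embedding_dim=8)
        provider = SyntheticEmbeddingProvider(8, seed=0)
        emb = {c: embed_chain(provider, s) for c, s in seqs.items()}
        mat = assemble_node_features(nodes, cfg, FeatureSources(cplx, {}, emb))
        assert mat.shape == (len(nodes), cfg.dim)
        assert np.isfinite(mat).all()
        # layout: one-hot block first, polarity next
        assert set(np.unique(mat[:, :24])) <= {0.0, 1.0}
        assert np.all(mat[:, :20].sum(axis=1) == 1)

    def test_missing_embedding_source_raises(self):
        _, cplx, _ = generate_complex(8, seed=6)
        nodes = select_interface_nodes(cplx)
        cfg = FeatureConfig.preset("esm", embedding_dim=8)
        with pytest.raises(MissingFeatureError, match="missing feature"):
            assemble_node_features(nodes, cfg, FeatureSources(cplx))
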