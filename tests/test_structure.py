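"""Structure descriptors: exchangeable protons, dipolar couplings, d_rss, SASA."""

import itertools
import math
from pathlib import Path

import numpy as np
import pytest
import biotite.structure as struc

from predope import CONSTANTS
from predope.structure import (
    StructureModel,
    read_pdb,
    select_exchangeable_protons,
    dipolar_coupling,
    d_rss,
    sasa,
    residue_sasa,
    compute_descriptors,
    correlate_descriptors,
    VDW_RADII,
    PROBE_RADIUS,
)

from conftest import make_atom_array, pdb_text, DIPEPTIDE_NO_H, TRP_RESIDUE


class TestReadPDB:
    def test_minimal_file_exact_coordinates(self, tmp_path):
        records = [
            ("N", "GLY", "A", 1, (1.0, 2.0, 3.0), "N"),
            ("CA", "GLY", "A", 1, (4.5, -2.25, 0.125), "C"),
            ("C", "GLY", "A", 1, (-7.0, 0.0, 9.5), "C"),
        ]
        path = tmp_path / "mini.pdb"
        path.write_text(pdb_text(records))
        model = read_pdb(path)
        assert model.atoms.array_length() == 3
        np.testing.assert_allclose(
            model.atoms.coord, [r[4] for r in records], atol=1e-3
        )

    def test_trp_fixture_has_cz3(self, tmp_path):
        path = tmp_path / "trp.pdb"
        path.write_text(pdb_text(TRP_RESIDUE))
        model = read_pdb(path)
        assert model.tryptophan_labels() == ["A/W10"]
        assert model.atom_position("A/W10", "CZ3") is not None

    def test_malformed_coordinates_reported_with_line_numbers(self, tmp_path):
        good = pdb_text(DIPEPTIDE_NO_H).splitlines()
        good[2] = good[2][:30] + "  xx.xxx" + good[2][38:]
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(good) + "\n")
        with pytest.raises(ValueError, match="3"):
            read_pdb(path)

    def test_full_assembly_if_available(self):
        # the dodecameric aminopeptidase model: 12 chains, 4 Trp per chain
        path = Path(__file__).parent / "data" / "1y0r.pdb"
        if not path.exists():
            pytest.skip("1Y0R coordinates not bundled")
        model = read_pdb(path)
        assert len(model.chains()) == 12
        for chain in model.chains():
            trps = [l for l in model.tryptophan_labels() if l.startswith(chain)]
            assert len(trps) == 4


class TestExchangeableProtons:
    def test_explicit_hydrogens_filtered_by_heavy_atom(self, glycine_model):
        protons = select_exchangeable_protons(glycine_model)
        # only the amide H (on N); HA on carbon is excluded
        assert len(protons) == 1
        assert protons.n_explicit == 1
        np.testing.assert_allclose(protons.positions[0], (-0.6, 0.8, 0.0))

    def test_constructed_amide_matches_analytic_geometry(self, dipeptide_model):
        protons = select_exchangeable_protons(dipeptide_model)
        assert len(protons) == 1
        assert protons.n_constructed == 1
        # independent construction: H = N2 + 1.01 * unit(C1 - O1)
        c1 = np.array([2.0, 1.4, 0.0])
        o1 = np.array([1.3, 2.4, 0.0])
        n2 = np.array([3.3, 1.5, 0.0])
        u = (c1 - o1) / np.linalg.norm(c1 - o1)
        np.testing.assert_allclose(protons.positions[0], n2 + 1.01 * u, atol=1e-10)
        # trans to the carbonyl O: the N-H vector opposes C=O
        nh = protons.positions[0] - n2
        co = o1 - c1
        cosine = nh @ co / (np.linalg.norm(nh) * np.linalg.norm(co))
        assert cosine == pytest.approx(-1.0, abs=1e-12)

    def test_sidechain_sites_counted_without_hydrogens(self, trp_model):
        # lone Trp with no preceding residue: only the indole NE1 site
        protons = select_exchangeable_protons(trp_model)
        assert len(protons) == 1
        ne1 = trp_model.atom_position("A/W10", "NE1")
        assert np.linalg.norm(protons.positions[0] - ne1) == pytest.approx(1.0, abs=1e-6)


class TestDipolarCoupling:
    def test_hand_evaluated_reference(self):
        gh = CONSTANTS.gamma_of("1H")
        r = 2.0  # A
        expected = 1e-7 * gh * gh * 1.054571817e-34 / (2 * math.pi * (2.0e-10) ** 3)
        assert dipolar_coupling(gh, gh, r) == pytest.approx(expected, rel=1e-12)

    def test_inverse_cube_law(self):
        gh = CONSTANTS.gamma_of("1H")
        assert dipolar_coupling(gh, gh, 4.0) == pytest.approx(
            dipolar_coupling(gh, gh, 2.0) / 8.0, rel=1e-12
        )

    def test_linear_in_gamma(self):
        gh, gf = CONSTANTS.gamma_of("1H"), CONSTANTS.gamma_of("19F")
        ratio = dipolar_coupling(gh, gf, 3.0) / dipolar_coupling(gh, gh, 3.0)
        assert ratio == pytest.approx(gf / gh, rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            dipolar_coupling(1e8, 1e8, 0.0)


def _trp_with_protons(proton_positions):
    from predope.structure import ProtonSet

    model = StructureModel(make_atom_array(TRP_RESIDUE), source="synthetic")
    return model, ProtonSet(np.asarray(proton_positions, dtype=float), len(proton_positions), 0)


class TestDrss:
    def test_single_proton_reduces_to_single_coupling(self):
        model = StructureModel(make_atom_array(TRP_RESIDUE))
        cz3 = model.atom_position("A/W10", "CZ3")
        model, protons = _trp_with_protons([cz3 + (3.0, 0, 0)])
        val, n = d_rss(model, "A/W10", protons=protons)
        gf, gh = CONSTANTS.gamma_of("19F"), CONSTANTS.gamma_of("1H")
        assert n == 1
        assert val == pytest.approx(dipolar_coupling(gf, gh, 3.0), rel=1e-12)

    def test_two_equidistant_protons_scale_sqrt2(self):
        model = StructureModel(make_atom_array(TRP_RESIDUE))
        cz3 = model.atom_position("A/W10", "CZ3")
        model, protons = _trp_with_protons([cz3 + (3.0, 0, 0), cz3 - (3.0, 0, 0)])
        val, _ = d_rss(model, "A/W10", protons=protons)
        gf, gh = CONSTANTS.gamma_of("19F"), CONSTANTS.gamma_of("1H")
        assert val == pytest.approx(math.sqrt(2) * dipolar_coupling(gf, gh, 3.0), rel=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        model = StructureModel(make_atom_array(TRP_RESIDUE))
        cz3 = model.atom_position("A/W10", "CZ3")
        cloud = cz3 + rng.uniform(-15, 15, size=(50, 3))
        model, protons = _trp_with_protons(cloud)
        val, n = d_rss(model, "A/W10", protons=protons)
        gf, gh = CONSTANTS.gamma_of("19F"), CONSTANTS.gamma_of("1H")
        acc = 0.0
        for h in cloud:
            r = float(np.linalg.norm(h - cz3))
            d = 1e-7 * gf * gh * 1.054571817e-34 / (2 * math.pi * (r * 1e-10) ** 3)
            acc += d * d
        assert n == 50
        assert val == pytest.approx(math.sqrt(acc), rel=1e-12)

    def test_inverse_cube_scaling_under_dilation(self):
        rng = np.random.default_rng(18)
        base = make_atom_array(TRP_RESIDUE)
        cloud = rng.uniform(-12, 12, size=(20, 3)) + base.coord[12]
        alpha = 1.9
        m1, p1 = _trp_with_protons(cloud)
        v1, _ = d_rss(m1, "A/W10", protons=p1)
        scaled_arr = make_atom_array(TRP_RESIDUE)
        scaled_arr.coord = scaled_arr.coord * alpha
        m2 = StructureModel(scaled_arr)
        from predope.structure import ProtonSet

        v2, _ = d_rss(m2, "A/W10", protons=ProtonSet(cloud * alpha, 20, 0))
        # float32 coordinates limit the dilation identity to ~1e-6 relative
        assert v2 == pytest.approx(v1 * alpha**-3, rel=1e-6)

    def test_missing_proxy_atom_named_in_error(self, glycine_model):
        with pytest.raises(KeyError, match="CZ3"):
            d_rss(glycine_model, "A/W1")


class TestSASA:
    def test_isolated_atom_is_probe_inflated_sphere(self):
        arr = make_atom_array([("C", "UNK", "A", 1, (0.0, 0.0, 0.0), "C")])
        area = sasa(arr)[0]
        expected = 4 * math.pi * (VDW_RADII["C"] + PROBE_RADIUS) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_caged_atom_fully_buried(self):
        # 14 large atoms on face+corner directions at 2 A occlude every
        # probe position around the central carbon
        dirs = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        ] + [
            tuple(s / math.sqrt(3) for s in signs)
            for signs in itertools.product((1, -1), repeat=3)
        ]
        records = [("C", "UNK", "A", 1, (0.0, 0.0, 0.0), "C")]
        for i, d in enumerate(dirs, start=2):
            records.append(("S", "UNK", "A", i, tuple(2.0 * x for x in d), "S"))
        area = sasa(make_atom_array(records))[0]
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_overlap_matches_grid_integration(self):
        d = 3.0
        records = [
            ("C", "UNK", "A", 1, (0.0, 0.0, 0.0), "C"),
            ("O", "UNK", "A", 2, (d, 0.0, 0.0), "O"),
        ]
        area = sasa(make_atom_array(records))[0]
        # independent numerical integration on a dense sphere point set
        ra = VDW_RADII["C"] + PROBE_RADIUS
        rb = VDW_RADII["O"] + PROBE_RADIUS
        n = 200_000
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        on_a = ra * pts
        exposed = np.linalg.norm(on_a - np.array([d, 0, 0]), axis=1) > rb
        oracle = 4 * math.pi * ra**2 * exposed.mean()
        assert area == pytest.approx(oracle, rel=0.02)

    def test_assembly_area_bounded_by_isolated_sum(self, trp_model):
        per_atom = sasa(trp_model.atoms)
        assert np.all(per_atom >= -1e-9)
        isolated = sum(
            4 * math.pi * (VDW_RADII[el] + PROBE_RADIUS) ** 2
            for el in trp_model.atoms.element
        )
        assert np.nansum(per_atom) <= isolated

    def test_unknown_element_reported(self):
        arr = make_atom_array([("XX", "UNK", "A", 1, (0.0, 0.0, 0.0), "XX")])
        with pytest.raises(KeyError, match="XX"):
            sasa(arr)

    def test_residue_sasa_deterministic(self, trp_model):
        a = residue_sasa(trp_model, "A/W10")
        b = residue_sasa(trp_model, "A/W10")
        assert a == b > 0


class TestDescriptorsAndCorrelation:
    def test_descriptor_table_covers_all_tryptophans(self, trp_model):
        rows = compute_descriptors(trp_model)
        assert [r.label for r in rows] == ["A/W10"]
        assert rows[0].d_rss >= 0 and rows[0].sasa >= 0

    def test_identical_vectors_correlate_perfectly(self):
        vals = {"W106": 1.0, "W136": 2.0, "W164": 3.0, "W276": 4.0}
        rep = correlate_descriptors(vals, dict(vals))
        assert rep["r"] == pytest.approx(1.0)

    def test_anti_ordered_vectors_anticorrelate(self):
        x = {"W106": 1.0, "W136": 2.0, "W164": 3.0, "W276": 4.0}
        y = {k: -v for k, v in x.items()}
        rep = correlate_descriptors(x, y)
        assert rep["r"] == pytest.approx(-1.0)

    def test_permutation_p_value_from_full_enumeration(self):
        x = {"W106": 0.3, "W136": 1.9, "W164": 0.7, "W276": 1.1}
        y = {"W106": 12.0, "W136": 5.0, "W164": 9.0, "W276": 7.5}
        rep = correlate_descriptors(x, y)
        assert rep["n_permutations"] == 24
        # independent enumeration of the 24-permutation null
        labels = sorted(x)
        xv = np.array([x[l] for l in labels])
        yv = np.array([y[l] for l in labels])
        r_obs = np.corrcoef(xv, yv)[0, 1]
        count = sum(
            abs(np.corrcoef(xv, yv[list(p)])[0, 1]) >= abs(r_obs) - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert rep["p"] == pytest.approx(count / 24)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlate_descriptors({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
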