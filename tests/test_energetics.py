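import numpy as np
import pytest

from sdsl import fixtures
from sdsl.energetics import (
    LJParams,
    flat_top_repulsive_lj,
    lennard_jones_12_6,
    reweight,
    sasa_augmented_energy,
    sasa_radii,
    shrake_rupley_sasa,
    trim,
    trim_indices,
)
from sdsl.errors import DegenerateWeightsError, UnknownElementError
from sdsl.rotamer_core import attach
from sdsl.structure_io import Atom, AtomSubset, StructureModel

KT = 0.593


def tiny_env(coords, elements):
    """AtomSubset over a bare structure with the given atoms."""
    atoms = [
        Atom(serial=i + 1, name=f"X{i}", element=e, resname="LIG",
             resnum=100 + i, chain="Z", het=True)
        for i, e in enumerate(elements)
    ]
    s = StructureModel(atoms=atoms, models=[np.asarray(coords, float)])
    return AtomSubset(s, np.arange(len(atoms)))


class FakeEnsemble:
    """Minimal object satisfying the energy-function contract inputs."""

    def __init__(self, clash_coords, clash_elements):
        self.clash_coords = np.asarray(clash_coords, float)
        self.clash_elements = list(clash_elements)
        self.n_rotamers = self.clash_coords.shape[0]


class TestFlatTopLJ:
    def test_single_cc_pair_at_f_rmin_gives_epsilon(self):
        params = LJParams()
        rmin_cc = 2 * params.table["C"][0]
        eps_cc = params.table["C"][1]
        r = params.forgive * rmin_cc
        ens = FakeEnsemble([[[0.0, 0.0, 0.0]]], ["C"])
        env = tiny_env([[r, 0.0, 0.0]], ["C"])
        e = flat_top_repulsive_lj(ens, env, params)
        assert e[0] == pytest.approx(eps_cc, abs=1e-12)

    def test_beyond_cutoff_zero(self):
        ens = FakeEnsemble([[[0.0, 0.0, 0.0]]], ["C"])
        env = tiny_env([[10.5, 0.0, 0.0]], ["C"])
        assert flat_top_repulsive_lj(ens, env, LJParams())[0] == 0.0

    def test_flat_top_cap(self):
        ens = FakeEnsemble([[[0.0, 0.0, 0.0]]], ["C"])
        env = tiny_env([[0.1, 0.0, 0.0]], ["C"])
        params = LJParams()
        assert flat_top_repulsive_lj(ens, env, params)[0] == params.cap

    def test_unknown_element(self):
        ens = FakeEnsemble([[[0.0, 0.0, 0.0]]], ["Xx"])
        env = tiny_env([[3.0, 0.0, 0.0]], ["C"])
        with pytest.raises(UnknownElementError, match="Xx"):
            flat_top_repulsive_lj(ens, env, LJParams())

    def test_monotone_in_forgive(self, rng):
        coords = rng.uniform(-4, 4, size=(2, 6, 3))
        ens = FakeEnsemble(coords, ["C", "N", "O", "S", "C", "H"])
        env = tiny_env(rng.uniform(-4, 4, size=(8, 3)),
                       ["C", "C", "N", "O", "S", "H", "C", "N"])
        last = None
        for f in (0.5, 0.7, 0.9, 1.1):
            e = flat_top_repulsive_lj(ens, env, LJParams(forgive=f))
            if last is not None:
                assert np.all(e >= last - 1e-12)
            last = e

    def test_monotone_noninc_in_distance(self):
        params = LJParams()
        ens = FakeEnsemble([[[0.0, 0.0, 0.0]]], ["C"])
        energies = [
            flat_top_repulsive_lj(
                ens, tiny_env([[d, 0.0, 0.0]], ["C"]), params
            )[0]
            for d in np.linspace(0.5, 9.5, 30)
        ]
        assert np.all(np.diff(energies) <= 1e-15)

    def test_full_12_6_attractive_well(self):
        params = LJParams(forgive=1.0)
        rmin_cc = 2 * params.table["C"][0]
        ens = FakeEnsemble([[[0.0, 0.0, 0.0]]], ["C"])
        env = tiny_env([[rmin_cc, 0.0, 0.0]], ["C"])
        e = lennard_jones_12_6(ens, env, params)
        assert e[0] == pytest.approx(-params.table["C"][1], abs=1e-12)


class TestReweight:
    def test_equal_energies_identity(self):
        prior = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(
            reweight(prior, [7.0, 7.0, 7.0], KT), prior, atol=1e-12
        )

    def test_closed_form_boltzmann(self):
        w = reweight([0.5, 0.5], [0.0, KT * np.log(2.0)], KT)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_single_rotamer(self):
        np.testing.assert_allclose(reweight([1.0], [123.4], KT), [1.0])

    def test_shift_invariance(self, rng):
        prior = rng.dirichlet(np.ones(5))
        e = rng.uniform(0, 5, size=5)
        np.testing.assert_allclose(
            reweight(prior, e, KT), reweight(prior, e + 17.3, KT), atol=1e-12
        )

    def test_composition(self, rng):
        prior = rng.dirichlet(np.ones(4))
        e1 = rng.uniform(0, 3, size=4)
        e2 = rng.uniform(0, 3, size=4)
        once = reweight(prior, e1 + e2, KT)
        twice = reweight(reweight(prior, e1, KT), e2, KT)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateWeightsError):
            reweight([0.0, 0.0], [1.0, 2.0], KT)

    def test_bad_kt(self):
        with pytest.raises(ValueError):
            reweight([1.0], [0.0], 0.0)


class TestTrim:
    def test_tol_zero_keeps_nonzero(self):
        keep = trim_indices([0.5, 0.0, 0.5], 0.0)
        assert keep.tolist() == [0, 2]

    def test_hand_cumulative_all_kept(self):
        keep = trim_indices([0.9, 0.06, 0.04], 0.005)
        assert keep.tolist() == [0, 1, 2]

    def test_hand_cumulative_one_kept(self):
        keep = trim_indices([0.998, 0.001, 0.001], 0.005)
        assert keep.tolist() == [0]

    def test_relative_weights_preserved(self, helix10, toy_lib):
        label = attach(toy_lib, helix10, "A", 5, eval_clash=False)
        label.weights = np.array([0.6, 0.3, 0.1])
        trimmed = trim(label, 0.15)
        assert trimmed.n_rotamers == 2
        np.testing.assert_allclose(
            trimmed.weights, [0.6 / 0.9, 0.3 / 0.9], atol=1e-12
        )

    def test_at_least_one_survives(self):
        assert len(trim_indices([1.0, 0.0, 0.0], 0.9)) >= 1


def analytic_two_sphere_area(R1, R2, d):
    """Accessible area of expanded sphere 1 against expanded sphere 2."""
    if d >= R1 + R2:
        return 4 * np.pi * R1**2
    # cap height on sphere 1 buried inside sphere 2
    h = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    return 4 * np.pi * R1**2 - 2 * np.pi * R1 * h


class TestSasa:
    def test_isolated_atom_analytic(self):
        area = shrake_rupley_sasa([[0.0, 0.0, 0.0]], [1.6], probe=1.4,
                                  n_points=960)
        assert area[0] == pytest.approx(4 * np.pi * 3.0**2, rel=0.02)

    def test_fully_enclosed_zero(self):
        # center atom inside a tight shell of large neighbors
        dirs = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
             [0, 0, -1], [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
             [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1]],
            dtype=float,
        )
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], dirs * 1.5])
        radii = np.array([1.0] + [2.0] * len(dirs))
        area = shrake_rupley_sasa(coords, radii, probe=1.4, n_points=512)
        assert area[0] == 0.0

    def test_two_sphere_analytic_oracle(self):
        R = 1.6 + 1.4
        for d in (1.0, 2.0, 3.0, 4.5, 5.9):
            area = shrake_rupley_sasa(
                [[0.0, 0.0, 0.0], [d, 0.0, 0.0]], [1.6, 1.6],
                probe=1.4, n_points=4096,
            )
            expected = analytic_two_sphere_area(R, R, d)
            assert area[0] == pytest.approx(expected, rel=0.02)

    def test_adding_neighbor_decreases(self, rng):
        coords = rng.uniform(-3, 3, size=(6, 3))
        radii = np.full(6, 1.6)
        before = shrake_rupley_sasa(coords, radii).sum()
        extra = np.vstack([coords, [[0.5, 0.5, 0.5]]])
        after = shrake_rupley_sasa(extra, np.full(7, 1.6))[:6].sum()
        assert after <= before + 1e-9

    def test_validation(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa([[0, 0, 0]], [1.0], probe=-1.0)
        with pytest.raises(ValueError):
            shrake_rupley_sasa([[0, 0, 0]], [1.0], n_points=8)


class TestSasaAugmented:
    def test_w_zero_reduces_to_lj(self, helix10, toy_lib):
        label = attach(toy_lib, helix10, "A", 5, eval_clash=False)
        env = tiny_env([[50.0, 0.0, 0.0]], ["C"])
        np.testing.assert_array_equal(
            sasa_augmented_energy(label, env, LJParams(), w_sasa=0.0),
            flat_top_repulsive_lj(label, env, LJParams()),
        )

    def test_buried_rotamer_penalized(self):
        # two one-atom rotamers; a cage of occluders sits 5 Å around
        # rotamer 1: outside the (shortened) LJ cutoff, so both rotamers
        # have zero LJ energy, but the cage buries rotamer 1's surface
        far = np.array([60.0, 60.0, 60.0])
        cage_dirs = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
             [0, 0, -1]], dtype=float,
        )
        ens = FakeEnsemble([[[0.0, 0.0, 0.0]], [far]], ["C"])
        env = tiny_env(far + cage_dirs * 5.0, ["C"] * 6)
        params = LJParams(cutoff=4.0)
        e_lj = flat_top_repulsive_lj(ens, env, params)
        np.testing.assert_array_equal(e_lj, [0.0, 0.0])
        e_aug = sasa_augmented_energy(ens, env, params, w_sasa=0.05)
        assert e_aug[1] > e_aug[0]  # buried rotamer is less favorable

    def test_negative_w_rejected(self, helix10, toy_lib):
        label = attach(toy_lib, helix10, "A", 5, eval_clash=False)
        env = tiny_env([[50.0, 0.0, 0.0]], ["C"])
        with pytest.raises(ValueError):
            sasa_augmented_energy(label, env, w_sasa=-1.0)


class TestPipelineEquivalence:
    def test_attach_equals_brute_force(self, toy_lib):
        """Full-pipeline oracle: attach + LJ + reweight + trim against a
        direct pair-enumeration script on a small environment."""
        helix3 = fixtures.make_helix(3)
        params = LJParams()
        label = attach(toy_lib, helix3, "A", 2, eval_clash=True,
                       params=params, trim_tol=0.005)

        table = params.table
        env = [
            (helix3.coords[i], helix3.atoms[i].element)
            for i in range(helix3.n_atoms)
            if helix3.atoms[i].resnum != 2
        ]
        free = attach(toy_lib, helix3, "A", 2, eval_clash=False)
        energies = np.zeros(3)
        for r in range(3):
            for name in ("SG", "C1", "N1", "O1"):
                a = toy_lib.atom_index(name)
                ra, ea = table[toy_lib.elements[a].capitalize()]
                for xyz, el in env:
                    dist = float(np.linalg.norm(free.coords[r, a] - xyz))
                    if dist > params.cutoff:
                        continue
                    rb, eb = table[el.capitalize()]
                    energies[r] += min(
                        params.cap,
                        np.sqrt(ea * eb)
                        * ((params.forgive * (ra + rb)) / dist) ** 12,
                    )
        w = toy_lib.weights * np.exp(-(energies - energies.min()) / KT)
        w /= w.sum()
        order = np.argsort(w)[::-1]
        kept = order[: np.searchsorted(np.cumsum(w[order]), 1 - 0.005) + 1]
        kept = np.sort(kept)
        expected = w[kept] / w[kept].sum()

        assert label.n_rotamers == len(kept)
        np.testing.assert_allclose(label.weights, expected, atol=1e-9)


class TestLoadConfig:
    def test_round_trip_keys(self, tmp_path):
        from sdsl.energetics import load_config

        cfg = tmp_path / "sdsl.cfg"
        cfg.write_text(
            "# comment\nforgive = 0.85\ncap: 12\nkT = 0.6\n"
            "sasa.n_points = 128\n"
        )
        out = load_config(cfg)
        assert out == {"forgive": 0.85, "cap": 12.0, "kT": 0.6,
                       "sasa.n_points": 128}

    def test_unknown_key_rejected(self, tmp_path):
        from sdsl.energetics import load_config

        cfg = tmp_path / "sdsl.cfg"
        cfg.write_text("frobnicate = 1\n")
        with pytest.raises(ValueError, match="frobnicate"):
            load_config(cfg)
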