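import numpy as np
import pytest
from scipy import stats

from sdsl import fixtures
from sdsl.errors import DegenerateGeometryError, EmptyEnsembleError
from sdsl.rotamer_core import (
    RigidTransform,
    attach,
    backbone_frame,
    bisect_superposition,
    build_coords_from_internal,
    measure_dihedral,
    sample_off_rotamers,
    set_dihedral,
    triad_superposition,
    wrap_angle,
)
from sdsl.structure_io import Atom, StructureModel


def oracle_dihedral(p1, p2, p3, p4):
    """Independent torsion formula (projection construction)."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    b2_hat = b2 / np.linalg.norm(b2)
    v = -b1 - np.dot(-b1, b2_hat) * b2_hat  # p1 arm projected off the axis
    w = b3 - np.dot(b3, b2_hat) * b2_hat
    x = np.dot(v, w)
    y = np.dot(np.cross(b2_hat, v), w)
    return np.degrees(np.arctan2(y, x))


def random_rigid(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return RigidTransform(Q, rng.normal(scale=5.0, size=3))


class TestMeasureDihedral:
    def test_cis_is_zero(self):
        p = [np.array(v, float) for v in
             [(1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)]]
        assert abs(measure_dihedral(*p)) < 1e-12

    def test_trans_is_180(self):
        p = [np.array(v, float) for v in
             [(1, 1, 0), (0, 1, 0), (0, 0, 0), (-1, 0, 0)]]
        assert measure_dihedral(*p) == pytest.approx(180.0)

    def test_matches_independent_formula(self, rng):
        for _ in range(50):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                got = measure_dihedral(*pts)
            except DegenerateGeometryError:
                continue
            assert got == pytest.approx(oracle_dihedral(*pts), abs=1e-9)

    def test_collinear_raises(self):
        p = [np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]),
             np.array([3.0, 1.0, 0])]
        with pytest.raises(DegenerateGeometryError):
            measure_dihedral(*p)

    def test_coincident_raises(self):
        p = [np.zeros(3), np.zeros(3), np.array([1.0, 0, 0]),
             np.array([1.0, 1.0, 0])]
        with pytest.raises(DegenerateGeometryError):
            measure_dihedral(*p)


class TestSetDihedral:
    @pytest.fixture
    def lib(self, toy_lib):
        return toy_lib

    def test_identity(self, lib):
        coords = lib.coords[0]
        quad = lib.dihedral_indices[0]
        cur = measure_dihedral(*coords[quad])
        out = set_dihedral(coords, quad, lib.downstream[0], cur)
        assert np.abs(out - coords).max() < 1e-9

    def test_set_then_measure(self, lib):
        quad = lib.dihedral_indices[0]
        out = set_dihedral(lib.coords[0], quad, lib.downstream[0], 73.0)
        assert measure_dihedral(*out[quad]) == pytest.approx(73.0, abs=1e-6)

    def test_geometry_preserved(self, lib):
        coords = lib.coords[0]
        out = set_dihedral(coords, lib.dihedral_indices[0],
                           lib.downstream[0], 42.0)
        adj = lib.adjacency
        for i in range(len(adj)):
            for j in adj[i]:
                d0 = np.linalg.norm(coords[i] - coords[j])
                d1 = np.linalg.norm(out[i] - out[j])
                assert d1 == pytest.approx(d0, abs=1e-6)

    def test_chained_dihedral_rides_rigidly(self, lib):
        coords = lib.coords[0]
        q0, q1 = lib.dihedral_indices
        before = measure_dihedral(*coords[q1])
        out = set_dihedral(coords, q0, lib.downstream[0], -130.0)
        after = measure_dihedral(*out[q1])
        assert after == pytest.approx(before, abs=1e-9)

    def test_upstream_untouched(self, lib):
        coords = lib.coords[0]
        out = set_dihedral(coords, lib.dihedral_indices[1],
                           lib.downstream[1], 99.0)
        fixed = np.setdiff1d(np.arange(len(coords)), lib.downstream[1])
        np.testing.assert_array_equal(out[fixed], coords[fixed])


def triad(angle_deg, n_len=1.458, c_len=1.525):
    """N, CA, C with a given N-CA-C angle, CA at origin."""
    a = np.radians(angle_deg / 2)
    return (
        np.array([np.cos(a) * n_len, np.sin(a) * n_len, 0.0]),
        np.zeros(3),
        np.array([np.cos(a) * c_len, -np.sin(a) * c_len, 0.0]),
    )


class TestBisect:
    def test_identity(self):
        N, CA, C = triad(111.0)
        tf = bisect_superposition(N, CA, C, N, CA, C)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_recovers_rigid_transform(self, rng):
        N, CA, C = triad(111.0)
        true = random_rigid(rng)
        tf = bisect_superposition(
            N, CA, C, true.apply(N), true.apply(CA), true.apply(C)
        )
        np.testing.assert_allclose(tf.rotation, true.rotation, atol=1e-9)
        np.testing.assert_allclose(tf.translation, true.translation, atol=1e-9)

    def test_symmetric_split_for_unequal_angles(self):
        # same bond lengths, different N-CA-C angles: arms split the
        # discrepancy symmetrically about the bisector
        src = triad(110.0, n_len=1.5, c_len=1.5)
        dst = triad(114.0, n_len=1.5, c_len=1.5)
        tf = bisect_superposition(*src, *dst)
        np.testing.assert_allclose(tf.apply(src[1]), dst[1], atol=1e-12)
        dev_n = np.linalg.norm(tf.apply(src[0]) - dst[0])
        dev_c = np.linalg.norm(tf.apply(src[2]) - dst[2])
        assert dev_n == pytest.approx(dev_c, abs=1e-9)
        assert dev_n > 1e-3  # angles differ, so arms cannot both coincide

    def test_degenerate_triad(self):
        with pytest.raises(DegenerateGeometryError):
            bisect_superposition(
                np.array([1.0, 0, 0]), np.zeros(3), np.array([2.0, 0, 0]),
                *triad(111.0),
            )


class TestTriadSuperposition:
    def test_identity(self):
        src = np.stack(triad(111.0))
        tf = triad_superposition(src, src)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery(self, rng):
        src = np.stack(triad(111.0))
        true = random_rigid(rng)
        tf = triad_superposition(src, true.apply(src))
        np.testing.assert_allclose(tf.apply(src), true.apply(src), atol=1e-9)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_triad_gives_proper_rotation(self):
        src = np.stack(triad(111.0))
        dst = src * np.array([1.0, 1.0, -1.0])  # reflection through z = 0
        # make dst non-planar-degenerate by perturbing out of plane
        dst = dst + np.array([[0, 0, 0.2], [0, 0, -0.1], [0, 0, 0.05]])
        tf = triad_superposition(src, dst)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        rmsd = np.sqrt(((tf.apply(src) - dst) ** 2).sum(axis=1).mean())
        assert rmsd > 1e-3

    def test_agrees_with_bisect_for_identical_geometry(self, rng):
        src = triad(111.0)
        true = random_rigid(rng)
        dst = tuple(true.apply(p) for p in src)
        tb = bisect_superposition(*src, *dst)
        tt = triad_superposition(np.stack(src), np.stack(dst))
        np.testing.assert_allclose(tb.rotation, tt.rotation, atol=1e-8)
        np.testing.assert_allclose(tb.translation, tt.translation, atol=1e-8)


class TestBuildFromInternal:
    def test_reproduces_stored_rotamers(self, toy_lib):
        for r in range(toy_lib.n_rotamers):
            got = build_coords_from_internal(toy_lib, toy_lib.dihedrals[r])
            assert np.abs(got - toy_lib.coords[r]).max() < 1e-3

    def test_deterministic_bitwise(self, toy_lib):
        a = build_coords_from_internal(toy_lib, [10.0, -20.0])
        b = build_coords_from_internal(toy_lib, [10.0, -20.0])
        np.testing.assert_array_equal(a, b)

    def test_all_zero_dihedrals_planar(self, toy_lib):
        coords = build_coords_from_internal(toy_lib, [0.0, 0.0])
        quads = toy_lib.dihedral_indices
        for quad in quads:
            assert measure_dihedral(*coords[quad]) == pytest.approx(0, abs=1e-6)
        # chi1 = 0 puts N, CA, CB, SG in one plane; chi2 = 0 puts
        # CA, CB, SG, C1 in one plane
        names = toy_lib.atom_names
        arm = coords[[names.index(n) for n in ("N", "CA", "CB", "SG")]]
        sv = np.linalg.svd(arm - arm.mean(axis=0))[1]
        assert sv[2] < 1e-6


class TestSampleOffRotamers:
    def test_sigma_zero_matches_parents(self, toy_lib, rng):
        out = sample_off_rotamers(toy_lib, 200, dihedral_sigmas=0.0, rng=rng)
        np.testing.assert_array_equal(
            out.dihedrals, toy_lib.dihedrals[out.parents]
        )
        assert np.all(out.weights == 1.0 / 200)

    def test_parent_frequencies_chi_square(self, toy_lib):
        n = 10_000
        out = sample_off_rotamers(toy_lib, n, dihedral_sigmas=0.0, rng=7)
        counts = np.bincount(out.parents, minlength=toy_lib.n_rotamers)
        res = stats.chisquare(counts, f_exp=toy_lib.weights * n)
        assert res.pvalue > 0.01

    def test_infinite_sigma_uniform(self, toy_lib):
        n = 10_000
        out = sample_off_rotamers(
            toy_lib, n, dihedral_sigmas=np.inf, rng=11
        )
        for k in range(toy_lib.n_dihedrals):
            res = stats.kstest(
                out.dihedrals[:, k], stats.uniform(-180.0, 360.0).cdf
            )
            assert res.pvalue > 0.01

    def test_same_seed_identical(self, toy_lib):
        a = sample_off_rotamers(toy_lib, 50, rng=42)
        b = sample_off_rotamers(toy_lib, 50, rng=42)
        np.testing.assert_array_equal(a.dihedrals, b.dihedrals)
        np.testing.assert_array_equal(a.parents, b.parents)

    def test_n_below_one_raises(self, toy_lib):
        with pytest.raises(ValueError):
            sample_off_rotamers(toy_lib, 0)

    def test_wrap_range(self, toy_lib):
        out = sample_off_rotamers(toy_lib, 500, dihedral_sigmas=170.0, rng=3)
        assert np.all(out.dihedrals > -180.0)
        assert np.all(out.dihedrals <= 180.0)


class TestAttach:
    def test_no_clash_identity(self, helix10, toy_lib):
        label = attach(toy_lib, helix10, "A", 5, eval_clash=False)
        np.testing.assert_allclose(label.weights, toy_lib.weights)
        np.testing.assert_allclose(label.dihedrals, toy_lib.dihedrals,
                                   atol=1e-6)

    def test_backbone_superposes(self, helix10, toy_lib):
        for alignment in ("bisect", "triad"):
            label = attach(toy_lib, helix10, "A", 5, eval_clash=False,
                           alignment=alignment)
            iN, iCA, iC = helix10.backbone_indices("A", 5)
            site = helix10.coords[[iN, iCA, iC]]
            lN, lCA, lC = toy_lib.backbone_triad
            for r in range(label.n_rotamers):
                got = label.coords[r][[lN, lCA, lC]]
                assert np.linalg.norm(got - site, axis=1).max() < 0.2
            if alignment == "bisect":
                got_ca = label.coords[:, lCA, :]
                np.testing.assert_allclose(
                    got_ca, np.tile(site[1], (label.n_rotamers, 1)),
                    atol=1e-9,
                )

    def test_single_clash_atom_lowers_weight(self, toy_lib):
        # isolated 3-residue backbone plus one foreign atom 0.5 Å from
        # rotamer 0's terminal O1; expected weights from a brute-force
        # pair-enumeration oracle written out here
        helix3 = fixtures.make_helix(3)
        free = attach(toy_lib, helix3, "A", 2, eval_clash=False)
        o1 = free.coords[0, toy_lib.atom_index("O1")]
        clash_pos = o1 + np.array([0.5, 0.0, 0.0])
        atoms = helix3.atoms + [
            Atom(serial=0, name="FE", element="C", resname="LIG",
                 resnum=99, chain="Z", het=True)
        ]
        s = StructureModel(
            atoms=atoms, models=[np.vstack([helix3.coords, clash_pos])]
        )
        label = attach(toy_lib, s, "A", 2, eval_clash=True, trim_tol=0.0)

        # oracle: enumerate every (label side-chain atom, environment atom)
        # pair directly with the published functional form
        from sdsl.energetics import LJParams

        params = LJParams()
        table = params.table
        env = [
            (s.coords[i], s.atoms[i].element)
            for i in range(s.n_atoms)
            if not (s.atoms[i].resnum == 2 and s.atoms[i].chain == "A")
        ]
        sc_names = [n for n in toy_lib.atom_names
                    if n not in ("N", "CA", "C", "O", "CB")]
        energies = []
        for r in range(3):
            e = 0.0
            for name in sc_names:
                a = toy_lib.atom_index(name)
                el_a = toy_lib.elements[a].capitalize()
                for xyz, el_b in env:
                    d = float(np.linalg.norm(free.coords[r, a] - xyz))
                    if d > params.cutoff:
                        continue
                    rmin = table[el_a][0] + table[el_b.capitalize()][0]
                    eps = np.sqrt(table[el_a][1] * table[el_b.capitalize()][1])
                    e += min(params.cap,
                             eps * ((params.forgive * rmin) / d) ** 12)
            energies.append(e)
        energies = np.asarray(energies)
        expected = toy_lib.weights * np.exp(-(energies - energies.min()) / 0.593)
        expected /= expected.sum()

        assert label.n_rotamers == 3
        np.testing.assert_allclose(label.weights, expected, atol=1e-9)
        assert label.weights[0] < toy_lib.weights[0]

    def test_weights_sum_to_one(self, helix10, toy_lib):
        for kwargs in (
            {"eval_clash": False},
            {"eval_clash": True},
            {"sample": 37, "rng_seed": 5},
            {"sample": 25, "dihedral_sigmas": np.inf, "rng_seed": 5},
        ):
            label = attach(toy_lib, helix10, "A", 5, **kwargs)
            assert label.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sample_method_provenance_and_count(self, helix10, toy_lib):
        label = attach(toy_lib, helix10, "A", 5, sample=40, rng_seed=2,
                       eval_clash=False)
        assert label.n_rotamers == 40
        assert label.provenance["method"] == "sample"

    def test_spin_properties(self, helix10, toy_lib):
        label = attach(toy_lib, helix10, "A", 5, eval_clash=False)
        # spin center i = spin-weighted mean of rotamer i's spin atoms
        idx = [toy_lib.atom_index(n) for n in toy_lib.spin_atoms]
        expected = label.coords[:, idx, :].mean(axis=1)  # weights 0.5/0.5
        np.testing.assert_allclose(label.spin_centers, expected, atol=1e-12)
        np.testing.assert_allclose(
            label.spin_centroid,
            (label.weights[:, None] * label.spin_centers).sum(axis=0),
            atol=1e-12,
        )

    def test_all_trimmed_raises(self, helix10, toy_lib):
        # bury every rotamer under a dense cage of foreign atoms
        free = attach(toy_lib, helix10, "A", 5, eval_clash=False)
        cage = free.coords.reshape(-1, 3)
        atoms = helix10.atoms + [
            Atom(serial=0, name=f"X{i}", element="C", resname="LIG",
                 resnum=200 + i, chain="Z", het=True)
            for i in range(len(cage))
        ]
        s = StructureModel(
            atoms=atoms, models=[np.vstack([helix10.coords, cage])]
        )
        with pytest.raises(EmptyEnsembleError):
            attach(toy_lib, s, "A", 5, eval_clash=True, kT=1e-8)

    def test_missing_backbone_raises(self, helix10, toy_lib):
        from sdsl.errors import IncompleteBackboneError
        from sdsl.structure_io import select

        sub = select(helix10, "not (resnum 5 and name CA)")
        s = StructureModel(atoms=sub.atoms, models=[sub.coords])
        with pytest.raises(IncompleteBackboneError):
            attach(toy_lib, s, "A", 5)


class TestWrapAngle:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.0), (180.0, 180.0), (-180.0, 180.0), (190.0, -170.0),
         (540.0, 180.0), (-190.0, 170.0)],
    )
    def test_values(self, x, expected):
        assert wrap_angle(x) == pytest.approx(expected)
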