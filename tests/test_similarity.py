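import numpy as np
import pytest
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.transform import Rotation

from foldswitch_bench.similarity import (
    Superposition,
    d0,
    kabsch,
    rmsd_backbone,
    tm_score,
)
from foldswitch_bench.structio import RegionSpec
from foldswitch_bench.synthetic import build_helix, make_pair, perturb

from conftest import make_structure


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


# ---------------------------------------------------------------- oracles


def tm_of(R, t, X, Y, d0_val):
    d2 = ((X @ R.T + t - Y) ** 2).sum(axis=1)
    return (1.0 / (1.0 + d2 / d0_val**2)).mean()


def random_restart_tm_oracle(X, Y, d0_val, n_restarts=500, seed=0):
    """Maximize TM over superpositions by many random rigid starts, each
    followed by local refinement (select close pairs, re-superpose). Uses its
    own SVD superposition, independent of the package's search strategy."""

    def svd_fit(A, B):
        ac, bc = A.mean(0), B.mean(0)
        U, S, Vt = np.linalg.svd((A - ac).T @ (B - bc))
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        return R, bc - R @ ac

    rng = np.random.default_rng(seed)
    R0, t0 = svd_fit(X, Y)
    candidates = [(tm_of(R0, t0, X, Y, d0_val), R0, t0)]
    for _ in range(n_restarts):
        R = Rotation.random(random_state=rng).as_matrix()
        # start by aligning centroids under the random rotation
        t = Y.mean(0) - X.mean(0) @ R.T
        for cutoff in (d0_val + 3, d0_val + 2, d0_val + 1, d0_val + 1, 3.0, 3.0, 3.0, 3.0):
            d2 = ((X @ R.T + t - Y) ** 2).sum(axis=1)
            sel = np.where(d2 < cutoff**2)[0]
            if len(sel) < 3:
                sel = np.argsort(d2)[:3]
            R, t = svd_fit(X[sel], Y[sel])
        candidates.append((tm_of(R, t, X, Y, d0_val), R, t))
    candidates.sort(key=lambda c: -c[0])
    best = candidates[0][0]
    # polish the leading basins with a direct simplex ascent of the TM itself
    from scipy.optimize import minimize

    for tm0, R, t in candidates[:10]:
        def neg_tm(x, R=R, t=t):
            Rx = Rotation.from_rotvec(x[:3]).as_matrix() @ R
            return -tm_of(Rx, t + x[3:], X, Y, d0_val)

        res = minimize(neg_tm, np.zeros(6), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 4000})
        best = max(best, -res.fun)
    return best


# ---------------------------------------------------------------- kabsch


class TestKabsch:
    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 5, (12, 3))
        R, t = random_rigid(rng)
        Y = X @ R.T + t
        sup = kabsch(X, Y)
        assert np.allclose(sup.apply(X), Y, atol=1e-9)
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_translation_only_toy(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        Y = X + np.array([5.0, 5.0, 5.0])
        sup = kabsch(X, Y)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, [5, 5, 5], atol=1e-9)

    def test_mirror_image_never_fit_by_reflection(self):
        # chiral 4-point set; brute-force over many proper rotations shows the
        # best achievable RMSD is strictly positive, and kabsch must not beat
        # it by sneaking in a reflection
        X = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 2.5]])
        Y = X.copy()
        Y[:, 2] *= -1  # mirror
        sup = kabsch(X, Y)
        rmsd_kabsch = np.sqrt(((sup.apply(X) - Y) ** 2).sum() / len(X))
        rng = np.random.default_rng(1)
        best_brute = np.inf
        for _ in range(20000):
            R = Rotation.random(random_state=rng).as_matrix()
            Xr = X @ R.T
            t = Y.mean(0) - Xr.mean(0)
            best_brute = min(best_brute, np.sqrt(((Xr + t - Y) ** 2).sum() / len(X)))
        assert rmsd_kabsch > 0.1
        assert rmsd_kabsch <= best_brute + 1e-6

    def test_matches_biopython_superimposer(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(0, 4, (20, 3))
            Y = rng.normal(0, 4, (20, 3))
            sup = kabsch(X, Y)
            ours = np.sqrt(((sup.apply(X) - Y) ** 2).sum() / len(X))
            svd = SVDSuperimposer()
            svd.set(Y, X)  # biopython maps the second onto the first
            svd.run()
            assert ours == pytest.approx(svd.get_rms(), abs=1e-9)

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="shape"):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError, match="3 point"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(np.zeros((5, 3)), line)  # coincident points


# ---------------------------------------------------------------- d0


@pytest.mark.parametrize(
    "L,expected",
    [(21, 0.5), (126, 4.159), (15, 0.5), (30, 1.2577)],
)
def test_d0_values(L, expected):
    assert d0(L) == pytest.approx(expected, abs=1e-3)


def test_d0_monotone_and_floor():
    values = [d0(L) for L in range(3, 200)]
    assert all(b >= a for a, b in zip(values, values[1:]))
    assert min(values) == 0.5
    with pytest.raises(ValueError):
        d0(2)


# ---------------------------------------------------------------- RMSD


class TestRmsdBackbone:
    def test_self_comparison_zero(self, default_pair):
        r = rmsd_backbone(default_pair.conf_a, default_pair.conf_a, default_pair.region_a)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self, default_pair):
        rng = np.random.default_rng(3)
        R, t = random_rigid(rng)
        from dataclasses import replace

        moved = replace(
            default_pair.conf_a,
            residues=tuple(
                replace(
                    res,
                    atoms=tuple(
                        replace(a, coords=tuple(R @ a.xyz + t)) for a in res.atoms
                    ),
                )
                for res in default_pair.conf_a.residues
            ),
        )
        r = rmsd_backbone(moved, default_pair.conf_a, default_pair.region_a)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_direct_formula_on_displaced_atom(self):
        # 4 residues of backbone; displace one O atom; the structures are
        # otherwise identical so the optimal superposition is not identity,
        # but a direct sum over a brute-force rotation search must agree
        base = {
            i: {
                "N": (3.8 * i, 0, 0),
                "CA": (3.8 * i + 1.2, 1.0, 0),
                "C": (3.8 * i + 2.2, 0.2, 1.0),
                "O": (3.8 * i + 2.0, -1.0, 1.4),
            }
            for i in range(1, 5)
        }
        ref = make_structure(base)
        moved = {k: dict(v) for k, v in base.items()}
        moved[3]["O"] = tuple(np.asarray(moved[3]["O"]) + np.array([0, 0, 2.0]))
        pred = make_structure(moved)
        region = RegionSpec(1, 4)
        ours = rmsd_backbone(pred, ref, region)
        X = pred.coords(("N", "CA", "C", "O"))
        Y = ref.coords(("N", "CA", "C", "O"))
        # independent oracle: biopython's superimposer computes the same
        # optimal RMSD = sqrt(sum d_i^2 / n) after its own SVD fit
        svd = SVDSuperimposer()
        svd.set(Y, X)
        svd.run()
        assert ours == pytest.approx(svd.get_rms(), abs=1e-9)
        # and no random proper rotation may do better than the optimum
        rng = np.random.default_rng(4)
        for _ in range(2000):
            R = Rotation.random(random_state=rng).as_matrix()
            Xr = X @ R.T
            t = Y.mean(0) - Xr.mean(0)
            assert ours <= np.sqrt(((Xr + t - Y) ** 2).sum() / len(X)) + 1e-9


# ---------------------------------------------------------------- TM-score


class TestTmScore:
    def test_self_is_one(self, default_pair):
        s = tm_score(default_pair.conf_a, default_pair.conf_a, default_pair.region_a)
        assert s.tm == pytest.approx(1.0, abs=1e-9)
        assert s.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self, default_pair):
        from dataclasses import replace

        rng = np.random.default_rng(5)
        R, t = random_rigid(rng)
        moved = replace(
            default_pair.conf_a,
            residues=tuple(
                replace(
                    res,
                    atoms=tuple(
                        replace(a, coords=tuple(R @ a.xyz + t)) for a in res.atoms
                    ),
                )
                for res in default_pair.conf_a.residues
            ),
        )
        s = tm_score(moved, default_pair.conf_a, default_pair.region_a)
        assert s.tm == pytest.approx(1.0, abs=1e-9)

    def test_noise_monotone_in_expectation(self, default_pair):
        means = []
        for sigma in (0.2, 0.6, 1.2):
            tms = [
                tm_score(
                    perturb(default_pair.conf_a, sigma, seed=k),
                    default_pair.conf_a,
                    default_pair.region_a,
                ).tm
                for k in range(6)
            ]
            means.append(np.mean(tms))
        assert means[0] > means[1] > means[2]

    def test_never_below_single_kabsch_seed(self, default_pair):
        pred = perturb(default_pair.conf_b, 2.0, seed=9)
        from foldswitch_bench.similarity import _tm_of, _paired_region_coords

        X, Y = _paired_region_coords(
            pred, default_pair.conf_a, default_pair.region_a, ("CA",)
        )
        single = _tm_of(kabsch(X, Y), X, Y, d0(len(Y)))
        full = tm_score(pred, default_pair.conf_a, default_pair.region_a).tm
        assert full >= single - 1e-12

    def test_matches_random_restart_oracle(self, default_pair):
        # smaller version of the full equivalence sweep in the acceptance suite
        region = default_pair.region_a
        from foldswitch_bench.similarity import _paired_region_coords

        for seed in range(3):
            pred = perturb(default_pair.conf_a, 1.0, seed=seed)
            ours = tm_score(pred, default_pair.conf_a, region).tm
            X, Y = _paired_region_coords(pred, default_pair.conf_a, region, ("CA",))
            oracle = random_restart_tm_oracle(X, Y, d0(len(Y)), n_restarts=200, seed=seed)
            assert ours == pytest.approx(oracle, abs=0.005)

    def test_sequence_mismatch_rejected(self, default_pair):
        other = make_pair_like(default_pair)
        with pytest.raises(Exception, match="mismatch"):
            tm_score(other, default_pair.conf_a, default_pair.region_a)

    def test_short_region_rejected(self, default_pair):
        with pytest.raises(Exception, match="shorter"):
            tm_score(default_pair.conf_a, default_pair.conf_a, RegionSpec(16, 19))


def make_pair_like(pair):
    seq = "W" * len(pair.conf_a)
    return build_helix(seq)
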