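"""The RMSD triad, torsional deviations and the selectivity parameter."""

import itertools

import numpy as np
import pytest

from glycodock._geometry import quaternion_to_matrix, random_unit_quaternion, wrap_angle
from glycodock.docking_engine import DockScore, Pose
from glycodock.fixtures import FixtureSpec, make_chain, make_decoys
from glycodock.glycan_core import TorsionTree
from glycodock.pose_analysis import (
    AnalysisConfig,
    CorrespondenceError,
    compute_metrics,
    metric_triad,
    pose_rmsd,
    protocol_report,
    selectivity_ratio,
    torsion_deviation,
    _equivalent_oxygen_groups,
)


def rmsd_oracle(a, b):
    total = 0.0
    for pa, pb in zip(a, b):
        for x, y in zip(pa, pb):
            total += (x - y) ** 2
    return (total / len(a)) ** 0.5


def symmetric_rmsd_oracle(a, b, groups):
    """Exhaustive minimum over the product of within-group permutations."""
    best = None
    perm_sets = [list(itertools.permutations(g)) for g in groups]
    for combo in itertools.product(*perm_sets):
        mapping = {i: i for i in range(len(a))}
        for group, perm in zip(groups, combo):
            for i, j in zip(group, perm):
                mapping[i] = j
        b2 = np.array([b[mapping[i]] for i in range(len(b))])
        r = rmsd_oracle(a, b2)
        best = r if best is None else min(best, r)
    return best


class TestPoseRmsd:
    def test_identical_poses_zero(self, tetrasaccharide):
        c = tetrasaccharide.coords
        assert pose_rmsd(c, c) == 0.0

    def test_uniform_translation_exact(self, tetrasaccharide):
        c = tetrasaccharide.coords
        assert pose_rmsd(c, c + np.array([0.0, 3.0, 0.0])) == pytest.approx(3.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, tetrasaccharide, rng):
        c = tetrasaccharide.coords
        d = c + rng.normal(size=c.shape)
        assert pose_rmsd(c, d) == pytest.approx(rmsd_oracle(c, d), rel=1e-12)

    def test_symmetry_matches_exhaustive_permutation_oracle(self, disaccharide, rng):
        groups = _equivalent_oxygen_groups(disaccharide)
        assert groups  # sulfate + carboxylate groups exist
        c = disaccharide.coords
        for _ in range(5):
            d = c + rng.normal(scale=1.5, size=c.shape)
            expected = symmetric_rmsd_oracle(c, d, groups)
            assert pose_rmsd(c, d, disaccharide, True) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_never_exceeds_plain(self, disaccharide, rng):
        c = disaccharide.coords
        for _ in range(10):
            d = c + rng.normal(scale=2.0, size=c.shape)
            assert pose_rmsd(c, d, disaccharide, True) <= pose_rmsd(c, d) + 1e-12

    def test_atom_count_mismatch(self, disaccharide, tetrasaccharide):
        with pytest.raises(CorrespondenceError):
            pose_rmsd(disaccharide.coords, tetrasaccharide.coords)

    def test_triangle_inequality(self, disaccharide, rng):
        c = disaccharide.coords
        for _ in range(10):
            a = c + rng.normal(size=c.shape)
            b = c + rng.normal(size=c.shape)
            d = c + rng.normal(size=c.shape)
            assert pose_rmsd(a, d) <= pose_rmsd(a, b) + pose_rmsd(b, d) + 1e-12


class TestMetricTriad:
    def _poses(self, coords_list):
        return [Pose(coords=c, score=None, chromosome=None) for c in coords_list]

    def test_six_native_copies(self, tetrasaccharide):
        c = tetrasaccharide.coords
        triad = metric_triad(self._poses([c] * 6)[0], self._poses([c] * 6))
        assert triad["rmsd_average"] == 0.0
        assert triad["rmsd_lowest"] == 0.0
        assert triad["rmsd_intrapose"] == 0.0
        assert triad["recapitulated"] and triad["consistent"]

    def test_matches_pairwise_oracle_on_constructed_set(self, tetrasaccharide, rng):
        c = tetrasaccharide.coords
        native = Pose(coords=c, score=None, chromosome=None)
        poses = self._poses([c + rng.normal(size=c.shape) for _ in range(6)])
        triad = metric_triad(native, poses)
        rmsds = [rmsd_oracle(c, p.coords) for p in poses]
        pair = [
            rmsd_oracle(p.coords, q.coords)
            for p, q in itertools.combinations(poses, 2)
        ]
        assert len(pair) == 15
        assert triad["rmsd_average"] == pytest.approx(np.mean(rmsds), rel=1e-12)
        assert triad["rmsd_lowest"] == pytest.approx(min(rmsds), rel=1e-12)
        assert triad["rmsd_intrapose"] == pytest.approx(np.mean(pair), rel=1e-12)

    def test_single_pose_intrapose_absent_not_zero(self, tetrasaccharide):
        c = tetrasaccharide.coords
        triad = metric_triad(Pose(c, None, None), self._poses([c + 1.0]))
        assert triad["rmsd_intrapose"] is None
        assert triad["consistent"] is None

    def test_lowest_never_exceeds_average(self, tetrasaccharide, rng):
        c = tetrasaccharide.coords
        native = Pose(c, None, None)
        for _ in range(20):
            poses = self._poses([c + rng.normal(scale=3, size=c.shape) for _ in range(4)])
            triad = metric_triad(native, poses)
            assert triad["rmsd_lowest"] <= triad["rmsd_average"] + 1e-12

    def test_intrapose_invariant_under_pose_permutation(self, tetrasaccharide, rng):
        c = tetrasaccharide.coords
        native = Pose(c, None, None)
        poses = self._poses([c + rng.normal(size=c.shape) for _ in range(5)])
        t1 = metric_triad(native, poses)
        t2 = metric_triad(native, poses[::-1])
        assert t1["rmsd_intrapose"] == pytest.approx(t2["rmsd_intrapose"], rel=1e-12)

    def test_centroid_mode(self, tetrasaccharide):
        c = tetrasaccharide.coords
        native = Pose(c, None, None)
        # two poses displaced oppositely: centroid coincides with native
        poses = self._poses([c + np.array([2.0, 0, 0]), c - np.array([2.0, 0, 0])])
        cfg = AnalysisConfig(rmsd_mode="rmsd-to-centroid")
        triad = metric_triad(native, poses, cfg)
        assert triad["rmsd_average"] == pytest.approx(0.0, abs=1e-12)
        assert metric_triad(native, poses)["rmsd_average"] == pytest.approx(2.0, abs=1e-12)

    def test_empty_set_rejected(self, tetrasaccharide):
        with pytest.raises(ValueError):
            metric_triad(Pose(tetrasaccharide.coords, None, None), [])


class TestTorsionDeviation:
    def test_zero_for_identical_poses(self, tetrasaccharide):
        native = Pose(tetrasaccharide.coords, None, None)
        dev = torsion_deviation(native, [native] * 6, tetrasaccharide)
        assert dev["mean_dphi"] == pytest.approx(0.0, abs=1e-9)
        assert dev["mean_dpsi"] == pytest.approx(0.0, abs=1e-9)

    def test_wrap_point_cluster_uses_circular_mean(self):
        plan = [(-80.0, 178.0)]  # Psi planted next to the seam
        chain = make_chain(FixtureSpec(chain_length=2, torsion_plan=plan))
        native = Pose(chain.coords, None, None)
        tree = TorsionTree(chain, "flexible")
        base = tree.measure(chain.coords)
        gi = next(
            i for i, b in enumerate(tree.bonds)
            if b.tag == "glycosidic" and b.torsion_name == "psi"
        )
        poses = []
        for offset in (-4.0, -2.0, 2.0, 4.0):  # straddles +/-180
            targets = base.copy()
            targets[gi] = wrap_angle(178.0 + offset)
            poses.append(Pose(tree.apply(chain.coords, targets), None, None))
        dev = torsion_deviation(native, poses, chain)
        assert dev["per_linkage_dpsi"]["2->1"] < 5.0

    def test_invariant_under_global_rigid_motion(self, tetrasaccharide, rng):
        native = Pose(tetrasaccharide.coords, None, None)
        decoys = make_decoys(native, tetrasaccharide, "mixed", 3.0, 4, seed=2)
        dev1 = torsion_deviation(native, decoys, tetrasaccharide)
        R = quaternion_to_matrix(random_unit_quaternion(rng))
        t = rng.normal(size=3) * 10
        native2 = Pose(native.coords @ R.T + t, None, None)
        moved = [Pose(p.coords @ R.T + t, None, None) for p in decoys]
        dev2 = torsion_deviation(native2, moved, tetrasaccharide)
        for label in dev1["per_linkage_dpsi"]:
            assert dev1["per_linkage_dpsi"][label] == pytest.approx(
                dev2["per_linkage_dpsi"][label], abs=1e-6
            )


class TestSelectivityRatio:
    def test_threshold_arithmetic(self):
        ratio, selective = selectivity_ratio(100.0, 2.0)
        assert ratio == 50.0 and selective
        ratio, selective = selectivity_ratio(100.0, 10.0)
        assert ratio == 10.0 and not selective

    def test_homogeneity_in_score(self):
        r1, _ = selectivity_ratio(80.0, 3.7)
        r2, _ = selectivity_ratio(160.0, 3.7)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_zero_rmsd_gives_inf_selective(self):
        ratio, selective = selectivity_ratio(10.0, 0.0)
        assert ratio == float("inf") and selective

    def test_negative_score_never_selective(self):
        with pytest.warns(UserWarning):
            ratio, selective = selectivity_ratio(-50.0, 1.0)
        assert ratio == -50.0 and not selective


class TestProtocolReport:
    def _system(self, chain, native, pose_sets, name="sys"):
        return {"name": name, "chain": chain, "native": native, "pose_sets": pose_sets}

    def test_all_recapitulating_gives_unit_fractions(self, tetrasaccharide):
        native = Pose(tetrasaccharide.coords, None, None)
        near = make_decoys(native, tetrasaccharide, "translate", 0.5, 6, seed=0)
        for p in near:
            p.score = DockScore(100.0, {})
        sets = {r: near for r in ("rigid", "semi-rigid", "flexible")}
        df, summary = protocol_report([self._system(tetrasaccharide, native, sets)])
        assert summary["recapitulation_fraction"] == {
            "rigid": 1.0, "semi-rigid": 1.0, "flexible": 1.0
        }

    def test_stratified_counts_partition_totals(self, disaccharide, hexasaccharide):
        systems = []
        for chain, name in ((disaccharide, "short"), (hexasaccharide, "long")):
            native = Pose(chain.coords, None, None)
            near = make_decoys(native, chain, "translate", 0.5, 6, seed=1)
            far = make_decoys(native, chain, "translate", 6.0, 6, seed=1)
            systems.append(self._system(chain, native, {"rigid": near, "flexible": far}, name))
        df, summary = protocol_report(systems)
        for regime in ("rigid", "flexible"):
            total = df[df.regime == regime]["recapitulated"].mean()
            short = summary["recapitulation_fraction_2_4mer"][regime]
            long_ = summary["recapitulation_fraction_5_10mer"][regime]
            assert total == pytest.approx((short + long_) / 2)

    def test_report_files_written(self, tmp_path, tetrasaccharide):
        native = Pose(tetrasaccharide.coords, None, None)
        near = make_decoys(native, tetrasaccharide, "translate", 1.0, 6, seed=0)
        for p in near:
            p.score = DockScore(100.0, {})
        sets = {"rigid": near}
        protocol_report(
            [self._system(tetrasaccharide, native, sets)], out_dir=tmp_path
        )
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "rmsd_average.png").exists()


class TestComputeMetrics:
    def test_full_metric_bundle(self, standard_complex):
        receptor, chain, native, site = standard_complex
        from glycodock.docking_engine import ScoringContext

        ctx = ScoringContext(chain, receptor, site)
        decoys = make_decoys(native, chain, "translate", 1.0, 6, seed=4)
        for p in decoys:
            p.score = ctx.score(p.coords)
        m = compute_metrics(native, decoys, chain)
        assert m.rmsd_average == pytest.approx(1.0, abs=1e-9)
        assert m.recapitulated
        assert m.selectivity_ratio == pytest.approx(m.mean_score / 1.0, rel=1e-12)
        assert set(m.per_linkage_dpsi) == {lk.label for lk in chain.linkages}
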