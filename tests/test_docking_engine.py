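"""Chromosome templates, decoding, the surrogate score and the GA."""

import numpy as np
import pytest

from glycodock._geometry import kabsch, wrap_angle
from glycodock.docking_engine import (
    Chromosome,
    ConfigurationError,
    DockingJob,
    GAConfig,
    ScoringContext,
    build_regime,
    decode,
    dock_replicates,
    run_ga,
    score_pose,
)
from glycodock.fixtures import FixtureSpec, make_chain
from glycodock.glycan_core import Atom, GagChain
from glycodock.structure_io import Receptor, SiteDefinition, define_site
from glycodock.torsion_library import build_histogram


def tiny_ga(**kw):
    defaults = dict(n_runs=1, n_operations=120, population_size=20, refine=False, seed=0)
    defaults.update(kw)
    return GAConfig(**defaults)


def point_system(r=3.0, lig_q=-1.0, rec_q=1.0):
    """One-acceptor ligand vs one-donor receptor at separation r."""
    lig = GagChain(
        [Atom(0, "O", "O1", np.zeros(3), residue_index=1, formal_charge=lig_q)],
        [], [],
    )
    rec_atoms = [
        Atom(0, "N", "NZ", np.array([r, 0.0, 0.0]), residue_index=1, formal_charge=rec_q),
        Atom(1, "C", "CZ", np.array([r + 1.35, 0.0, 0.0]), residue_index=1),
    ]
    receptor = Receptor(atoms=rec_atoms, labels=["GND1", "GND1"])
    site = SiteDefinition(
        radius=6.0, site_atom_ids=(0, 1), residue_labels=("GND1", "GND1"),
        box_min=np.array([-5.0, -5.0, -5.0]), box_max=np.array([r + 5.0, 5.0, 5.0]),
    )
    return lig, receptor, site


class TestBuildRegime:
    def test_rigid_has_no_mutable_glycosidic_genes(self, tetrasaccharide):
        template = build_regime(tetrasaccharide, "rigid")
        for bond, mob in zip(template.tree.bonds, template.mobility):
            if bond.tag == "glycosidic":
                assert mob == "fixed"
            else:
                assert mob == "free"

    def test_semi_rigid_default_histograms_centered_on_initial(self, tetrasaccharide):
        template = build_regime(tetrasaccharide, "semi-rigid")
        for gi, hist in template.histograms.items():
            assert hist.center == pytest.approx(template.initial[gi])
            assert hist.halfwidth == 30.0

    def test_flexible_hexamer_has_at_least_36_free_genes(self, hexasaccharide):
        template = build_regime(hexasaccharide, "flexible")
        assert sum(m == "free" for m in template.mobility) >= 36

    def test_histogram_excluding_initial_rejected(self, tetrasaccharide):
        template = build_regime(tetrasaccharide, "flexible")
        bond = next(b for b in template.tree.bonds if b.tag == "glycosidic")
        gi = template.tree.bonds.index(bond)
        off_center = build_histogram(wrap_angle(template.initial[gi] + 120.0), 30.0)
        with pytest.raises(ConfigurationError):
            build_regime(
                tetrasaccharide, "semi-rigid",
                histograms={(bond.linkage_index, bond.torsion_name): off_center},
            )


class TestDecode:
    def test_identity_chromosome_reproduces_template(self, tetrasaccharide):
        template = build_regime(tetrasaccharide, "rigid")
        coords = decode(template.identity_chromosome(), template)
        assert np.abs(coords - template.template_coords).max() < 1e-9

    def test_pure_translation(self, tetrasaccharide):
        template = build_regime(tetrasaccharide, "rigid")
        chrom = template.identity_chromosome()
        chrom.translation = np.array([3.0, 0.0, 0.0])
        coords = decode(chrom, template)
        assert np.allclose(coords - template.template_coords, [3.0, 0.0, 0.0], atol=1e-9)

    def test_single_psi_gene_moves_only_distal_atoms(self, tetrasaccharide):
        template = build_regime(tetrasaccharide, "flexible")
        chrom = template.identity_chromosome()
        gi = next(
            i for i, b in enumerate(template.tree.bonds)
            if b.tag == "glycosidic" and b.torsion_name == "psi"
        )
        chrom.torsions[gi] = wrap_angle(template.initial[gi] + 20.0)
        coords = decode(chrom, template)
        assert template.tree.measure(coords)[gi] == pytest.approx(
            wrap_angle(template.initial[gi] + 20.0), abs=1e-9
        )
        mask = template.tree.distal_mask(gi)
        assert np.allclose(coords[~mask], template.template_coords[~mask])

    def test_rigid_body_genes_recoverable(self, tetrasaccharide, rng):
        from glycodock._geometry import quaternion_to_matrix, random_unit_quaternion

        template = build_regime(tetrasaccharide, "rigid")
        chrom = template.identity_chromosome()
        chrom.quaternion = random_unit_quaternion(rng)
        chrom.translation = rng.normal(size=3) * 4
        coords = decode(chrom, template)
        R, t = kabsch(template.template_coords - template.centroid,
                      coords - template.centroid)
        assert np.abs(R - quaternion_to_matrix(chrom.quaternion)).max() < 1e-9
        assert np.abs(t - chrom.translation).max() < 1e-9


class TestScore:
    def test_infinite_separation_zeroes_interaction_terms(self, standard_complex):
        receptor, chain, native, site = standard_complex
        far = native.coords + np.array([500.0, 0.0, 0.0])
        # move inside the accepted box? far poses are rejected with -inf
        s = score_pose(far, chain, receptor, site)
        assert s.total == -np.inf or all(
            abs(s.terms[k]) < 1e-12 for k in ("hbond", "electrostatic")
        )

    def test_electrostatic_closed_form_single_pair(self):
        lig, receptor, site = point_system(r=3.0)
        ctx = ScoringContext(lig, receptor, site)
        s = ctx.score(np.zeros((1, 3)))
        # O at origin vs N+ at 3.0 and C at 4.35; per-pair 332*q1*q2/(4 r^2)
        expected = 332.0 * (-1.0) / (4.0 * 9.0)
        assert s.terms["electrostatic"] == pytest.approx(expected, abs=1e-12)

    def test_elec_pair_clamp(self):
        lig, receptor, site = point_system(r=0.6)
        ctx = ScoringContext(lig, receptor, site)
        s = ctx.score(np.zeros((1, 3)))
        # 332/(4*0.36) >> 10, clamped at -10 per pair
        assert s.terms["electrostatic"] == pytest.approx(-10.0, abs=1e-12)

    def test_clash_cap_engages_below_contact(self):
        lig, receptor, site = point_system()
        ctx = ScoringContext(lig, receptor, site)
        rm = 1.52 + 1.55
        at_optimum = ctx.score(np.array([[receptor.atoms[0].coords[0] - rm, 0.0, 0.0]]))
        clashed = ctx.score(np.array([[receptor.atoms[0].coords[0] - 0.5 * rm, 0.0, 0.0]]))
        assert clashed.total < at_optimum.total

    def test_score_deterministic_bit_for_bit(self, standard_complex):
        receptor, chain, native, site = standard_complex
        a = score_pose(native, chain, receptor, site)
        b = score_pose(native, chain, receptor, site)
        assert a.total == b.total
        assert a.terms == b.terms


class TestRegimeNestingOracle:
    def test_grid_search_best_scores_nest(self, standard_complex):
        """Exhaustive glycosidic-torsion grid: the best reachable score can
        only grow as the regime widens from rigid to +/-30 deg to free."""
        receptor, chain, native, site = standard_complex
        template = build_regime(chain, "flexible")
        ctx = ScoringContext(chain, receptor, site)
        gi = next(
            i for i, b in enumerate(template.tree.bonds)
            if b.tag == "glycosidic" and b.torsion_name == "psi"
        )
        chrom = template.identity_chromosome()

        def best_over(deltas):
            best = -np.inf
            for d in deltas:
                chrom.torsions[gi] = wrap_angle(template.initial[gi] + d)
                best = max(best, ctx.score(decode(chrom, template)).total)
            return best

        rigid_best = best_over([0.0])
        semi_best = best_over(np.arange(-30.0, 30.1, 5.0))
        flex_best = best_over(np.arange(-180.0, 180.0, 5.0))
        assert rigid_best <= semi_best + 1e-9
        assert semi_best <= flex_best + 1e-9


class TestRunGA:
    def test_fixed_seed_reproducible(self, standard_complex):
        receptor, chain, native, site = standard_complex
        job = DockingJob(receptor, site, chain, "rigid", tiny_ga())
        a = run_ga(job, run_seed=99, max_poses=2)
        b = run_ga(job, run_seed=99, max_poses=2)
        assert a[0].score.total == b[0].score.total
        assert np.array_equal(a[0].coords, b[0].coords)

    def test_zero_operations_returns_best_of_random_start(self, standard_complex):
        receptor, chain, native, site = standard_complex
        job = DockingJob(receptor, site, chain, "rigid", tiny_ga(n_operations=0))
        poses = run_ga(job, run_seed=1)
        assert len(poses) >= 1
        assert np.isfinite(poses[0].score.total)

    def test_semi_rigid_bound_holds_for_every_evaluation(self, standard_complex):
        receptor, chain, native, site = standard_complex
        template = build_regime(chain, "semi-rigid")
        bounded = [gi for gi, m in enumerate(template.mobility) if m == "bounded"]
        violations = []

        def observer(chrom):
            for gi in bounded:
                delta = abs(wrap_angle(chrom.torsions[gi] - template.initial[gi]))
                if delta > 30.0 + 1e-9:
                    violations.append(delta)

        job = DockingJob(receptor, site, chain, "semi-rigid", tiny_ga(n_operations=300))
        run_ga(job, run_seed=5, observer=observer)
        assert violations == []

    def test_ranked_descending_and_deduplicated(self, standard_complex):
        receptor, chain, native, site = standard_complex
        job = DockingJob(receptor, site, chain, "rigid", tiny_ga(n_operations=200))
        poses = run_ga(job, run_seed=3, max_poses=4)
        scores = [p.score.total for p in poses]
        assert scores == sorted(scores, reverse=True)
        from glycodock.pose_analysis import pose_rmsd

        for i in range(len(poses)):
            for j in range(i + 1, len(poses)):
                assert pose_rmsd(poses[i], poses[j]) >= 0.25 - 1e-9


class TestDockReplicates:
    def test_default_triplicate_top2_gives_six_poses(self, standard_complex):
        receptor, chain, native, site = standard_complex
        cfg = tiny_ga(n_runs=3, n_operations=60, replicates=3, top_per_run=2)
        job = DockingJob(receptor, site, chain, "rigid", cfg)
        ps = dock_replicates(job)
        assert len(ps) == 6
        assert sorted(p.rank for p in ps) == [1, 2, 3, 4, 5, 6]
        assert {p.replicate_id for p in ps} == {0, 1, 2}

    def test_single_run_single_replicate_gives_one(self, standard_complex):
        receptor, chain, native, site = standard_complex
        cfg = tiny_ga(n_runs=1, n_operations=60, replicates=1, top_per_run=1)
        job = DockingJob(receptor, site, chain, "rigid", cfg)
        assert len(dock_replicates(job)) == 1

    def test_deterministic_ordering(self, standard_complex):
        receptor, chain, native, site = standard_complex
        cfg = tiny_ga(n_runs=2, n_operations=60, replicates=2, top_per_run=2)
        job = DockingJob(receptor, site, chain, "rigid", cfg)
        a = dock_replicates(job)
        b = dock_replicates(job)
        for pa, pb in zip(a, b):
            assert pa.score.total == pb.score.total
            assert (pa.replicate_id, pa.run_id, pa.rank) == (pb.replicate_id, pb.run_id, pb.rank)

    def test_provenance_recorded(self, standard_complex):
        receptor, chain, native, site = standard_complex
        cfg = tiny_ga(n_runs=1, n_operations=30, replicates=2, top_per_run=1, seed=7)
        job = DockingJob(receptor, site, chain, "semi-rigid", cfg)
        ps = dock_replicates(job)
        assert ps.provenance["regime"] == "semi-rigid"
        assert ps.provenance["replicate_seeds"] == [7, 8]
        assert len(ps.provenance["config_hash"]) == 12
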