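"""Genetic-algorithm pose search with regime-dependent glycosidic flexibility.

A chromosome is (translation, orientation quaternion, one torsion gene per
rotatable bond).  Substituent torsions are always free; glycosidic Phi/Psi
genes are fixed at their initial values (rigid regime), resampled from a
bounded torsional histogram (semi-rigid, +/-30 deg by default) or free over
the full circle (flexible).  Ring puckers are never sampled.

The interaction score is a documented surrogate for a commercial docking
score (which is proprietary): an additive combination of a hydrogen-bond
well, distance-dielectric screened electrostatics, a 6-12 dispersion term
and clash/strain penalties, weighted so that well-docked synthetic GAG
complexes land in a 40-150 range where the conventional score/RMSD
selectivity threshold of 50 remains meaningful.  Score-dependent thresholds
are configuration, not constants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from ._geometry import (
    axis_angle_quaternion,
    quaternion_multiply,
    quaternion_to_matrix,
    random_unit_quaternion,
    wrap_angle,
)
from .glycan_core import GagChain, TorsionTree, nonbonded_pairs
from .torsion_library import TorsionHistogram, build_histogram

__all__ = [
    "GAConfig",
    "ScoreWeights",
    "DockScore",
    "Chromosome",
    "Pose",
    "PoseSet",
    "ChromosomeTemplate",
    "DockingJob",
    "ConfigurationError",
    "build_regime",
    "decode",
    "score_pose",
    "run_ga",
    "dock_replicates",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10, "P": 1.80}


class ConfigurationError(ValueError):
    pass


@dataclass
class GAConfig:
    """Search-budget and operator parameters for the genetic algorithm."""

    n_runs: int = 100
    n_operations: int = 10_000  # offspring evaluations per run
    population_size: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1  # per gene
    tournament_size: int = 2
    replicates: int = 3
    top_per_run: int = 2  # retained per replicate experiment
    seed: int = 0
    translation_sigma: float = 1.0  # Å
    orientation_sigma_deg: float = 20.0
    reorient_prob: float = 0.25  # chance an orientation mutation is a full resample
    retranslate_prob: float = 0.1  # chance a translation mutation is a full resample
    dedup_rmsd: float = 0.25  # Å
    box_margin: float = 2.0  # Å around the site bounding box
    refine: bool = True  # pattern-search refinement of the top poses
    refine_top: int = 2  # archive entries refined per run

    def __post_init__(self):
        for name in ("n_runs", "population_size", "replicates", "top_per_run"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_operations < 0:
            raise ConfigurationError("n_operations must be >= 0")
        for name in ("crossover_prob", "mutation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ScoreWeights:
    hbond: float = 8.0
    electrostatic: float = 2.0
    vdw: float = 0.5
    repulsion: float = 1.0
    strain: float = 1.0


@dataclass
class DockScore:
    total: float
    terms: dict


@dataclass
class Chromosome:
    translation: np.ndarray  # (3,) Å, offset of the ligand centroid
    quaternion: np.ndarray  # (4,) unit, (w, x, y, z)
    torsions: np.ndarray  # (n_bonds,) degrees, absolute targets

    def copy(self) -> "Chromosome":
        return Chromosome(self.translation.copy(), self.quaternion.copy(), self.torsions.copy())


@dataclass
class Pose:
    coords: np.ndarray
    score: DockScore | None
    chromosome: Chromosome | None
    run_id: int | None = None
    replicate_id: int | None = None
    rank: int | None = None
    ground_truth: dict | None = None


@dataclass
class PoseSet:
    poses: list
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.poses)

    def __len__(self):
        return len(self.poses)

    def __getitem__(self, i):
        return self.poses[i]


# ---------------------------------------------------------------------------
# regimes / chromosome templates


class ChromosomeTemplate:
    """Gene layout for one ligand under one torsional regime.

    Holds the torsion tree (built over the full flexible bond set so the
    three regimes share one gene layout), per-gene mobility tags, initial
    values measured on the input geometry, and the bounded-gene histograms.
    """

    def __init__(self, chain: GagChain, regime: str, histograms=None):
        self.chain = chain
        self.regime = regime
        self.tree = TorsionTree(chain, "flexible")
        self.template_coords = chain.coords
        self.centroid = self.template_coords.mean(axis=0)
        self.initial = self.tree.measure(self.template_coords)
        self.mobility: list[str] = []
        self.histograms: dict[int, TorsionHistogram] = {}
        for gi, bond in enumerate(self.tree.bonds):
            if bond.tag == "substituent":
                self.mobility.append("free")
                continue
            if regime == "rigid":
                self.mobility.append("fixed")
            elif regime == "flexible":
                self.mobility.append("free")
            else:  # semi-rigid
                self.mobility.append("bounded")
                hist = None
                if histograms is not None:
                    hist = histograms.get((bond.linkage_index, bond.torsion_name))
                if hist is None:
                    hist = build_histogram(center=self.initial[gi], halfwidth=30.0)
                if not hist.supports(self.initial[gi]):
                    raise ConfigurationError(
                        f"histogram support excludes the initial torsion "
                        f"({self.initial[gi]:.1f} deg) of linkage "
                        f"{bond.linkage_index} {bond.torsion_name}"
                    )
                self.histograms[gi] = hist

        self.fixed_mask = np.array([m == "fixed" for m in self.mobility])

    @property
    def n_torsions(self) -> int:
        return len(self.tree.bonds)

    def identity_chromosome(self) -> Chromosome:
        return Chromosome(
            np.zeros(3), np.array([1.0, 0.0, 0.0, 0.0]), self.initial.copy()
        )


def build_regime(chain: GagChain, regime: str, histograms=None) -> ChromosomeTemplate:
    """Chromosome template for a regime; histogram defaults are centered on
    the chain's initial torsions with +/-30 deg support (semi-rigid only)."""
    return ChromosomeTemplate(chain, regime, histograms)


def decode(chrom: Chromosome, template: ChromosomeTemplate) -> np.ndarray:
    """Chromosome -> heavy-atom coordinates in the receptor frame.

    Torsions are applied along the reducing-end-rooted spanning tree, then
    the whole ligand is rotated about the template centroid and translated.
    """
    torsions = np.where(template.fixed_mask, template.initial, chrom.torsions)
    coords = template.tree.apply(
        template.template_coords, torsions, reference_torsions=template.initial
    )
    R = quaternion_to_matrix(chrom.quaternion)
    return (coords - template.centroid) @ R.T + template.centroid + chrom.translation


# ---------------------------------------------------------------------------
# scoring


@njit(cache=True)
def _score_kernel(coords, rec_xyz, lig_q, rec_q, lig_r, rec_r,
                  acc_idx, donor_idx, donor_ante, strain_i, strain_j):
    n_lig = coords.shape[0]
    n_rec = rec_xyz.shape[0]
    elec = 0.0
    vdw_attr = 0.0
    repulsion = 0.0
    for i in range(n_lig):
        for j in range(n_rec):
            dx = coords[i, 0] - rec_xyz[j, 0]
            dy = coords[i, 1] - rec_xyz[j, 1]
            dz = coords[i, 2] - rec_xyz[j, 2]
            d = (dx * dx + dy * dy + dz * dz) ** 0.5
            if d < 0.5:
                d = 0.5
            # screened electrostatics, distance-dependent dielectric eps = 4r
            e = 332.0 * lig_q[i] * rec_q[j] / (4.0 * d * d)
            if e > 10.0:
                e = 10.0
            elif e < -10.0:
                e = -10.0
            elec += e
            # 6-12 dispersion/repulsion, clash-capped
            x6 = ((lig_r[i] + rec_r[j]) / d) ** 6
            lj = 0.2 * (x6 * x6 - 2.0 * x6)
            if lj < 0.0:
                vdw_attr -= lj
            else:
                repulsion += lj if lj < 10.0 else 10.0
    # hydrogen bonds: each cationic donor N contributes its single best
    # (distance x angle) weight over the ligand O acceptors
    hbond = 0.0
    for jj in range(donor_idx.size):
        j = donor_idx[jj]
        best = 0.0
        v1x = donor_ante[jj, 0] - rec_xyz[j, 0]
        v1y = donor_ante[jj, 1] - rec_xyz[j, 1]
        v1z = donor_ante[jj, 2] - rec_xyz[j, 2]
        n1 = (v1x * v1x + v1y * v1y + v1z * v1z) ** 0.5
        for ii in range(acc_idx.size):
            i = acc_idx[ii]
            v2x = coords[i, 0] - rec_xyz[j, 0]
            v2y = coords[i, 1] - rec_xyz[j, 1]
            v2z = coords[i, 2] - rec_xyz[j, 2]
            dd = (v2x * v2x + v2y * v2y + v2z * v2z) ** 0.5
            wd = (3.5 - dd) / 0.5
            if wd <= 0.0:
                continue
            if wd > 1.0:
                wd = 1.0
            cosang = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * dd)
            if cosang > 1.0:
                cosang = 1.0
            elif cosang < -1.0:
                cosang = -1.0
            ang = np.degrees(np.arccos(cosang))
            wa = (ang - 120.0) / 30.0
            if wa <= 0.0:
                continue
            if wa > 1.0:
                wa = 1.0
            wgt = wd * wa
            if wgt > best:
                best = wgt
        hbond += best
    # internal strain: capped repulsion over >=4-bond-separated pairs
    strain = 0.0
    for m in range(strain_i.size):
        i = strain_i[m]
        j = strain_j[m]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        if d < 0.5:
            d = 0.5
        y6 = (0.85 * (lig_r[i] + lig_r[j]) / d) ** 6
        ljs = 0.2 * (y6 * y6 - 2.0 * y6)
        if ljs > 0.0:
            strain += ljs if ljs < 10.0 else 10.0
    return hbond, elec, vdw_attr, repulsion, strain


class ScoringContext:
    """Precomputed arrays for fast pose scoring against one site."""

    def __init__(self, chain: GagChain, receptor, site, weights: ScoreWeights = ScoreWeights()):
        self.weights = weights
        self.site = site
        lig = chain.atoms
        self.lig_q = np.array([a.formal_charge for a in lig])
        self.lig_r = np.array([VDW_RADII.get(a.element, 1.7) for a in lig])
        self.lig_acceptor = np.array([a.element == "O" for a in lig])
        self.acc_idx = np.nonzero(self.lig_acceptor)[0].astype(np.int64)
        sid = list(site.site_atom_ids)
        satoms = [receptor.atoms[i] for i in sid]
        self.rec_xyz = np.array([a.coords for a in satoms])
        self.rec_q = np.array([a.formal_charge for a in satoms])
        self.rec_r = np.array([VDW_RADII.get(a.element, 1.7) for a in satoms])
        donor = [k for k, a in enumerate(satoms) if a.element == "N" and a.formal_charge > 0]
        self.donor_idx = np.array(donor, dtype=int)
        # antecedent heavy atom of each donor: nearest C in the same residue
        ante = []
        for k in donor:
            lab = site.residue_labels[k]
            cands = [
                m
                for m, a in enumerate(satoms)
                if site.residue_labels[m] == lab and a.element == "C"
            ]
            if cands:
                dists = [np.linalg.norm(self.rec_xyz[m] - self.rec_xyz[k]) for m in cands]
                ante.append(self.rec_xyz[cands[int(np.argmin(dists))]])
            else:
                ante.append(self.rec_xyz[k] + np.array([0.0, 0.0, 1.0]))
        self.donor_ante = np.array(ante) if donor else np.zeros((0, 3))
        # intra-ligand pairs >= 4 bonds apart (strain term)
        self.strain_i, self.strain_j = nonbonded_pairs(chain, 4)
        self.box_min = site.box_min - 2.0
        self.box_max = site.box_max + 2.0

    def score(self, coords: np.ndarray) -> DockScore:
        w = self.weights
        centroid = coords.mean(axis=0)
        if np.any(centroid < self.box_min - 10.0) or np.any(centroid > self.box_max + 10.0):
            return DockScore(-np.inf, {"rejected": True})
        hbond, elec, vdw_attr, repulsion, strain = _score_kernel(
            np.ascontiguousarray(coords),
            self.rec_xyz,
            self.lig_q,
            self.rec_q,
            self.lig_r,
            self.rec_r,
            self.acc_idx,
            self.donor_idx,
            self.donor_ante,
            self.strain_i,
            self.strain_j,
        )
        elec_attr = max(-elec, 0.0)
        total = (
            w.hbond * hbond
            + w.electrostatic * elec_attr
            + w.vdw * vdw_attr
            - w.repulsion * repulsion
            - w.strain * strain
        )
        return DockScore(
            float(total),
            {
                "hbond": hbond,
                "electrostatic": elec,
                "vdw_external": vdw_attr - repulsion,
                "internal_strain": strain,
            },
        )


def score_pose(pose_or_coords, chain: GagChain, receptor, site,
               weights: ScoreWeights = ScoreWeights()) -> DockScore:
    """Score one pose; builds a throwaway context (use ScoringContext for loops)."""
    coords = getattr(pose_or_coords, "coords", pose_or_coords)
    return ScoringContext(chain, receptor, site, weights).score(np.asarray(coords, float))


# ---------------------------------------------------------------------------
# the GA


@dataclass
class DockingJob:
    receptor: object
    site: object
    chain: GagChain
    regime: str
    config: GAConfig = field(default_factory=GAConfig)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    histograms: dict | None = None

    def template(self) -> ChromosomeTemplate:
        return build_regime(self.chain, self.regime, self.histograms)


def _random_chromosome(template, cfg, ctx, rng) -> Chromosome:
    target = rng.uniform(ctx.box_min, ctx.box_max)
    translation = target - template.centroid
    quaternion = random_unit_quaternion(rng)
    torsions = template.initial.copy()
    for gi, mob in enumerate(template.mobility):
        if mob == "free":
            torsions[gi] = rng.uniform(-180.0, 180.0)
        elif mob == "bounded":
            torsions[gi] = template.histograms[gi].sample(rng)
    return Chromosome(translation, quaternion, torsions)


def _mutate(chrom, template, cfg, ctx, rng) -> None:
    for k in range(3):
        if rng.random() < cfg.mutation_prob:
            lo = ctx.box_min[k] - template.centroid[k]
            hi = ctx.box_max[k] - template.centroid[k]
            if rng.random() < cfg.retranslate_prob:
                chrom.translation[k] = rng.uniform(lo, hi)
            else:
                chrom.translation[k] = np.clip(
                    chrom.translation[k] + rng.normal(scale=cfg.translation_sigma), lo, hi
                )
    if rng.random() < cfg.mutation_prob:
        if rng.random() < cfg.reorient_prob:
            chrom.quaternion = random_unit_quaternion(rng)
        else:
            axis = rng.normal(size=3)
            dq = axis_angle_quaternion(axis, rng.normal(scale=cfg.orientation_sigma_deg))
            q = quaternion_multiply(dq, chrom.quaternion)
            chrom.quaternion = q / np.linalg.norm(q)
    for gi, mob in enumerate(template.mobility):
        if mob == "fixed":
            continue
        if rng.random() < cfg.mutation_prob:
            if mob == "free":
                chrom.torsions[gi] = rng.uniform(-180.0, 180.0)
            else:
                chrom.torsions[gi] = template.histograms[gi].sample(rng)


def _crossover(a: Chromosome, b: Chromosome, rng) -> Chromosome:
    """One-point crossover over the gene vector [t0 t1 t2 | q | torsions...].

    The quaternion is treated as a single gene so it stays normalized."""
    n_genes = 3 + 1 + a.torsions.size
    cut = int(rng.integers(1, n_genes))
    child = a.copy()
    for g in range(cut, n_genes):
        if g < 3:
            child.translation[g] = b.translation[g]
        elif g == 3:
            child.quaternion = b.quaternion.copy()
        else:
            child.torsions[g - 4] = b.torsions[g - 4]
    return child


_REFINE_SCALES = (
    (2.0, 40.0),
    (1.0, 20.0),
    (0.5, 10.0),
    (0.25, 5.0),
    (0.12, 2.5),
    (0.06, 1.25),
)


def _refine_chromosome(chrom: Chromosome, template: ChromosomeTemplate,
                       ctx: ScoringContext, flip_scan: bool = True) -> Chromosome:
    """Deterministic local refinement (the GA's memetic step).

    Each cycle alternates (i) pattern search over the rigid-body genes on a
    shrinking translation/rotation schedule, with rotation pivots at the
    ligand center and both chain ends so an elongated chain can rock about
    a contact point, (ii) a jump scan over the characteristic near-
    degeneracies of a quasi-helical polymer in a complementary groove --
    end-to-end flips about the pose's principal axes combined with
    one-residue register shifts along the chain axis, each rigid-polished
    and adopted when it scores higher -- and (iii) a torsion sweep (coarse
    rotamer scan, then fine polishing) over the non-fixed genes, with
    bounded genes never leaving their histogram support.  Running the jump
    scan before each torsion sweep keeps the comparison between competing
    placements on an equal footing.
    """
    chrom = chrom.copy()
    axes = np.eye(3)
    ring_ends = []
    residues = template.chain.residues
    for res in (residues[0], residues[-1]):
        if res.ring_atom_ids:
            ring_ends.append(np.array(res.ring_atom_ids, dtype=int))

    def torsioned_base(c):
        torsions = np.where(template.fixed_mask, template.initial, c.torsions)
        return template.tree.apply(
            template.template_coords, torsions, reference_torsions=template.initial
        ) - template.centroid

    base = torsioned_base(chrom)

    def rigid_score(q, t):
        R = quaternion_to_matrix(q)
        return ctx.score(base @ R.T + template.centroid + t).total

    def rigid_pattern(c, best, scales, max_passes=8):
        for step, ang in scales:
            improved, passes = True, 0
            while improved and passes < max_passes:
                passes += 1
                improved = False
                for k in range(3):
                    for sgn in (1.0, -1.0):
                        t = c.translation + sgn * step * axes[k]
                        s = rigid_score(c.quaternion, t)
                        if s > best + 1e-9:
                            best, c.translation, improved = s, t, True
                R = quaternion_to_matrix(c.quaternion)
                pivots = [np.zeros(3)] + [(base[ids].mean(axis=0)) @ R.T for ids in ring_ends]
                for pivot in pivots:
                    for k in range(3):
                        for sgn in (1.0, -1.0):
                            dq = axis_angle_quaternion(axes[k], sgn * ang)
                            q = quaternion_multiply(dq, c.quaternion)
                            q = q / np.linalg.norm(q)
                            D = quaternion_to_matrix(dq)
                            t = c.translation + pivot - D @ pivot
                            s = rigid_score(q, t)
                            if s > best + 1e-9:
                                best, improved = s, True
                                c.quaternion, c.translation = q, t
        return best

    def degeneracy_jumps(c, best):
        R = quaternion_to_matrix(c.quaternion)
        pose = base @ R.T
        pivot = pose.mean(axis=0)
        centered = pose - pivot
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        long_axis = Vt[0]
        for kr in range(3):
            dq = axis_angle_quaternion(Vt[kr], 180.0)
            for shift_mag in (-9.0, -4.5, 0.0, 4.5, 9.0):
                for use_rot in ((True,) if shift_mag == 0.0 else (True, False)):
                    cand = c.copy()
                    if use_rot:
                        q = quaternion_multiply(dq, cand.quaternion)
                        cand.quaternion = q / np.linalg.norm(q)
                        D = quaternion_to_matrix(dq)
                        cand.translation = cand.translation + pivot - D @ pivot
                    elif kr > 0:
                        continue  # pure shifts only need enumerating once
                    cand.translation = cand.translation + shift_mag * long_axis
                    s = rigid_pattern(
                        cand,
                        rigid_score(cand.quaternion, cand.translation),
                        ((1.0, 20.0), (0.5, 10.0), (0.25, 5.0)),
                        max_passes=6,
                    )
                    if s > best + 1e-9:
                        best = s
                        c.quaternion, c.translation = cand.quaternion, cand.translation
        return best

    def torsion_sweep(c, best, angles):
        for ang in angles:
            for gi, mob in enumerate(template.mobility):
                if mob == "fixed":
                    continue
                for sgn in (1.0, -1.0):
                    cand = wrap_angle(c.torsions[gi] + sgn * ang)
                    if mob == "bounded" and not template.histograms[gi].supports(cand):
                        continue
                    old = c.torsions[gi]
                    c.torsions[gi] = cand
                    s = ctx.score(decode(c, template)).total
                    if s > best + 1e-9:
                        best = s
                    else:
                        c.torsions[gi] = old
        return best

    best = rigid_score(chrom.quaternion, chrom.translation)
    for _ in range(3):
        before = best
        best = rigid_pattern(chrom, best, _REFINE_SCALES)
        if flip_scan:
            best = degeneracy_jumps(chrom, best)
            best = rigid_pattern(chrom, best, _REFINE_SCALES[2:])
        best = torsion_sweep(chrom, best, (120.0, 60.0, 30.0, 10.0, 3.0))
        if best <= before + 1e-9:
            break
        base = torsioned_base(chrom)
    return chrom


def _tournament(pop, scores, k, rng) -> int:
    idx = rng.integers(0, len(pop), size=k)
    return int(idx[np.argmax(scores[idx])])


def _inplace_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    return float(np.sqrt((diff * diff).sum(axis=1).mean()))


def run_ga(job: DockingJob, run_seed=None, run_id: int | None = None,
           observer=None, max_poses: int = 5) -> list[Pose]:
    """One GA run: generational search with tournament selection, one-point
    crossover, per-gene mutation and single-individual elitism; stops after
    exactly config.n_operations offspring evaluations (the initial random
    population is evaluated separately, so n_operations=0 returns the best
    of the random start).  Returns poses ranked by score, deduplicated at
    config.dedup_rmsd; always at least one pose.
    """
    cfg = job.config
    template = job.template()
    ctx = ScoringContext(job.chain, job.receptor, job.site, job.weights)
    rng = np.random.default_rng(cfg.seed if run_seed is None else run_seed)

    archive: list[tuple[float, int, Chromosome]] = []
    counter = 0

    def _record(chrom, total):
        nonlocal counter
        archive.append((total, counter, chrom.copy()))
        counter += 1
        if len(archive) > 200:
            archive.sort(key=lambda e: (-e[0], e[1]))
            del archive[80:]

    def _evaluate(chrom):
        if observer is not None:
            observer(chrom)
        s = ctx.score(decode(chrom, template)).total
        _record(chrom, s)
        return s

    pop = [_random_chromosome(template, cfg, ctx, rng) for _ in range(cfg.population_size)]
    scores = np.array([_evaluate(c) for c in pop])

    ops = 0
    while ops < cfg.n_operations:
        n_children = min(cfg.population_size - 1, cfg.n_operations - ops)
        elite = int(np.argmax(scores))
        new_pop = [pop[elite].copy()]
        new_scores = [scores[elite]]
        for _ in range(n_children):
            i = _tournament(pop, scores, cfg.tournament_size, rng)
            if rng.random() < cfg.crossover_prob:
                j = _tournament(pop, scores, cfg.tournament_size, rng)
                child = _crossover(pop[i], pop[j], rng)
            else:
                child = pop[i].copy()
            _mutate(child, template, cfg, ctx, rng)
            new_pop.append(child)
            new_scores.append(_evaluate(child))
            ops += 1
        pop = new_pop
        scores = np.array(new_scores)

    archive.sort(key=lambda e: (-e[0], e[1]))
    if cfg.refine:
        # polish the top distinct archive entries with local pattern search
        refined: list[tuple[float, int, Chromosome]] = []
        taken: list[np.ndarray] = []
        for total, order, chrom in archive:
            coords = decode(chrom, template)
            if any(_inplace_rmsd(coords, c) < max(cfg.dedup_rmsd, 1.0) for c in taken):
                continue
            taken.append(coords)
            better = _refine_chromosome(chrom, template, ctx)
            refined.append((ctx.score(decode(better, template)).total, order, better))
            if len(taken) >= cfg.refine_top:
                break
        archive = refined + archive
        archive.sort(key=lambda e: (-e[0], e[1]))
    poses: list[Pose] = []
    for total, order, chrom in archive:
        coords = decode(chrom, template)
        if any(_inplace_rmsd(coords, p.coords) < cfg.dedup_rmsd for p in poses):
            continue
        poses.append(
            Pose(coords=coords, score=ctx.score(coords), chromosome=chrom, run_id=run_id)
        )
        if len(poses) >= max_poses:
            break
    return poses


def dock_replicates(job: DockingJob, observer=None) -> PoseSet:
    """Replicate orchestration: replicate r reseeds the GA at base_seed + r,
    pools the single best pose of each GA run, and keeps the top_per_run
    highest-scoring distinct poses; score ties break by (replicate, run)
    order.  Defaults (3 replicates x top 2) give the six analysis poses.
    """
    cfg = job.config
    all_poses: list[Pose] = []
    rep_seeds = []
    for r in range(cfg.replicates):
        ss = np.random.SeedSequence([cfg.seed + r])
        rep_seeds.append(cfg.seed + r)
        run_seeds = ss.spawn(cfg.n_runs)
        best_per_run: list[Pose] = []
        for run_idx, rs in enumerate(run_seeds):
            ranked = run_ga(job, run_seed=rs, run_id=run_idx, observer=observer, max_poses=1)
            pose = ranked[0]
            pose.replicate_id = r
            best_per_run.append(pose)
        best_per_run.sort(
            key=lambda p: (-(p.score.total if p.score else -np.inf), p.run_id)
        )
        kept: list[Pose] = []
        for pose in best_per_run:
            if any(_inplace_rmsd(pose.coords, q.coords) < cfg.dedup_rmsd for q in kept):
                continue
            kept.append(pose)
            if len(kept) >= cfg.top_per_run:
                break
        all_poses.extend(kept)
    for rank, pose in enumerate(
        sorted(all_poses, key=lambda p: (-(p.score.total if p.score else -np.inf),
                                         p.replicate_id, p.run_id)),
        start=1,
    ):
        pose.rank = rank
    return PoseSet(
        poses=all_poses,
        provenance={
            "regime": job.regime,
            "replicate_seeds": rep_seeds,
            "config_hash": cfg.config_hash(),
            "n_runs": cfg.n_runs,
            "n_operations": cfg.n_operations,
        },
    )
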