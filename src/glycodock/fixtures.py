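"""Synthetic Hp/HS-like test systems: chains, toy receptors, decoys, corpora.

Everything the test surface needs is generated programmatically from a
:class:`FixtureSpec`: idealized sulfated oligosaccharides with exactly
controlled glycosidic torsions, rigid cationic groove receptors with a
planted native pose, decoy pose sets with analytically known RMSDs, and
synthetic torsion corpora for the curation machinery.

Geometry is idealized, not force-field refined: pyranose rings are built by
inverting the Cremer-Pople transform at canonical chair/skew amplitudes
(Q ~ 0.57 Å for chairs), substituents are placed at tetrahedral/trigonal
positions with standard bond lengths, and residues are joined by exact
natural-extension (NeRF) construction so that every glycosidic Phi/Psi
re-measures to the requested plan within numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import TETRAHEDRAL, dihedral, kabsch, nerf_place, wrap_angle
from .glycan_core import (
    RING_ORDER,
    Atom,
    GagChain,
    Residue,
    TorsionTree,
    classify_pucker,
    cremer_pople_ring,
    nonbonded_pairs,
)

__all__ = [
    "FixtureSpec",
    "make_chain",
    "make_complex",
    "make_decoys",
    "make_torsion_corpus",
    "minimal_substituents",
    "standard_fixture_spec",
    "benchmark_specs",
    "DEFAULT_CLASS_CENTERS",
]

# bond lengths, Å
L_CC = 1.53
L_CO = 1.43
L_CN = 1.47
L_C_OGLY = 1.41  # anomeric C1-O
L_SO_ESTER = 1.60
L_SO_TERM = 1.44
L_C_OCARB = 1.25
# glycosidic C1-O4'-C4' angle, degrees
ANG_GLYCOSIDIC = 116.0

#: chair/skew Cremer-Pople parameters used for the idealized ring templates
PUCKER_PARAMS = {"4C1": (0.57, 0.0, 0.0), "1C4": (0.57, 180.0, 0.0), "2SO": (0.62, 90.0, 150.0)}

#: literature minima of the glycosidic torsions; UA->GlcN is bimodal
DEFAULT_CLASS_CENTERS = {
    "UA->GlcN": [(-80.0, -100.0), (-80.0, 65.0)],
    "GlcN->UA": [(80.0, -145.0)],
}

GLCN_SUBSTITUENTS = frozenset({"2N-sulfate", "2N-acetate", "6O-sulfate", "3O-sulfate"})
UA_SUBSTITUENTS = frozenset({"2O-sulfate", "3O-sulfate", "carboxylate"})


class FixtureSpecError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Specification of one synthetic Hp/HS system.

    pocket_tightness scales the number of cationic contact sites the toy
    receptor places around the ligand's anionic groups (1.0 = one site per
    group, 0.0 = no site within reach of the ligand).
    """

    chain_length: int = 4
    reducing_end_kind: str = "GlcN"
    uronic_kind: str = "IdoA"
    iduronate_pucker: str = "1C4"  # or "2SO"
    sulfation_pattern: list | None = None  # per-residue substituent sets
    torsion_plan: list | None = None  # per-linkage (phi, psi), reducing end first
    pocket_tightness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.chain_length <= 10:
            raise FixtureSpecError("chain_length must be in 2..10")
        if self.torsion_plan is not None and len(self.torsion_plan) != self.chain_length - 1:
            raise FixtureSpecError("torsion_plan length must be chain_length - 1")

    def residue_kinds(self) -> list[str]:
        kinds = []
        for i in range(1, self.chain_length + 1):
            if (i % 2 == 1) == (self.reducing_end_kind == "GlcN"):
                kinds.append("GlcN")
            else:
                kinds.append(self.uronic_kind)
        return kinds


def minimal_substituents(index: int, kind: str) -> frozenset:
    """Canonical minimal substituent complement per residue.

    GlcN residues carry N- and 6-O-sulfates; the reducing-end GlcN is
    additionally 3-O-sulfated (the rare antithrombin-type motif), and uronic
    acids carry the carboxylate plus a 2-O-sulfate.  Under the flexible
    regime this complement yields the canonical 6n rotatable bonds for an
    n-mer: 12 for a disaccharide up to 60 for a decasaccharide.
    """
    if kind == "GlcN":
        subs = {"2N-sulfate", "6O-sulfate"}
        if index == 1:
            subs.add("3O-sulfate")
        return frozenset(subs)
    return frozenset({"2O-sulfate", "carboxylate"})


# ---------------------------------------------------------------------------
# residue templates


def _tetra_dirs(x, n1, n2):
    """The two unit vectors completing a tetrahedron at x bonded to n1, n2."""
    u1 = (n1 - x) / np.linalg.norm(n1 - x)
    u2 = (n2 - x) / np.linalg.norm(n2 - x)
    bis = -(u1 + u2)
    bis = bis / np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp = perp / np.linalg.norm(perp)
    c1 = float(np.dot(bis, u1))
    cos_a = np.clip(np.cos(np.radians(TETRAHEDRAL)) / c1, -1.0, 1.0)
    sin_a = np.sqrt(max(0.0, 1.0 - cos_a * cos_a))
    return cos_a * bis + sin_a * perp, cos_a * bis - sin_a * perp


class _ResidueTemplate:
    """Atoms/bonds of one residue in its local frame, plus the attach points."""

    def __init__(self, kind: str, substituents: frozenset, pucker: str):
        self.kind = kind
        self.substituents = frozenset(substituents)
        self.names: list[str] = []
        self.elements: list[str] = []
        self.xyz: list[np.ndarray] = []
        self.bonds: list[tuple[str, str]] = []
        self._build(pucker)

    def _add(self, name: str, element: str, pos, bond_to: str | None = None):
        self.names.append(name)
        self.elements.append(element)
        self.xyz.append(np.asarray(pos, dtype=float))
        if bond_to is not None:
            self.bonds.append((bond_to, name))

    def pos(self, name: str) -> np.ndarray:
        return self.xyz[self.names.index(name)]

    def _substituent_dir(self, cname: str, normal):
        """Equatorial-ish exocyclic direction at ring carbon `cname`."""
        i = RING_ORDER.index(cname)
        prev_name = RING_ORDER[(i - 1) % 6]
        next_name = RING_ORDER[(i + 1) % 6]
        d1, d2 = _tetra_dirs(self.pos(cname), self.pos(prev_name), self.pos(next_name))
        return d1 if abs(np.dot(d1, normal)) <= abs(np.dot(d2, normal)) else d2

    def _add_sulfate(self, prefix: str, ref_grand: str, ref_parent: str, ester: str):
        s_name = f"S{prefix}"
        s = nerf_place(self.pos(ref_grand), self.pos(ref_parent), self.pos(ester), L_SO_ESTER, 117.0, 180.0)
        self._add(s_name, "S", s, bond_to=ester)
        for k, chi in enumerate((60.0, 180.0, 300.0), start=1):
            o = nerf_place(self.pos(ref_parent), self.pos(ester), s, L_SO_TERM, TETRAHEDRAL, chi)
            self._add(f"O{prefix}S{k}", "O", o, bond_to=s_name)

    def _build(self, pucker: str):
        Q, theta, phi = PUCKER_PARAMS[pucker]
        ring = cremer_pople_ring(Q, theta, phi)
        for name, pos in zip(RING_ORDER, ring):
            element = "O" if name == "O5" else "C"
            self._add(name, element, pos)
        for k in range(6):
            self.bonds.append((RING_ORDER[k], RING_ORDER[(k + 1) % 6]))
        normal = np.array([0.0, 0.0, 1.0])

        # first exocyclic shell
        self._add("O1", "O", self.pos("C1") + L_C_OGLY * self._substituent_dir("C1", normal), "C1")
        if self.kind == "GlcN":
            self._add("N2", "N", self.pos("C2") + L_CN * self._substituent_dir("C2", normal), "C2")
        else:
            self._add("O2", "O", self.pos("C2") + L_CO * self._substituent_dir("C2", normal), "C2")
        self._add("O3", "O", self.pos("C3") + L_CO * self._substituent_dir("C3", normal), "C3")
        self._add("O4", "O", self.pos("C4") + L_CO * self._substituent_dir("C4", normal), "C4")
        self._add("C6", "C", self.pos("C5") + L_CC * self._substituent_dir("C5", normal), "C5")

        # second shell
        if self.kind == "GlcN":
            o6 = nerf_place(self.pos("C4"), self.pos("C5"), self.pos("C6"), L_CO, TETRAHEDRAL, 180.0)
            self._add("O6", "O", o6, "C6")
            if "6O-sulfate" in self.substituents:
                self._add_sulfate("6", "C5", "C6", "O6")
            if "3O-sulfate" in self.substituents:
                self._add_sulfate("3", "C2", "C3", "O3")
            if "2N-sulfate" in self.substituents:
                sn = nerf_place(self.pos("C1"), self.pos("C2"), self.pos("N2"), L_SO_ESTER, 117.0, 180.0)
                self._add("SN", "S", sn, "N2")
                for k, chi in enumerate((60.0, 180.0, 300.0), start=1):
                    o = nerf_place(self.pos("C2"), self.pos("N2"), sn, L_SO_TERM, TETRAHEDRAL, chi)
                    self._add(f"ONS{k}", "O", o, "SN")
            elif "2N-acetate" in self.substituents:
                c7 = nerf_place(self.pos("C1"), self.pos("C2"), self.pos("N2"), 1.33, 120.0, 180.0)
                self._add("C7", "C", c7, "N2")
                self._add("O7", "O", nerf_place(self.pos("C2"), self.pos("N2"), c7, 1.23, 121.0, 0.0), "C7")
                self._add("C8", "C", nerf_place(self.pos("C2"), self.pos("N2"), c7, 1.50, 116.0, 180.0), "C7")
        else:
            # uronic acid: C6 is the carboxylate carbon on C5
            o6a = nerf_place(self.pos("O5"), self.pos("C5"), self.pos("C6"), L_C_OCARB, 117.0, 120.0)
            o6b = nerf_place(self.pos("O5"), self.pos("C5"), self.pos("C6"), L_C_OCARB, 117.0, -60.0)
            self._add("O6A", "O", o6a, "C6")
            self._add("O6B", "O", o6b, "C6")
            if "2O-sulfate" in self.substituents:
                self._add_sulfate("2", "C1", "C2", "O2")
            if "3O-sulfate" in self.substituents:
                self._add_sulfate("3", "C2", "C3", "O3")


def _validate_substituents(kind: str, subs: frozenset) -> None:
    allowed = GLCN_SUBSTITUENTS if kind == "GlcN" else UA_SUBSTITUENTS
    bad = set(subs) - set(allowed)
    if bad:
        raise FixtureSpecError(f"substituents {sorted(bad)} not allowed on {kind}")
    if kind == "GlcN" and {"2N-sulfate", "2N-acetate"} <= set(subs):
        raise FixtureSpecError("GlcN cannot carry both N-sulfate and N-acetate")


# ---------------------------------------------------------------------------
# chain assembly


def make_chain(spec: FixtureSpec) -> GagChain:
    """Build an idealized Hp/HS chain with glycosidic torsions set exactly to
    the spec's torsion plan (class-default minima when no plan is given).
    """
    kinds = spec.residue_kinds()
    patterns = []
    for i, kind in enumerate(kinds, start=1):
        if spec.sulfation_pattern is not None:
            subs = frozenset(spec.sulfation_pattern[i - 1])
        else:
            subs = minimal_substituents(i, kind)
        if kind != "GlcN":
            subs = subs | {"carboxylate"}
        _validate_substituents(kind, subs)
        patterns.append(subs)

    plan = spec.torsion_plan
    if plan is None:
        plan = []
        for i in range(1, spec.chain_length):
            donor_kind = kinds[i]  # residue i+1, 0-based index i
            link_class = "UA->GlcN" if donor_kind != "GlcN" else "GlcN->UA"
            plan.append(DEFAULT_CLASS_CENTERS[link_class][0])

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    residues: list[Residue] = []
    prev_ids: dict[str, int] = {}

    for i, (kind, subs) in enumerate(zip(kinds, patterns), start=1):
        pucker = spec.iduronate_pucker if kind == "IdoA" else "4C1"
        tpl = _ResidueTemplate(kind, subs, pucker)
        if i == 1:
            placed = {n: np.array(x) for n, x in zip(tpl.names, tpl.xyz)}
            keep = list(tpl.names)  # O1 stays as the reducing-end hydroxyl
        else:
            phi, psi = plan[i - 2]
            c3a = atoms[prev_ids["C3"]].coords
            c4a = atoms[prev_ids["C4"]].coords
            o4a = atoms[prev_ids["O4"]].coords
            r_c1o5 = float(np.linalg.norm(tpl.pos("O5") - tpl.pos("C1")))
            v1 = tpl.pos("O5") - tpl.pos("C1")
            v2 = tpl.pos("O1") - tpl.pos("C1")
            ang_o5 = float(
                np.degrees(np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
            )
            c1_t = nerf_place(c3a, c4a, o4a, L_C_OGLY, ANG_GLYCOSIDIC, psi)
            o5_t = nerf_place(c4a, o4a, c1_t, r_c1o5, ang_o5, phi)
            moving = np.array([tpl.pos("O1"), tpl.pos("C1"), tpl.pos("O5")])
            target = np.array([o4a, c1_t, o5_t])
            R, t = kabsch(moving, target)
            placed = {n: R @ np.asarray(x) + t for n, x in zip(tpl.names, tpl.xyz)}
            keep = [n for n in tpl.names if n != "O1"]  # O1 merges into O4(i-1)

        local_ids: dict[str, int] = {}
        for name in keep:
            aid = len(atoms)
            local_ids[name] = aid
            element = tpl.elements[tpl.names.index(name)]
            atoms.append(Atom(aid, element, name, placed[name], residue_index=i))
        for na, nb in tpl.bonds:
            if na in local_ids and nb in local_ids:
                bonds.append((local_ids[na], local_ids[nb]))
        if i > 1:
            bonds.append((local_ids["C1"], prev_ids["O4"]))
        ring_ids = tuple(local_ids[n] for n in RING_ORDER)
        residues.append(
            Residue(
                index=i,
                kind=kind,
                substituents=subs,
                ring_atom_ids=ring_ids,
                atom_ids=tuple(local_ids.values()),
                pucker=classify_pucker(np.array([atoms[a].coords for a in ring_ids])),
            )
        )
        prev_ids = local_ids

    chain = GagChain(atoms, bonds, residues)
    chain.validate()
    _relax_substituents(chain)
    return chain


_CLASH_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}


def _internal_clash(coords, ii, jj, radii) -> float:
    """Capped 6-12 repulsion over nonbonded pairs (mirrors the dock score's
    strain term); ~0 for a physically reasonable conformer."""
    d = np.maximum(np.linalg.norm(coords[ii] - coords[jj], axis=1), 0.5)
    y6 = (0.85 * (radii[ii] + radii[jj]) / d) ** 6
    return float(np.minimum(np.maximum(0.2 * (y6 * y6 - 2.0 * y6), 0.0), 10.0).sum())


def _relax_substituents(chain: GagChain, n_sweeps: int = 3, step: float = 30.0) -> None:
    """Greedy torsion sweep over substituent bonds to remove self-clashes.

    Glycosidic torsions are never touched (the sweep runs over the rigid
    regime's bond set), so the planned Phi/Psi survive exactly; the sweep is
    deterministic coordinate descent over a 30-degree grid per bond.  Each
    bond rotation only moves its distal atoms, so only clash pairs crossing
    the bond need re-evaluation.
    """
    tree = TorsionTree(chain, "rigid")  # substituent bonds only
    if not tree.bonds:
        return
    ii, jj = nonbonded_pairs(chain, 4)
    radii = np.array([_CLASH_RADII.get(a.element, 1.7) for a in chain.atoms])
    coords = chain.coords
    crossing = []
    for gi in range(len(tree.bonds)):
        mask = tree.distal_mask(gi)
        sel = mask[ii] ^ mask[jj]
        crossing.append((ii[sel], jj[sel]))
    targets = tree.measure(coords)
    offsets = np.arange(0.0, 360.0, step)
    for _ in range(n_sweeps):
        improved = False
        for gi in range(len(tree.bonds)):
            ci, cj = crossing[gi]
            if ci.size == 0:
                continue
            best_val = _internal_clash(coords, ci, cj, radii)
            best_coords = None
            for offset in offsets[1:]:
                c = tree.apply_single(coords, gi, wrap_angle(targets[gi] + offset))
                v = _internal_clash(c, ci, cj, radii)
                if v < best_val - 1e-9:
                    best_val = v
                    best_coords = c
            if best_coords is not None:
                coords = best_coords
                targets = tree.measure(coords)
                improved = True
        if not improved:
            break
    chain.set_coords(coords)


# ---------------------------------------------------------------------------
# toy receptor with a planted native pose


def make_complex(spec: FixtureSpec):
    """Build (receptor, chain, native_pose) for a synthetic groove complex.

    The receptor is a rigid set of pseudo-residues, each an Arg/Lys-like
    cationic triad (NZ+, CZ, CB) placed at hydrogen-bond distance (2.8 Å)
    opposite an anionic group of the ligand, so the planted ligand geometry
    is the score optimum of the pocket.
    """
    from .docking_engine import Pose
    from .structure_io import Receptor, assign_atom_types

    chain = make_chain(spec)
    assign_atom_types(chain)
    centroid = chain.coords.mean(axis=0)
    anchors = _anionic_anchor_atoms(chain)
    tightness = float(np.clip(spec.pocket_tightness, 0.0, 1.0))
    n_sites = int(round(tightness * len(anchors)))

    rec_atoms: list[Atom] = []

    def _add(element, name, pos, charge, res_label, res_index):
        rec_atoms.append(
            Atom(
                len(rec_atoms),
                element,
                name,
                pos,
                residue_index=res_index,
                formal_charge=charge,
                atom_type={"N": "N.4", "C": "C.3"}[element],
            )
        )

    if n_sites == 0:
        far = centroid + np.array([40.0, 0.0, 0.0])
        _add("N", "NZ", far, 1.0, "GND", 1)
        _add("C", "CZ", far + np.array([1.35, 0.0, 0.0]), 0.0, "GND", 1)
    else:
        idx = sorted(set(np.round(np.linspace(0, len(anchors) - 1, n_sites)).astype(int)))
        for k, ai in enumerate(idx, start=1):
            anchor = chain.atoms[anchors[ai]].coords
            # approach along the S->O (or C->O) bond so the cationic site sees
            # the anchor oxygen head-on rather than the rest of the group
            parent = next(
                (n for n in chain.adjacency[anchors[ai]]
                 if chain.atoms[n].element in ("S", "C")),
                None,
            )
            u = anchor - (chain.atoms[parent].coords if parent is not None else centroid)
            nu = np.linalg.norm(u)
            u = u / nu if nu > 1e-9 else np.array([0.0, 0.0, 1.0])
            nz = anchor + 2.8 * u
            cz = nz + 1.35 * u
            perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
            perp = perp / np.linalg.norm(perp)
            _add("N", "NZ", nz, 1.0, "GND", k)
            _add("C", "CZ", cz, 0.0, "GND", k)
            _add("C", "CB", cz + 1.5 * perp, 0.0, "GND", k)
            # a steric collar around the approach vector: the acceptor can
            # only reach the cationic N head-on, giving the pocket the shape
            # complementarity of a buried side chain
            perp2 = np.cross(u, perp)
            # carve the collar around the native complex: candidate positions
            # that would contact the planted ligand are skipped, so the native
            # pose is clash-free by construction while any other approach to
            # the site threads a sterically constrained funnel
            all_xyz = chain.coords
            for kc, phi_c in enumerate(np.radians((0.0, 90.0, 180.0, 270.0)), start=1):
                cpos = anchor + 2.2 * u + 3.6 * (np.cos(phi_c) * perp + np.sin(phi_c) * perp2)
                if np.linalg.norm(all_xyz - cpos, axis=1).min() >= 3.4:
                    _add("C", f"CG{kc}", cpos, 0.0, "GND", k)

    receptor = Receptor(atoms=rec_atoms, labels=[f"GND{a.residue_index}" for a in rec_atoms])
    native = Pose(coords=chain.coords, score=None, chromosome=None)
    if n_sites > 0:
        native = _equilibrate_native(receptor, chain, native)
    return receptor, chain, native


def _equilibrate_native(receptor, chain, native):
    """Relax the planted pose to a local optimum of the dock score.

    A reference pose should sit at a minimum of the scoring function, the way
    a crystal conformation sits at a minimum of the physical energy; only
    substituent torsions and the rigid-body placement move (glycosidic
    torsions and ring puckers stay planted).
    """
    from .docking_engine import (
        Pose,
        ScoringContext,
        _refine_chromosome,
        build_regime,
        decode,
    )
    from .structure_io import define_site

    site = define_site(receptor, native)
    template = build_regime(chain, "rigid")
    ctx = ScoringContext(chain, receptor, site, )
    chrom = _refine_chromosome(template.identity_chromosome(), template, ctx)
    coords = decode(chrom, template)
    return Pose(coords=coords, score=ctx.score(coords), chromosome=chrom)


def _anionic_anchor_atoms(chain: GagChain) -> list[int]:
    """One representative terminal oxygen per anionic group, chain order."""
    anchors = []
    for res in chain.residues:
        for aid in res.atom_ids:
            name = chain.atoms[aid].name
            if name.endswith("S1") or name == "ONS1" or name == "O6A":
                anchors.append(aid)
    return anchors


# ---------------------------------------------------------------------------
# decoy pose sets with known ground truth


def make_decoys(native, chain: GagChain, kind: str, magnitude: float, n: int, seed: int = 0):
    """Perturbed copies of a native pose with analytically known errors.

    kind "translate": rigid translations of length `magnitude` along random
    directions (ground-truth RMSD = magnitude).  kind "torsion-perturb":
    shift the reducing-end linkage Psi by exactly `magnitude` degrees.
    kind "mixed": random sub-`magnitude` translations plus torsion jitter.
    """
    from .docking_engine import Pose

    rng = np.random.default_rng(seed)
    poses = []
    if kind == "translate":
        for k in range(n):
            u = rng.normal(size=3)
            u = u / np.linalg.norm(u)
            coords = native.coords + magnitude * u
            poses.append(Pose(coords=coords, score=None, chromosome=None,
                              ground_truth={"rmsd": float(magnitude)}))
    elif kind == "torsion-perturb":
        tree = TorsionTree(chain, "flexible")
        base = tree.measure(chain.coords)
        psi_idx = next(
            i for i, b in enumerate(tree.bonds)
            if b.tag == "glycosidic" and b.torsion_name == "psi" and b.linkage_index == 0
        )
        targets = base.copy()
        targets[psi_idx] = wrap_angle(base[psi_idx] + magnitude)
        coords = tree.apply(chain.coords, targets)
        for k in range(n):
            poses.append(Pose(coords=coords.copy(), score=None, chromosome=None,
                              ground_truth={"dpsi": float(abs(wrap_angle(magnitude))),
                                            "linkage": 0}))
    elif kind == "mixed":
        tree = TorsionTree(chain, "flexible")
        base = tree.measure(chain.coords)
        for k in range(n):
            targets = wrap_angle(base + rng.normal(scale=magnitude, size=base.size))
            coords = tree.apply(chain.coords, targets)
            u = rng.normal(size=3)
            u = u / np.linalg.norm(u)
            coords = coords + rng.uniform(0, magnitude) * u
            poses.append(Pose(coords=coords, score=None, chromosome=None, ground_truth={}))
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    return poses


# ---------------------------------------------------------------------------
# torsion corpora


def make_torsion_corpus(
    n_chains: int,
    class_centers: dict | None = None,
    noise_sd: float = 10.0,
    seed: int = 0,
    chain_length: int = 4,
):
    """Chains whose torsions are wrapped-normal draws around class centers.

    Returns (chains, source_ids); bimodal classes draw their center uniformly
    from the listed modes.
    """
    centers = class_centers if class_centers is not None else DEFAULT_CLASS_CENTERS
    rng = np.random.default_rng(seed)
    chains, ids = [], []
    for k in range(n_chains):
        spec = FixtureSpec(chain_length=chain_length)
        kinds = spec.residue_kinds()
        plan = []
        for i in range(1, chain_length):
            link_class = "UA->GlcN" if kinds[i] != "GlcN" else "GlcN->UA"
            modes = centers[link_class]
            modes = modes if isinstance(modes, list) else [modes]
            c_phi, c_psi = modes[rng.integers(len(modes))]
            plan.append(
                (
                    wrap_angle(c_phi + rng.normal(scale=noise_sd)),
                    wrap_angle(c_psi + rng.normal(scale=noise_sd)),
                )
            )
        spec.torsion_plan = plan
        chains.append(make_chain(spec))
        ids.append(f"SYN{k:04d}")
    return chains, ids


# ---------------------------------------------------------------------------
# presets


def standard_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The standard tight tetrasaccharide complex used across the test surface.

    The sulfation pattern is deliberately aperiodic (a 3-O-sulfated reducing
    end, an unsulfated non-reducing iduronate) so the groove has a single
    unambiguous register instead of the near-degenerate shifted registers a
    repeating disaccharide pattern would produce.
    """
    return FixtureSpec(
        chain_length=4,
        pocket_tightness=1.0,
        sulfation_pattern=[
            {"2N-sulfate", "3O-sulfate", "6O-sulfate"},
            {"2O-sulfate", "carboxylate"},
            {"2N-sulfate", "6O-sulfate"},
            {"carboxylate"},
        ],
        seed=seed,
    )


def heterogeneous_substituents(length: int, seed: int = 0) -> list[set]:
    """Per-residue substituent sets with aperiodic, HS-like heterogeneity.

    Real Hp/HS chains are irregularly N-/O-sulfated; an aperiodic pattern
    also gives the planted groove a single unambiguous register, unlike the
    fully repeating minimal complement.  Deterministic in (length, seed).
    """
    rng = np.random.default_rng([seed, length, 20231633])
    subs = []
    for i in range(1, length + 1):
        if i % 2 == 1:  # GlcN positions (reducing end = residue 1)
            s = {"6O-sulfate"}
            s.add("2N-sulfate" if rng.random() < 0.7 else "2N-acetate")
            if i == 1 or rng.random() < 0.25:
                s.add("3O-sulfate")
        else:  # uronic acid
            s = {"carboxylate"}
            if rng.random() < 0.5:
                s.add("2O-sulfate")
        subs.append(s)
    return subs


def benchmark_specs(seed: int = 0) -> list[tuple[str, FixtureSpec]]:
    """Six named fixtures spanning 2-10 residues and two pocket tightness levels."""
    out = []
    for length in (2, 4, 6, 8, 10):
        out.append(
            (
                f"tight-{length}mer",
                FixtureSpec(
                    chain_length=length,
                    pocket_tightness=1.0,
                    sulfation_pattern=heterogeneous_substituents(length, seed),
                    seed=seed,
                ),
            )
        )
    out.append(
        (
            "loose-4mer",
            FixtureSpec(
                chain_length=4,
                pocket_tightness=0.25,
                sulfation_pattern=heterogeneous_substituents(4, seed),
                seed=seed,
            ),
        )
    )
    return out
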