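"""Domain model for heparin/heparan-sulfate (Hp/HS) oligosaccharide chains.

An Hp/HS chain is an alternating sequence of glucosamine (GlcN) and uronic-acid
(GlcA or IdoA) pyranoses joined by 1->4 glycosidic linkages.  Each linkage
carries two dihedral degrees of freedom, the glycosidic torsions Phi and Psi,
which dominate the overall chain conformation; ring puckers are treated as
invariant.  This module provides the residue/atom/bond containers, torsion
measurement, Cremer-Pople ring-pucker classification, regime-dependent
rotatable-bond enumeration and the sequence-space combinatorics.

Torsion convention (tag "O5-C1-Ox-Cx"): for a 1->x linkage with glycosidic
oxygen Ox on the acceptor residue,

    Phi = O5(donor) - C1(donor) - Ox - Cx(acceptor)
    Psi = C1(donor) - Ox - Cx(acceptor) - C(x-1)(acceptor)

the heavy-atom crystallographic convention.  All angles are wrapped to
(-180, 180].  Residues are indexed 1-based from the reducing end, so linkage
"2->1" joins the reducing-end residue 1 (acceptor) to residue 2 (donor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from ._geometry import (
    DegenerateGeometryError,
    dihedral,
    rotation_about_axis,
    wrap_angle,
)

__all__ = [
    "Atom",
    "Residue",
    "RingPucker",
    "GlycosidicLinkage",
    "GagChain",
    "RotatableBond",
    "TorsionTree",
    "PuckerWindows",
    "MalformedChainError",
    "compute_dihedral",
    "identify_linkages",
    "cremer_pople",
    "classify_pucker",
    "enumerate_rotatable_bonds",
    "topology_count",
    "REGIMES",
    "TORSION_CONVENTION",
]

TORSION_CONVENTION = "O5-C1-Ox-Cx"
REGIMES = ("rigid", "semi-rigid", "flexible")

URONIC_KINDS = frozenset({"GlcA", "IdoA"})
AMINE_KINDS = frozenset({"GlcN"})

#: ring-atom ordering used throughout: O5 first, then C1..C5 around the ring.
RING_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")


class MalformedChainError(ValueError):
    """Chain topology violates the alternating 1->4 Hp/HS pattern."""


@dataclass
class Atom:
    id: int
    element: str
    name: str
    coords: np.ndarray
    residue_index: int
    formal_charge: float = 0.0
    atom_type: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class RingPucker:
    label: str  # one of {"4C1", "1C4", "2SO", "other"}
    cp_Q: float
    cp_theta: float
    cp_phi: float
    planar: bool = False


@dataclass
class Residue:
    index: int  # 1-based from the reducing end
    kind: str  # GlcN | GlcA | IdoA | pseudo
    substituents: frozenset = frozenset()
    ring_atom_ids: tuple = ()  # ordered (O5, C1, C2, C3, C4, C5)
    atom_ids: tuple = ()
    pucker: RingPucker | None = None

    @property
    def is_uronic(self) -> bool:
        return self.kind in URONIC_KINDS


@dataclass
class GlycosidicLinkage:
    donor_index: int
    acceptor_index: int
    linkage_class: str  # "UA->GlcN" | "GlcN->UA"
    phi_atoms: tuple  # 4 atom ids: O5d, C1d, Og, Cx
    psi_atoms: tuple  # 4 atom ids: C1d, Og, Cx, C(x-1)
    phi: float
    psi: float
    convention: str = TORSION_CONVENTION

    @property
    def label(self) -> str:
        """Donor->acceptor label, e.g. '2->1' for the reducing-end linkage."""
        return f"{self.donor_index}->{self.acceptor_index}"


@dataclass
class RotatableBond:
    atom_a: int  # proximal (root-side) atom id
    atom_b: int  # distal atom id
    tag: str  # "glycosidic" | "substituent"
    mobility: str  # "fixed" | "bounded" | "free"
    torsion_name: str | None = None  # "phi" | "psi" for glycosidic bonds
    linkage_index: int | None = None  # index into chain.linkages
    quad: tuple = ()  # reference dihedral quadruple (atom ids)

    @property
    def key(self) -> tuple:
        return tuple(sorted((self.atom_a, self.atom_b)))


class GagChain:
    """Ordered residue/atom graph of an Hp/HS oligosaccharide."""

    def __init__(self, atoms, bonds, residues, convention: str = TORSION_CONVENTION):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: set[tuple[int, int]] = {tuple(sorted(b)) for b in bonds}
        self.residues: list[Residue] = sorted(residues, key=lambda r: r.index)
        self.convention = convention
        self._adjacency: dict[int, set[int]] | None = None
        self.linkages: list[GlycosidicLinkage] = []
        if self.atoms:
            self.linkages = identify_linkages(self)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    @property
    def adjacency(self) -> dict[int, set[int]]:
        if self._adjacency is None:
            adj: dict[int, set[int]] = {a.id: set() for a in self.atoms}
            for i, j in self.bonds:
                adj[i].add(j)
                adj[j].add(i)
            self._adjacency = adj
        return self._adjacency

    def atom(self, atom_id: int) -> Atom:
        return self.atoms[atom_id]

    def find_atom(self, residue_index: int, name: str) -> Atom:
        for aid in self.residues[residue_index - 1].atom_ids:
            if self.atoms[aid].name == name:
                return self.atoms[aid]
        raise KeyError(f"no atom {name} in residue {residue_index}")

    def residue_of(self, atom_id: int) -> Residue:
        return self.residues[self.atoms[atom_id].residue_index - 1]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise MalformedChainError on any violated chain invariant."""
        if not self.atoms:
            raise MalformedChainError("empty chain")
        names_seen = set()
        for atom in self.atoms:
            key = (atom.residue_index, atom.name)
            if key in names_seen:
                raise MalformedChainError(f"duplicate atom name {key}")
            names_seen.add(key)
        kinds = [r.kind for r in self.residues]
        for prev, curr in zip(kinds, kinds[1:]):
            prev_u = prev in URONIC_KINDS
            curr_u = curr in URONIC_KINDS
            if prev_u == curr_u:
                raise MalformedChainError(f"non-alternating residue kinds: {kinds}")
        for res in self.residues:
            if res.kind != "pseudo" and len(res.ring_atom_ids) != 6:
                raise MalformedChainError(
                    f"residue {res.index} has {len(res.ring_atom_ids)} ring atoms"
                )
        if len(self.linkages) != self.n_residues - 1:
            raise MalformedChainError(
                f"{len(self.linkages)} linkages for {self.n_residues} residues"
            )
        classes = [lk.linkage_class for lk in self.linkages]
        for a, b in zip(classes, classes[1:]):
            if a == b:
                raise MalformedChainError("linkage classes do not alternate")

    def ring_bond_set(self) -> set[tuple[int, int]]:
        ring_bonds = set()
        for res in self.residues:
            ring = res.ring_atom_ids
            for k in range(len(ring)):
                ring_bonds.add(tuple(sorted((ring[k], ring[(k + 1) % len(ring)]))))
        return ring_bonds

    def heavy_degree(self, atom_id: int) -> int:
        return sum(1 for n in self.adjacency[atom_id] if self.atoms[n].element != "H")

    def to_dict(self) -> dict:
        """JSON-serializable report of the chain topology and torsions."""
        return {
            "convention": self.convention,
            "residues": [
                {
                    "index": r.index,
                    "kind": r.kind,
                    "substituents": sorted(r.substituents),
                    "pucker": None if r.pucker is None else r.pucker.label,
                }
                for r in self.residues
            ],
            "linkages": [
                {
                    "label": lk.label,
                    "class": lk.linkage_class,
                    "phi": lk.phi,
                    "psi": lk.psi,
                }
                for lk in self.linkages
            ],
            "n_atoms": len(self.atoms),
        }


# ---------------------------------------------------------------------------
# torsion measurement


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral (degrees) of plane(p1,p2,p3) vs plane(p2,p3,p4).

    Wrap convention (-180, 180]; colinear triples raise DegenerateGeometryError.
    """
    return dihedral(p1, p2, p3, p4)


def _anomeric_carbon(chain: GagChain, residue: Residue) -> int:
    """C1 by name, falling back to the ring carbon bonded to two oxygens."""
    for aid in residue.ring_atom_ids:
        if chain.atoms[aid].name == "C1":
            return aid
    for aid in residue.ring_atom_ids:
        atom = chain.atoms[aid]
        if atom.element != "C":
            continue
        n_ox = sum(1 for n in chain.adjacency[aid] if chain.atoms[n].element == "O")
        if n_ox >= 2:
            return aid
    raise MalformedChainError(f"no anomeric carbon in residue {residue.index}")


def identify_linkages(chain: GagChain, convention: str = TORSION_CONVENTION):
    """One GlycosidicLinkage per adjacent residue pair, torsions measured.

    The donor residue is the one further from the reducing end: its anomeric
    C1 bonds to the glycosidic oxygen of the acceptor residue.
    """
    if convention != TORSION_CONVENTION:
        raise ValueError(f"unsupported torsion convention {convention!r}")
    linkages = []
    for acceptor, donor in zip(chain.residues, chain.residues[1:]):
        if acceptor.kind == "pseudo" or donor.kind == "pseudo":
            continue
        c1d = _anomeric_carbon(chain, donor)
        # glycosidic oxygen: the acceptor-residue O bonded to the donor C1
        og = None
        for n in chain.adjacency[c1d]:
            natom = chain.atoms[n]
            if natom.element == "O" and natom.residue_index == acceptor.index:
                og = n
                break
        if og is None:
            raise MalformedChainError(
                f"missing glycosidic oxygen between residues "
                f"{donor.index} and {acceptor.index}"
            )
        cx = None
        for n in chain.adjacency[og]:
            natom = chain.atoms[n]
            if natom.element == "C" and natom.residue_index == acceptor.index:
                cx = n
                break
        if cx is None:
            raise MalformedChainError(f"dangling glycosidic oxygen {og}")
        o5d = chain.find_atom(donor.index, "O5").id
        cx_name = chain.atoms[cx].name  # e.g. C4 for a 1->4 linkage
        prev_name = f"C{int(cx_name[1:]) - 1}"
        c_prev = chain.find_atom(acceptor.index, prev_name).id
        coords = lambda aid: chain.atoms[aid].coords  # noqa: E731
        phi = compute_dihedral(coords(o5d), coords(c1d), coords(og), coords(cx))
        psi = compute_dihedral(coords(c1d), coords(og), coords(cx), coords(c_prev))
        link_class = "UA->GlcN" if donor.kind in URONIC_KINDS else "GlcN->UA"
        linkages.append(
            GlycosidicLinkage(
                donor_index=donor.index,
                acceptor_index=acceptor.index,
                linkage_class=link_class,
                phi_atoms=(o5d, c1d, og, cx),
                psi_atoms=(c1d, og, cx, c_prev),
                phi=phi,
                psi=psi,
                convention=convention,
            )
        )
    return linkages


# ---------------------------------------------------------------------------
# ring puckers


@dataclass(frozen=True)
class PuckerWindows:
    """Angular windows for the Cremer-Pople label assignment.

    The biologically dominant puckers are the two chairs (4C1, 1C4) and the 2SO
    skew-boat; everything else maps to "other".  The skew azimuth is tied to
    the O5-first ring ordering used throughout this package.
    """

    chair_theta: float = 45.0  # theta <= chair_theta  -> 4C1
    inverted_theta: float = 135.0  # theta >= inverted_theta -> 1C4
    skew_phi_center: float = 150.0  # canonical 2SO azimuth (O5-first ordering)
    skew_phi_window: float = 30.0
    min_amplitude: float = 0.1  # Å; below this the ring is flagged planar


def cremer_pople(ring_coords) -> tuple[float, float, float]:
    """Cremer-Pople puckering coordinates (Q [Å], theta [deg], phi [deg])
    for a six-membered ring given in ring order.
    """
    r = np.asarray(ring_coords, dtype=float)
    if r.shape != (6, 3):
        raise ValueError("ring_coords must be 6x3")
    r = r - r.mean(axis=0)
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    # normal chosen so a ring laid out counterclockwise in its mean plane
    # reads back the same out-of-plane displacements it was built with
    n = np.cross(rpp, rp)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateGeometryError("degenerate ring geometry")
    n = n / nn
    z = r @ n
    q2cos = np.sqrt(2.0 / 6.0) * (z * np.cos(4 * np.pi * j / 6)).sum()
    q2sin = -np.sqrt(2.0 / 6.0) * (z * np.sin(4 * np.pi * j / 6)).sum()
    q2 = float(np.hypot(q2cos, q2sin))
    phi2 = float(np.degrees(np.arctan2(q2sin, q2cos))) % 360.0
    q3 = float(np.sqrt(1.0 / 6.0) * ((-1.0) ** j * z).sum())
    Q = float(np.hypot(q2, q3))
    theta = float(np.degrees(np.arctan2(q2, q3)))
    return Q, theta, phi2


def cremer_pople_ring(Q: float, theta: float, phi: float, side: float = 1.447) -> np.ndarray:
    """Construct idealized 6-ring coordinates with the given CP parameters.

    The ring is laid out as a regular hexagon in the xy plane (circumradius
    `side`) with out-of-plane displacements inverted from the CP definition;
    used by the synthetic fixture generator and by the classifier tests.
    """
    j = np.arange(6)
    q2 = Q * np.sin(np.radians(theta))
    q3 = Q * np.cos(np.radians(theta))
    z = np.sqrt(2.0 / 6.0) * q2 * np.cos(np.radians(phi) + 4 * np.pi * j / 6) + np.sqrt(
        1.0 / 6.0
    ) * q3 * (-1.0) ** j
    x = side * np.cos(2 * np.pi * j / 6)
    y = side * np.sin(2 * np.pi * j / 6)
    return np.column_stack([x, y, z])


def classify_pucker(ring_coords, windows: PuckerWindows = PuckerWindows()) -> RingPucker:
    """Assign a pucker label from six ring-atom positions in ring order.

    Label windows: 4C1 for theta <= 45 deg, 1C4 for theta >= 135 deg, 2SO for
    the equatorial band with azimuth within +/-30 deg of the canonical skew
    position; anything else (including near-planar rings) is "other".
    """
    Q, theta, phi = cremer_pople(ring_coords)
    if Q < windows.min_amplitude:
        return RingPucker("other", Q, theta, phi, planar=True)
    if theta <= windows.chair_theta:
        label = "4C1"
    elif theta >= windows.inverted_theta:
        label = "1C4"
    elif abs(wrap_angle(phi - windows.skew_phi_center)) <= windows.skew_phi_window:
        label = "2SO"
    else:
        label = "other"
    return RingPucker(label, Q, theta, phi)


# ---------------------------------------------------------------------------
# rotatable bonds


def _glycosidic_bond_map(chain: GagChain) -> dict[tuple, tuple]:
    """Map sorted bond tuple -> (torsion_name, linkage_idx, quad)."""
    out = {}
    for li, lk in enumerate(chain.linkages):
        o5d, c1d, og, cx = lk.phi_atoms
        out[tuple(sorted((c1d, og)))] = ("phi", li, lk.phi_atoms)
        out[tuple(sorted((og, cx)))] = ("psi", li, lk.psi_atoms)
    return out


def enumerate_rotatable_bonds(chain: GagChain, regime: str) -> list[RotatableBond]:
    """Rotatable bonds of a chain under a torsional regime.

    A bond is rotatable when it is a non-ring single bond between heavy atoms
    and neither endpoint is a terminus (both endpoints carry >= 2 heavy
    neighbours); this automatically excludes hydroxyl C-O bonds, sulfate
    S-O(terminal) bonds and carboxylate C=O bonds.  Glycosidic Phi/Psi bonds
    are excluded under the rigid regime, tagged "bounded" under semi-rigid and
    "free" under flexible; substituent bonds are always free.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    ring_bonds = chain.ring_bond_set()
    glyco = _glycosidic_bond_map(chain)
    tree = _TreeOrientation(chain)
    out: list[RotatableBond] = []
    for bond in sorted(chain.bonds):
        a, b = bond
        if bond in ring_bonds:
            continue
        if chain.atoms[a].element == "H" or chain.atoms[b].element == "H":
            continue
        if chain.heavy_degree(a) < 2 or chain.heavy_degree(b) < 2:
            continue
        prox, dist = tree.orient(a, b)
        if bond in glyco:
            if regime == "rigid":
                continue
            torsion_name, li, quad = glyco[bond]
            mobility = "bounded" if regime == "semi-rigid" else "free"
            out.append(
                RotatableBond(prox, dist, "glycosidic", mobility, torsion_name, li, quad)
            )
        else:
            quad = tree.substituent_quad(prox, dist)
            if quad is None:
                continue
            out.append(RotatableBond(prox, dist, "substituent", "free", quad=quad))
    return out


class _TreeOrientation:
    """Orients bonds relative to the reducing-end root of the chain graph."""

    def __init__(self, chain: GagChain):
        self.chain = chain
        root_res = chain.residues[0]
        self.root = root_res.ring_atom_ids[0] if root_res.ring_atom_ids else chain.atoms[0].id
        # BFS depth from the root over the full bond graph
        self.depth = {self.root: 0}
        queue = [self.root]
        while queue:
            nxt = []
            for u in queue:
                for v in chain.adjacency[u]:
                    if v not in self.depth:
                        self.depth[v] = self.depth[u] + 1
                        nxt.append(v)
            queue = nxt

    def orient(self, a: int, b: int) -> tuple[int, int]:
        """Return (proximal, distal) endpoints of the bond."""
        return (a, b) if self.depth.get(a, 0) <= self.depth.get(b, 0) else (b, a)

    def distal_atoms(self, prox: int, dist: int) -> np.ndarray:
        """Atom ids on the distal side of the (prox, dist) bond."""
        seen = {prox, dist}
        stack = [dist]
        out = [dist]
        adj = self.chain.adjacency
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    out.append(v)
                    stack.append(v)
        return np.array(sorted(out), dtype=int)

    def substituent_quad(self, prox: int, dist: int) -> tuple | None:
        """Reference quadruple (n_prox, prox, dist, n_dist) for a bond torsion."""
        adj = self.chain.adjacency
        atoms = self.chain.atoms
        n_prox = sorted(n for n in adj[prox] if n != dist and atoms[n].element != "H")
        n_dist = sorted(n for n in adj[dist] if n != prox and atoms[n].element != "H")
        if not n_prox or not n_dist:
            return None
        return (n_prox[0], prox, dist, n_dist[0])


@njit(cache=True)
def _apply_deltas_nb(coords, a_idx, b_idx, signs, deltas, distal_flat, distal_off):
    for gi in range(a_idx.size):
        delta = deltas[gi]
        if abs(delta) < 1e-12:
            continue
        a = a_idx[gi]
        b = b_idx[gi]
        ux = coords[b, 0] - coords[a, 0]
        uy = coords[b, 1] - coords[a, 1]
        uz = coords[b, 2] - coords[a, 2]
        un = (ux * ux + uy * uy + uz * uz) ** 0.5
        ux /= un
        uy /= un
        uz /= un
        th = signs[gi] * delta * np.pi / 180.0
        c = np.cos(th)
        s = np.sin(th)
        px, py, pz = coords[a, 0], coords[a, 1], coords[a, 2]
        for m in range(distal_off[gi], distal_off[gi + 1]):
            k = distal_flat[m]
            x = coords[k, 0] - px
            y = coords[k, 1] - py
            z = coords[k, 2] - pz
            dot = ux * x + uy * y + uz * z
            cx = uy * z - uz * y
            cy = uz * x - ux * z
            cz = ux * y - uy * x
            coords[k, 0] = px + x * c + cx * s + ux * dot * (1.0 - c)
            coords[k, 1] = py + y * c + cy * s + uy * dot * (1.0 - c)
            coords[k, 2] = pz + z * c + cz * s + uz * dot * (1.0 - c)


class TorsionTree:
    """Spanning-tree machinery to apply absolute torsion targets to a chain.

    Rotatable bonds are processed in increasing depth from the reducing-end
    root; each rotation moves only the atoms distal to its bond, leaving rigid
    fragments internally undistorted.
    """

    def __init__(self, chain: GagChain, regime: str = "flexible"):
        self.chain = chain
        self._orient = _TreeOrientation(chain)
        bonds = enumerate_rotatable_bonds(chain, regime)
        bonds.sort(key=lambda b: (self._orient.depth[b.atom_a], b.key))
        self.bonds = bonds
        n_atoms = len(chain.atoms)
        coords = chain.coords
        self._distal_masks = []
        self._signs = []
        for bond in bonds:
            distal = self._orient.distal_atoms(bond.atom_a, bond.atom_b)
            mask = np.zeros(n_atoms, dtype=bool)
            mask[distal] = True
            self._distal_masks.append(mask)
            # the rotation sense that increments the reference dihedral depends
            # on the quad orientation relative to the a->b axis; calibrate it
            # once with a trial rotation on the template geometry
            p1, p2, p3, p4 = bond.quad
            before = compute_dihedral(coords[p1], coords[p2], coords[p3], coords[p4])
            R, t = rotation_about_axis(coords[bond.atom_a], coords[bond.atom_b] - coords[bond.atom_a], 10.0)
            probe = np.array(coords)
            probe[mask] = probe[mask] @ R.T + t
            after = compute_dihedral(probe[p1], probe[p2], probe[p3], probe[p4])
            self._signs.append(1.0 if wrap_angle(after - before) > 0 else -1.0)
        # flat arrays for the jitted fast path
        self._a_idx = np.array([b.atom_a for b in bonds], dtype=np.int64)
        self._b_idx = np.array([b.atom_b for b in bonds], dtype=np.int64)
        self._signs_arr = np.array(self._signs, dtype=float)
        flat, off = [], [0]
        for mask in self._distal_masks:
            flat.extend(np.nonzero(mask)[0].tolist())
            off.append(len(flat))
        self._distal_flat = np.array(flat, dtype=np.int64)
        self._distal_off = np.array(off, dtype=np.int64)

    def distal_mask(self, gi: int) -> np.ndarray:
        return self._distal_masks[gi]

    def apply_single(self, coords: np.ndarray, gi: int, target: float) -> np.ndarray:
        """Coordinates with only torsion `gi` set to `target` (others untouched)."""
        bond = self.bonds[gi]
        mask = self._distal_masks[gi]
        p1, p2, p3, p4 = bond.quad
        current = compute_dihedral(coords[p1], coords[p2], coords[p3], coords[p4])
        delta = wrap_angle(target - current)
        out = np.array(coords, dtype=float)
        if abs(delta) < 1e-12:
            return out
        R, t = rotation_about_axis(
            out[bond.atom_a], out[bond.atom_b] - out[bond.atom_a], self._signs[gi] * delta
        )
        out[mask] = out[mask] @ R.T + t
        return out

    def measure(self, coords: np.ndarray) -> np.ndarray:
        """Current dihedral (degrees) of every tree bond for given coords."""
        vals = []
        for bond in self.bonds:
            p1, p2, p3, p4 = bond.quad
            vals.append(compute_dihedral(coords[p1], coords[p2], coords[p3], coords[p4]))
        return np.array(vals, dtype=float)

    def apply(
        self,
        coords: np.ndarray,
        targets: np.ndarray,
        reference_torsions: np.ndarray | None = None,
    ) -> np.ndarray:
        """Return new coordinates with every tree torsion set to its target.

        When `reference_torsions` (the measured torsions of `coords`) is
        supplied, per-bond re-measurement is skipped: rotations applied in
        tree order preserve the not-yet-rotated dihedrals, so each delta is
        simply target - reference.
        """
        out = np.array(coords, dtype=float)
        if reference_torsions is not None and len(self.bonds):
            deltas = wrap_angle(np.asarray(targets, float) - np.asarray(reference_torsions, float))
            _apply_deltas_nb(
                out, self._a_idx, self._b_idx, self._signs_arr,
                np.atleast_1d(deltas), self._distal_flat, self._distal_off,
            )
            return out
        for gi, (bond, mask, sign) in enumerate(
            zip(self.bonds, self._distal_masks, self._signs)
        ):
            p1, p2, p3, p4 = bond.quad
            current = compute_dihedral(out[p1], out[p2], out[p3], out[p4])
            delta = wrap_angle(targets[gi] - current)
            if abs(delta) < 1e-12:
                continue
            axis_point = out[bond.atom_a]
            axis_dir = out[bond.atom_b] - out[bond.atom_a]
            R, t = rotation_about_axis(axis_point, axis_dir, sign * delta)
            out[mask] = out[mask] @ R.T + t
        return out


def nonbonded_pairs(chain: GagChain, min_separation: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (i, j) of heavy-atom pairs >= min_separation bonds apart."""
    n = len(chain.atoms)
    dist = np.full((n, n), 99, dtype=np.int16)
    np.fill_diagonal(dist, 0)
    adj = chain.adjacency
    for i in range(n):
        frontier = [i]
        seen = {i}
        d = 0
        while frontier and d < min_separation:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        dist[i, v] = min(dist[i, v], d)
                        nxt.append(v)
            frontier = nxt
    ii, jj = np.triu_indices(n, k=1)
    far = dist[ii, jj] >= min_separation
    return ii[far], jj[far]


# ---------------------------------------------------------------------------
# combinatorics


def topology_count(alphabet_size: int, length: int) -> int:
    """Exact number of linear sequences over an opaque building-block alphabet.

    With 72 Hp/HS building blocks a hexamer admits 72**6 = 139,314,069,504
    topologies, versus 20**6 for a hexapeptide and 4**6 for a hexanucleotide.
    """
    if not (isinstance(alphabet_size, (int, np.integer)) and alphabet_size >= 1):
        raise ValueError("alphabet_size must be a positive integer")
    if not (isinstance(length, (int, np.integer)) and length >= 1):
        raise ValueError("length must be a positive integer")
    return int(alphabet_size) ** int(length)
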