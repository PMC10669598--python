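"""Structure I/O: receptors and ligands, atom typing, docking-site definition.

Receptors are read and written as PDB through gemmi; oligosaccharide ligands
and pose sets use a minimal TRIPOS mol2 dialect written by this module (SYBYL
atom-type strings, including the O.co2 surrogate type given to sulfate
terminal oxygens so they behave like carboxylate oxygens in scoring).

The charge model is deliberately formal rather than fitted: each charged
substituent group carries an integer net charge divided equally over the
group's heavy atoms (sulfates -1 over S+3 terminal O, carboxylates -1 over
C+2 O, free amines +1 on N), and protein side chains get Arg/Lys +1,
Asp/Glu -1, His neutral by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .glycan_core import RING_ORDER, Atom, GagChain, Residue

__all__ = [
    "Receptor",
    "SiteDefinition",
    "EmptySiteError",
    "StructureFormatError",
    "read_structure",
    "read_receptor_pdb",
    "write_receptor_pdb",
    "read_chain_mol2",
    "write_chain_mol2",
    "write_poses",
    "read_poses",
    "assign_atom_types",
    "assign_protein_charges",
    "total_formal_charge",
    "define_site",
]

COVALENT_RADII = {"H": 0.37, "C": 0.77, "N": 0.75, "O": 0.73, "S": 1.03, "P": 1.06}
BOND_SLACK = 0.45  # Å added to the covalent-radius sum when inferring bonds

SUGAR_RESIDUE_TOKENS = {"GLCN", "IDOA", "GLCA"}


class StructureFormatError(ValueError):
    pass


class EmptySiteError(ValueError):
    pass


@dataclass
class Receptor:
    atoms: list
    labels: list  # per-atom residue label, e.g. "ARG45" or "GND3"
    site: "SiteDefinition | None" = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class SiteDefinition:
    """All receptor residues with >= 1 atom within `radius` of the reference
    pose's heavy atoms, plus the bounding box of the selected atoms."""

    radius: float
    site_atom_ids: tuple
    residue_labels: tuple
    box_min: np.ndarray
    box_max: np.ndarray

    def to_dict(self) -> dict:
        return {
            "radius": self.radius,
            "n_site_atoms": len(self.site_atom_ids),
            "residues": sorted(set(self.residue_labels)),
            "box_min": [float(v) for v in self.box_min],
            "box_max": [float(v) for v in self.box_max],
        }


# ---------------------------------------------------------------------------
# atom typing and formal charges

_SULFATE_GROUPS = {
    "6O-sulfate": ("S6", ("O6S1", "O6S2", "O6S3"), "O6"),
    "3O-sulfate": ("S3", ("O3S1", "O3S2", "O3S3"), "O3"),
    "2O-sulfate": ("S2", ("O2S1", "O2S2", "O2S3"), "O2"),
    "2N-sulfate": ("SN", ("ONS1", "ONS2", "ONS3"), "N2"),
}


def assign_atom_types(chain: GagChain) -> GagChain:
    """Fill atom_type and formal_charge in place (and return the chain).

    Sulfate terminal oxygens get the carboxylate-oxygen surrogate type O.co2;
    each charged group's net charge is spread equally over its heavy atoms.
    """
    for atom in chain.atoms:
        atom.formal_charge = 0.0
        atom.atom_type = {"C": "C.3", "O": "O.3", "N": "N.3", "S": "S.3", "H": "H"}.get(
            atom.element, atom.element
        )
    for res in chain.residues:
        names = {chain.atoms[aid].name: aid for aid in res.atom_ids}
        for sub in res.substituents:
            if sub in _SULFATE_GROUPS:
                s_name, term_names, ester = _SULFATE_GROUPS[sub]
                if s_name not in names:
                    warnings.warn(f"residue {res.index}: no atoms for {sub}; left neutral")
                    continue
                group = [names[s_name]] + [names[t] for t in term_names]
                for aid in group:
                    chain.atoms[aid].formal_charge = -1.0 / len(group)
                chain.atoms[names[s_name]].atom_type = "S.o2"
                for t in term_names:
                    chain.atoms[names[t]].atom_type = "O.co2"
                if ester in names and chain.atoms[names[ester]].element == "O":
                    chain.atoms[names[ester]].atom_type = "O.3"
            elif sub == "carboxylate":
                group = [names[n] for n in ("C6", "O6A", "O6B") if n in names]
                if len(group) != 3:
                    warnings.warn(f"residue {res.index}: incomplete carboxylate; left neutral")
                    continue
                for aid in group:
                    chain.atoms[aid].formal_charge = -1.0 / 3.0
                chain.atoms[names["C6"]].atom_type = "C.2"
                chain.atoms[names["O6A"]].atom_type = "O.co2"
                chain.atoms[names["O6B"]].atom_type = "O.co2"
            elif sub == "2N-acetate":
                for n, t in (("N2", "N.am"), ("C7", "C.2"), ("O7", "O.2"), ("C8", "C.3")):
                    if n in names:
                        chain.atoms[names[n]].atom_type = t
            elif sub == "hydroxyl":
                pass
            else:
                warnings.warn(f"unrecognized substituent {sub!r}; neutral typing")
        if res.kind == "GlcN" and not ({"2N-sulfate", "2N-acetate"} & res.substituents):
            if "N2" in names:  # free amine, protonated
                chain.atoms[names["N2"]].formal_charge = 1.0
                chain.atoms[names["N2"]].atom_type = "N.4"
        if "2N-sulfate" in res.substituents and "N2" in names:
            chain.atoms[names["N2"]].atom_type = "N.3"
    return chain


def total_formal_charge(chain: GagChain) -> float:
    return float(sum(a.formal_charge for a in chain.atoms))


_PROTEIN_CHARGES = {
    "ARG": (("NE", "NH1", "NH2"), 1.0),
    "LYS": (("NZ",), 1.0),
    "ASP": (("OD1", "OD2"), -1.0),
    "GLU": (("OE1", "OE2"), -1.0),
}


def assign_protein_charges(receptor: Receptor, charged_his: bool = False) -> Receptor:
    """Formal side-chain charges: Arg/Lys +1, Asp/Glu -1, His neutral unless
    `charged_his`; the group charge is split over the listed side-chain atoms."""
    table = dict(_PROTEIN_CHARGES)
    if charged_his:
        table["HIS"] = (("ND1", "NE2"), 1.0)
    by_label: dict[str, list[int]] = {}
    for i, lab in enumerate(receptor.labels):
        by_label.setdefault(lab, []).append(i)
    for lab, idxs in by_label.items():
        resname = "".join(ch for ch in lab if ch.isalpha()).upper()[:3]
        if resname not in table:
            continue
        atom_names, q = table[resname]
        hits = [i for i in idxs if receptor.atoms[i].name in atom_names]
        for i in hits:
            receptor.atoms[i].formal_charge = q / len(hits)
    return receptor


# ---------------------------------------------------------------------------
# docking site


def define_site(receptor: Receptor, reference, radius: float = 6.0) -> SiteDefinition:
    """Select all receptor residues within `radius` Å of the reference pose.

    Membership is by residue: every atom of a residue having at least one
    atom within the radius of any reference heavy atom is included.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ref_coords = np.asarray(reference.coords, dtype=float)
    if ref_coords.size == 0:
        raise ValueError("reference pose has no atoms")
    rec_coords = receptor.coords
    d = cdist(rec_coords, ref_coords).min(axis=1)
    hit_labels = {receptor.labels[i] for i in np.nonzero(d <= radius)[0]}
    if not hit_labels:
        raise EmptySiteError(f"no receptor residue within {radius} Å of the reference pose")
    site_ids = tuple(i for i, lab in enumerate(receptor.labels) if lab in hit_labels)
    site_xyz = rec_coords[list(site_ids)]
    site = SiteDefinition(
        radius=float(radius),
        site_atom_ids=site_ids,
        residue_labels=tuple(receptor.labels[i] for i in site_ids),
        box_min=site_xyz.min(axis=0),
        box_max=site_xyz.max(axis=0),
    )
    receptor.site = site
    return site


# ---------------------------------------------------------------------------
# PDB (via gemmi)


def read_receptor_pdb(path) -> Receptor:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()  # first altloc kept
    atoms: list[Atom] = []
    labels: list[str] = []
    model = st[0]
    res_counter = 0
    for chain_ in model:
        for res in chain_:
            res_counter += 1
            label = f"{res.name}{res.seqid.num}"
            for a in res:
                atoms.append(
                    Atom(
                        len(atoms),
                        a.element.name,
                        a.name,
                        np.array([a.pos.x, a.pos.y, a.pos.z]),
                        residue_index=res_counter,
                    )
                )
                labels.append(label)
    if not atoms:
        raise StructureFormatError(f"{path}: no atoms")
    return Receptor(atoms=atoms, labels=labels)


def write_receptor_pdb(receptor: Receptor, path) -> None:
    st = gemmi.Structure()
    st.name = "receptor"
    model = gemmi.Model("1")
    chain_ = gemmi.Chain("A")
    by_label: dict[str, list[int]] = {}
    for i, lab in enumerate(receptor.labels):
        by_label.setdefault(lab, []).append(i)
    seq = 0
    for lab, idxs in by_label.items():
        seq += 1
        res = gemmi.Residue()
        res.name = "".join(ch for ch in lab if ch.isalpha())[:3] or "UNK"
        res.seqid = gemmi.SeqId(seq, " ")
        res.het_flag = "H"
        for i in idxs:
            a = receptor.atoms[i]
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            res.add_atom(ga)
        chain_.add_residue(res)
    model.add_chain(chain_)
    st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# mol2 (minimal TRIPOS dialect, documented here)

_KIND_TOKEN = {"GlcN": "GLCN", "IdoA": "IDOA", "GlcA": "GLCA", "pseudo": "PSEU"}
_TOKEN_KIND = {v: k for k, v in _KIND_TOKEN.items()}


def write_chain_mol2(chain: GagChain, path, name: str = "gag", comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_chain_mol2_block(chain, name, comment))


def _chain_mol2_block(chain: GagChain, name: str, comment: str = "") -> str:
    lines = ["@<TRIPOS>MOLECULE", name,
             f"{len(chain.atoms)} {len(chain.bonds)} {chain.n_residues}",
             "SMALL", "USER_CHARGES"]
    lines.append(comment if comment else "****")
    lines.append("@<TRIPOS>ATOM")
    for a in chain.atoms:
        res = chain.residues[a.residue_index - 1]
        subst = f"{_KIND_TOKEN[res.kind]}{res.index}"
        t = a.atom_type or a.element
        lines.append(
            f"{a.id + 1:>6} {a.name:<6} {a.coords[0]:>12.4f} {a.coords[1]:>12.4f} "
            f"{a.coords[2]:>12.4f} {t:<6} {a.residue_index:>3} {subst:<8} "
            f"{a.formal_charge:>9.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(sorted(chain.bonds), start=1):
        lines.append(f"{k:>6} {i + 1:>6} {j + 1:>6} 1")
    return "\n".join(lines) + "\n"


def _infer_substituents(kind: str, names: set) -> frozenset:
    subs = set()
    if "S6" in names:
        subs.add("6O-sulfate")
    if "S3" in names:
        subs.add("3O-sulfate")
    if "S2" in names:
        subs.add("2O-sulfate")
    if "SN" in names:
        subs.add("2N-sulfate")
    if "C7" in names:
        subs.add("2N-acetate")
    if "O6A" in names:
        subs.add("carboxylate")
    return frozenset(subs)


def read_chain_mol2(path) -> GagChain:
    """Read a single-molecule mol2 ligand back into a GagChain."""
    chains = _read_mol2_blocks(path)
    if not chains:
        raise StructureFormatError(f"{path}: no molecules")
    return chains[0][0]


def _read_mol2_blocks(path):
    """Parse all MOLECULE blocks; returns list of (GagChain, comment)."""
    with open(path) as fh:
        raw_lines = fh.read().splitlines()
    blocks = []
    current: list[tuple[int, str]] = []
    for ln, line in enumerate(raw_lines, start=1):
        if line.strip() == "@<TRIPOS>MOLECULE" and current:
            blocks.append(current)
            current = []
        current.append((ln, line))
    if current:
        blocks.append(current)
    out = []
    for block in blocks:
        if not any(l.strip() == "@<TRIPOS>MOLECULE" for _, l in block):
            continue
        out.append(_parse_mol2_block(block, path))
    return out


def _parse_mol2_block(block, path):
    section = None
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    res_info: dict[int, str] = {}
    mol_header: list[str] = []
    comment = ""
    for ln, line in block:
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[len("@<TRIPOS>"):]
            continue
        if section == "MOLECULE":
            mol_header.append(stripped)
            if len(mol_header) == 5:
                comment = stripped
            continue
        if not stripped:
            continue
        if section == "ATOM":
            parts = stripped.split()
            if len(parts) < 9:
                raise StructureFormatError(f"{path}:{ln}: malformed ATOM record")
            try:
                aid = int(parts[0]) - 1
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                res_idx = int(parts[6])
                charge = float(parts[8])
            except ValueError as exc:
                raise StructureFormatError(f"{path}:{ln}: {exc}") from None
            name, a_type, subst = parts[1], parts[5], parts[7]
            element = a_type.split(".")[0].upper()
            element = element[0] + element[1:].lower() if len(element) > 1 else element
            if element not in COVALENT_RADII:
                element = name[0].upper()
            atoms.append(Atom(aid, element, name, xyz, residue_index=res_idx,
                              formal_charge=charge, atom_type=a_type))
            res_info[res_idx] = subst
        elif section == "BOND":
            parts = stripped.split()
            if len(parts) < 4:
                raise StructureFormatError(f"{path}:{ln}: malformed BOND record")
            try:
                bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
            except ValueError as exc:
                raise StructureFormatError(f"{path}:{ln}: {exc}") from None
    if not atoms:
        raise StructureFormatError(f"{path}: empty molecule block")
    atoms.sort(key=lambda a: a.id)
    residues = []
    for res_idx in sorted(res_info):
        subst = res_info[res_idx]
        token = "".join(ch for ch in subst if ch.isalpha()).upper()
        kind = _TOKEN_KIND.get(token, "pseudo")
        atom_ids = tuple(a.id for a in atoms if a.residue_index == res_idx)
        names = {atoms[aid].name for aid in atom_ids}
        name_to_id = {atoms[aid].name: aid for aid in atom_ids}
        ring = tuple(name_to_id[n] for n in RING_ORDER if n in name_to_id)
        residues.append(
            Residue(
                index=res_idx,
                kind=kind,
                substituents=_infer_substituents(kind, names),
                ring_atom_ids=ring if len(ring) == 6 else (),
                atom_ids=atom_ids,
            )
        )
    return GagChain(atoms, bonds, residues), comment


def infer_bonds(atoms) -> list[tuple[int, int]]:
    """Distance-rule bond inference: d <= r_cov(i) + r_cov(j) + 0.45 Å."""
    coords = np.array([a.coords for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.77) for a in atoms])
    d = cdist(coords, coords)
    cutoff = radii[:, None] + radii[None, :] + BOND_SLACK
    bonds = []
    n = len(atoms)
    for i in range(n):
        for j in range(i + 1, n):
            if 0.4 < d[i, j] <= cutoff[i, j]:
                bonds.append((i, j))
    return bonds


def read_structure(path, format: str | None = None):
    """Dispatch on format/extension: mol2 -> GagChain, PDB -> Receptor."""
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "mol2":
        return read_chain_mol2(path)
    if fmt == "pdb":
        return read_receptor_pdb(path)
    raise StructureFormatError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# pose sets


def write_poses(poses, chain: GagChain, path, format: str = "mol2") -> None:
    """Write a pose set, ordered by (rank, pose index), score embedded in the
    per-molecule comment line (mol2) or REMARK table (PDB)."""
    ordered = sorted(
        enumerate(poses), key=lambda kv: (getattr(kv[1], "rank", None) or kv[0], kv[0])
    )
    if format == "mol2":
        blocks = []
        for k, pose in ordered:
            chain.set_coords(pose.coords)
            score = pose.score.total if pose.score is not None else float("nan")
            comment = f"pose={k} rank={getattr(pose, 'rank', k)} score={score:.6f}"
            blocks.append(_chain_mol2_block(chain, f"pose_{k}", comment))
        with open(path, "w") as fh:
            fh.write("".join(blocks))
    elif format == "pdb":
        lines = []
        for k, pose in ordered:
            score = pose.score.total if pose.score is not None else float("nan")
            lines.append(f"REMARK 100 POSE {k} RANK {getattr(pose, 'rank', k)} SCORE {score:.6f}")
        for m, (k, pose) in enumerate(ordered, start=1):
            lines.append(f"MODEL {m:>8}")
            for a, xyz in zip(chain.atoms, pose.coords):
                lines.append(
                    f"HETATM{a.id + 1:>5} {a.name:<4}{'LIG':>4} A{a.residue_index:>4}    "
                    f"{xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}  1.00  0.00"
                    f"          {a.element:>2}"
                )
            lines.append("ENDMDL")
        lines.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise StructureFormatError(f"unsupported pose format {format!r}")


def read_poses(path, format: str = "mol2"):
    """Read pose coordinates (and scores when present) back from write_poses output."""
    if format == "mol2":
        out = []
        for chain, comment in _read_mol2_blocks(path):
            score = None
            for tok in comment.split():
                if tok.startswith("score="):
                    score = float(tok.split("=", 1)[1])
            out.append((chain.coords, score))
        return out
    if format == "pdb":
        scores: list[float] = []  # REMARK order matches MODEL order
        coords_by_model: list[list[list[float]]] = []
        with open(path) as fh:
            current: list[list[float]] | None = None
            for line in fh:
                if line.startswith("REMARK 100 POSE"):
                    scores.append(float(line.split()[7]))
                elif line.startswith("MODEL"):
                    current = []
                elif line.startswith("ENDMDL"):
                    coords_by_model.append(current or [])
                    current = None
                elif line.startswith(("ATOM", "HETATM")) and current is not None:
                    current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        if not scores:
            scores = [None] * len(coords_by_model)
        return [(np.array(c), s) for c, s in zip(coords_by_model, scores)]
    raise StructureFormatError(f"unsupported pose format {format!r}")
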