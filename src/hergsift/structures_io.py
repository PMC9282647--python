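"""Receptor and docked-pose I/O.

Parses tetrameric receptor structures (PDB) and docked ligand poses
(SDF V2000, or HETATM blocks of a PDB) into a uniform in-memory complex
model. Coordinates are Angstroms in the PDB frame; no re-centering is
performed, so receptor and pose share a coordinate frame by construction.

Docking-score orientation (GLIDE-style lower-is-better kcal/mol vs
GOLD-style higher-is-better fitness) is always explicit configuration,
never inferred from the numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from rdkit import Chem

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

LOWER_IS_BETTER = "lower_is_better"
HIGHER_IS_BETTER = "higher_is_better"

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True)
class Residue:
    chain_id: str
    residue_number: int
    residue_name: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_number, self.residue_name)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms if not a.is_hydrogen], float)


@dataclass(frozen=True)
class ReceptorStructure:
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.residue_number) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain_id, residue_number) in receptor")

    @property
    def monomer_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return tuple(seen)

    def by_key(self, key: tuple[int, str]) -> list[Residue]:
        """All monomer copies of a (residue_number, residue_name) key."""
        return [r for r in self.residues if r.key == key]


@dataclass(frozen=True)
class LigandAtom:
    element: str
    xyz: tuple[float, float, float]
    formal_charge: int = 0
    n_attached_h: int = 0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True)
class LigandPose:
    compound_id: str
    atoms: tuple[LigandAtom, ...]
    docking_score: float
    score_units: str = "kcal/mol"
    score_orientation: str = LOWER_IS_BETTER

    def __post_init__(self) -> None:
        if not any(not a.is_hydrogen for a in self.atoms):
            raise ValueError("pose must contain at least one heavy atom")
        if not math.isfinite(self.docking_score):
            raise ValueError("docking score must be finite")
        if self.score_orientation not in (LOWER_IS_BETTER, HIGHER_IS_BETTER):
            raise ValueError(f"bad score orientation {self.score_orientation!r}")

    def heavy_atoms(self) -> tuple[LigandAtom, ...]:
        return tuple(a for a in self.atoms if not a.is_hydrogen)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.heavy_atoms()], float)


@dataclass(frozen=True)
class ComplexModel:
    receptor: ReceptorStructure
    pose: LigandPose


def is_better(score_a: float, score_b: float, orientation: str) -> bool:
    """True if score_a beats score_b under the given convention."""
    if orientation == LOWER_IS_BETTER:
        return score_a < score_b
    return score_a > score_b


def best_pose(poses: Iterable[LigandPose]) -> LigandPose:
    poses = list(poses)
    if not poses:
        raise ValueError("no poses")
    best = poses[0]
    for p in poses[1:]:
        if is_better(p.docking_score, best.docking_score, p.score_orientation):
            best = p
    return best


# ---------------------------------------------------------------------------
# PDB receptor reading / writing
# ---------------------------------------------------------------------------

def read_receptor(path) -> ReceptorStructure:
    """Parse the standard amino-acid residues of a PDB file.

    HETATM ligands and waters are dropped; disordered (altloc) atoms keep the
    highest-occupancy conformer.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(path))
    residues: list[Residue] = []
    for model in structure:
        for chain in model:
            for res in chain:
                hetflag, resseq, _ = res.id
                if hetflag != " " or res.get_resname() not in STANDARD_RESIDUES:
                    continue
                atoms = []
                for atom in res:
                    if atom.is_disordered():
                        logger.info(
                            "altloc at %s/%s %s: keeping highest occupancy",
                            chain.id, resseq, atom.get_name(),
                        )
                    elem = atom.element or atom.get_name()[0]
                    atoms.append(
                        Atom(atom.get_name(), elem.strip().capitalize(),
                             tuple(float(x) for x in atom.coord))
                    )
                residues.append(
                    Residue(chain.id, resseq, res.get_resname(), tuple(atoms))
                )
        break  # first model only
    if not residues:
        raise ValueError(f"no standard amino-acid ATOM records in {path}")
    return ReceptorStructure(tuple(residues))


def write_receptor(receptor: ReceptorStructure, path) -> None:
    """Write ATOM records in fixed-column PDB format (coordinates to 3 dp)."""
    lines = []
    serial = 1
    for res in receptor.residues:
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.xyz
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.residue_name:<3s} "
                f"{res.chain_id}{res.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pose reading (SDF / PDB HETATM) and writing (SDF)
# ---------------------------------------------------------------------------

def _pose_from_mol(mol, compound_id, score, units, orientation) -> LigandPose:
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append(
            LigandAtom(
                element=atom.GetSymbol(),
                xyz=(pos.x, pos.y, pos.z),
                formal_charge=atom.GetFormalCharge(),
                n_attached_h=atom.GetTotalNumHs(),
            )
        )
    return LigandPose(compound_id, tuple(atoms), score, units, orientation)


def read_poses(
    path,
    score_field: str = "docking_score",
    *,
    best_only: bool = False,
    score_orientation: str = LOWER_IS_BETTER,
    score_units: str = "kcal/mol",
    scores_csv=None,
) -> list[LigandPose]:
    """Read docked poses from an SDF (V2000) file.

    Scores come from the per-record SDF tag ``score_field`` or, if absent
    there, from a sidecar CSV with columns (compound_id, score). Records with
    no score anywhere are skipped with a log message, mirroring the exclusion
    of undocked molecules. With ``best_only``, only the best-scoring pose per
    compound_id is retained.
    """
    sidecar: dict[str, float] = {}
    if scores_csv is not None:
        df = pd.read_csv(scores_csv)
        sidecar = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))

    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    poses: list[LigandPose] = []
    n_skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("record %d: unreadable molecule, skipped", i)
            n_skipped += 1
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        if mol.HasProp(score_field):
            score = float(mol.GetProp(score_field))
        elif cid in sidecar:
            score = sidecar[cid]
        else:
            logger.warning("record %d (%s): no score, skipped (undocked)", i, cid)
            n_skipped += 1
            continue
        poses.append(_pose_from_mol(mol, cid, score, score_units, score_orientation))
    if n_skipped:
        logger.info("read_poses: %d record(s) skipped", n_skipped)
    if best_only:
        by_cid: dict[str, list[LigandPose]] = {}
        for p in poses:
            by_cid.setdefault(p.compound_id, []).append(p)
        poses = [best_pose(ps) for ps in by_cid.values()]
    return poses


def read_pose_from_pdb(
    path,
    compound_id: str,
    docking_score: float,
    *,
    score_orientation: str = LOWER_IS_BETTER,
    score_units: str = "kcal/mol",
    resname: str | None = None,
) -> LigandPose:
    """Read one ligand pose from the HETATM records of a PDB file."""
    atoms = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith("HETATM"):
            continue
        rn = line[17:20].strip()
        if rn == "HOH" or (resname is not None and rn != resname):
            continue
        element = line[76:78].strip() or line[12:16].strip()[0]
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        atoms.append(LigandAtom(element.capitalize(), xyz))
    if not atoms:
        raise ValueError(f"no ligand HETATM records in {path}")
    return LigandPose(compound_id, tuple(atoms), docking_score,
                      score_units, score_orientation)


def write_poses_sdf(poses: Sequence[LigandPose], path,
                    score_field: str = "docking_score") -> None:
    """Write poses as a minimal V2000 SDF (atoms only, score as a data tag)."""
    blocks = []
    for pose in poses:
        lines = [pose.compound_id, "  hergsift", ""]
        lines.append(f"{len(pose.atoms):3d}{0:3d}  0  0  0  0  0  0  0  0999 V2000")
        for a in pose.atoms:
            x, y, z = a.xyz
            # valence field pins the H count (15 = explicit zero valence) so
            # readers do not invent implicit hydrogens on bond-less atoms
            valence = a.n_attached_h if a.n_attached_h > 0 else 15
            fields = [0, 0, 0, 0, valence, 0, 0, 0, 0, 0, 0]
            lines.append(
                f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s}{0:2d}"
                + "".join(f"{f:3d}" for f in fields)
            )
        charged = [(i + 1, a.formal_charge)
                   for i, a in enumerate(pose.atoms) if a.formal_charge]
        if charged:
            entries = "".join(f" {idx:3d} {chg:3d}" for idx, chg in charged)
            lines.append(f"M  CHG  {len(charged)}{entries}")
        lines.append("M  END")
        lines.append(f"> <{score_field}>")
        lines.append(f"{pose.docking_score}")
        lines.append("")
        lines.append("$$$$")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n".join(blocks) + "\n")
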