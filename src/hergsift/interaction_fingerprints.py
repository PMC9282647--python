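"""Per-residue protein-ligand interaction fingerprints.

A docked pose is summarised, per binding-site residue, by a nine-bit string
(SIFt convention): any contact, backbone contact, side-chain contact, contact
with a polar residue, contact with a hydrophobic residue, hydrogen bond with
a binding-site acceptor, hydrogen bond with a binding-site donor, contact
with an aromatic residue, and contact with a charged residue. The receptor
is a homotetramer: a bit is on if the interaction occurs with that residue
in at least one monomer (OR-merge across chains).

The binding site itself is the set of residues with any heavy atom within a
cutoff radius (default 9 A) of any heavy atom of the best-scoring docked
molecule, collapsed over monomers to (residue_number, residue_name) keys.

Geometric criteria: a contact is any heavy-atom pair within ``contact_max_A``
(default 4.5 A); a hydrogen bond is a donor/acceptor heavy-atom pair within
``hbond_dist_max_A`` (default 3.5 A), with the D-H...A angle test applied
only when explicit hydrogen coordinates are available (docked poses are
typically handled heavy-atom-only). Every specific bit implies the contact
bit. All cutoffs and class sets are configuration recorded in run manifests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures_io import (
    BACKBONE_ATOMS,
    ComplexModel,
    LigandAtom,
    LigandPose,
    ReceptorStructure,
    Residue,
)

logger = logging.getLogger(__name__)

INTERACTION_TYPES = (
    "contact",
    "backbone",
    "sidechain",
    "polar",
    "hydrophobic",
    "hbond_acceptor",  # a binding-site atom accepts from a ligand donor
    "hbond_donor",     # a binding-site atom donates to a ligand acceptor
    "aromatic",
    "charged",
)
N_TYPES = len(INTERACTION_TYPES)

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
)
AROMATIC_RESIDUES = frozenset({"PHE", "TYR", "TRP", "HIS"})
POLAR_RESIDUES = frozenset({"SER", "THR", "ASN", "GLN", "CYS", "TYR", "HIS"})
CHARGED_RESIDUES = frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"})

# Side-chain H-bond capabilities per residue: atom name -> {"donor","acceptor"}
SIDECHAIN_HBOND_TABLE: dict[str, dict[str, frozenset[str]]] = {
    "SER": {"OG": frozenset({"donor", "acceptor"})},
    "THR": {"OG1": frozenset({"donor", "acceptor"})},
    "TYR": {"OH": frozenset({"donor", "acceptor"})},
    "CYS": {"SG": frozenset({"donor"})},
    "ASN": {"OD1": frozenset({"acceptor"}), "ND2": frozenset({"donor"})},
    "GLN": {"OE1": frozenset({"acceptor"}), "NE2": frozenset({"donor"})},
    "ASP": {"OD1": frozenset({"acceptor"}), "OD2": frozenset({"acceptor"})},
    "GLU": {"OE1": frozenset({"acceptor"}), "OE2": frozenset({"acceptor"})},
    "LYS": {"NZ": frozenset({"donor"})},
    "ARG": {
        "NE": frozenset({"donor"}),
        "NH1": frozenset({"donor"}),
        "NH2": frozenset({"donor"}),
    },
    "HIS": {
        "ND1": frozenset({"donor", "acceptor"}),
        "NE2": frozenset({"donor", "acceptor"}),
    },
    "TRP": {"NE1": frozenset({"donor"})},
}


@dataclass(frozen=True)
class BindingSiteConfig:
    cutoff_A: float = 9.0

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise ValueError("cutoff_A must be > 0")


@dataclass(frozen=True)
class BindingSite:
    """Monomer-collapsed residue keys, ordered by residue number then name."""

    residue_keys: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.residue_keys:
            raise ValueError("binding site is empty")

    def column_labels(self) -> list[str]:
        return [
            f"{num}_{itype}"
            for num, _name in self.residue_keys
            for itype in INTERACTION_TYPES
        ]


@dataclass(frozen=True)
class GeometryRules:
    contact_max_A: float = 4.5
    hbond_dist_max_A: float = 3.5
    hbond_angle_min_deg: float = 120.0
    hydrophobic: frozenset[str] = HYDROPHOBIC_RESIDUES
    aromatic: frozenset[str] = AROMATIC_RESIDUES
    polar: frozenset[str] = POLAR_RESIDUES
    charged: frozenset[str] = CHARGED_RESIDUES

    def __post_init__(self) -> None:
        if min(self.contact_max_A, self.hbond_dist_max_A) <= 0:
            raise ValueError("geometric cutoffs must be > 0")

    def to_manifest(self) -> dict:
        d = asdict(self)
        for k in ("hydrophobic", "aromatic", "polar", "charged"):
            d[k] = sorted(d[k])
        return d


@dataclass(frozen=True)
class InteractionFingerprint:
    compound_id: str
    residue_keys: tuple[tuple[int, str], ...]
    bits: np.ndarray  # shape (n_residues, 9), values {0,1}

    def to_series(self) -> pd.Series:
        labels = [
            f"{num}_{itype}"
            for num, _ in self.residue_keys
            for itype in INTERACTION_TYPES
        ]
        return pd.Series(self.bits.ravel(), index=labels, name=self.compound_id)


# ---------------------------------------------------------------------------
# Binding-site definition
# ---------------------------------------------------------------------------

def define_binding_site(
    receptor: ReceptorStructure,
    reference_pose: LigandPose,
    cfg: BindingSiteConfig = BindingSiteConfig(),
) -> BindingSite:
    """Residues with any heavy atom within ``cutoff_A`` of any heavy atom of
    the reference (best-scoring) pose, in any monomer, as collapsed keys."""
    lig = reference_pose.heavy_coords()
    keys: set[tuple[int, str]] = set()
    for res in receptor.residues:
        coords = res.heavy_coords()
        if coords.size and cdist(coords, lig).min() <= cfg.cutoff_A:
            keys.add(res.key)
    if not keys:
        raise ValueError("pose outside receptor: empty binding site")
    return BindingSite(tuple(sorted(keys)))


# ---------------------------------------------------------------------------
# Hydrogen-bond atom typing
# ---------------------------------------------------------------------------

def _residue_hbond_roles(res: Residue, atom) -> frozenset[str]:
    """Donor/acceptor roles of one receptor atom (heavy atoms only)."""
    roles: set[str] = set()
    if atom.name == "N" and res.residue_name != "PRO":
        roles.add("donor")  # backbone amide NH
    if atom.name in ("O", "OXT"):
        roles.add("acceptor")  # backbone carbonyl
    table = SIDECHAIN_HBOND_TABLE.get(res.residue_name, {})
    entry = table.get(atom.name)
    if entry is None and atom.element in ("N", "O") and not atom.is_backbone:
        logger.info(
            "no donor/acceptor table entry for %s %s atom %s: treated as neither",
            res.residue_name, res.residue_number, atom.name,
        )
    if entry:
        roles |= set(entry)
    return frozenset(roles)


def _ligand_hbond_roles(atom: LigandAtom) -> frozenset[str]:
    roles: set[str] = set()
    if atom.element in ("N", "O"):
        if atom.n_attached_h >= 1 or (atom.element == "N" and atom.formal_charge > 0):
            roles.add("donor")
        # quaternary / fully substituted positively-charged N has no lone pair
        if not (atom.element == "N" and atom.formal_charge > 0
                and atom.n_attached_h == 0):
            roles.add("acceptor")
    return frozenset(roles)


def _angle_ok(donor_xyz, acceptor_xyz, h_coords, min_deg: float) -> bool:
    """D-H...A angle criterion; passes vacuously without explicit hydrogens."""
    if h_coords is None or len(h_coords) == 0:
        return True
    d = np.asarray(donor_xyz, float)
    a = np.asarray(acceptor_xyz, float)
    for h in h_coords:
        h = np.asarray(h, float)
        v1, v2 = d - h, a - h
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= min_deg:
            return True
    return False


def _attached_hydrogens(res: Residue, donor) -> list[tuple[float, float, float]]:
    """Explicit H atoms covalently close (<1.3 A) to a receptor donor atom."""
    out = []
    d = np.array(donor.xyz)
    for a in res.atoms:
        if a.is_hydrogen and np.linalg.norm(np.array(a.xyz) - d) < 1.3:
            out.append(a.xyz)
    return out


# ---------------------------------------------------------------------------
# Fingerprint computation
# ---------------------------------------------------------------------------

def _monomer_bits(res: Residue, pose: LigandPose, rules: GeometryRules) -> np.ndarray:
    """Nine interaction bits of one ligand pose against one monomer copy."""
    bits = np.zeros(N_TYPES, dtype=np.int8)
    heavy = [a for a in res.atoms if not a.is_hydrogen]
    if not heavy:
        return bits
    lig_atoms = pose.heavy_atoms()
    res_xyz = np.array([a.xyz for a in heavy], float)
    lig_xyz = np.array([a.xyz for a in lig_atoms], float)
    dmat = cdist(res_xyz, lig_xyz)

    contact_pairs = dmat <= rules.contact_max_A
    if not contact_pairs.any():
        return bits
    bits[0] = 1  # contact

    backbone_mask = np.array([a.is_backbone for a in heavy])
    bits[1] = int(contact_pairs[backbone_mask].any())
    bits[2] = int(contact_pairs[~backbone_mask].any())
    name = res.residue_name
    bits[3] = int(name in rules.polar)
    bits[4] = int(name in rules.hydrophobic)
    bits[7] = int(name in rules.aromatic)
    bits[8] = int(name in rules.charged)

    hb_pairs = dmat <= rules.hbond_dist_max_A
    if hb_pairs.any():
        for i, ratom in enumerate(heavy):
            roles = _residue_hbond_roles(res, ratom)
            if not roles:
                continue
            for j, latom in enumerate(lig_atoms):
                if not hb_pairs[i, j]:
                    continue
                lroles = _ligand_hbond_roles(latom)
                if "acceptor" in roles and "donor" in lroles:
                    bits[5] = 1  # BS atom accepts from ligand donor
                if "donor" in roles and "acceptor" in lroles:
                    hcoords = _attached_hydrogens(res, ratom)
                    if _angle_ok(ratom.xyz, latom.xyz, hcoords,
                                 rules.hbond_angle_min_deg):
                        bits[6] = 1  # BS atom donates to ligand acceptor
            if bits[5] and bits[6]:
                break

    # every specific interaction implies a contact
    bits[1:] &= bits[0]
    return bits


def compute_fingerprint(
    complex_model: ComplexModel,
    site: BindingSite,
    rules: GeometryRules = GeometryRules(),
) -> InteractionFingerprint:
    """Nine-bit-per-residue fingerprint of the pose, OR-merged over monomers."""
    receptor, pose = complex_model.receptor, complex_model.pose
    bits = np.zeros((len(site.residue_keys), N_TYPES), dtype=np.int8)
    for row, key in enumerate(site.residue_keys):
        copies = receptor.by_key(key)
        if not copies:
            raise ValueError(f"site residue {key} absent from receptor")
        for res in copies:
            bits[row] |= _monomer_bits(res, pose, rules)
    return InteractionFingerprint(pose.compound_id, site.residue_keys, bits)


def fingerprint_matrix(
    complexes: Sequence[ComplexModel],
    site: BindingSite,
    rules: GeometryRules = GeometryRules(),
) -> pd.DataFrame:
    """One fingerprint row per compound; columns 'NNN_type' in fixed order."""
    ids = [c.pose.compound_id for c in complexes]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate compound_id(s): {sorted(dupes)}")
    rows = [compute_fingerprint(c, site, rules).to_series() for c in complexes]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fingerprint_table(
    table: pd.DataFrame,
    path,
    *,
    site: BindingSite | None = None,
    site_cfg: BindingSiteConfig | None = None,
    rules: GeometryRules | None = None,
) -> None:
    """Write the fingerprint table as CSV with a JSON geometry manifest."""
    table.to_csv(path, index_label="compound_id")
    manifest = {
        "binding_site_cutoff_A": site_cfg.cutoff_A if site_cfg else None,
        "residue_keys": list(site.residue_keys) if site else None,
        "geometry_rules": rules.to_manifest() if rules else None,
        "interaction_types": list(INTERACTION_TYPES),
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))


def read_fingerprint_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="compound_id")
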