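"""Synthetic fixtures: toy tetrameric receptors, placed ligand poses, and
score/fingerprint/potency datasets with planted statistical structure.

Two generators cover the pipeline end to end with no external downloads:

``make_toy_complex``
    A C4-symmetric poly-residue receptor whose chains are rotated copies of
    one inward-facing column of residues, with ligand atoms placed at exact
    requested distances from named residue atoms. Each residue carries the
    four backbone atoms plus one representative side-chain atom chosen so
    every interaction detector (hydrophobic, aromatic, polar, charged and
    both hydrogen-bond directions) is exercisable. The construction is its
    own oracle: a planted 3 A approach to a PHE ring carbon must light the
    contact/side-chain/hydrophobic/aromatic bits and nothing else.

``make_dataset``
    Tabular data emulating a docked, curated compound set: docking scores
    drawn from class-conditional Gaussians (binders shifted to better
    scores - the bimodality the docking engines show on this target),
    fingerprint bits drawn Bernoulli per class, and log-normal IC50 values
    (median 10 uM, geometric sd 10, clipped to [1 nM, 1 mM] - the dynamic
    range of the bioactivity data) with optional multiplicative effects tied
    to planted bits. Ground-truth parameters are returned for recovery tests.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import BINDER_CLASS, NONBINDER_CLASS
from .structures_io import (
    Atom,
    ComplexModel,
    LigandAtom,
    LigandPose,
    ReceptorStructure,
    Residue,
)

# representative side-chain atom per residue type (name, element)
SIDECHAIN_ATOM = {
    "ALA": ("CB", "C"), "VAL": ("CB", "C"), "LEU": ("CB", "C"),
    "ILE": ("CB", "C"), "MET": ("SD", "S"), "PHE": ("CZ", "C"),
    "TRP": ("NE1", "N"), "PRO": ("CB", "C"), "TYR": ("OH", "O"),
    "SER": ("OG", "O"), "THR": ("OG1", "O"), "ASN": ("OD1", "O"),
    "GLN": ("NE2", "N"), "CYS": ("SG", "S"), "HIS": ("NE2", "N"),
    "ASP": ("OD1", "O"), "GLU": ("OE1", "O"), "LYS": ("NZ", "N"),
    "ARG": ("NH1", "N"),
}


@dataclass(frozen=True)
class LigandPlacement:
    """One ligand atom at an exact distance from a named receptor atom,
    displaced toward the pore axis (so the distance to that atom is exact)."""

    chain_id: str
    residue_number: int
    atom_name: str
    distance_A: float
    element: str = "C"
    formal_charge: int = 0
    n_attached_h: int = 0


@dataclass(frozen=True)
class ToyComplexSpec:
    n_chains: int = 4
    residues_per_chain: tuple[tuple[int, str], ...] = (
        (557, "PHE"), (623, "THR"), (624, "SER"), (652, "TYR"), (656, "PHE"),
    )
    placements: tuple[LigandPlacement, ...] = (
        LigandPlacement("A", 557, "CZ", 3.5),
    )
    ring_radius_A: float = 12.0
    rise_per_residue_A: float = 5.0
    compound_id: str = "toy-ligand"
    docking_score: float = -8.0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if any(p.distance_A <= 0 for p in self.placements):
            raise ValueError("placement distances must be > 0")
        bad = [name for _, name in self.residues_per_chain
               if name != "GLY" and name not in SIDECHAIN_ATOM]
        if bad:
            raise ValueError(f"unsupported residue names: {bad}")


def _rotation_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _chain_id(i: int) -> str:
    return "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[i]


def make_toy_receptor(spec: ToyComplexSpec) -> ReceptorStructure:
    """C4-symmetric (generally Cn) receptor: chain A is a vertical column of
    residues at ``ring_radius_A`` from the z axis, side chains pointing at
    the axis; the other chains are rotated copies."""
    residues = []
    for ci in range(spec.n_chains):
        rot = _rotation_z(2.0 * math.pi * ci / spec.n_chains)
        for ri, (resnum, resname) in enumerate(spec.residues_per_chain):
            ca = np.array([spec.ring_radius_A, 0.0, ri * spec.rise_per_residue_A])
            inward = np.array([-1.0, 0.0, 0.0])
            atoms = [
                Atom("N", "N", tuple(rot @ (ca + [0.0, -1.46, 0.0]))),
                Atom("CA", "C", tuple(rot @ ca)),
                Atom("C", "C", tuple(rot @ (ca + [0.0, 1.52, 0.0]))),
                Atom("O", "O", tuple(rot @ (ca + [0.6, 2.2, 0.0]))),
            ]
            if resname != "GLY":
                scname, scelem = SIDECHAIN_ATOM[resname]
                atoms.append(Atom(scname, scelem, tuple(rot @ (ca + 1.5 * inward))))
            residues.append(Residue(_chain_id(ci), resnum, resname, tuple(atoms)))
    return ReceptorStructure(tuple(residues))


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ComplexModel:
    """Receptor plus a ligand whose atoms sit at the exact requested
    distances from the named receptor atoms, displaced toward the pore axis."""
    receptor = make_toy_receptor(spec)
    atom_lookup = {
        (r.chain_id, r.residue_number, a.name): np.array(a.xyz)
        for r in receptor.residues
        for a in r.atoms
    }
    lig_atoms = []
    for p in spec.placements:
        key = (p.chain_id, p.residue_number, p.atom_name)
        if key not in atom_lookup:
            raise ValueError(f"no receptor atom {key}")
        anchor = atom_lookup[key]
        axis_point = np.array([0.0, 0.0, anchor[2]])
        direction = axis_point - anchor
        norm = np.linalg.norm(direction)
        if norm == 0 or p.distance_A > 2 * norm:
            raise ValueError(
                f"placement at {p.distance_A} A from {key} is geometrically "
                "infeasible inside the pore"
            )
        pos = anchor + direction / norm * p.distance_A
        lig_atoms.append(
            LigandAtom(p.element, tuple(pos), p.formal_charge, p.n_attached_h)
        )
    pose = LigandPose(spec.compound_id, tuple(lig_atoms), spec.docking_score)
    return ComplexModel(receptor, pose)


# ---------------------------------------------------------------------------
# Tabular dataset with planted structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedBit:
    """One fingerprint column with class-conditional firing probabilities and
    an optional multiplicative IC50 effect when the bit is on."""

    label: str
    prob_in_binders: float
    prob_in_nonbinders: float
    ic50_effect: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.prob_in_binders, self.prob_in_nonbinders):
            if not (0.0 <= p <= 1.0):
                raise ValueError("bit probabilities must lie in [0, 1]")
        if self.ic50_effect <= 0:
            raise ValueError("ic50_effect must be > 0")


@dataclass(frozen=True)
class SyntheticSpec:
    n_binders: int = 400
    n_nonbinders: int = 400
    ds_mean_binder: float = -8.0
    ds_mean_nonbinder: float = -6.0
    ds_sd: float = 1.0
    planted_bits: tuple[PlantedBit, ...] = ()
    ic50_median_uM: float = 10.0
    ic50_gsd: float = 10.0
    ic50_clip_uM: tuple[float, float] = (1e-3, 1e3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ds_sd <= 0:
            raise ValueError("ds_sd must be > 0")
        if min(self.n_binders, self.n_nonbinders) < 60:
            raise ValueError(
                "need >= 60 compounds per class for the resampling protocol"
            )


@dataclass(frozen=True)
class SyntheticDataset:
    ds: pd.Series                 # raw docking scores, lower is better
    if_table: pd.DataFrame        # binary 0/1 fingerprint columns
    ic50_uM: pd.Series
    labels: pd.Series             # +1 binder / -1 nonbinder
    truth: dict


def make_dataset(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_binders + spec.n_nonbinders
    ids = [f"CPD{i:05d}" for i in range(n)]
    y = np.concatenate(
        [np.full(spec.n_binders, BINDER_CLASS),
         np.full(spec.n_nonbinders, NONBINDER_CLASS)]
    )
    means = np.where(y == BINDER_CLASS, spec.ds_mean_binder, spec.ds_mean_nonbinder)
    ds = rng.normal(means, spec.ds_sd)

    bit_cols = {}
    for bit in spec.planted_bits:
        probs = np.where(y == BINDER_CLASS, bit.prob_in_binders,
                         bit.prob_in_nonbinders)
        bit_cols[bit.label] = (rng.random(n) < probs).astype(int)
    if_table = pd.DataFrame(bit_cols, index=ids, dtype=int)

    log_ic50 = rng.normal(math.log(spec.ic50_median_uM),
                          math.log(spec.ic50_gsd), size=n)
    for bit in spec.planted_bits:
        if bit.ic50_effect != 1.0:
            log_ic50 += bit_cols[bit.label] * math.log(bit.ic50_effect)
    ic50 = np.clip(np.exp(log_ic50), *spec.ic50_clip_uM)

    return SyntheticDataset(
        ds=pd.Series(ds, index=ids, name="docking_score"),
        if_table=if_table,
        ic50_uM=pd.Series(ic50, index=ids, name="ic50_uM"),
        labels=pd.Series(y, index=ids, name="label"),
        truth={
            "ds_delta": spec.ds_mean_nonbinder - spec.ds_mean_binder,
            "ds_sd": spec.ds_sd,
            "theoretical_ds_auc": theoretical_two_gaussian_auc(
                spec.ds_mean_binder, spec.ds_mean_nonbinder, spec.ds_sd
            ),
            "planted_bits": [bit.label for bit in spec.planted_bits],
        },
    )


def theoretical_two_gaussian_auc(mean_binder: float, mean_nonbinder: float,
                                 sd: float) -> float:
    """Closed-form AUC of a two-Gaussian score mixture with common sd when
    binders score lower (better): Phi(|delta| / (sd * sqrt(2)))."""
    from scipy.stats import norm

    delta = abs(mean_nonbinder - mean_binder)
    return float(norm.cdf(delta / (sd * math.sqrt(2.0))))
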