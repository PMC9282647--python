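"""Curation of ChEMBL-style hERG bioactivity tables.

Filters raw activity records down to the analysis dataset, assigns
binder/nonbinder labels for a chosen inactivity threshold, measures the
internal (structural) diversity of the curated set, and picks representative
binders by fingerprint clustering.

Conventions
-----------
IC50 values are carried in nM (the ChEMBL ``standard_value`` convention for
this target) and converted to uM only where thresholds are expressed in uM.
A missing potency reported as ``"not a number"`` in the activity field is a
legitimate nonbinder annotation, not a parse failure, and is kept as NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, DataStructs, Descriptors
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

NAN_SENTINELS = {"not a number", "nan", "na", ""}

BINDER = "binder"
NONBINDER = "nonbinder"


# ---------------------------------------------------------------------------
# Record and policy types
# ---------------------------------------------------------------------------

@dataclass
class ActivityRecord:
    """One bioactivity entry as exported from a ChEMBL activity table."""

    compound_id: str
    smiles: str
    ic50_nM: float  # NaN encodes the "not a number" annotation
    assay_type: str = "B"
    target_organism: str = "Homo sapiens"
    data_validity_comment: str = ""
    molecular_weight_Da: float | None = None
    standard_type: str = "IC50"

    def ic50_uM(self) -> float:
        return self.ic50_nM / 1000.0


@dataclass(frozen=True)
class CurationPolicy:
    """Predicates a record must satisfy to enter the curated dataset."""

    require_ic50: bool = True
    organism: str = "Homo sapiens"
    assay_type: str = "B"
    reject_validity_warnings: bool = True
    mw_min_Da: float = 200.0
    mw_max_Da: float = 600.0
    dedup: bool = True

    def __post_init__(self) -> None:
        if not self.mw_min_Da < self.mw_max_Da:
            raise ValueError("mw_min_Da must be < mw_max_Da")


@dataclass(frozen=True)
class LabelingPolicy:
    """IC50 cutoffs (uM) defining binders and nonbinders.

    Compounds with IC50 <= ``active_max_uM`` are binders; compounds with
    IC50 > ``inactive_min_uM`` (or an unquantified "not a number" potency,
    when ``nan_is_negative``) are nonbinders; anything strictly between the
    two bounds is excluded from the labeled set.
    """

    active_max_uM: float = 1.0
    inactive_min_uM: float = 80.0
    nan_is_negative: bool = True

    def __post_init__(self) -> None:
        if self.inactive_min_uM < self.active_max_uM:
            raise ValueError(
                "inactive_min_uM must be >= active_max_uM "
                f"(got {self.inactive_min_uM} < {self.active_max_uM})"
            )


@dataclass(frozen=True)
class LabeledDataset:
    records: tuple[tuple[str, str], ...]  # (compound_id, BINDER|NONBINDER)
    threshold_uM: float
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate compound_id in labeled dataset")
        bad = {lab for _, lab in self.records} - {BINDER, NONBINDER}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    @property
    def binders(self) -> list[str]:
        return [cid for cid, lab in self.records if lab == BINDER]

    @property
    def nonbinders(self) -> list[str]:
        return [cid for cid, lab in self.records if lab == NONBINDER]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["compound_id", "label"])


@dataclass(frozen=True)
class DiversityConfig:
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError("n_bits must be a power of two")


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 5
    radius: int = 2
    n_bits: int = 2048
    max_iter: int = 300
    seed: int = 0


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def parse_ic50(value) -> float:
    """Parse an activity value; the 'not a number' annotation maps to NaN."""
    if value is None:
        return math.nan
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().lower()
    if text in NAN_SENTINELS:
        return math.nan
    return float(text)


def _mol_from_smiles(smiles: str):
    return Chem.MolFromSmiles(smiles) if smiles else None


def _parent_mol(mol):
    """Largest organic fragment: the desalted parent structure."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def canonical_parent_key(smiles: str) -> str | None:
    mol = _mol_from_smiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(_parent_mol(mol))


# ---------------------------------------------------------------------------
# curate
# ---------------------------------------------------------------------------

def curate(
    records: Sequence[ActivityRecord], policy: CurationPolicy = CurationPolicy()
) -> tuple[list[ActivityRecord], dict[str, int]]:
    """Apply the curation filters and return (survivors, audit counts).

    Filters, in order: activity type is IC50; human target organism; direct
    binding ('B') assays; no data-validity warning; parsable SMILES;
    molecular weight within [mw_min_Da, mw_max_Da]; structural duplicates
    collapsed onto the desalted parent, keeping the record with the lowest
    numeric IC50 (conservative for a toxicity endpoint).
    """
    audit = {
        "input": len(records),
        "removed_not_ic50": 0,
        "removed_organism": 0,
        "removed_assay_type": 0,
        "removed_validity_warning": 0,
        "removed_bad_smiles": 0,
        "removed_mw": 0,
        "removed_duplicates": 0,
    }
    survivors: list[ActivityRecord] = []
    for rec in records:
        if policy.require_ic50 and rec.standard_type.strip().upper() != "IC50":
            audit["removed_not_ic50"] += 1
            continue
        if rec.target_organism.strip() != policy.organism:
            audit["removed_organism"] += 1
            continue
        if rec.assay_type.strip().upper() != policy.assay_type.upper():
            audit["removed_assay_type"] += 1
            continue
        comment = (rec.data_validity_comment or "").strip().lower()
        if policy.reject_validity_warnings and comment not in {"", "nan"}:
            audit["removed_validity_warning"] += 1
            continue
        mol = _mol_from_smiles(rec.smiles)
        if mol is None:
            logger.warning("rejecting %s: unparsable SMILES %r",
                           rec.compound_id, rec.smiles)
            audit["removed_bad_smiles"] += 1
            continue
        mw = rec.molecular_weight_Da
        if mw is None:
            mw = Descriptors.MolWt(mol)
            rec = replace(rec, molecular_weight_Da=mw)
        if not (policy.mw_min_Da <= mw <= policy.mw_max_Da):
            audit["removed_mw"] += 1
            continue
        survivors.append(rec)

    if policy.dedup:
        best: dict[str, ActivityRecord] = {}
        order: list[str] = []
        for rec in survivors:
            key = canonical_parent_key(rec.smiles)
            if key not in best:
                best[key] = rec
                order.append(key)
            else:
                audit["removed_duplicates"] += 1
                old = best[key].ic50_nM
                new = rec.ic50_nM
                # lowest numeric IC50 wins; NaN ranks last
                if not math.isnan(new) and (math.isnan(old) or new < old):
                    best[key] = rec
        survivors = [best[k] for k in order]

    audit["output"] = len(survivors)
    return survivors, audit


# ---------------------------------------------------------------------------
# assign_labels
# ---------------------------------------------------------------------------

def assign_labels(
    records: Sequence[ActivityRecord], policy: LabelingPolicy = LabelingPolicy()
) -> LabeledDataset:
    """Partition curated records into binders / nonbinders / excluded."""
    labeled: list[tuple[str, str]] = []
    excluded: list[str] = []
    for rec in records:
        ic50 = rec.ic50_uM()
        if math.isnan(ic50):
            if policy.nan_is_negative:
                labeled.append((rec.compound_id, NONBINDER))
            else:
                excluded.append(rec.compound_id)
        elif ic50 <= policy.active_max_uM:
            labeled.append((rec.compound_id, BINDER))
        elif ic50 > policy.inactive_min_uM:
            labeled.append((rec.compound_id, NONBINDER))
        else:
            excluded.append(rec.compound_id)
    return LabeledDataset(
        records=tuple(labeled),
        threshold_uM=policy.inactive_min_uM,
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# internal diversity
# ---------------------------------------------------------------------------

def _morgan_fps(smiles: Iterable[str], radius: int, n_bits: int):
    fps = []
    for smi in smiles:
        mol = _mol_from_smiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smi!r}")
        fps.append(AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits))
    return fps


def internal_diversity(
    smiles: Sequence[str], cfg: DiversityConfig = DiversityConfig()
) -> float:
    """Mean pairwise Tanimoto distance (1 - similarity) over all unordered
    pairs of hashed circular (Morgan) fingerprints; 0 for an identical set."""
    if len(smiles) < 2:
        raise ValueError("internal_diversity needs at least 2 molecules")
    fps = _morgan_fps(smiles, cfg.radius, cfg.n_bits)
    total = 0.0
    n_pairs = 0
    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        total += sum(1.0 - s for s in sims)
        n_pairs += i
    return total / n_pairs


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def select_representatives(
    records: Sequence[ActivityRecord], cfg: ClusteringConfig = ClusteringConfig()
) -> list[str]:
    """Cluster compounds on binary circular fingerprints and return, per
    cluster, the compound with the lowest IC50 (the most potent binder)."""
    if cfg.k > len(records):
        raise ValueError(f"k={cfg.k} exceeds n={len(records)} compounds")
    if any(math.isnan(r.ic50_nM) for r in records):
        raise ValueError("select_representatives requires numeric IC50 for all records")
    if cfg.k == len(records):  # singleton clusters
        return [r.compound_id for r in records]
    fps = _morgan_fps([r.smiles for r in records], cfg.radius, cfg.n_bits)
    X = np.zeros((len(fps), cfg.n_bits), dtype=np.float64)
    for i, fp in enumerate(fps):
        DataStructs.ConvertToNumpyArray(fp, X[i])
    km = KMeans(
        n_clusters=cfg.k, max_iter=cfg.max_iter, n_init=10, random_state=cfg.seed
    ).fit(X)
    chosen: list[str] = []
    for cluster in range(cfg.k):
        members = [r for r, lab in zip(records, km.labels_) if lab == cluster]
        if not members:
            raise ValueError(
                f"k-means produced an empty cluster (k={cfg.k}); the set has "
                "fewer distinct fingerprints than k"
            )
        chosen.append(min(members, key=lambda r: r.ic50_nM).compound_id)
    return chosen


# ---------------------------------------------------------------------------
# I/O: ChEMBL-style activity tables
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "compound_id": "Molecule ChEMBL ID",
    "smiles": "Smiles",
    "ic50": "Standard Value",
    "standard_type": "Standard Type",
    "assay_type": "Assay Type",
    "target_organism": "Target Organism",
    "data_validity_comment": "Data Validity Comment",
    "molecular_weight": "Molecular Weight",
}


def read_activity_table(
    path, column_map: dict[str, str] | None = None, sep: str | None = None
) -> list[ActivityRecord]:
    """Read a ChEMBL-style activity CSV/TSV export into ActivityRecords.

    ``column_map`` maps the canonical field names used here onto the file's
    column headers; the default matches ChEMBL web exports. The separator is
    sniffed from the extension unless given.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [v for k, v in cmap.items()
               if k in ("compound_id", "smiles", "ic50") and v not in df.columns]
    if missing:
        raise ValueError(f"activity table lacks required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        mw_text = row.get(cmap["molecular_weight"], "")
        records.append(
            ActivityRecord(
                compound_id=row[cmap["compound_id"]],
                smiles=row[cmap["smiles"]],
                ic50_nM=parse_ic50(row[cmap["ic50"]]),
                assay_type=row.get(cmap["assay_type"], "B"),
                target_organism=row.get(cmap["target_organism"], "Homo sapiens"),
                data_validity_comment=row.get(cmap["data_validity_comment"], ""),
                molecular_weight_Da=float(mw_text) if mw_text.strip() else None,
                standard_type=row.get(cmap["standard_type"], "IC50"),
            )
        )
    return records


def write_curated(records: Sequence[ActivityRecord], path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "ic50_nM": [r.ic50_nM for r in records],
            "assay_type": [r.assay_type for r in records],
            "target_organism": [r.target_organism for r in records],
            "molecular_weight_Da": [r.molecular_weight_Da for r in records],
        }
    ).to_csv(path, index=False)
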