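"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from scratch with plain Python
loops and its own literal constants, so agreement with the package is a
genuine dual-route check rather than a tautology.
"""

from __future__ import annotations

import itertools
import math

# --- literal geometry/typing constants (re-declared on purpose) -----------

ORACLE_CONTACT = 4.5
ORACLE_HBOND = 3.5
ORACLE_BACKBONE = {"N", "CA", "C", "O", "OXT"}
ORACLE_HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
ORACLE_AROMATIC = {"PHE", "TYR", "TRP", "HIS"}
ORACLE_POLAR = {"SER", "THR", "ASN", "GLN", "CYS", "TYR", "HIS"}
ORACLE_CHARGED = {"ASP", "GLU", "LYS", "ARG", "HIS"}

ORACLE_SC_HBOND = {
    ("SER", "OG"): {"donor", "acceptor"},
    ("THR", "OG1"): {"donor", "acceptor"},
    ("TYR", "OH"): {"donor", "acceptor"},
    ("CYS", "SG"): {"donor"},
    ("ASN", "OD1"): {"acceptor"},
    ("ASN", "ND2"): {"donor"},
    ("GLN", "OE1"): {"acceptor"},
    ("GLN", "NE2"): {"donor"},
    ("ASP", "OD1"): {"acceptor"},
    ("ASP", "OD2"): {"acceptor"},
    ("GLU", "OE1"): {"acceptor"},
    ("GLU", "OE2"): {"acceptor"},
    ("LYS", "NZ"): {"donor"},
    ("ARG", "NE"): {"donor"},
    ("ARG", "NH1"): {"donor"},
    ("ARG", "NH2"): {"donor"},
    ("HIS", "ND1"): {"donor", "acceptor"},
    ("HIS", "NE2"): {"donor", "acceptor"},
    ("TRP", "NE1"): {"donor"},
}


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _residue_atom_roles(resname, atom_name):
    roles = set()
    if atom_name == "N" and resname != "PRO":
        roles.add("donor")
    if atom_name in ("O", "OXT"):
        roles.add("acceptor")
    roles |= ORACLE_SC_HBOND.get((resname, atom_name), set())
    return roles


def _ligand_atom_roles(element, charge, n_h):
    roles = set()
    if element in ("N", "O"):
        if n_h >= 1 or (element == "N" and charge > 0):
            roles.add("donor")
        if not (element == "N" and charge > 0 and n_h == 0):
            roles.add("acceptor")
    return roles


def brute_force_bits(residue, ligand_atoms):
    """Nine bits of one monomer residue vs a ligand, by exhaustive pair loops.

    ``residue`` is a hergsift Residue; ``ligand_atoms`` an iterable of
    (element, xyz, formal_charge, n_attached_h). Returns a list of 9 ints in
    the fixed type order contact, backbone, sidechain, polar, hydrophobic,
    hbond_acceptor, hbond_donor, aromatic, charged.
    """
    heavy = [a for a in residue.atoms if a.element.upper() != "H"]
    lig = [a for a in ligand_atoms if a[0].upper() != "H"]
    contact = False
    backbone = False
    sidechain = False
    acc = False  # BS accepts from ligand donor
    don = False  # BS donates to ligand acceptor
    for ra in heavy:
        for (elem, xyz, charge, n_h) in lig:
            d = _dist(ra.xyz, xyz)
            if d <= ORACLE_CONTACT:
                contact = True
                if ra.name in ORACLE_BACKBONE:
                    backbone = True
                else:
                    sidechain = True
            if d <= ORACLE_HBOND:
                rroles = _residue_atom_roles(residue.residue_name, ra.name)
                lroles = _ligand_atom_roles(elem, charge, n_h)
                if "acceptor" in rroles and "donor" in lroles:
                    acc = True
                if "donor" in rroles and "acceptor" in lroles:
                    don = True
    name = residue.residue_name
    bits = [
        contact,
        backbone,
        sidechain,
        contact and name in ORACLE_POLAR,
        contact and name in ORACLE_HYDROPHOBIC,
        acc,
        don,
        contact and name in ORACLE_AROMATIC,
        contact and name in ORACLE_CHARGED,
    ]
    # specific implies contact
    bits = [bits[0]] + [b and bits[0] for b in bits[1:]]
    return [int(b) for b in bits]


def brute_force_fingerprint(receptor, pose, site_keys):
    """OR over monomer copies of brute_force_bits, per site residue key."""
    lig = [(a.element, a.xyz, a.formal_charge, a.n_attached_h)
           for a in pose.atoms]
    rows = []
    for key in site_keys:
        merged = [0] * 9
        for res in receptor.residues:
            if (res.residue_number, res.residue_name) == key:
                bits = brute_force_bits(res, lig)
                merged = [m | b for m, b in zip(merged, bits)]
        rows.append(merged)
    return rows


def brute_force_site(receptor, pose, cutoff):
    """Residue keys with any heavy-atom pair within cutoff, by full loops."""
    lig = [a.xyz for a in pose.atoms if a.element.upper() != "H"]
    keys = set()
    for res in receptor.residues:
        for ra in res.atoms:
            if ra.element.upper() == "H":
                continue
            if any(_dist(ra.xyz, lx) <= cutoff for lx in lig):
                keys.add((res.residue_number, res.residue_name))
                break
    return sorted(keys)


# --- statistics oracles ----------------------------------------------------

def brute_force_auc(scores, labels):
    """AUC by explicit pair counting: P(s+ > s-) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def ecdf_ks_statistic(a, b):
    """sup |ECDF_a - ECDF_b| evaluated at every pooled point."""
    points = sorted(set(a) | set(b))
    best = 0.0
    for x in points:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


def permutation_ks_pvalue(a, b):
    """Exact KS p-value by enumerating every split of the pooled sample."""
    pooled = list(a) + list(b)
    n_a = len(a)
    observed = ecdf_ks_statistic(a, b)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if ecdf_ks_statistic(aa, bb) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def trapezoidal_roc_auc(scores, labels):
    """AUC as the trapezoidal area under the empirical ROC curve."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(1 for y in labels if y == 1)
    n_neg = len(labels) - n_pos
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    area = 0.0
    for k in range(1, len(tpr)):
        area += (fpr[k] - fpr[k - 1]) * (tpr[k] + tpr[k - 1]) / 2.0
    return area
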