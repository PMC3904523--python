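"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain
Python loops over atoms, pairs and cutoffs, so that agreement with the
library is a meaningful cross-check.  The only shared element is the
documented comparison contract (inclusive distance bounds with a 1e-9
float tolerance).
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

TOL = 1e-9

BINARY_OF = {
    "hydrophobic": "hydrophobic",
    "aromatic": "hydrophobic",
    "neutral": "hydrophobic",
    "sulphur": "hydrophobic",
    "positive": "polar",
    "negative": "polar",
    "hydrogen_acceptor": "polar",
    "hydrogen_donor": "polar",
}

CLASS_ORDER = [
    "hydrophobic", "positive", "negative", "hydrogen_acceptor",
    "hydrogen_donor", "aromatic", "sulphur", "neutral",
]


def naive_distance(a: Sequence[float], b: Sequence[float]) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def naive_distance_matrix(coords: Sequence[Sequence[float]]) -> List[List[float]]:
    n = len(coords)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            out[i][j] = naive_distance(coords[i], coords[j])
    return out


def pair_label(ca: str, cb: str, order: Sequence[str]) -> str:
    ia, ib = order.index(ca), order.index(cb)
    if ia <= ib:
        return f"{ca}|{cb}"
    return f"{cb}|{ca}"


def scheme_atom_classes(classes: Sequence[str], scheme: str) -> List[str]:
    if scheme == "one_class":
        return ["atom"] * len(classes)
    if scheme == "binary":
        return [BINARY_OF[c] for c in classes]
    return list(classes)


def scheme_order(scheme: str) -> List[str]:
    if scheme == "one_class":
        return ["atom"]
    if scheme == "binary":
        return ["hydrophobic", "polar"]
    return CLASS_ORDER


def brute_force_scan(
    coords: Sequence[Sequence[float]],
    classes: Sequence[str],
    cutoffs: Sequence[float],
    scheme: str,
) -> Dict[str, List[int]]:
    """Triple loop over (pair, cutoff): cumulative counts per pair label."""
    order = scheme_order(scheme)
    labels = [
        f"{a}|{b}" for a, b in itertools.combinations_with_replacement(order, 2)
    ]
    counts: Dict[str, List[int]] = {lab: [0] * len(cutoffs) for lab in labels}
    atom_cls = scheme_atom_classes(classes, scheme)
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = naive_distance(coords[i], coords[j])
            lab = pair_label(atom_cls[i], atom_cls[j], order)
            for k, c in enumerate(cutoffs):
                if d <= c + TOL:
                    counts[lab][k] += 1
    return counts


def brute_force_signature(
    structure,
    chain: str,
    position: int,
    wt: str,
    mt: str,
    cutoffs: Sequence[float],
    radius: float,
    table,
    ph: float,
    temperature: float,
    rsa: float,
    schemes: Sequence[str] = ("one_class", "binary", "pharmacophore"),
) -> Tuple[List[float], List[str]]:
    """Monolithic end-to-end reimplementation of the signature pipeline.

    Works directly on a labelled ProteinStructure with plain loops:
    residue centre, environment membership, cumulative scans per scheme,
    pharmacophore change by direct table tally, then flat assembly in the
    documented scheme -> pair-class -> cutoff order.
    """
    key = (chain, position, "")
    own = [a for a in structure.atoms if a.residue_key == key]
    assert own, "residue not found"
    centre = [
        sum(a.coords[k] for a in own) / len(own) for k in range(3)
    ]
    env = [
        a for a in structure.atoms
        if naive_distance(a.coords, centre) <= radius + TOL
    ]
    coords = [list(a.coords) for a in env]
    classes = [a.pharmacophore for a in env]

    features: List[float] = []
    names: List[str] = []
    for scheme in schemes:
        scan = brute_force_scan(coords, classes, cutoffs, scheme)
        order = scheme_order(scheme)
        for a, b in itertools.combinations_with_replacement(order, 2):
            lab = f"{a}|{b}"
            for k, c in enumerate(cutoffs):
                features.append(float(scan[lab][k]))
                names.append(f"{scheme}:{lab}:{c:g}")

    p_wt = tally_residue(table, wt)
    p_mt = tally_residue(table, mt)
    for cls in CLASS_ORDER:
        features.append(float(p_mt[cls] - p_wt[cls]))
        names.append(f"p_change:{cls}")
    features.extend([ph, temperature, rsa])
    names.extend(["ph", "temperature", "rsa"])
    return features, names


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def tally_residue(table, code: str) -> Dict[str, int]:
    """Independent per-class tally over a residue's table inventory."""
    res = _ONE_TO_THREE.get(code.upper(), code.upper())
    counts = {cls: 0 for cls in CLASS_ORDER}
    for (r, atom), cls in table._mapping.items():
        if r == res and atom != "OXT":
            counts[cls] += 1
    return counts


def all_pairs_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the concordance fraction over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = len(pos) * len(neg)
    assert total > 0
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / total
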