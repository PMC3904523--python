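"""Cutoff-scanning signature computation around a mutation site.

The signature of a mutation encodes the wild-type residue environment as a
cumulative atomic distance distribution.  All labelled heavy atoms within a
radius ``r`` of the geometric centre of the mutated residue form a contact
graph whose edge count is recorded while the edge-defining distance cutoff
sweeps a grid from ``d_min`` to ``d_max``.  The counts are segmented by
atom-class pairs under up to three classification schemes (one class;
binary polar/hydrophobic; the eight pharmacophore classes), and the flat
vector is completed with the pharmacophore-change vector of the
substitution plus pH, temperature and relative solvent accessibility.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import UnsupportedResidueError, WildTypeMismatchError
from .structure import (
    BINARY_CLASS_OF,
    ONE_TO_THREE,
    PHARMACOPHORE_CLASSES,
    THREE_TO_ONE,
    AtomRecord,
    PharmacophoreTable,
    ProteinStructure,
    ResidueKey,
    _normalize_key,
    compute_rsa,
    residue_pharmacophore_vector,
)

SCHEMES: Tuple[str, ...] = ("one_class", "binary", "pharmacophore")

_SCHEME_CLASSES: Dict[str, Tuple[str, ...]] = {
    "one_class": ("atom",),
    "binary": ("hydrophobic", "polar"),
    "pharmacophore": PHARMACOPHORE_CLASSES,
}

DEFAULT_PH = 7.0
DEFAULT_TEMPERATURE_C = 25.0


@dataclass(frozen=True)
class SignatureParams:
    """Geometry and layout parameters of the signature.

    radius
        Environment radius *r* around the residue's geometric centre (Å).
    d_min, d_max, d_step
        Inclusive cutoff grid over which the contact graph is scanned (Å).
    schemes
        Atom-classification schemes whose scans are concatenated.
    centre_mode
        ``all_atoms`` (default) uses every heavy atom of the wild-type
        residue for the geometric centre; ``side_chain`` uses side-chain
        atoms only (falling back to all atoms for glycine).
    include_intra_residue
        Whether atom pairs inside the mutated residue itself are counted.
    """

    radius: float = 10.0
    d_min: float = 0.0
    d_max: float = 10.0
    d_step: float = 0.5
    schemes: Tuple[str, ...] = SCHEMES
    centre_mode: str = "all_atoms"
    include_intra_residue: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.d_min < self.d_max):
            raise ValueError("require 0 <= d_min < d_max")
        if self.d_step <= 0:
            raise ValueError("d_step must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not self.schemes:
            raise ValueError("at least one scheme required")
        for scheme in self.schemes:
            if scheme not in SCHEMES:
                raise ValueError(f"unknown scheme {scheme!r}")
        if self.centre_mode not in ("all_atoms", "side_chain"):
            raise ValueError(f"unknown centre_mode {self.centre_mode!r}")

    @property
    def cutoffs(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.d_step)) + 1
        grid = self.d_min + self.d_step * np.arange(n)
        return grid[grid <= self.d_max + 1e-9]


def pair_class_labels(scheme: str) -> List[str]:
    """Unordered atom-class pair labels of one scheme, in canonical order."""
    classes = _SCHEME_CLASSES[scheme]
    return [
        f"{a}|{b}" for a, b in itertools.combinations_with_replacement(classes, 2)
    ]


@dataclass
class ResidueEnvironment:
    """Atoms within radius ``r`` of the mutated residue's geometric centre."""

    centre: np.ndarray
    atoms: List[AtomRecord]
    source: Tuple[str, ResidueKey]
    radius: float


@dataclass
class CutoffScan:
    """Cumulative pair counts over the cutoff grid for one scheme.

    ``counts[k, c]`` is the number of unordered atom pairs at distance
    ``<= cutoffs[k]`` whose class pair is ``pair_labels[c]``; each column
    is non-decreasing down the grid.
    """

    scheme: str
    cutoffs: np.ndarray
    counts: np.ndarray
    pair_labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pair_labels:
            self.pair_labels = pair_class_labels(self.scheme)
        if self.counts.shape != (len(self.cutoffs), len(self.pair_labels)):
            raise ValueError("counts shape inconsistent with grid and pair labels")


@dataclass
class MutationSignature:
    """Flat feature vector plus parallel names and provenance."""

    features: np.ndarray
    feature_names: List[str]
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.feature_names):
            raise ValueError("features and names must be parallel")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.feature_names, self.features))


# ---------------------------------------------------------------------------
# Geometry


def geometric_centre(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Unweighted mean of heavy-atom coordinates."""
    if not atoms:
        raise ValueError("geometric centre of an empty atom list is undefined")
    return np.mean([a.coords for a in atoms], axis=0)


_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def residue_centre(
    structure: ProteinStructure, residue: ResidueKey, mode: str = "all_atoms"
) -> np.ndarray:
    atoms = structure.residue_atoms(residue)
    if mode == "side_chain":
        side = [a for a in atoms if a.atom_name not in _BACKBONE_NAMES]
        if side:
            atoms = side
    return geometric_centre(atoms)


def extract_residue_environment(
    structure: ProteinStructure,
    residue: ResidueKey,
    radius: float = 10.0,
    centre_mode: str = "all_atoms",
) -> ResidueEnvironment:
    """All labelled heavy atoms within ``radius`` of the residue centre.

    Membership is inclusive (distance ``<= radius``) and spans every chain
    and retained hetero atom; the mutated residue's own atoms always
    qualify because the centre lies inside the residue.
    """
    key = _normalize_key(residue)
    centre = residue_centre(structure, key, centre_mode)
    coords = structure.coords_array()
    dist = np.linalg.norm(coords - centre, axis=1)
    members = [a for a, d in zip(structure.atoms, dist) if d <= radius]
    return ResidueEnvironment(centre, members, (structure.structure_id, key), radius)


def pairwise_distances(env: ResidueEnvironment | Sequence[AtomRecord]) -> np.ndarray:
    """Symmetric Euclidean distance matrix over the environment atoms."""
    atoms = env.atoms if isinstance(env, ResidueEnvironment) else list(env)
    coords = np.array([a.coords for a in atoms], dtype=float)
    if len(coords) < 2:
        return np.zeros((len(coords), len(coords)))
    return squareform(pdist(coords))


# ---------------------------------------------------------------------------
# Cutoff scanning


def _scheme_labels_for_atoms(classes: Sequence[str], scheme: str) -> List[str]:
    if scheme == "one_class":
        return ["atom"] * len(classes)
    if scheme == "binary":
        return [BINARY_CLASS_OF[c] for c in classes]
    return list(classes)


def cutoff_scan(
    dmatrix: np.ndarray,
    classes: Sequence[str],
    params: SignatureParams,
    scheme: str = "pharmacophore",
) -> CutoffScan:
    """Cumulative distribution of pairwise distances, segmented by class pair.

    ``counts[k, c]`` counts unordered pairs ``i < j`` with
    ``dmatrix[i, j] <= cutoffs[k]`` and unordered class pair ``c``.
    """
    n = len(classes)
    if dmatrix.shape != (n, n):
        raise ValueError(
            f"distance matrix {dmatrix.shape} does not match {n} class labels"
        )
    cutoffs = params.cutoffs
    labels = pair_class_labels(scheme)
    label_index = {lab: i for i, lab in enumerate(labels)}
    atom_labels = _scheme_labels_for_atoms(classes, scheme)

    counts = np.zeros((len(cutoffs), len(labels)), dtype=int)
    if n >= 2:
        iu, ju = np.triu_indices(n, k=1)
        dists = dmatrix[iu, ju]
        pair_idx = np.array(
            [
                label_index["|".join(sorted((atom_labels[i], atom_labels[j]),
                                            key=_class_order))]
                for i, j in zip(iu, ju)
            ]
        )
        # first cutoff index at which each pair is counted (inclusive bound)
        step_idx = np.searchsorted(cutoffs, dists - 1e-9, side="left")
        inside = step_idx < len(cutoffs)
        np.add.at(counts, (step_idx[inside], pair_idx[inside]), 1)
        counts = np.cumsum(counts, axis=0)
    return CutoffScan(scheme=scheme, cutoffs=cutoffs, counts=counts, pair_labels=labels)


def _class_order(label: str) -> int:
    for scheme_classes in _SCHEME_CLASSES.values():
        if label in scheme_classes:
            return scheme_classes.index(label)
    raise KeyError(label)


# ---------------------------------------------------------------------------
# Pharmacophore change


def pharmacophore_change(
    wt_residue: str, mt_residue: str, table: Optional[PharmacophoreTable] = None
) -> np.ndarray:
    """Difference vector p_change = p(mutant) − p(wild type), 8 integers."""
    wt3 = _as_three_letter(wt_residue)
    mt3 = _as_three_letter(mt_residue)
    p_wt = residue_pharmacophore_vector(wt3, table)
    p_mt = residue_pharmacophore_vector(mt3, table)
    return p_mt - p_wt


def _as_three_letter(code: str) -> str:
    code = code.upper().strip()
    if len(code) == 1:
        if code not in ONE_TO_THREE:
            raise UnsupportedResidueError(f"unknown residue code {code!r}")
        return ONE_TO_THREE[code]
    if code not in THREE_TO_ONE:
        raise UnsupportedResidueError(f"unknown residue code {code!r}")
    return code


# ---------------------------------------------------------------------------
# Assembly


def assemble_signature(
    scans: Sequence[CutoffScan],
    p_change: np.ndarray,
    ph: Optional[float] = None,
    temperature: Optional[float] = None,
    rsa: float = 0.0,
    provenance: Optional[Dict[str, object]] = None,
) -> MutationSignature:
    """Concatenate scans and condition terms into the final flat vector.

    Layout: for each scan in order, columns flattened pair-class-major
    (pair class → cutoff); then the 8 p_change entries; then pH,
    temperature (°C) and RSA.  Missing pH/temperature are imputed with
    7.0 / 25 °C and flagged in the provenance.
    """
    if not scans:
        raise ValueError("at least one cutoff scan required")
    grid = scans[0].cutoffs
    for scan in scans[1:]:
        if len(scan.cutoffs) != len(grid) or not np.allclose(scan.cutoffs, grid):
            raise ValueError("all scans must share one cutoff grid")
    p_change = np.asarray(p_change)
    if p_change.shape != (len(PHARMACOPHORE_CLASSES),):
        raise ValueError("p_change must have 8 entries")

    provenance = dict(provenance or {})
    if ph is None:
        ph = DEFAULT_PH
        provenance["ph_imputed"] = True
    if temperature is None:
        temperature = DEFAULT_TEMPERATURE_C
        provenance["temperature_imputed"] = True

    parts: List[np.ndarray] = []
    names: List[str] = []
    for scan in scans:
        parts.append(scan.counts.T.reshape(-1).astype(float))
        names.extend(
            f"{scan.scheme}:{pair}:{cut:g}"
            for pair in scan.pair_labels
            for cut in scan.cutoffs
        )
    parts.append(p_change.astype(float))
    names.extend(f"p_change:{cls}" for cls in PHARMACOPHORE_CLASSES)
    parts.append(np.array([float(ph), float(temperature), float(rsa)]))
    names.extend(["ph", "temperature", "rsa"])
    return MutationSignature(np.concatenate(parts), names, provenance)


def compute_signature(
    structure: ProteinStructure,
    chain_id: str,
    position: int,
    wt: str,
    mt: str,
    params: Optional[SignatureParams] = None,
    table: Optional[PharmacophoreTable] = None,
    insertion_code: str = "",
    ph: Optional[float] = None,
    temperature: Optional[float] = None,
    rsa: Optional[float] = None,
) -> MutationSignature:
    """Full signature of one mutation on a labelled wild-type structure.

    ``structure`` must already carry pharmacophore labels (see
    :func:`csmpred.structure.assign_pharmacophores`).  ``wt``/``mt`` are
    one-letter residue codes; the stated wild type is validated against
    the structure.  ``temperature`` is in °C here (a display/condition
    value, not the Kelvin used for free-energy conversion).  ``rsa`` may
    be passed pre-computed to avoid repeated surface calculations.
    """
    params = params or SignatureParams()
    table = table or PharmacophoreTable.default()
    key = _normalize_key((chain_id, position, insertion_code))

    found = THREE_TO_ONE.get(structure.residue_name(key))
    if found != wt.upper():
        raise WildTypeMismatchError(
            f"{structure.structure_id} {chain_id}{position}{insertion_code}: "
            f"expected wild type {wt!r}, structure has "
            f"{structure.residue_name(key)} ({found})"
        )

    env = extract_residue_environment(structure, key, params.radius, params.centre_mode)
    for atom in env.atoms:
        if atom.pharmacophore is None:
            raise ValueError(
                "structure atoms are unlabelled; run assign_pharmacophores first"
            )
    dmat = pairwise_distances(env)
    classes = [a.pharmacophore for a in env.atoms]
    scans = [cutoff_scan(dmat, classes, params, scheme) for scheme in params.schemes]

    if not params.include_intra_residue:
        own = [a for a in env.atoms if a.residue_key == key]
        own_dmat = pairwise_distances(own)
        own_classes = [a.pharmacophore for a in own]
        for scan, scheme in zip(scans, params.schemes):
            scan.counts -= cutoff_scan(own_dmat, own_classes, params, scheme).counts

    p_change = pharmacophore_change(wt, mt, table)
    if rsa is None:
        rsa = compute_rsa(structure, key)
    provenance: Dict[str, object] = {
        "structure_id": structure.structure_id,
        "mutation": f"{wt.upper()}{position}{insertion_code}{mt.upper()}",
        "chain_id": chain_id,
        "params": params,
    }
    return assemble_signature(scans, p_change, ph, temperature, rsa, provenance)


def signature_length(params: SignatureParams) -> int:
    """Expected feature-vector length under a parameter set."""
    n_cut = len(params.cutoffs)
    n_pairs = sum(len(pair_class_labels(s)) for s in params.schemes)
    return n_cut * n_pairs + len(PHARMACOPHORE_CLASSES) + 3
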