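"""Deterministic synthetic structures and mutation datasets.

Real training corpora for mutation-effect prediction need hundreds of
curated crystal structures, so the test and demonstration surface of this
package runs on synthetic inputs instead: random residue "clouds" with
protein-like composition, an ideal poly-alanine helix, a two-chain
contact fixture with a controlled interface gap, and mutation tables
whose ΔΔG values are generated from a known linear effect model over the
signature features (plus optional curvature and Gaussian noise).  Every
generator is a pure function of its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import Dataset, MutationRecord
from .errors import FixtureSpecError
from .signature import SignatureParams, compute_signature
from .structure import (
    ONE_TO_THREE,
    STANDARD_RESIDUES,
    THREE_TO_ONE,
    PharmacophoreTable,
    ProteinStructure,
    assign_pharmacophores,
    compute_rsa_all,
    read_pdb,
)

# heavy-atom inventories used to synthesize residues (backbone + side chain)
_SIDE_CHAINS: Dict[str, Tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic structure.

    kind: ``point-cloud`` | ``ideal-helix`` | ``two-chain-contact``.
    For point clouds, ``n_residues`` residues with random identities are
    scattered at protein-like density (``spacing`` Å between residue
    centres on a jittered grid).  For helices, ``rise`` and ``radius``
    set the helical geometry.  For two-chain fixtures, ``gap`` is the
    exact minimum inter-chain heavy-atom distance (quantized to the
    0.001 Å precision of PDB coordinates).
    """

    kind: str = "point-cloud"
    n_residues: int = 12
    spacing: float = 5.5
    rise: float = 1.5
    radius: float = 2.3
    gap: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("point-cloud", "ideal-helix", "two-chain-contact"):
            raise FixtureSpecError(f"unknown fixture kind {self.kind!r}")
        if self.n_residues < 1:
            raise FixtureSpecError("n_residues must be >= 1")
        if self.spacing <= 0 or self.rise <= 0 or self.radius <= 0:
            raise FixtureSpecError("geometry parameters must be positive")
        if self.kind == "two-chain-contact" and self.gap <= 0:
            raise FixtureSpecError("gap must be positive")


def _q(x: float) -> float:
    """Quantize to the 3-decimal precision of PDB coordinate fields."""
    return round(float(x), 3)


def _atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    x: float, y: float, z: float,
) -> str:
    element = name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:5d} {name_field} {resname:<3s} {chain}{resnum:4d}    "
        f"{_q(x):8.3f}{_q(y):8.3f}{_q(z):8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _cloud_residues(
    rng: np.random.Generator, n_residues: int, spacing: float, origin: np.ndarray
) -> List[Tuple[str, np.ndarray, List[Tuple[str, np.ndarray]]]]:
    """Residues on a jittered cubic grid; atoms clustered around centres."""
    side = max(1, math.ceil(n_residues ** (1 / 3)))
    while side**3 < n_residues:
        side += 1
    cells = [
        np.array([i, j, k], dtype=float)
        for i in range(side)
        for j in range(side)
        for k in range(side)
    ][:n_residues]
    residues = []
    for cell in cells:
        resname = str(rng.choice(STANDARD_RESIDUES))
        centre = origin + cell * spacing + rng.uniform(-0.8, 0.8, size=3)
        atoms = []
        for atom_name in ("N", "CA", "C", "O") + _SIDE_CHAINS[resname]:
            coords = centre + rng.normal(scale=1.3, size=3)
            atoms.append((atom_name, coords))
        residues.append((resname, centre, atoms))
    return residues


def _cloud_lines(
    residues, chain: str, start_serial: int, start_resnum: int
) -> Tuple[List[str], int, int]:
    lines = []
    serial, resnum = start_serial, start_resnum
    for resname, _centre, atoms in residues:
        for atom_name, coords in atoms:
            lines.append(_atom_line(serial, atom_name, resname, chain, resnum, *coords))
            serial += 1
        resnum += 1
    return lines, serial, resnum


# per-atom helical parameters: (radius offset, phase offset deg, z offset)
_HELIX_ATOMS = {
    "N": (-0.72, -27.0, -0.85),
    "CA": (0.0, 0.0, 0.0),
    "C": (-0.28, 26.0, 0.60),
    "O": (-0.25, 32.0, 1.75),
    "CB": (1.02, -4.0, -0.35),
}


def generate_structure(spec: FixtureSpec) -> str:
    """Synthesize a PDB-format text for the given fixture spec.

    The output is syntactically valid PDB and round-trips through
    :func:`csmpred.structure.read_pdb`; identical specs give identical
    bytes.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "point-cloud":
        residues = _cloud_residues(rng, spec.n_residues, spec.spacing, np.zeros(3))
        lines, _, _ = _cloud_lines(residues, "A", 1, 1)
    elif spec.kind == "ideal-helix":
        lines = []
        serial = 1
        for i in range(spec.n_residues):
            theta = math.radians(100.0 * i)
            z = spec.rise * i
            for atom_name, (dr, dphase, dz) in _HELIX_ATOMS.items():
                r = spec.radius + dr
                phi = theta + math.radians(dphase)
                lines.append(
                    _atom_line(
                        serial, atom_name, "ALA", "A", i + 1,
                        r * math.cos(phi), r * math.sin(phi), z + dz,
                    )
                )
                serial += 1
    else:  # two-chain-contact
        gap = _q(spec.gap)
        n_a = max(1, spec.n_residues // 2)
        n_b = spec.n_residues - n_a
        side = max(1, math.ceil(max(n_a, n_b, 1) ** (1 / 3)))
        extent_a = side * spec.spacing + 8.0
        margin = gap + 2.0
        res_a = _cloud_residues(rng, n_a, spec.spacing, np.zeros(3))
        contact_x_a = _q(extent_a + margin)
        # contact pair: two CA atoms with identical y/z, exactly `gap` apart in x
        res_a.append(("GLY", None, [
            ("N", np.array([contact_x_a - 1.2, 0.8, 0.0])),
            ("CA", np.array([contact_x_a, 0.0, 0.0])),
            ("C", np.array([contact_x_a - 1.0, -1.1, 0.6])),
            ("O", np.array([contact_x_a - 1.6, -1.9, 0.2])),
        ]))
        contact_x_b = _q(contact_x_a + gap)
        res_b: List = [("GLY", None, [
            ("N", np.array([contact_x_b + 1.2, 0.8, 0.0])),
            ("CA", np.array([contact_x_b, 0.0, 0.0])),
            ("C", np.array([contact_x_b + 1.0, -1.1, 0.6])),
            ("O", np.array([contact_x_b + 1.6, -1.9, 0.2])),
        ])]
        if n_b:
            origin_b = np.array([contact_x_b + margin, 0.0, 0.0])
            res_b.extend(_cloud_residues(rng, n_b, spec.spacing, origin_b))
        lines_a, serial, _ = _cloud_lines(res_a, "A", 1, 1)
        lines_b, _, _ = _cloud_lines(res_b, "B", serial, 1)
        lines = lines_a + ["TER"] + lines_b
    return "\n".join(lines + ["END"]) + "\n"


def write_structure(spec: FixtureSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(generate_structure(spec))
    return path


# ---------------------------------------------------------------------------
# Synthetic mutation datasets


@dataclass
class SyntheticEffectModel:
    """Known generative model: ΔΔG = intercept + w·z(features) + curvature + noise.

    ``weights`` maps signature feature names to coefficients applied on
    z-scored features.  ``noise_sd`` is absolute (kcal/mol) unless
    ``noise_sd_relative`` is set, in which case the noise SD is that
    multiple of the noise-free signal SD.  ``quadratic`` adds a mild
    squared term on the first weighted feature to exercise nonlinear
    learners (clearly synthetic; no physical meaning).
    """

    weights: Optional[Dict[str, float]] = None
    intercept: float = -1.0
    noise_sd: float = 0.5
    noise_sd_relative: Optional[float] = None
    quadratic: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.weights is not None:
            for name, w in self.weights.items():
                if not np.isfinite(w):
                    raise ValueError(f"non-finite weight for {name!r}")


def default_effect_weights(rng: np.random.Generator) -> Dict[str, float]:
    """A named, low-dimensional feature subset with random coefficients.

    Uses overall packing counts at short/medium/long range, two
    polar/hydrophobic contrasts, the pharmacophore-change entries and
    RSA — the feature groups the signature is built around.
    """
    names = [
        "one_class:atom|atom:4",
        "one_class:atom|atom:7",
        "one_class:atom|atom:10",
        "binary:hydrophobic|hydrophobic:8",
        "binary:hydrophobic|polar:8",
        "p_change:hydrophobic",
        "p_change:positive",
        "p_change:negative",
        "p_change:hydrogen_acceptor",
        "p_change:hydrogen_donor",
        "p_change:aromatic",
        "p_change:sulphur",
        "p_change:neutral",
        "rsa",
    ]
    return {name: float(rng.normal(scale=1.0)) for name in names}


@dataclass
class SyntheticTruth:
    """Everything needed to audit a generated dataset."""

    signal: np.ndarray  # noise-free ΔΔG per record
    noise_sd: float
    weights: Dict[str, float]
    intercept: float
    feature_means: Dict[str, float]
    feature_sds: Dict[str, float]


def generate_mutation_dataset(
    structures: Sequence[ProteinStructure],
    effect: Optional[SyntheticEffectModel] = None,
    n: int = 200,
    seed: int = 0,
    params: Optional[SignatureParams] = None,
    table: Optional[PharmacophoreTable] = None,
) -> Tuple[Dataset, pd.DataFrame, SyntheticTruth]:
    """Sample mutations, compute signatures, and plant a known ΔΔG model.

    Structures must already carry pharmacophore labels.  Returns the
    dataset (``native`` dialect fields), the signature matrix as a
    DataFrame (one row per record, feature-name columns) and the
    generative truth.
    """
    if n < 1:
        raise FixtureSpecError("n must be >= 1")
    params = params or SignatureParams()
    table = table or PharmacophoreTable.default()
    effect = effect or SyntheticEffectModel(noise_sd_relative=0.5)
    rng = np.random.default_rng(seed)

    sites = []
    for structure in structures:
        rsa_all = compute_rsa_all(structure)
        for key in structure.residues():
            resname = structure.residue_name(key)
            if resname in THREE_TO_ONE and key in rsa_all:
                sites.append((structure, key, THREE_TO_ONE[resname], rsa_all[key]))
    if not sites:
        raise FixtureSpecError("no mutable standard residues in the fixtures")

    aa_codes = sorted(ONE_TO_THREE)
    records: List[MutationRecord] = []
    rows: List[Dict[str, float]] = []
    for _ in range(n):
        structure, key, wt, rsa = sites[int(rng.integers(len(sites)))]
        mt = str(rng.choice([a for a in aa_codes if a != wt]))
        chain, pos, icode = key
        ph = float(np.round(rng.uniform(5.0, 9.0), 2))
        temp_c = float(np.round(rng.uniform(15.0, 37.0), 1))
        sig = compute_signature(
            structure, chain, pos, wt, mt,
            params=params, table=table, insertion_code=icode,
            ph=ph, temperature=temp_c, rsa=rsa,
        )
        records.append(
            MutationRecord(
                structure_id=structure.structure_id,
                chain_id=chain,
                code=f"{wt}{pos}{mt}",
                wt=wt,
                position=pos,
                insertion_code=icode,
                mt=mt,
                ph=ph,
                temperature=temp_c + 273.15,
                source="synthetic",
            )
        )
        rows.append(sig.as_dict())

    X = pd.DataFrame(rows)
    weights = dict(effect.weights or default_effect_weights(rng))
    missing = [name for name in weights if name not in X.columns]
    if missing:
        raise FixtureSpecError(f"effect model names unknown features: {missing}")

    means = {name: float(X[name].mean()) for name in weights}
    sds = {name: float(X[name].std(ddof=0)) for name in weights}
    signal = np.full(n, effect.intercept, dtype=float)
    first = next(iter(weights))
    for name, w in weights.items():
        sd = sds[name]
        z = (X[name].to_numpy() - means[name]) / sd if sd > 0 else 0.0
        signal = signal + w * z
        if effect.quadratic and name == first and sd > 0:
            signal = signal + effect.quadratic * z**2

    if effect.noise_sd_relative is not None:
        noise_sd = effect.noise_sd_relative * float(np.std(signal))
    else:
        noise_sd = effect.noise_sd
    noise = rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for rec, value in zip(records, signal + noise):
        rec.ddg = float(value)

    truth = SyntheticTruth(signal, noise_sd, weights, effect.intercept, means, sds)
    return Dataset(records, name="synthetic", task="stability"), X, truth


def labelled_structures(
    specs: Sequence[FixtureSpec], workdir: Optional[Path] = None
) -> List[ProteinStructure]:
    """Generate fixture PDBs, parse them back and label them (dog-fooding)."""
    import tempfile

    table = PharmacophoreTable.default()
    structures = []
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        for i, spec in enumerate(specs):
            path = base / f"fixture_{i}_{spec.kind}.pdb"
            write_structure(spec, path)
            structures.append(assign_pharmacophores(read_pdb(path), table))
    return structures


# ---------------------------------------------------------------------------
# SKEMPI-style filter fixture


def skempi_like_fixture(
    directory: str | Path, seed: int = 20
) -> Tuple[Path, Dict[str, object]]:
    """Write a small SKEMPI-style table with planted defects plus a manifest.

    The table has 20 rows: 13 valid single-point records with affinities,
    2 multi-point rows, 1 malformed mutation code, 1 silent mutation,
    1 row missing the structure id, 1 row missing the mutant affinity and
    1 row with a non-numeric affinity (skipped at load).  The manifest
    documents the composition so filter tests can assert exact counts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    aas = sorted(ONE_TO_THREE)
    pdb_ids = ["1AAA", "1BBB", "2CCC", "3DDD", "4EEE"]

    def valid_row(i: int) -> Dict[str, str]:
        wt, mt = rng.choice(aas, size=2, replace=False)
        kd_wt = 10.0 ** rng.uniform(-10, -5)
        return {
            "pdb_id": pdb_ids[i % len(pdb_ids)],
            "chain": "A",
            "mutation": f"{wt}{int(rng.integers(2, 200))}{mt}",
            "affinity_wt": f"{kd_wt:.3e}",
            "affinity_mut": f"{kd_wt * 10 ** rng.uniform(-2, 2):.3e}",
            "ph": f"{rng.uniform(6, 8):.1f}",
            "temperature": "298",
        }

    rows = [valid_row(i) for i in range(13)]
    rows.append({**valid_row(13), "mutation": "A10G,L30P"})
    rows.append({**valid_row(14), "mutation": "G5A;K8R"})
    rows.append({**valid_row(15), "mutation": "Z9Q"})
    rows.append({**valid_row(16), "mutation": "A5A"})
    rows.append({**valid_row(17), "pdb_id": ""})
    rows.append({**valid_row(18), "affinity_mut": ""})
    rows.append({**valid_row(19), "affinity_wt": "n/a"})

    path = directory / "skempi_like.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    manifest: Dict[str, object] = {
        "n_rows": 20,
        "load_skipped": 1,
        "survivors": 13,
        "exclusions": {
            "multi_point": 2,
            "malformed_code": 1,
            "silent": 1,
            "no_structure": 1,
            "missing_measurement": 1,
        },
    }
    (directory / "skempi_like.manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )
    return path, manifest
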