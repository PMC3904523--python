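"""Mutation/thermodynamics tables: parsing, unit conversion and filtering.

Supports three delimited-text dialects modelled on the common exports of
the ProTherm (folding stability), SKEMPI (protein–protein affinity) and
ProNIT (protein–nucleic-acid affinity) databases, plus the package's own
``native`` round-trip format.  Dissociation constants are converted to
Gibbs free energies with ΔG = R·T·ln K_D.

Sign convention (applied uniformly): **negative ΔΔG = destabilizing /
affinity-reducing**.  Loaders accept a ``flip_sign`` flag for tables using
the opposite convention.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    DatasetError,
    MutationParseError,
    SilentMutationError,
)
from .structure import ONE_TO_THREE

logger = logging.getLogger(__name__)

#: ideal gas constant in kcal·mol⁻¹·K⁻¹
R_GAS = 1.9872e-3

#: standard temperature used when a binding record lacks one (Kelvin)
DEFAULT_TEMPERATURE_K = 298.0

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z]?)([A-Za-z])$")


def parse_mutation_code(code: str) -> Tuple[str, int, str]:
    """Parse a compact mutation code like ``"R282W"`` into (wt, position, mt).

    One-letter codes are validated against the 20 standard residues;
    identical wild-type and mutant codes are rejected as silent mutations.
    """
    m = _MUTATION_RE.match(code.strip())
    if not m:
        raise MutationParseError(f"malformed mutation code {code!r}")
    wt, pos, icode, mt = m.group(1).upper(), int(m.group(2)), m.group(3), m.group(4).upper()
    if icode:
        # codes like "R282aW" carry an insertion code; keep parse strict here
        raise MutationParseError(f"unsupported insertion code in {code!r}")
    for aa in (wt, mt):
        if aa not in ONE_TO_THREE:
            raise MutationParseError(f"{code!r}: {aa!r} is not a standard residue")
    if wt == mt:
        raise SilentMutationError(f"{code!r} is a silent mutation")
    return wt, pos, mt


@dataclass
class MutationRecord:
    """One experimental data point.

    ``code`` keeps the raw mutation string from the source table (possibly
    multi-point, e.g. ``"A12G,L30P"``); the parsed single-substitution
    fields are filled only when the code is a valid single point mutation.
    ``temperature`` is stored in Kelvin.
    """

    structure_id: str
    chain_id: str
    code: str
    wt: Optional[str] = None
    position: Optional[int] = None
    insertion_code: str = ""
    mt: Optional[str] = None
    ddg: Optional[float] = None
    kd_wt: Optional[float] = None
    kd_mt: Optional[float] = None
    ph: Optional[float] = None
    temperature: Optional[float] = None
    source: str = ""

    @property
    def is_single_point(self) -> bool:
        return self.wt is not None and self.mt is not None

    @property
    def temperature_celsius(self) -> Optional[float]:
        if self.temperature is None:
            return None
        return self.temperature - 273.15


@dataclass
class Dataset:
    records: List[MutationRecord]
    name: str = "dataset"
    task: str = "stability"  # stability | protein-protein | protein-DNA


@dataclass
class Exclusion:
    record: MutationRecord
    reason: str


# ---------------------------------------------------------------------------
# Free-energy conversion


def delta_g_from_kd(kd: float, temperature: float) -> float:
    """Gibbs free energy of binding, ΔG = R·T·ln K_D, in kcal/mol.

    ``kd`` in molar, ``temperature`` in Kelvin.  Tighter binding (smaller
    K_D) gives a more negative ΔG.
    """
    if not (kd > 0):
        raise ValueError(f"kd must be positive, got {kd}")
    if not (temperature > 0):
        raise ValueError(f"temperature must be positive Kelvin, got {temperature}")
    return R_GAS * temperature * math.log(kd)


def ddg_binding(kd_wt: float, kd_mt: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Affinity change ΔΔG = ΔG(mutant) − ΔG(wild type) at one temperature."""
    return delta_g_from_kd(kd_mt, temperature) - delta_g_from_kd(kd_wt, temperature)


def record_ddg(record: MutationRecord) -> Optional[float]:
    """The record's ΔΔG: direct if present, else derived from affinities."""
    if record.ddg is not None:
        return record.ddg
    if record.kd_wt is not None and record.kd_mt is not None:
        t = record.temperature or DEFAULT_TEMPERATURE_K
        return ddg_binding(record.kd_wt, record.kd_mt, t)
    return None


@dataclass(frozen=True)
class StabilityCall:
    label: str  # "destabilizing" | "stabilizing"
    boundary: bool = False


def stability_class(ddg: float) -> StabilityCall:
    """Direction-of-change label under the documented sign convention.

    Negative ΔΔG = destabilizing; exactly zero is assigned to the
    destabilizing class with a boundary flag.
    """
    if not np.isfinite(ddg):
        raise ValueError(f"ddG must be finite, got {ddg}")
    if ddg < 0:
        return StabilityCall("destabilizing")
    if ddg == 0:
        return StabilityCall("destabilizing", boundary=True)
    return StabilityCall("stabilizing")


# ---------------------------------------------------------------------------
# Filtering


def filter_single_point(
    records: Sequence[MutationRecord],
) -> Tuple[List[MutationRecord], List[Exclusion]]:
    """Keep usable single-point records; log every exclusion with a reason.

    A record survives when it is a parsed single substitution, names a
    structure, and carries either a direct ΔΔG or both wild-type and
    mutant affinities.  Reasons: ``multi_point``, ``malformed_code``,
    ``silent``, ``no_structure``, ``missing_measurement``.
    """
    kept: List[MutationRecord] = []
    excluded: List[Exclusion] = []
    for rec in records:
        reason = _exclusion_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            excluded.append(Exclusion(rec, reason))
    return kept, excluded


def _exclusion_reason(rec: MutationRecord) -> Optional[str]:
    if not rec.is_single_point:
        code = rec.code.strip()
        if "," in code or ";" in code or len(code.split()) > 1:
            return "multi_point"
        try:
            parse_mutation_code(code)
        except SilentMutationError:
            return "silent"
        except MutationParseError:
            return "malformed_code"
        return "malformed_code"
    if not rec.structure_id or not rec.structure_id.strip():
        return "no_structure"
    if rec.ddg is None and not (rec.kd_wt is not None and rec.kd_mt is not None):
        return "missing_measurement"
    return None


def collapse_duplicates(dataset: Dataset) -> Dataset:
    """Collapse repeated measurements of one mutation to their median ΔΔG.

    Grouping key: (structure, chain, code).  Affinity pairs are first
    converted to ΔΔG.  Conditions keep the group medians.
    """
    groups: Dict[Tuple[str, str, str], List[MutationRecord]] = {}
    for rec in dataset.records:
        groups.setdefault((rec.structure_id, rec.chain_id, rec.code), []).append(rec)
    collapsed: List[MutationRecord] = []
    for recs in groups.values():
        first = recs[0]
        ddgs = [v for v in (record_ddg(r) for r in recs) if v is not None]
        phs = [r.ph for r in recs if r.ph is not None]
        temps = [r.temperature for r in recs if r.temperature is not None]
        collapsed.append(
            replace(
                first,
                ddg=float(np.median(ddgs)) if ddgs else None,
                kd_wt=None,
                kd_mt=None,
                ph=float(np.median(phs)) if phs else None,
                temperature=float(np.median(temps)) if temps else None,
            )
        )
    return Dataset(collapsed, name=dataset.name + "-collapsed", task=dataset.task)


# ---------------------------------------------------------------------------
# Loading

#: column maps per dialect; edit to track upstream export changes
DIALECTS: Dict[str, Dict[str, object]] = {
    "protherm": {
        "pdb": "pdb_id",
        "chain": "chain",
        "mutation": "mutation",
        "ddg": "ddg",
        "ph": "ph",
        "temperature": "temperature",
        "temperature_unit": "C",
    },
    "skempi": {
        "pdb": "pdb_id",
        "chain": "chain",
        "mutation": "mutation",
        "kd_wt": "affinity_wt",
        "kd_mt": "affinity_mut",
        "ph": "ph",
        "temperature": "temperature",
        "temperature_unit": "K",
    },
    "pronit": {
        "pdb": "pdb_id",
        "chain": "chain",
        "mutation": "mutation",
        "kd_wt": "kd_wild",
        "kd_mt": "kd_mutant",
        "ddg": "ddg",
        "ph": "ph",
        "temperature": "temperature",
        "temperature_unit": "C",
    },
    "native": {
        "pdb": "structure_id",
        "chain": "chain_id",
        "mutation": "code",
        "ddg": "ddg",
        "kd_wt": "kd_wt",
        "kd_mt": "kd_mt",
        "ph": "ph",
        "temperature": "temperature",
        "temperature_unit": "K",
    },
}

_DIALECT_TASK = {
    "protherm": "stability",
    "skempi": "protein-protein",
    "pronit": "protein-DNA",
    "native": "stability",
}


def load_dataset(
    path: str | Path,
    dialect: str = "native",
    name: Optional[str] = None,
    flip_sign: bool = False,
) -> Dataset:
    """Load a delimited mutation table into a :class:`Dataset`.

    Temperatures are normalized to Kelvin using the dialect's unit (a
    per-value ``C``/``K`` suffix overrides it).  Rows whose numeric fields
    cannot be parsed are logged and skipped; rows with *empty* optional
    fields are kept with ``None`` values and left to
    :func:`filter_single_point`.
    """
    if dialect not in DIALECTS:
        raise DatasetError(
            f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}"
        )
    cols = DIALECTS[dialect]
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    records: List[MutationRecord] = []
    for i, row in frame.iterrows():
        try:
            records.append(_row_to_record(row, cols, dialect, flip_sign))
        except (ValueError, KeyError) as exc:
            logger.warning("%s row %d skipped: %s", path.name, i, exc)
    if not records:
        raise DatasetError(f"{path}: no parsable rows")
    return Dataset(
        records,
        name=name or path.stem,
        task=_DIALECT_TASK[dialect],
    )


def _get(row: pd.Series, cols: Dict[str, object], key: str) -> str:
    col = cols.get(key)
    if col is None or col not in row:
        return ""
    return str(row[col]).strip()


def _parse_float(text: str, what: str) -> Optional[float]:
    if text == "" or text.lower() in ("na", "nan", "none", "-"):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"unparsable {what} value {text!r}") from exc


def _parse_temperature(text: str, default_unit: str) -> Optional[float]:
    if not text:
        return None
    unit = default_unit
    if text[-1].upper() in ("C", "K"):
        unit = text[-1].upper()
        text = text[:-1].strip()
    value = _parse_float(text, "temperature")
    if value is None:
        return None
    return value + 273.15 if unit == "C" else value


def _row_to_record(
    row: pd.Series, cols: Dict[str, object], dialect: str, flip_sign: bool
) -> MutationRecord:
    code = _get(row, cols, "mutation")
    if not code:
        raise ValueError("empty mutation code")
    wt = pos = mt = None
    try:
        wt, pos, mt = parse_mutation_code(code)
    except MutationParseError:
        pass  # kept raw; filter_single_point assigns the exclusion reason
    ddg = _parse_float(_get(row, cols, "ddg"), "ddg")
    if flip_sign and ddg is not None:
        ddg = -ddg
    kd_wt = _parse_float(_get(row, cols, "kd_wt"), "kd_wt")
    kd_mt = _parse_float(_get(row, cols, "kd_mt"), "kd_mt")
    for kd, what in ((kd_wt, "kd_wt"), (kd_mt, "kd_mt")):
        if kd is not None and kd <= 0:
            raise ValueError(f"non-positive {what} {kd!r}")
    return MutationRecord(
        structure_id=_get(row, cols, "pdb"),
        chain_id=_get(row, cols, "chain") or "A",
        code=code,
        wt=wt,
        position=pos,
        mt=mt,
        ddg=ddg,
        kd_wt=kd_wt,
        kd_mt=kd_mt,
        ph=_parse_float(_get(row, cols, "ph"), "ph"),
        temperature=_parse_temperature(
            _get(row, cols, "temperature"), str(cols.get("temperature_unit", "K"))
        ),
        source=dialect,
    )


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the ``native`` dialect (round-trips exactly)."""
    rows = []
    for rec in dataset.records:
        rows.append(
            {
                "structure_id": rec.structure_id,
                "chain_id": rec.chain_id,
                "code": rec.code,
                "ddg": "" if rec.ddg is None else repr(rec.ddg),
                "kd_wt": "" if rec.kd_wt is None else repr(rec.kd_wt),
                "kd_mt": "" if rec.kd_mt is None else repr(rec.kd_mt),
                "ph": "" if rec.ph is None else repr(rec.ph),
                "temperature": "" if rec.temperature is None else repr(rec.temperature),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
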