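"""Compound-activity data model and curation.

Raw input is a table of per-compound potency measurements (Ki in nM, or
pKi directly).  Curation standardizes structures, filters measurement
types, aggregates replicates and assembles one activity class per target.
An activity class — all curated compounds with a pKi for one target — is
the unit on which every downstream cliff analysis operates.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import SmilesError, standardize


class MeasurementType(str, enum.Enum):
    KI = "Ki"
    KD = "Kd"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: "MeasurementType | str") -> "MeasurementType":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            return cls.OTHER


def to_pki(value_nM: float) -> float:
    """Convert a potency in nM to the pKi scale: -log10 of the molar value.

    10 nM -> 8.0, 1 nM -> 9.0.  A twofold potency change is ~0.3 pKi units;
    a 100-fold change is 2 units.
    """
    if not (value_nM > 0) or not math.isfinite(value_nM):
        raise ValueError(f"potency must be a positive finite nM value, got {value_nM!r}")
    return 9.0 - math.log10(value_nM)


@dataclass(frozen=True)
class PotencyMeasurement:
    """A single potency determination of one compound against one target.

    Exactly one of ``value_nM`` / ``pki`` is the authoritative input; the
    other is derived.
    """

    target_id: str
    measurement_type: MeasurementType = MeasurementType.KI
    value_nM: float | None = None
    pki: float | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        if (self.value_nM is None) == (self.pki is None):
            raise ValueError("exactly one of value_nM / pki must be given")
        if self.value_nM is not None and not self.value_nM > 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")
        if self.pki is not None and not math.isfinite(self.pki):
            raise ValueError(f"pki must be finite, got {self.pki}")
        object.__setattr__(
            self, "measurement_type", MeasurementType.coerce(self.measurement_type)
        )

    @property
    def pki_value(self) -> float:
        return self.pki if self.pki is not None else to_pki(self.value_nM)


@dataclass
class CompoundRecord:
    compound_id: str
    smiles: str
    measurements: list[PotencyMeasurement] = field(default_factory=list)


@dataclass
class ActivityClass:
    """All curated compounds with an aggregated pKi for one target."""

    target_id: str
    members: list[tuple[str, float]]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def compound_ids(self) -> list[str]:
        return [cid for cid, _ in self.members]

    @property
    def pkis(self) -> list[float]:
        return [p for _, p in self.members]

    def pki_of(self, compound_id: str) -> float:
        for cid, p in self.members:
            if cid == compound_id:
                return p
        raise KeyError(compound_id)


@dataclass
class CurationConfig:
    allowed_types: frozenset[MeasurementType] = frozenset({MeasurementType.KI})
    spread_limit: float = 1.0  # max pKi range across replicates
    min_class_size: int = 100
    aggregate: str = "mean"  # arithmetic mean of pKi == geometric mean of Ki

    def __post_init__(self) -> None:
        self.allowed_types = frozenset(
            MeasurementType.coerce(t) for t in self.allowed_types
        )
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"unknown aggregation rule {self.aggregate!r}")


@dataclass
class CurationResult:
    classes: list[ActivityClass]
    structures: dict[str, str]  # compound_id -> standardized canonical SMILES
    log: list[dict]

    def class_for(self, target_id: str) -> ActivityClass:
        for cls in self.classes:
            if cls.target_id == target_id:
                return cls
        raise KeyError(target_id)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)


def _aggregate(values: Sequence[float], rule: str) -> float:
    if rule == "median":
        s = sorted(values)
        n = len(s)
        return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
    return sum(values) / len(values)


def curate(
    records: Iterable[CompoundRecord], config: CurationConfig | None = None
) -> CurationResult:
    """Curate raw records into per-target activity classes.

    Steps, each logged with a reason code so that every input record is
    accounted for (retained + dropped = total):

    1. parse + standardize SMILES (unparseable -> ``smiles_error``);
    2. keep measurements of the allowed types (``Ki`` by default);
    3. per (compound, target): drop if replicate pKi values spread wider
       than ``spread_limit`` (``replicate_spread``), else aggregate;
    4. keep targets with at least ``min_class_size`` compounds
       (``class_too_small``).
    """
    config = config or CurationConfig()
    log: list[dict] = []
    structures: dict[str, str] = {}
    # (target, cid) -> list of replicate pKi values
    by_target: dict[str, dict[str, list[float]]] = {}

    seen_smiles: dict[str, str] = {}
    for rec in records:
        if rec.compound_id in structures or rec.compound_id in seen_smiles:
            log.append(
                {"compound_id": rec.compound_id, "reason": "duplicate_id", "detail": ""}
            )
            continue
        try:
            smi = standardize(rec.smiles)
        except SmilesError as exc:
            log.append(
                {"compound_id": rec.compound_id, "reason": "smiles_error", "detail": str(exc)}
            )
            continue
        seen_smiles[rec.compound_id] = smi
        kept_any = False
        for m in rec.measurements:
            if m.measurement_type not in config.allowed_types:
                log.append(
                    {
                        "compound_id": rec.compound_id,
                        "reason": "measurement_type",
                        "detail": m.measurement_type.value,
                    }
                )
                continue
            by_target.setdefault(m.target_id, {}).setdefault(rec.compound_id, []).append(
                m.pki_value
            )
            kept_any = True
        if kept_any:
            structures[rec.compound_id] = smi
        else:
            log.append(
                {"compound_id": rec.compound_id, "reason": "no_usable_measurement", "detail": ""}
            )

    classes: list[ActivityClass] = []
    referenced: set[str] = set()
    for target_id in sorted(by_target):
        members: list[tuple[str, float]] = []
        for cid in sorted(by_target[target_id]):
            values = by_target[target_id][cid]
            if max(values) - min(values) > config.spread_limit:
                log.append(
                    {
                        "compound_id": cid,
                        "target_id": target_id,
                        "reason": "replicate_spread",
                        "detail": f"range {max(values) - min(values):.3g}",
                    }
                )
                continue
            members.append((cid, _aggregate(values, config.aggregate)))
        if len(members) < config.min_class_size:
            log.append(
                {
                    "target_id": target_id,
                    "reason": "class_too_small",
                    "detail": f"{len(members)} < {config.min_class_size}",
                }
            )
            continue
        classes.append(ActivityClass(target_id=target_id, members=members))
        referenced.update(cid for cid, _ in members)

    structures = {cid: smi for cid, smi in structures.items() if cid in referenced}
    return CurationResult(classes=classes, structures=structures, log=log)


# ---------------------------------------------------------------------------
# I/O


def read_activity_table(path: str | Path) -> list[CompoundRecord]:
    """Read the standard delimited activity table (CSV, or TSV by suffix).

    Required columns: ``compound_id``, ``smiles``, ``target_id`` and either
    ``pki`` or ``standard_value_nM`` + ``standard_type``.  A row carrying
    both a pKi and an nM value is rejected: units may not be mixed within
    one measurement row.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"empty activity table: {path}")
    required = {"compound_id", "smiles", "target_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    has_pki = "pki" in df.columns
    has_nm = "standard_value_nM" in df.columns
    if not has_pki and not has_nm:
        raise ValueError("need a 'pki' or a 'standard_value_nM' column")

    records: dict[str, CompoundRecord] = {}
    for row in df.itertuples(index=False):
        cid = str(row.compound_id)
        pki = getattr(row, "pki", None) if has_pki else None
        nm = getattr(row, "standard_value_nM", None) if has_nm else None
        pki = None if pki is None or pd.isna(pki) else float(pki)
        nm = None if nm is None or pd.isna(nm) else float(nm)
        if pki is not None and nm is not None:
            raise ValueError(
                f"row for {cid!r} mixes pki and standard_value_nM; use one unit per row"
            )
        mtype = getattr(row, "standard_type", "Ki")
        if pd.isna(mtype):
            mtype = "Ki"
        m = PotencyMeasurement(
            target_id=str(row.target_id),
            measurement_type=MeasurementType.coerce(str(mtype)),
            value_nM=nm,
            pki=pki,
            source_tag=str(getattr(row, "source_tag", "")),
        )
        rec = records.setdefault(cid, CompoundRecord(compound_id=cid, smiles=str(row.smiles)))
        rec.measurements.append(m)
    return list(records.values())


def read_structures_sdf(path: str | Path, id_property: str = "compound_id") -> dict[str, str]:
    """Read structures from an SDF keyed by an id property -> canonical SMILES."""
    from rdkit import Chem

    out: dict[str, str] = {}
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None or not mol.HasProp(id_property):
            continue
        out[mol.GetProp(id_property)] = standardize(Chem.MolToSmiles(mol))
    return out


def write_curated(result: CurationResult, table_path: str | Path, log_path: str | Path | None = None) -> None:
    rows = [
        {
            "target_id": cls.target_id,
            "compound_id": cid,
            "smiles": result.structures[cid],
            "pki": round(pki, 6),
        }
        for cls in result.classes
        for cid, pki in cls.members
    ]
    pd.DataFrame(rows, columns=["target_id", "compound_id", "smiles", "pki"]).to_csv(
        table_path, index=False
    )
    if log_path is not None:
        Path(log_path).write_text(json.dumps(result.log, indent=1))
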