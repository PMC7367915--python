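"""Fingerprints and Tanimoto-based qualifying-pair decisions.

Two 2D fingerprints of different design are supported: MACCS structural
keys (166 defined keys) and the extended-connectivity fingerprint with
bond diameter 4 (ECFP4, Morgan radius 2).  The ECFP4 variant is stored as
a sparse feature set by default — folding to a fixed width changes
Tanimoto values, so it is only done on request.  A compound pair whose
Tanimoto coefficient strictly exceeds the fingerprint-specific threshold
(0.55 for ECFP4, 0.85 for MACCS) is a *qualifying pair*: it satisfies the
similarity criterion for cliff formation regardless of potency.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chem import mol_from_smiles


class FingerprintKind(str, enum.Enum):
    MACCS = "maccs"  # 166-bit structural keys
    ECFP4 = "ecfp4"  # circular, bond diameter 4 (Morgan radius 2), sparse


#: Tc above which a pair qualifies (strict >; "exceeding" is read literally).
DEFAULT_TC_THRESHOLDS: dict[FingerprintKind, float] = {
    FingerprintKind.MACCS: 0.85,
    FingerprintKind.ECFP4: 0.55,
}

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2)
_MORGAN_FOLDED = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass(frozen=True)
class Fingerprint:
    kind: FingerprintKind
    on_bits: frozenset[int]

    def __len__(self) -> int:
        return len(self.on_bits)


@dataclass(frozen=True)
class SimilarityResult:
    tc: float
    kind: FingerprintKind
    qualifies: bool


def compute_fingerprint(
    smiles: str, kind: FingerprintKind | str, folded: bool = False
) -> Fingerprint:
    kind = FingerprintKind(kind)
    mol = mol_from_smiles(smiles)
    if kind is FingerprintKind.MACCS:
        bits = frozenset(MACCSkeys.GenMACCSKeys(mol).GetOnBits())
    else:
        gen = _MORGAN_FOLDED if folded else _MORGAN
        bits = frozenset(gen.GetSparseFingerprint(mol).GetOnBits() if not folded
                         else gen.GetFingerprint(mol).GetOnBits())
    return Fingerprint(kind=kind, on_bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two same-kind fingerprints."""
    if a.kind is not b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    if not a.on_bits and not b.on_bits:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    inter = len(a.on_bits & b.on_bits)
    union = len(a.on_bits | b.on_bits)
    return inter / union


def qualifying_pair(
    a: Fingerprint,
    b: Fingerprint,
    thresholds: dict[FingerprintKind, float] | None = None,
) -> SimilarityResult:
    """Decide whether two compounds form a qualifying pair (Tc strictly
    above the kind-specific threshold)."""
    thr = (thresholds or DEFAULT_TC_THRESHOLDS)[a.kind]
    tc = tanimoto(a, b)
    return SimilarityResult(tc=tc, kind=a.kind, qualifies=tc > thr)


# ---------------------------------------------------------------------------
# Fingerprint cache (JSON lines: {"id": ..., "kind": ..., "on_bits": [...]})


def write_fingerprint_cache(path: str | Path, fps: dict[str, Fingerprint]) -> None:
    with open(path, "w") as fh:
        for cid in sorted(fps):
            fp = fps[cid]
            fh.write(
                json.dumps(
                    {"id": cid, "kind": fp.kind.value, "on_bits": sorted(fp.on_bits)}
                )
                + "\n"
            )


def read_fingerprint_cache(path: str | Path) -> dict[str, Fingerprint]:
    out: dict[str, Fingerprint] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out[d["id"]] = Fingerprint(
                kind=FingerprintKind(d["kind"]), on_bits=frozenset(d["on_bits"])
            )
    return out


def fingerprints_for(
    structures: dict[str, str], kind: FingerprintKind | str
) -> dict[str, Fingerprint]:
    """Fingerprints for every compound; empty-fingerprint molecules are
    excluded (they cannot be paired meaningfully) and reported."""
    kind = FingerprintKind(kind)
    out: dict[str, Fingerprint] = {}
    for cid, smi in structures.items():
        fp = compute_fingerprint(smi, kind)
        if not fp.on_bits:
            import warnings

            warnings.warn(f"empty {kind.value} fingerprint for {cid}; excluded from pairing")
            continue
        out[cid] = fp
    return out
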