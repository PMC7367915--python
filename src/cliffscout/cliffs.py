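"""Activity-cliff detection.

An activity cliff (AC) is a pair of structurally similar compounds active
against the same target whose potency difference meets a threshold.  The
way similarity and potency criteria are combined defines three
generations of 2D cliffs:

* G1 — numerical (fingerprint Tc) or substructure (MMP) similarity with a
  constant potency threshold (ΔpKi >= 2 by default);
* G2 — retrosynthetic matched molecular pairs (single substitution site)
  with an activity-class-dependent threshold (mean + 2 sd of the class's
  analog-pair potency differences);
* G3 — analog pairs with one or two substitution sites (ss-/ds-ACs) with
  class-dependent thresholds.

On top of the generational detectors, special categories are identified:
iso-ACs (constitutional isomers carrying the same substituent at
different sites), chirality cliffs (epimers at a single stereocenter),
isomer/MMP-cliffs, privileged-substructure ACs, and consensus ACs
(cliffs found under multiple representations).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from rdkit import Chem

from .chem import canonical, mol_from_smiles, molecular_formula, strip_stereo
from .data_model import ActivityClass
from .mmp import (
    Fragmentation,
    MatchedPair,
    PairConfig,
    fragment,
    pairs_for_class,
)
from .similarity import (
    DEFAULT_TC_THRESHOLDS,
    FingerprintKind,
    fingerprints_for,
    tanimoto,
)
from .thresholds import (
    DEFAULT_CONSTANT_THRESHOLD,
    ThresholdMode,
    ThresholdProfile,
    build_profile,
    constant_threshold,
)

log = logging.getLogger(__name__)

CRITERION_FP_MACCS = "fp_maccs"
CRITERION_FP_ECFP4 = "fp_ecfp4"
CRITERION_MMP = "mmp"
CRITERION_RMMP = "rmmp"
CRITERION_ANALOG_PAIR = "analog_pair"
CRITERION_ISO = "iso_pair"
CRITERION_STEREO = "stereo_pair"
CRITERION_ISOMER_OF_MMP = "isomer_of_mmp"


@dataclass(frozen=True)
class ActivityCliff:
    """A qualifying pair whose potency difference meets the threshold.

    ``id_high`` / ``id_low`` are ordered by potency; ``n_sites`` is the
    number of substitution sites for substructure criteria (0 for
    whole-molecule fingerprint similarity).
    """

    target_id: str
    id_high: str
    id_low: str
    pki_high: float
    pki_low: float
    criterion: str
    generation: str  # "G1" | "G2" | "G3"
    n_sites: int = 0
    flags: frozenset[str] = frozenset()
    tc: float | None = None
    pair: MatchedPair | None = None

    @property
    def delta_pki(self) -> float:
        return self.pki_high - self.pki_low

    @property
    def key(self) -> tuple[str, str, str]:
        """Criterion-independent identity: target plus unordered id pair."""
        a, b = sorted((self.id_high, self.id_low))
        return (self.target_id, a, b)

    def with_flags(self, *new: str) -> "ActivityCliff":
        return replace(self, flags=self.flags | frozenset(new))


@dataclass
class ClassSummary:
    """Per-class cliff statistics (counts of qualifying pairs and ACs,
    percentage of QPs forming ACs, compounds involved in cliffs, and the
    single-/dual-site split)."""

    target_id: str
    n_compounds: int
    n_qp: int
    n_ac: int
    n_ac_compounds: int
    n_ss_ac: int
    n_ds_ac: int

    @property
    def pct_ac(self) -> float | None:
        return 100.0 * self.n_ac / self.n_qp if self.n_qp else None

    @property
    def pct_ac_compounds(self) -> float | None:
        return 100.0 * self.n_ac_compounds / self.n_compounds if self.n_compounds else None


# ---------------------------------------------------------------------------
# helpers


def _thr(threshold: float | ThresholdProfile | None, default: float = DEFAULT_CONSTANT_THRESHOLD):
    if threshold is None:
        return constant_threshold(default)
    if isinstance(threshold, ThresholdProfile):
        return threshold
    return constant_threshold(float(threshold))


def _oriented(cls: ActivityClass, id_a: str, id_b: str):
    pa, pb = cls.pki_of(id_a), cls.pki_of(id_b)
    if pa >= pb:
        return id_a, id_b, pa, pb
    return id_b, id_a, pb, pa


def fingerprint_qualifying_pairs(
    cls: ActivityClass,
    structures: dict[str, str],
    kind: FingerprintKind | str,
    tc_thresholds: dict[FingerprintKind, float] | None = None,
) -> list[tuple[str, str, float]]:
    """All unordered member pairs whose Tc strictly exceeds the
    kind-specific threshold."""
    kind = FingerprintKind(kind)
    thr = (tc_thresholds or DEFAULT_TC_THRESHOLDS)[kind]
    fps = fingerprints_for({cid: structures[cid] for cid in cls.compound_ids}, kind)
    out = []
    for a, b in itertools.combinations(sorted(fps), 2):
        tc = tanimoto(fps[a], fps[b])
        if tc > thr:
            out.append((a, b, tc))
    return out


def class_profile(
    cls: ActivityClass,
    structures: dict[str, str],
    pair_config: PairConfig | None = None,
    min_pairs: int = 10,
    fallback: float = DEFAULT_CONSTANT_THRESHOLD,
    pairs: Sequence[MatchedPair] | None = None,
) -> ThresholdProfile:
    """Class-dependent threshold profile from the class's RMMP potency
    differences (IQR category + mean + 2 sd)."""
    cfg = pair_config or PairConfig(k_max=1, rules="retrosynthetic")
    if pairs is None:
        pairs = pairs_for_class(cls, structures, cfg)
    diffs = [abs(cls.pki_of(p.id_a) - cls.pki_of(p.id_b)) for p in pairs]
    return build_profile(cls.target_id, cls.pkis, diffs, min_pairs=min_pairs, fallback=fallback)


def _emit_from_pairs(
    cls: ActivityClass,
    pairs: Iterable[MatchedPair],
    profile: ThresholdProfile,
    criterion: str,
    generation: str,
) -> list[ActivityCliff]:
    acs = []
    for p in pairs:
        hi, lo, ph, pl = _oriented(cls, p.id_a, p.id_b)
        if ph - pl >= profile.threshold:
            acs.append(
                ActivityCliff(
                    target_id=cls.target_id,
                    id_high=hi,
                    id_low=lo,
                    pki_high=ph,
                    pki_low=pl,
                    criterion=criterion,
                    generation=generation,
                    n_sites=p.n_sites,
                    pair=p,
                )
            )
    return sorted(acs, key=lambda a: a.key)


# ---------------------------------------------------------------------------
# generational detectors


def detect_g1(
    cls: ActivityClass,
    structures: dict[str, str],
    criterion: str = CRITERION_FP_ECFP4,
    threshold: float = DEFAULT_CONSTANT_THRESHOLD,
    tc_thresholds: dict[FingerprintKind, float] | None = None,
    pair_config: PairConfig | None = None,
    qps: Sequence | None = None,
) -> list[ActivityCliff]:
    """First-generation cliffs: fingerprint or MMP similarity, constant
    potency threshold (inclusive, ΔpKi >= threshold)."""
    profile = constant_threshold(threshold, target_id=cls.target_id)
    if criterion in (CRITERION_FP_MACCS, CRITERION_FP_ECFP4):
        kind = FingerprintKind.MACCS if criterion == CRITERION_FP_MACCS else FingerprintKind.ECFP4
        if qps is None:
            qps = fingerprint_qualifying_pairs(cls, structures, kind, tc_thresholds)
        acs = []
        for a, b, tc in qps:
            hi, lo, ph, pl = _oriented(cls, a, b)
            if ph - pl >= profile.threshold:
                acs.append(
                    ActivityCliff(
                        target_id=cls.target_id,
                        id_high=hi,
                        id_low=lo,
                        pki_high=ph,
                        pki_low=pl,
                        criterion=criterion,
                        generation="G1",
                        n_sites=0,
                        tc=tc,
                    )
                )
        return sorted(acs, key=lambda a: a.key)
    if criterion == CRITERION_MMP:
        cfg = pair_config or PairConfig(k_max=1, rules="all_single_bonds")
        pairs = qps if qps is not None else pairs_for_class(cls, structures, cfg)
        return _emit_from_pairs(cls, pairs, profile, CRITERION_MMP, "G1")
    raise ValueError(f"unknown first-generation criterion {criterion!r}")


def detect_g2(
    cls: ActivityClass,
    structures: dict[str, str],
    profile: ThresholdProfile | None = None,
    pair_config: PairConfig | None = None,
    qps: Sequence[MatchedPair] | None = None,
) -> list[ActivityCliff]:
    """Second-generation cliffs: retrosynthetic MMPs (single site) with
    the class-dependent threshold.  CAT1 classes yield no cliffs."""
    cfg = pair_config or PairConfig(k_max=1, rules="retrosynthetic")
    pairs = qps if qps is not None else pairs_for_class(cls, structures, cfg)
    if profile is None:
        profile = class_profile(cls, structures, cfg, pairs=pairs)
    if profile.excluded:
        log.info("class %s is CAT1 (IQR %.2f < 1); excluded from cliff analysis",
                 cls.target_id, profile.iqr if profile.iqr is not None else float("nan"))
        return []
    return _emit_from_pairs(cls, pairs, profile, CRITERION_RMMP, "G2")


def detect_g3(
    cls: ActivityClass,
    structures: dict[str, str],
    profile: ThresholdProfile | None = None,
    pair_config: PairConfig | None = None,
    qps: Sequence[MatchedPair] | None = None,
) -> list[ActivityCliff]:
    """Third-generation cliffs: analog pairs with one or two substitution
    sites (ss-/ds-ACs) with the class-dependent threshold.

    The threshold profile is derived from single-site retrosynthetic
    pairs, as for G2, so every second-generation cliff is also a
    third-generation cliff.
    """
    cfg = pair_config or PairConfig(k_max=2, rules="retrosynthetic")
    pairs = qps if qps is not None else pairs_for_class(cls, structures, cfg)
    if profile is None:
        ss_cfg = PairConfig(
            k_max=1,
            rules=cfg.rules,
            retro_rules=cfg.retro_rules,
            max_substituent_atoms=cfg.max_substituent_atoms,
            min_core_ratio=cfg.min_core_ratio,
            max_substituent_size_diff=cfg.max_substituent_size_diff,
        )
        profile = class_profile(cls, structures, ss_cfg,
                                pairs=[p for p in pairs if p.n_sites == 1])
    if profile.excluded:
        log.info("class %s is CAT1; excluded from cliff analysis", cls.target_id)
        return []
    return _emit_from_pairs(cls, pairs, profile, CRITERION_ANALOG_PAIR, "G3")


# ---------------------------------------------------------------------------
# special categories


def _core_skeleton(core_smiles: str) -> str:
    """Core with its attachment point hydrogen-capped: identifies cores
    that are the same molecule attached at different positions."""
    mol = Chem.MolFromSmiles(core_smiles)
    rw = Chem.RWMol(mol)
    for atom in list(rw.GetAtoms()):
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


def detect_iso_acs(
    cls: ActivityClass,
    structures: dict[str, str],
    threshold: float | ThresholdProfile = DEFAULT_CONSTANT_THRESHOLD,
    pair_config: PairConfig | None = None,
) -> list[ActivityCliff]:
    """Iso-ACs: constitutional isomers carrying an identical substituent
    at two different attachment positions of the same core."""
    profile = _thr(threshold)
    cfg = pair_config or PairConfig(k_max=1, rules="all_single_bonds")
    generation = "G1" if profile.mode is ThresholdMode.CONSTANT else "G3"

    members = [cid for cid in cls.compound_ids if cid in structures]
    by_formula: dict[str, list[str]] = {}
    for cid in members:
        by_formula.setdefault(molecular_formula(structures[cid]), []).append(cid)

    frag_cache: dict[str, list[Fragmentation]] = {}

    def frags(cid: str) -> list[Fragmentation]:
        if cid not in frag_cache:
            frag_cache[cid] = fragment(
                cid, structures[cid], k=1, rules=cfg.rules,
                retro_rules=cfg.retro_rules,
                max_substituent_atoms=cfg.max_substituent_atoms,
                min_core_ratio=cfg.min_core_ratio,
            )
        return frag_cache[cid]

    acs = []
    for formula in sorted(by_formula):
        group = sorted(by_formula[formula])
        if len(group) < 2:
            continue
        for a, b in itertools.combinations(group, 2):
            if canonical(structures[a]) == canonical(structures[b]):
                continue
            is_iso = False
            for fa in frags(a):
                for fb in frags(b):
                    if (
                        fa.substituents == fb.substituents
                        and fa.core_smiles != fb.core_smiles
                        and _core_skeleton(fa.core_smiles) == _core_skeleton(fb.core_smiles)
                    ):
                        is_iso = True
                        break
                if is_iso:
                    break
            if not is_iso:
                continue
            hi, lo, ph, pl = _oriented(cls, a, b)
            if ph - pl >= profile.threshold:
                acs.append(
                    ActivityCliff(
                        target_id=cls.target_id,
                        id_high=hi,
                        id_low=lo,
                        pki_high=ph,
                        pki_low=pl,
                        criterion=CRITERION_ISO,
                        generation=generation,
                        n_sites=1,
                        flags=frozenset({"iso"}),
                    )
                )
    return sorted(acs, key=lambda a: a.key)


def detect_isomer_mmp_cliffs(
    acs: Sequence[ActivityCliff],
    cls: ActivityClass,
    structures: dict[str, str],
    threshold: float | ThresholdProfile = DEFAULT_CONSTANT_THRESHOLD,
) -> list[ActivityCliff]:
    """Isomer/MMP-cliffs: starting from MMP-cliffs, constitutional isomers
    of either cliff compound that meet the potency criterion against the
    opposite cliff partner form additional flagged cliffs."""
    profile = _thr(threshold)
    existing = {ac.key for ac in acs}
    formula_of = {cid: molecular_formula(structures[cid]) for cid in cls.compound_ids
                  if cid in structures}
    canon_of = {cid: canonical(structures[cid]) for cid in formula_of}

    new: dict[tuple, ActivityCliff] = {}
    for ac in acs:
        for member, partner in ((ac.id_high, ac.id_low), (ac.id_low, ac.id_high)):
            for cid in sorted(formula_of):
                if cid in (member, partner):
                    continue
                if formula_of[cid] != formula_of[member] or canon_of[cid] == canon_of[member]:
                    continue
                hi, lo, ph, pl = _oriented(cls, cid, partner)
                if ph - pl < profile.threshold:
                    continue
                candidate = ActivityCliff(
                    target_id=cls.target_id,
                    id_high=hi,
                    id_low=lo,
                    pki_high=ph,
                    pki_low=pl,
                    criterion=CRITERION_ISOMER_OF_MMP,
                    generation=ac.generation,
                    n_sites=1,
                    flags=frozenset({"isomer_mmp"}),
                )
                if candidate.key not in existing:
                    new.setdefault(candidate.key, candidate)
    return sorted(new.values(), key=lambda a: a.key)


def _stereocenter_map(smiles: str) -> dict[int, str] | None:
    """Map canonical atom rank (on the stereo-stripped graph) -> CIP code.

    Returns None when the molecule has unassigned stereocenters, which
    disqualifies it from chirality-cliff pairing (ambiguity).
    """
    mol = mol_from_smiles(smiles)
    centers = Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    if any(code == "?" for _, code in centers):
        return None
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    ranks = list(Chem.CanonicalRankAtoms(flat))
    return {ranks[idx]: code for idx, code in centers}


def detect_chirality_cliffs(
    cls: ActivityClass,
    structures: dict[str, str],
    threshold: float | ThresholdProfile = DEFAULT_CONSTANT_THRESHOLD,
) -> list[ActivityCliff]:
    """Chirality cliffs: stereoisomers with identical constitution that
    differ in configuration at exactly one defined stereocenter."""
    profile = _thr(threshold)
    generation = "G1" if profile.mode is ThresholdMode.CONSTANT else "G3"
    members = [cid for cid in cls.compound_ids if cid in structures]
    by_flat: dict[str, list[str]] = {}
    for cid in members:
        by_flat.setdefault(strip_stereo(structures[cid]), []).append(cid)

    acs = []
    for flat in sorted(by_flat):
        group = sorted(by_flat[flat])
        if len(group) < 2:
            continue
        smaps = {cid: _stereocenter_map(structures[cid]) for cid in group}
        for a, b in itertools.combinations(group, 2):
            ma, mb = smaps[a], smaps[b]
            if ma is None or mb is None or not ma or set(ma) != set(mb):
                continue
            differing = [r for r in ma if ma[r] != mb[r]]
            if len(differing) != 1:
                continue
            hi, lo, ph, pl = _oriented(cls, a, b)
            if ph - pl >= profile.threshold:
                acs.append(
                    ActivityCliff(
                        target_id=cls.target_id,
                        id_high=hi,
                        id_low=lo,
                        pki_high=ph,
                        pki_low=pl,
                        criterion=CRITERION_STEREO,
                        generation=generation,
                        n_sites=1,
                        flags=frozenset({"chirality"}),
                    )
                )
    return sorted(acs, key=lambda a: a.key)


def flag_privileged(
    acs: Sequence[ActivityCliff],
    ps_smarts: Sequence[str],
    structures: dict[str, str],
) -> list[ActivityCliff]:
    """Flag cliffs whose two compounds share at least one of the supplied
    privileged-substructure patterns (the PS is the shared context)."""
    patterns = []
    for smarts in ps_smarts:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid privileged-substructure SMARTS: {smarts!r}")
        patterns.append(patt)
    if not patterns:
        return list(acs)
    mols = {cid: mol_from_smiles(structures[cid])
            for ac in acs for cid in (ac.id_high, ac.id_low) if cid in structures}
    out = []
    for ac in acs:
        shared = any(
            mols[ac.id_high].HasSubstructMatch(p) and mols[ac.id_low].HasSubstructMatch(p)
            for p in patterns
        )
        out.append(ac.with_flags("privileged_substructure") if shared else ac)
    return out


def consensus(ac_sets: Sequence[Sequence[ActivityCliff]]) -> list[ActivityCliff]:
    """Cliffs present in every supplied set (by target and unordered
    compound pair), flagged ``consensus``."""
    if len(ac_sets) < 2:
        raise ValueError("consensus needs at least two cliff sets")
    keys = set.intersection(*(set(ac.key for ac in s) for s in ac_sets))
    first = {ac.key: ac for ac in ac_sets[0]}
    return sorted(
        (first[k].with_flags("consensus") for k in keys), key=lambda a: a.key
    )


# ---------------------------------------------------------------------------
# summaries


def summarize(
    acs: Sequence[ActivityCliff],
    qps: Sequence | int,
    cls: ActivityClass,
) -> ClassSummary:
    """Per-class roll-up of cliff statistics."""
    n_qp = qps if isinstance(qps, int) else len(qps)
    ac_compounds = {cid for ac in acs for cid in (ac.id_high, ac.id_low)}
    return ClassSummary(
        target_id=cls.target_id,
        n_compounds=cls.size,
        n_qp=n_qp,
        n_ac=len(acs),
        n_ac_compounds=len(ac_compounds),
        n_ss_ac=sum(1 for ac in acs if ac.n_sites == 1),
        n_ds_ac=sum(1 for ac in acs if ac.n_sites == 2),
    )


def summarize_global(summaries: Sequence[ClassSummary]) -> dict:
    n_qp = sum(s.n_qp for s in summaries)
    n_ac = sum(s.n_ac for s in summaries)
    return {
        "n_classes": len(summaries),
        "n_qp": n_qp,
        "n_ac": n_ac,
        "pct_ac": 100.0 * n_ac / n_qp if n_qp else None,
        "n_ss_ac": sum(s.n_ss_ac for s in summaries),
        "n_ds_ac": sum(s.n_ds_ac for s in summaries),
    }


def cliffs_table(acs: Sequence[ActivityCliff]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "target_id": ac.target_id,
                "id_high": ac.id_high,
                "id_low": ac.id_low,
                "pki_high": round(ac.pki_high, 6),
                "pki_low": round(ac.pki_low, 6),
                "delta_pki": round(ac.delta_pki, 6),
                "criterion": ac.criterion,
                "generation": ac.generation,
                "n_sites": ac.n_sites,
                "flags": ",".join(sorted(ac.flags)),
            }
            for ac in acs
        ],
        columns=[
            "target_id", "id_high", "id_low", "pki_high", "pki_low",
            "delta_pki", "criterion", "generation", "n_sites", "flags",
        ],
    )
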