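"""Fragmentation-based analog detection.

A matched molecular pair (MMP) is a pair of compounds distinguished only
by a structural modification at a single site; cutting one acyclic single
bond in each compound and matching the large remainders (cores) finds
them without pre-defining substructures.  The retrosynthetic variant
(RMMP) restricts cuts to bonds of synthetically meaningful classes
(amide, ester, sulfonamide, aromatic ether/amine, biaryl, benzylic), and
the dual-site extension cuts two bonds simultaneously so analog pairs
differing at two substitution sites are found as well.

Size restrictions keep pairs confined to recognizable analogs: each
exchanged substituent is limited to 13 heavy atoms, the shared core must
carry at least twice the heavy atoms of the larger exchanged substituent,
and the two exchanged substituents may differ by at most 8 heavy atoms.
All three limits are configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .chem import canonical, mol_from_smiles
from .data_model import ActivityClass

# ---------------------------------------------------------------------------
# Cut rules

#: Retrosynthetic bond classes.  Each SMARTS marks the cuttable bond with
#: atom maps 1 and 2; only acyclic single bonds between heavy atoms are cut.
DEFAULT_RETRO_RULES: list[dict[str, str]] = [
    {"name": "amide_C_N", "smarts": "[CX3:1](=[OX1])-[NX3:2]"},
    {"name": "ester_C_O", "smarts": "[CX3:1](=[OX1])-[OX2:2]"},
    {"name": "sulfonamide_S_N", "smarts": "[SX4:1](=[OX1])(=[OX1])-[NX3:2]"},
    {"name": "aromatic_ether_amine", "smarts": "[c:1]-[OX2,NX3:2]"},
    {"name": "biaryl", "smarts": "[c:1]-[c:2]"},
    {"name": "benzylic_C_ring", "smarts": "[CX4:1]-[c:2]"},
]

RULE_SETS = ("all_single_bonds", "retrosynthetic")


def load_retro_rules(path: str | Path) -> list[dict[str, str]]:
    """Load retrosynthetic cut rules from a YAML file (list of
    {name, smarts} entries, same shape as ``DEFAULT_RETRO_RULES``)."""
    import yaml

    rules = yaml.safe_load(Path(path).read_text())
    if not isinstance(rules, list) or not all("smarts" in r for r in rules):
        raise ValueError(f"malformed rule file: {path}")
    return rules


def _rule_patterns(rules: Sequence[dict[str, str]]):
    pats = []
    for rule in rules:
        patt = Chem.MolFromSmarts(rule["smarts"])
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule {rule.get('name')!r}: {rule['smarts']!r}")
        maps = {a.GetAtomMapNum(): a.GetIdx() for a in patt.GetAtoms() if a.GetAtomMapNum()}
        if set(maps) != {1, 2}:
            raise ValueError(f"rule {rule.get('name')!r} must map exactly atoms :1 and :2")
        pats.append((patt, maps[1], maps[2]))
    return pats


def cuttable_bonds(
    mol: Chem.Mol,
    rules: str = "all_single_bonds",
    retro_rules: Sequence[dict[str, str]] | None = None,
) -> list[int]:
    """Indices of bonds that may be severed: acyclic single bonds between
    heavy atoms, optionally restricted to retrosynthetic bond classes."""
    if rules not in RULE_SETS:
        raise ValueError(f"unknown rule set {rules!r}; expected one of {RULE_SETS}")
    allowed: set[int] = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        allowed.add(bond.GetIdx())
    if rules == "all_single_bonds":
        return sorted(allowed)
    matched: set[int] = set()
    for patt, i1, i2 in _rule_patterns(retro_rules or DEFAULT_RETRO_RULES):
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[i1], match[i2])
            if bond is not None and bond.GetIdx() in allowed:
                matched.add(bond.GetIdx())
    return sorted(matched)


# ---------------------------------------------------------------------------
# Fragmentation


@dataclass(frozen=True)
class Fragmentation:
    """One way of splitting a compound into a core plus k substituents.

    ``core_smiles`` carries numbered attachment points ([*:1], [*:2]);
    ``substituents`` is ordered to match those site labels, each with one
    unlabelled attachment point.  Reassembling core + substituents
    reproduces the parent molecule.
    """

    compound_id: str
    core_smiles: str
    substituents: tuple[str, ...]
    cut_bond_ids: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.substituents)


def _frag_smiles(frag: Chem.Mol, site_labels: dict[int, int]) -> str:
    """Canonical SMILES of a fragment; dummy isotopes -> atom map numbers."""
    frag = Chem.Mol(frag)
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() == 0:
            iso = atom.GetIsotope()
            atom.SetIsotope(0)
            atom.SetAtomMapNum(site_labels.get(iso, 0))
    return Chem.MolToSmiles(frag)


def _split(mol: Chem.Mol, bond_ids: Sequence[int]):
    """Fragment on bonds; returns (pieces, dummy isotope labels per piece)."""
    labels = [(i + 1, i + 1) for i in range(len(bond_ids))]
    fragged = Chem.FragmentOnBonds(mol, list(bond_ids), addDummies=True, dummyLabels=labels)
    pieces = Chem.GetMolFrags(fragged, asMols=True, sanitizeFrags=True)
    out = []
    for piece in pieces:
        isos = sorted(
            a.GetIsotope() for a in piece.GetAtoms() if a.GetAtomicNum() == 0
        )
        out.append((piece, isos))
    return out


def _n_heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def fragment(
    compound_id: str,
    smiles: str,
    k: int = 1,
    rules: str = "all_single_bonds",
    retro_rules: Sequence[dict[str, str]] | None = None,
    max_substituent_atoms: int = 13,
    min_core_ratio: float = 2.0,
    include_hydrogen_substituents: bool = False,
) -> list[Fragmentation]:
    """Enumerate all k-cut fragmentations of one compound.

    For k=1 every cuttable bond is severed once; the larger piece serves
    as the core, and the swapped orientation is also emitted when it
    satisfies the ``min_core_ratio`` core/substituent size rule (so
    equal-sized halves are never lost to an arbitrary orientation).
    Substituents above ``max_substituent_atoms`` heavy atoms are
    discarded.  For k=2
    every simultaneous pair of cuts is made and the piece bearing both
    attachment points is the core.  With
    ``include_hydrogen_substituents`` an additional cut per heavy atom
    bearing hydrogens exposes the substituent ``[H]``, which makes
    H -> CH3 style transformations detectable.
    """
    if k not in (1, 2):
        raise ValueError(f"k must be 1 or 2, got {k}")
    mol = mol_from_smiles(smiles)
    bonds = cuttable_bonds(mol, rules, retro_rules)
    out: list[Fragmentation] = []

    if k == 1:
        for bid in bonds:
            pieces = _split(mol, [bid])
            if len(pieces) != 2:  # pragma: no cover - acyclic single bond always splits
                continue
            (p1, _), (p2, _) = pieces
            for core, sub in ((p1, p2), (p2, p1)):
                n_core, n_sub = _n_heavy(core), _n_heavy(sub)
                if n_sub > max_substituent_atoms:
                    continue
                if n_core < n_sub and n_core < min_core_ratio * n_sub:
                    continue
                out.append(
                    Fragmentation(
                        compound_id=compound_id,
                        core_smiles=_frag_smiles(core, {1: 1}),
                        substituents=(_frag_smiles(sub, {}),),
                        cut_bond_ids=(bid,),
                    )
                )
        if include_hydrogen_substituents:
            for atom in mol.GetAtoms():
                if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() < 1:
                    continue
                rw = Chem.RWMol(mol)
                dummy = rw.AddAtom(Chem.Atom(0))
                rw.GetAtomWithIdx(dummy).SetAtomMapNum(1)
                rw.AddBond(atom.GetIdx(), dummy, Chem.BondType.SINGLE)
                rw.GetAtomWithIdx(atom.GetIdx()).SetNumExplicitHs(
                    max(0, atom.GetTotalNumHs() - 1)
                )
                rw.GetAtomWithIdx(atom.GetIdx()).SetNoImplicit(True)
                try:
                    core = rw.GetMol()
                    Chem.SanitizeMol(core)
                except Exception:
                    continue
                out.append(
                    Fragmentation(
                        compound_id=compound_id,
                        core_smiles=Chem.MolToSmiles(core),
                        substituents=("[H][*]",),
                        cut_bond_ids=(-1 - atom.GetIdx(),),
                    )
                )
        return out

    for b1, b2 in itertools.combinations(bonds, 2):
        pieces = _split(mol, [b1, b2])
        if len(pieces) != 3:
            continue
        core_piece = None
        subs: dict[int, Chem.Mol] = {}
        for piece, isos in pieces:
            if len(isos) == 2:
                core_piece = piece
            elif len(isos) == 1:
                subs[isos[0]] = piece
        if core_piece is None or len(subs) != 2:
            continue
        if any(_n_heavy(s) > max_substituent_atoms for s in subs.values()):
            continue
        # canonicalize site numbering: try both labelings, keep the smaller
        cand = []
        for lab in ({1: 1, 2: 2}, {1: 2, 2: 1}):
            core_smi = _frag_smiles(core_piece, lab)
            ordered = tuple(
                _frag_smiles(subs[iso], {}) for iso in sorted(subs, key=lambda i: lab[i])
            )
            cand.append((core_smi, ordered))
        core_smi, ordered = min(cand)
        out.append(
            Fragmentation(
                compound_id=compound_id,
                core_smiles=core_smi,
                substituents=ordered,
                cut_bond_ids=(b1, b2),
            )
        )
    return out


def reassemble(core_smiles: str, substituents: Sequence[str]) -> str:
    """Rebuild the parent molecule's canonical SMILES from a fragmentation."""
    core = Chem.MolFromSmiles(core_smiles)
    combined = core
    for site, sub in enumerate(substituents, start=1):
        smol = Chem.MolFromSmiles(sub, sanitize=False)
        for atom in smol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(site)
        combined = Chem.CombineMols(combined, smol)
    zipped = Chem.molzip(combined)
    zipped = Chem.RemoveHs(zipped)
    return Chem.MolToSmiles(zipped)


# ---------------------------------------------------------------------------
# Pair finding


@dataclass(frozen=True)
class MatchedPair:
    """Two compounds sharing a core and differing at every listed site.

    Unordered: ``id_a`` < ``id_b`` lexicographically.  ``exchanged`` lists
    per site the substituent of a and of b.
    """

    id_a: str
    id_b: str
    core_smiles: str
    exchanged: tuple[tuple[str, str], ...]
    retrosynthetic: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.exchanged)

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    def substituents_of(self, compound_id: str) -> tuple[str, ...]:
        if compound_id == self.id_a:
            return tuple(a for a, _ in self.exchanged)
        if compound_id == self.id_b:
            return tuple(b for _, b in self.exchanged)
        raise KeyError(compound_id)


@dataclass
class PairConfig:
    k_max: int = 1
    rules: str = "all_single_bonds"
    retro_rules: Sequence[dict[str, str]] | None = None
    max_substituent_atoms: int = 13
    min_core_ratio: float = 2.0  # core >= ratio * heavy atoms of larger substituent
    max_substituent_size_diff: int = 8
    include_hydrogen_substituents: bool = False

    def __post_init__(self) -> None:
        if self.k_max not in (1, 2):
            raise ValueError("k_max must be 1 or 2")


def _sub_heavy(sub_smiles: str) -> int:
    mol = Chem.MolFromSmiles(sub_smiles, sanitize=False)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _core_heavy(core_smiles: str) -> int:
    mol = Chem.MolFromSmiles(core_smiles, sanitize=False)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _pair_ok(core: str, subs_a: Sequence[str], subs_b: Sequence[str], cfg: PairConfig) -> bool:
    if any(sa == sb for sa, sb in zip(subs_a, subs_b)):
        return False  # must differ at every site
    sizes = [_sub_heavy(s) for s in (*subs_a, *subs_b)]
    if _core_heavy(core) < cfg.min_core_ratio * max(sizes):
        return False
    for sa, sb in zip(subs_a, subs_b):
        if abs(_sub_heavy(sa) - _sub_heavy(sb)) > cfg.max_substituent_size_diff:
            return False
    return True


def _all_fragmentations(
    structures: dict[str, str], cfg: PairConfig
) -> dict[str, list[Fragmentation]]:
    out: dict[str, list[Fragmentation]] = {}
    for cid in sorted(structures):
        frags: list[Fragmentation] = []
        for k in range(1, cfg.k_max + 1):
            frags.extend(
                fragment(
                    cid,
                    structures[cid],
                    k=k,
                    rules=cfg.rules,
                    retro_rules=cfg.retro_rules,
                    max_substituent_atoms=cfg.max_substituent_atoms,
                    min_core_ratio=cfg.min_core_ratio,
                    include_hydrogen_substituents=(
                        cfg.include_hydrogen_substituents if k == 1 else False
                    ),
                )
            )
        out[cid] = frags
    return out


def _dedupe(pairs: Iterable[MatchedPair]) -> list[MatchedPair]:
    """One record per (pair, site count): keep the largest-core representative."""
    best: dict[tuple[str, str, int], MatchedPair] = {}
    for p in pairs:
        k = (p.id_a, p.id_b, p.n_sites)
        cur = best.get(k)
        if cur is None or (_core_heavy(p.core_smiles), p.core_smiles) > (
            _core_heavy(cur.core_smiles),
            cur.core_smiles,
        ):
            best[k] = p
    return sorted(best.values(), key=lambda p: (p.id_a, p.id_b, p.n_sites))


def _make_pair(ca: str, cb: str, core: str, subs_a, subs_b, retro: bool) -> MatchedPair:
    if cb < ca:
        ca, cb = cb, ca
        subs_a, subs_b = subs_b, subs_a
    return MatchedPair(
        id_a=ca,
        id_b=cb,
        core_smiles=core,
        exchanged=tuple(zip(subs_a, subs_b)),
        retrosynthetic=retro,
    )


def find_matched_pairs(
    structures: dict[str, str],
    config: PairConfig | None = None,
    members: Sequence[str] | None = None,
) -> list[MatchedPair]:
    """Core-indexed matched-pair discovery over a set of structures.

    Builds a hash map keyed by canonical core SMILES, so discovery is
    linear in the number of fragmentations rather than quadratic in
    compounds.  ``members`` restricts the search to a subset of ids.
    """
    cfg = config or PairConfig()
    if members is not None:
        structures = {cid: structures[cid] for cid in members}
    canon = {cid: canonical(smi) for cid, smi in structures.items()}
    frags = _all_fragmentations(structures, cfg)
    retro = cfg.rules == "retrosynthetic"

    index: dict[tuple[str, int], list[tuple[str, tuple[str, ...]]]] = {}
    for cid in sorted(frags):
        seen: set[tuple[str, tuple[str, ...]]] = set()
        for fr in frags[cid]:
            key = (fr.core_smiles, fr.substituents)
            if key in seen:
                continue
            seen.add(key)
            index.setdefault((fr.core_smiles, fr.n_sites), []).append(
                (cid, fr.substituents)
            )

    pairs: list[MatchedPair] = []
    for (core, _n), entries in index.items():
        if len(entries) < 2:
            continue
        for (ca, sa), (cb, sb) in itertools.combinations(entries, 2):
            if ca == cb or canon[ca] == canon[cb]:
                continue
            if _pair_ok(core, sa, sb, cfg):
                pairs.append(_make_pair(ca, cb, core, sa, sb, retro))
    return _dedupe(pairs)


def find_matched_pairs_brute_force(
    structures: dict[str, str],
    config: PairConfig | None = None,
) -> list[MatchedPair]:
    """All-pairs fragment matching: for every compound pair, the two
    fragmentation sets are compared directly.  Quadratic reference path,
    independent of the global core index."""
    cfg = config or PairConfig()
    canon = {cid: canonical(smi) for cid, smi in structures.items()}
    frags = _all_fragmentations(structures, cfg)
    retro = cfg.rules == "retrosynthetic"
    by_core: dict[str, dict[tuple[str, int], list[tuple[str, ...]]]] = {}
    for cid, flist in frags.items():
        d: dict[tuple[str, int], list[tuple[str, ...]]] = {}
        for fr in flist:
            d.setdefault((fr.core_smiles, fr.n_sites), []).append(fr.substituents)
        by_core[cid] = d
    ids = sorted(structures)
    pairs: list[MatchedPair] = []
    for ca, cb in itertools.combinations(ids, 2):
        if canon[ca] == canon[cb]:
            continue
        da, db = by_core[ca], by_core[cb]
        for key in set(da) & set(db):
            core, _n = key
            for sa in da[key]:
                for sb in db[key]:
                    if _pair_ok(core, sa, sb, cfg):
                        pairs.append(_make_pair(ca, cb, core, sa, sb, retro))
    return _dedupe(pairs)


def pairs_for_class(
    cls: ActivityClass,
    structures: dict[str, str],
    config: PairConfig | None = None,
) -> list[MatchedPair]:
    """Matched pairs among the members of one activity class."""
    return find_matched_pairs(structures, config, members=cls.compound_ids)


def pairs_table(pairs: Iterable[MatchedPair], target_id: str = "") -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for p in pairs:
        rows.append(
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "target_id": target_id,
                "core": p.core_smiles,
                "n_sites": p.n_sites,
                "exchanged": ";".join(f"{a}>>{b}" for a, b in p.exchanged),
                "rule_set": "retrosynthetic" if p.retrosynthetic else "all_single_bonds",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "target_id", "core", "n_sites", "exchanged", "rule_set"],
    )
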