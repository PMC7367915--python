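"""Synthetic activity classes with known cliff structure.

Every downstream stage (pair finding, thresholds, cliff detection,
networks, multi-site decomposition) is tested against classes generated
here, where the ground truth is analytic: compounds are scaffold ×
substituent enumerations and potency follows an additive model

    pKi = base + sum(contribution(substituent_at_site)) + interaction + noise.

Design choices that make exact recovery checkable:

* Substituent contributions are drawn from two clusters — "low"
  (0 to 0.3 pKi) and "high" (1.5 to 1.8 pKi).  The resulting bimodal
  potency distribution keeps the class interquartile range above 1
  (CAT2, eligible for class-dependent cliff analysis) while bounding
  every background analog-pair difference at 1.8 pKi, safely below the
  mean + 2 sd threshold the detector derives.
* Planted cliffs live on dedicated scaffolds: a reserved cliff
  substituent with a large contribution (5.0 for single-site cliffs,
  2.5 per site for dual-site cliffs) is exchanged against low-cluster
  substituents, so planted differences start at 4.4 pKi — well above any
  attainable class threshold — and no unplanned cliff can form.
* Scaffolds are mutually dissimilar ring/linker combinations, so matched
  pairs only arise within a scaffold.

The generator emulates the shape of curated compound-activity classes
(shared cores, clustered analog potencies, a few steep SAR jumps); it
does not attempt realistic medicinal-chemistry structure sampling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import canonical

# ---------------------------------------------------------------------------
# Building blocks

#: Background substituents: attachment-first SMILES, <= 4 heavy atoms, first
#: atom sp3-C / O / N so the ring-attachment bond is retrosynthetically
#: cuttable (benzylic, aromatic ether or aromatic amine bond class).
DEFAULT_SUBSTITUENT_LIBRARY: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "C(C)(C)C", "CC(C)O",
    "CCO", "CCCO", "CCN", "CCCN", "C(C)O", "C(C)N", "CO", "CN",
    "COC", "CCOC", "CNC", "CCNC", "CC=C", "CCC=C", "CF", "C(F)CC",
    "CC(C)F", "CCCF", "OC", "OCC", "OCCC", "OC(C)C", "OCCO", "OCCN",
    "OCOC", "OCC=C", "N(C)C", "N(C)CC", "NC(C)C", "NCCO", "NCC", "NCCC",
    "NC", "N(C)CO", "NCC=C", "NC=O",
)

#: Reserved cliff substituents (never drawn as background).
SS_CLIFF_SUBSTITUENTS: tuple[str, ...] = ("C(F)(F)F", "OC(F)F", "CC#N", "OCF")
DS_CLIFF_SUBSTITUENTS: tuple[str, ...] = ("CC(F)F", "C(F)F", "CCF", "OCC#N")

#: One-site scaffold pool ({R} marks the substitution site).  Ring/linker
#: combinations are pairwise distinct so cores never match across scaffolds.
ONE_SITE_SCAFFOLDS: tuple[str, ...] = (
    "O=C(Nc1ccc({R})cc1)c1ccco1",
    "O=S(=O)(Nc1ccc({R})nc1)c1cccs1",
    "O=C(Cc1ccccc1)Nc1cnc({R})cn1",
    "C(n1ccnc1)c1ccc({R})cc1",
    "O=C(N1CCCC1)c1ccc({R})cn1",
    "O=C(NC1CCCC1)c1cc({R})ccn1",
    "O=S(=O)(N1CCOCC1)c1ccc({R})s1",
    "O=C(NCc1ccco1)c1ccc({R})cc1C",
    "C(c1ccc({R})nc1)N1CCCCC1",
    "O=C(Nc1ccon1)c1ccc({R})cc1",
    "O=C(Nc1nccs1)c1ccc({R})cc1F",
    "O=C(N(C)Cc1ccccc1)c1cc({R})cs1",
    "O=C(NCC1CCC1)c1ccc({R})o1",
    "O=C(NCCc1ccccc1)c1ccc({R})cn1",
)

#: Two-site scaffold pool ({R1}, {R2} on different rings).
TWO_SITE_SCAFFOLDS: tuple[str, ...] = (
    "O=C(Nc1ccc({R2})cc1)c1ccc({R1})cn1",
    "O=S(=O)(Nc1cnc({R2})cn1)c1ccc({R1})s1",
    "O=C(Cc1ccc({R1})cc1)Nc1ccc({R2})nc1",
    "C(Nc1ccc({R2})cc1C)c1ccc({R1})cc1",
    "O=C(N(C)c1ccc({R2})cc1)c1ccc({R1})o1",
    "O=C(NCc1ccc({R2})cc1)c1ccc({R1})s1",
)


class GeneratorError(ValueError):
    """Configuration cannot be satisfied (pool or library exhausted)."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic activity class.

    Defaults generate the standard recovery benchmark: a 120-compound
    class with 10 planted single-site and 4 planted dual-site cliffs and
    no potency noise.
    """

    seed: int = 0
    target_id: str = "SYN1"
    n_scaffolds: int = 6  # background scaffolds (two thirds 1-site, rest 2-site)
    substituent_library: tuple[str, ...] = DEFAULT_SUBSTITUENT_LIBRARY
    cliff_substituents: tuple[str, ...] = SS_CLIFF_SUBSTITUENTS
    ds_cliff_substituents: tuple[str, ...] = DS_CLIFF_SUBSTITUENTS
    sites_per_scaffold: int = 2  # maximum sites used on background scaffolds
    base_pki: float = 5.0
    low_contribution: tuple[float, float] = (0.0, 0.3)
    high_contribution: tuple[float, float] = (1.5, 1.8)
    cliff_contribution: float = 5.0
    ds_site_contribution: float = 2.5
    contributions: dict | None = None  # explicit substituent -> pKi override
    n_planted_ss: int = 10
    n_planted_ds: int = 4
    ss_partner_counts: tuple[int, ...] | None = None  # analogs per ss scaffold
    ss_partner_pool: str = "low"  # "low" or "any"
    n_quartets: int = 0
    interaction_pki: float = 0.0  # added when both sites carry cliff substituents
    noise_sd: float = 0.0
    class_size: int | None = 120  # None: planted compounds only, no background


@dataclass
class GroundTruth:
    """What the generator planted, with the analytic potency model."""

    target_id: str
    planted_acs: list[dict] = field(default_factory=list)  # {id_a, id_b, n_sites, delta}
    hubs: list[dict] = field(default_factory=list)  # {compound_id, degree}
    quartets: list[dict] = field(default_factory=list)
    contributions: dict = field(default_factory=dict)
    max_background_delta: float = 0.0
    min_planted_delta: float = float("inf")

    @property
    def planted_keys(self) -> set[tuple[str, str, int]]:
        return {
            (*sorted((p["id_a"], p["id_b"])), p["n_sites"]) for p in self.planted_acs
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float))


def _substitute(template: str, subs: dict[str, str]) -> str:
    smiles = template.format(**subs)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GeneratorError(f"template {template!r} with {subs} gives invalid SMILES")
    return Chem.MolToSmiles(mol)


class _Builder:
    def __init__(self, config: GeneratorConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.rows: list[dict] = []
        self.truth = GroundTruth(target_id=config.target_id)
        self.seen_smiles: dict[str, str] = {}  # canonical smiles -> compound id
        self._next_id = 0
        self._assign_contributions()

    def _assign_contributions(self) -> None:
        cfg = self.cfg
        reserved = set(cfg.cliff_substituents) | set(cfg.ds_cliff_substituents)
        overlap = reserved & set(cfg.substituent_library)
        if overlap:
            raise GeneratorError(f"cliff substituents also in background library: {overlap}")
        contrib: dict[str, float] = {}
        for sub in cfg.substituent_library:
            lo, hi = (
                cfg.low_contribution
                if self.rng.random() < 0.5
                else cfg.high_contribution
            )
            contrib[sub] = float(self.rng.uniform(lo, hi))
        for sub in cfg.cliff_substituents:
            contrib[sub] = cfg.cliff_contribution
        for sub in cfg.ds_cliff_substituents:
            contrib[sub] = cfg.ds_site_contribution
        if cfg.contributions:
            contrib.update(cfg.contributions)
        self.contrib = contrib
        self.truth.contributions = dict(contrib)
        cutoff = 0.5 * (cfg.low_contribution[1] + cfg.high_contribution[0])
        self.low_subs = [s for s in cfg.substituent_library if contrib[s] < cutoff]

    def add_compound(self, template: str, subs: dict[str, str], pki: float) -> str:
        smiles = _substitute(template, subs)
        if canonical(smiles) in self.seen_smiles:
            raise GeneratorError(f"duplicate structure generated: {smiles}")
        cid = f"C{self._next_id:04d}"
        self.seen_smiles[canonical(smiles)] = cid
        self._next_id += 1
        self.rows.append(
            {
                "compound_id": cid,
                "smiles": smiles,
                "target_id": self.cfg.target_id,
                "pki": pki,
            }
        )
        return cid

    def get_or_add(self, template: str, subs: dict[str, str], pki: float) -> str:
        """Reuse an already generated structure (quartets share compounds)."""
        cid = self.seen_smiles.get(canonical(_substitute(template, subs)))
        return cid if cid is not None else self.add_compound(template, subs, pki)

    def sample_subs(self, n: int, pool: list[str]) -> list[str]:
        if n > len(pool):
            raise GeneratorError(
                f"substituent library too small: need {n}, have {len(pool)}"
            )
        idx = self.rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(idx)]

    def note_background_delta(self, delta: float) -> None:
        self.truth.max_background_delta = max(self.truth.max_background_delta, abs(delta))

    def plant(self, id_a: str, id_b: str, n_sites: int, delta: float) -> None:
        self.truth.planted_acs.append(
            {"id_a": id_a, "id_b": id_b, "n_sites": n_sites, "delta": round(delta, 6)}
        )
        self.truth.min_planted_delta = min(self.truth.min_planted_delta, delta)


def generate_class(config: GeneratorConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one activity class plus its ground truth.

    The output table has the standard columns (compound_id, smiles,
    target_id, pki) consumed by curation; the same configuration always
    produces byte-identical output.
    """
    cfg = config or GeneratorConfig()
    b = _Builder(cfg)
    pool_1site = list(ONE_SITE_SCAFFOLDS)
    pool_2site = list(TWO_SITE_SCAFFOLDS)

    # --- planted single-site cliffs (one dedicated scaffold each) ---------
    partner_counts = cfg.ss_partner_counts or (1,) * cfg.n_planted_ss
    if len(partner_counts) != cfg.n_planted_ss:
        raise GeneratorError("ss_partner_counts length must equal n_planted_ss")
    partner_pool = (
        b.low_subs if cfg.ss_partner_pool == "low" else list(cfg.substituent_library)
    )
    for i in range(cfg.n_planted_ss):
        if not pool_1site:
            raise GeneratorError("one-site scaffold pool exhausted")
        template = pool_1site.pop(0)
        cliff_sub = cfg.cliff_substituents[i % len(cfg.cliff_substituents)]
        cliff_id = b.add_compound(
            template, {"R": cliff_sub}, cfg.base_pki + b.contrib[cliff_sub]
        )
        partners = b.sample_subs(partner_counts[i], partner_pool)
        for sub in partners:
            pid = b.add_compound(template, {"R": sub}, cfg.base_pki + b.contrib[sub])
            b.plant(cliff_id, pid, 1, b.contrib[cliff_sub] - b.contrib[sub])
        if partner_counts[i] >= 2:
            b.truth.hubs.append({"compound_id": cliff_id, "degree": partner_counts[i]})

    # --- planted dual-site cliffs ------------------------------------------
    for i in range(cfg.n_planted_ds):
        if not pool_2site:
            raise GeneratorError("two-site scaffold pool exhausted")
        template = pool_2site.pop(0)
        d1 = cfg.ds_cliff_substituents[i % len(cfg.ds_cliff_substituents)]
        d2 = cfg.ds_cliff_substituents[(i + 1) % len(cfg.ds_cliff_substituents)]
        l1, l2 = b.sample_subs(2, b.low_subs)
        low_id = b.add_compound(
            template, {"R1": l1, "R2": l2}, cfg.base_pki + b.contrib[l1] + b.contrib[l2]
        )
        high_id = b.add_compound(
            template, {"R1": d1, "R2": d2}, cfg.base_pki + b.contrib[d1] + b.contrib[d2]
        )
        b.plant(
            high_id, low_id, 2,
            b.contrib[d1] + b.contrib[d2] - b.contrib[l1] - b.contrib[l2],
        )

    # --- quartets for multi-site decomposition -----------------------------
    used_low_pairs: dict[str, set[tuple[str, str]]] = {}
    for i in range(cfg.n_quartets):
        if not pool_2site:
            raise GeneratorError("two-site scaffold pool exhausted for quartets")
        template = pool_2site[i % len(pool_2site)]
        h1 = cfg.ds_cliff_substituents[0]
        h2 = cfg.ds_cliff_substituents[1]
        taken = used_low_pairs.setdefault(template, set())
        for _ in range(200):
            l1, l2 = b.sample_subs(2, b.low_subs)
            if (l1, l2) not in taken:
                break
        else:
            raise GeneratorError("could not find a fresh low-substituent pair")
        taken.add((l1, l2))
        base = cfg.base_pki
        c = b.contrib
        low_id = b.add_compound(template, {"R1": l1, "R2": l2}, base + c[l1] + c[l2])
        a1_id = b.get_or_add(template, {"R1": h1, "R2": l2}, base + c[h1] + c[l2])
        a2_id = b.get_or_add(template, {"R1": l1, "R2": h2}, base + c[l1] + c[h2])
        high_id = b.get_or_add(
            template, {"R1": h1, "R2": h2},
            base + c[h1] + c[h2] + cfg.interaction_pki,
        )
        delta_total = (c[h1] - c[l1]) + (c[h2] - c[l2]) + cfg.interaction_pki
        b.plant(high_id, low_id, 2, delta_total)
        b.truth.quartets.append(
            {
                "low": low_id, "high": high_id,
                "analog_1": a1_id, "analog_2": a2_id,
                "delta_1": c[h1] - c[l1], "delta_2": c[h2] - c[l2],
                "delta_total": delta_total,
                "interaction": cfg.interaction_pki,
            }
        )

    # --- background scaffolds ----------------------------------------------
    n_background = 0 if cfg.class_size is None else cfg.class_size - len(b.rows)
    if n_background < 0:
        raise GeneratorError(
            f"class_size {cfg.class_size} smaller than planted compounds {len(b.rows)}"
        )
    if cfg.n_scaffolds and n_background:
        n1 = max(1, round(cfg.n_scaffolds * 2 / 3)) if cfg.sites_per_scaffold >= 1 else 0
        n2 = cfg.n_scaffolds - n1 if cfg.sites_per_scaffold >= 2 else 0
        n1 = cfg.n_scaffolds - n2
        quota = [n_background // cfg.n_scaffolds] * cfg.n_scaffolds
        for j in range(n_background % cfg.n_scaffolds):
            quota[j] += 1
        scaffold_no = 0
        for _ in range(n1):
            if not pool_1site:
                raise GeneratorError("one-site scaffold pool exhausted")
            template = pool_1site.pop(0)
            subs = b.sample_subs(quota[scaffold_no], list(cfg.substituent_library))
            pkis = [cfg.base_pki + b.contrib[s] for s in subs]
            for s, p in zip(subs, pkis):
                b.add_compound(template, {"R": s}, p)
            for x in pkis:
                for y in pkis:
                    b.note_background_delta(x - y)
            scaffold_no += 1
        for _ in range(n2):
            if not pool_2site:
                raise GeneratorError("two-site scaffold pool exhausted")
            template = pool_2site.pop(0)
            # both sites from the low cluster: dual-site background pairs
            # stay far below any class threshold
            want = quota[scaffold_no]
            k = int(np.ceil(np.sqrt(want)))
            s1 = b.sample_subs(min(k, len(b.low_subs)), b.low_subs)
            s2 = b.sample_subs(min(int(np.ceil(want / len(s1))), len(b.low_subs)), b.low_subs)
            made = 0
            for x in s1:
                for y in s2:
                    if made >= want:
                        break
                    b.add_compound(
                        template, {"R1": x, "R2": y},
                        cfg.base_pki + b.contrib[x] + b.contrib[y],
                    )
                    b.note_background_delta(b.contrib[x] + b.contrib[y])
                    made += 1
            if made < want:
                raise GeneratorError("substituent library too small for background quota")
            scaffold_no += 1
    elif n_background:
        raise GeneratorError(
            "background compounds requested but n_scaffolds is 0; "
            "reduce class_size or add scaffolds"
        )

    # --- noise and output ---------------------------------------------------
    noise = b.rng.normal(0.0, cfg.noise_sd, size=len(b.rows)) if cfg.noise_sd else None
    for i, row in enumerate(b.rows):
        if noise is not None:
            row["pki"] += float(noise[i])
        row["pki"] = round(row["pki"], 4)
    frame = pd.DataFrame(b.rows, columns=["compound_id", "smiles", "target_id", "pki"])
    return frame, b.truth


# ---------------------------------------------------------------------------
# Enantiomer pairs (chirality-cliff fixtures)

_ENANTIOMER_TEMPLATES = (
    "C[C{tag}](O)c1ccc({X})cc1",
    "C[C{tag}](N)c1ccc({X})cn1",
    "C[C{tag}](CO)c1ccc({X})cc1F",
)


def generate_enantiomer_pairs(
    seed: int = 0,
    n_pairs: int = 10,
    gaps: tuple[float, ...] | None = None,
    base_pki: float = 7.0,
    target_id: str = "SYN-CHIRAL",
    threshold: float = 2.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """R/S enantiomer pairs with configurable potency gaps.

    By default 3 of 10 pairs get a gap of 2.5 pKi (planted chirality
    cliffs under the 100-fold constant threshold) and the rest 0.3.
    """
    if gaps is None:
        gaps = (2.5,) * 3 + (0.3,) * (n_pairs - 3)
    if len(gaps) != n_pairs:
        raise GeneratorError("need one gap per pair")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(target_id=target_id)
    rows = []
    library = list(DEFAULT_SUBSTITUENT_LIBRARY)
    if n_pairs > len(library) * len(_ENANTIOMER_TEMPLATES):
        raise GeneratorError("too many enantiomer pairs requested")
    for i in range(n_pairs):
        template = _ENANTIOMER_TEMPLATES[i // len(library)]
        sub = library[i % len(library)]
        high = base_pki + float(rng.uniform(0, 0.5))
        r_id, s_id = f"R{i:03d}", f"S{i:03d}"
        for cid, tag, pki in ((r_id, "@@H", high), (s_id, "@H", high - gaps[i])):
            smiles = template.format(tag=tag, X=sub)
            if Chem.MolFromSmiles(smiles) is None:
                raise GeneratorError(f"bad enantiomer template {smiles!r}")
            rows.append(
                {"compound_id": cid, "smiles": smiles, "target_id": target_id,
                 "pki": round(pki, 4)}
            )
        if gaps[i] >= threshold:
            truth.planted_acs.append(
                {"id_a": r_id, "id_b": s_id, "n_sites": 1, "delta": gaps[i]}
            )
        else:
            truth.max_background_delta = max(truth.max_background_delta, gaps[i])
    frame = pd.DataFrame(rows, columns=["compound_id", "smiles", "target_id", "pki"])
    return frame, truth


# ---------------------------------------------------------------------------
# Presets


def preset(name: str, seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Named study conditions.

    - ``recovery``: 120 compounds, 10 planted ss- and 4 ds-cliffs, no noise.
    - ``ss``: as recovery but single-site cliffs only.
    - ``ds``: 20 complete quartets for multi-site decomposition.
    - ``chirality``: 10 enantiomer pairs, 3 planted chirality cliffs.
    - ``network``: one hub (degree 8) plus two isolated cliff pairs.
    - ``benchmark``: 40-compound class where planted cliff pairs are
      exactly 5% of qualifying pairs.
    """
    if name == "recovery":
        return generate_class(GeneratorConfig(seed=seed))
    if name == "ss":
        return generate_class(GeneratorConfig(seed=seed, n_planted_ds=0, class_size=112))
    if name == "ds":
        return generate_class(
            GeneratorConfig(
                seed=seed,
                n_planted_ss=0,
                n_planted_ds=0,
                n_quartets=20,
                ds_site_contribution=1.5,
                n_scaffolds=0,
                class_size=None,
                target_id="SYN-DS",
            )
        )
    if name == "chirality":
        return generate_enantiomer_pairs(seed=seed)
    if name == "network":
        return generate_class(
            GeneratorConfig(
                seed=seed,
                n_planted_ss=3,
                ss_partner_counts=(8, 1, 1),
                n_planted_ds=0,
                n_scaffolds=0,
                class_size=13,
                target_id="SYN-NET",
            )
        )
    if name == "benchmark":
        return generate_class(
            GeneratorConfig(
                seed=seed,
                n_planted_ss=1,
                ss_partner_counts=(39,),
                ss_partner_pool="any",
                n_planted_ds=0,
                n_scaffolds=0,
                class_size=40,
                target_id="SYN-5PCT",
            )
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("recovery", "ss", "ds", "chirality", "network", "benchmark")


# ---------------------------------------------------------------------------
# Random small molecules (for pair-finding oracle tests)

_ATOM_CHOICES = ("C", "C", "C", "C", "C", "N", "N", "O", "O")
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def random_small_molecules(
    n: int, max_heavy: int = 15, seed: int = 0, ring_probability: float = 0.3
) -> dict[str, str]:
    """Random connected molecules of at most ``max_heavy`` heavy atoms.

    Molecules are random trees over C/N/O with valence bookkeeping and an
    optional single ring closure; duplicates are discarded.  Deterministic
    for a given seed.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        size = int(rng.integers(4, max_heavy + 1))
        symbols = [str(rng.choice(_ATOM_CHOICES)) for _ in range(size)]
        mol = Chem.RWMol()
        free = []
        for i, sym in enumerate(symbols):
            mol.AddAtom(Chem.Atom(sym))
            free.append(_MAX_VALENCE[sym])
            if i == 0:
                continue
            candidates = [j for j in range(i) if free[j] > 0]
            if not candidates:
                break
            j = int(rng.choice(candidates))
            mol.AddBond(i, j, Chem.BondType.SINGLE)
            free[i] -= 1
            free[j] -= 1
        else:
            if rng.random() < ring_probability:
                open_atoms = [i for i in range(size) if free[i] > 0]
                if len(open_atoms) >= 2:
                    i, j = rng.choice(open_atoms, size=2, replace=False)
                    i, j = int(i), int(j)
                    if mol.GetBondBetweenAtoms(i, j) is None:
                        mol.AddBond(i, j, Chem.BondType.SINGLE)
            try:
                m = mol.GetMol()
                Chem.SanitizeMol(m)
            except Exception:
                continue
            smi = Chem.MolToSmiles(m)
            if smi in seen or "." in smi:
                continue
            seen.add(smi)
            out[f"M{len(out):04d}"] = smi
    if len(out) < n:
        raise GeneratorError(f"could only generate {len(out)} of {n} molecules")
    return out
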