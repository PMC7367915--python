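"""Decomposition of dual-site cliffs with single-site analogs.

A dual-site cliff (ds-AC) pairs compounds differing at two substitution
sites.  When the class also contains the two *single-site analogs* — each
carrying one of the highly potent partner's substituents on the weakly
potent partner's background — a four-compound data structure results and
the contribution of each site to cliff formation can be measured:

* delta_1, delta_2 — signed pKi change of introducing each substitution
  alone into the weakly potent compound;
* delta_total — the ds cliff's potency difference.

The effect of combining both substitutions is then classified as
redundant (one substitution accounts for the whole cliff), additive
(delta_total ~ delta_1 + delta_2), synergistic (more than additive) or
compensatory (the combination falls short of the best single
substitution).  The epsilon band separating the categories defaults to
0.3 pKi units, a typical inter-assay noise level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .chem import canonical
from .cliffs import ActivityCliff
from .data_model import ActivityClass
from .mmp import reassemble

log = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.3

EFFECTS = ("redundant", "additive", "synergistic", "compensatory", "undetermined")


@dataclass
class DsCliffContext:
    """A ds cliff together with its (possibly partial) single-site analogs."""

    ds_ac: ActivityCliff
    analog_1: str | None
    analog_2: str | None
    delta_1: float | None
    delta_2: float | None
    delta_total: float
    effect: str = "undetermined"


def find_single_site_analogs(
    ds_ac: ActivityCliff,
    cls: ActivityClass,
    structures: dict[str, str],
) -> tuple[str | None, str | None]:
    """Locate the two single-site analogs of a ds cliff in its class.

    The site-i analog carries the highly potent partner's substituent at
    site i and the weakly potent partner's substituent at the other site.
    Analogs absent from the class, or present without a potency for the
    target, are reported as missing.
    """
    pair = ds_ac.pair
    if pair is None or pair.n_sites != 2:
        raise ValueError("dual-site cliff with a resolved matched pair required")
    subs_high = pair.substituents_of(ds_ac.id_high)
    subs_low = pair.substituents_of(ds_ac.id_low)

    with_pki = set(cls.compound_ids)
    by_smiles = {canonical(structures[cid]): cid for cid in cls.compound_ids
                 if cid in structures}

    analogs: list[str | None] = []
    for site in (0, 1):
        wanted = list(subs_low)
        wanted[site] = subs_high[site]
        smi = canonical(reassemble(pair.core_smiles, wanted))
        cid = by_smiles.get(smi)
        if cid is not None and cid not in with_pki:
            log.info("single-site analog %s lacks a potency for %s; treated as missing",
                     cid, cls.target_id)
            cid = None
        analogs.append(cid)
    return analogs[0], analogs[1]


def classify_effect(
    delta_1: float | None,
    delta_2: float | None,
    delta_total: float,
    epsilon: float = DEFAULT_EPSILON,
    threshold: float = 2.0,
) -> str:
    """Classify the combined effect of the two substitutions.

    Rules, in order (``epsilon`` is the indifference band):

    1. redundant — one substitution alone reaches the cliff threshold and
       accounts for the whole potency difference, while the other is
       inert: max(d1, d2) >= threshold, |delta_total - max| <= eps and
       min(d1, d2) within [-eps, eps];
    2. additive — |d1 + d2 - delta_total| <= eps;
    3. synergistic — delta_total > d1 + d2 + eps;
    4. compensatory — delta_total < max(d1, d2) - eps;
    otherwise undetermined.  Missing deltas give undetermined.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    if delta_1 is None or delta_2 is None:
        return "undetermined"
    lo, hi = sorted((delta_1, delta_2))
    if hi >= threshold and abs(delta_total - hi) <= epsilon and -epsilon <= lo <= epsilon:
        return "redundant"
    if abs(delta_1 + delta_2 - delta_total) <= epsilon:
        return "additive"
    if delta_total > delta_1 + delta_2 + epsilon:
        return "synergistic"
    if delta_total < hi - epsilon:
        return "compensatory"
    return "undetermined"


def analyze_ds_cliff(
    ds_ac: ActivityCliff,
    cls: ActivityClass,
    structures: dict[str, str],
    epsilon: float = DEFAULT_EPSILON,
    threshold: float = 2.0,
) -> DsCliffContext:
    """Build the four-compound context for one ds cliff and classify it."""
    a1, a2 = find_single_site_analogs(ds_ac, cls, structures)
    pki_low = ds_ac.pki_low
    d1 = cls.pki_of(a1) - pki_low if a1 is not None else None
    d2 = cls.pki_of(a2) - pki_low if a2 is not None else None
    effect = classify_effect(d1, d2, ds_ac.delta_pki, epsilon=epsilon, threshold=threshold)
    return DsCliffContext(
        ds_ac=ds_ac,
        analog_1=a1,
        analog_2=a2,
        delta_1=d1,
        delta_2=d2,
        delta_total=ds_ac.delta_pki,
        effect=effect,
    )


def analyze_all(
    acs: Sequence[ActivityCliff],
    cls: ActivityClass,
    structures: dict[str, str],
    epsilon: float = DEFAULT_EPSILON,
    threshold: float = 2.0,
) -> list[DsCliffContext]:
    return [
        analyze_ds_cliff(ac, cls, structures, epsilon=epsilon, threshold=threshold)
        for ac in acs
        if ac.n_sites == 2 and ac.pair is not None
    ]


def quartet_table(contexts: Sequence[DsCliffContext], epsilon: float = DEFAULT_EPSILON) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id_high": c.ds_ac.id_high,
                "id_low": c.ds_ac.id_low,
                "analog_1": c.analog_1,
                "analog_2": c.analog_2,
                "delta_1": None if c.delta_1 is None else round(c.delta_1, 6),
                "delta_2": None if c.delta_2 is None else round(c.delta_2, 6),
                "delta_total": round(c.delta_total, 6),
                "effect": c.effect,
                "epsilon": epsilon,
            }
            for c in contexts
        ],
        columns=[
            "id_high", "id_low", "analog_1", "analog_2",
            "delta_1", "delta_2", "delta_total", "effect", "epsilon",
        ],
    )
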