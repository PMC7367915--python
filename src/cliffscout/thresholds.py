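"""Potency-difference criteria for cliff formation.

Two modes are supported.  The *constant* mode applies one threshold to all
activity classes, by default ΔpKi >= 2 (an at least 100-fold potency
difference).  The *class-dependent* mode derives the threshold from the
class itself: the class potency distribution is first categorized by its
interquartile range (CAT1: IQR < 1, excluded from cliff analysis;
CAT2: 1 <= IQR < 2; CAT3: IQR >= 2), and for CAT2/CAT3 classes the
threshold is the mean of the class's analog-pair potency-difference
distribution plus two standard deviations.

Conventions fixed here so results are reproducible: quartiles use linear
interpolation (the "type 7" estimator); the standard deviation is the
sample (n-1) estimate; cliff comparison is inclusive (ΔpKi >= threshold).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_CONSTANT_THRESHOLD = 2.0  # ΔpKi 2 == 100-fold
DEFAULT_MIN_PAIRS = 10


class IqrCategory(str, enum.Enum):
    CAT1 = "CAT1"  # IQR < 1: too little potency spread, excluded
    CAT2 = "CAT2"  # 1 <= IQR < 2
    CAT3 = "CAT3"  # IQR >= 2


class ThresholdMode(str, enum.Enum):
    CONSTANT = "constant"
    CLASS_DEPENDENT = "class_dependent"


@dataclass(frozen=True)
class ThresholdProfile:
    target_id: str
    mode: ThresholdMode
    threshold: float | None
    iqr: float | None = None
    category: IqrCategory | None = None
    pairdiff_mean: float | None = None
    pairdiff_sd: float | None = None
    n_pairs: int | None = None

    @property
    def excluded(self) -> bool:
        """CAT1 classes carry no class-dependent threshold."""
        return self.mode is ThresholdMode.CLASS_DEPENDENT and self.category is IqrCategory.CAT1


def iqr_category(pkis: Sequence[float]) -> tuple[float, IqrCategory]:
    """Interquartile range (Q3 - Q1, linear interpolation) of a class
    potency distribution and its category."""
    values = np.asarray(pkis, dtype=float)
    if values.size < 4:
        raise ValueError(f"need at least 4 potency values to estimate the IQR, got {values.size}")
    q1, q3 = np.percentile(values, [25, 75])  # numpy default: linear (type 7)
    iqr = float(q3 - q1)
    if iqr < 1.0:
        cat = IqrCategory.CAT1
    elif iqr < 2.0:
        cat = IqrCategory.CAT2
    else:
        cat = IqrCategory.CAT3
    return iqr, cat


def class_threshold(
    pair_diffs: Sequence[float],
    min_pairs: int = DEFAULT_MIN_PAIRS,
    fallback: float = DEFAULT_CONSTANT_THRESHOLD,
    target_id: str = "",
    iqr: float | None = None,
    category: IqrCategory | None = None,
) -> ThresholdProfile:
    """Class-dependent threshold: mean + 2*sd of the absolute pairwise
    potency differences of the class's analog pairs.

    With fewer than ``min_pairs`` differences the estimate is unstable and
    the profile falls back to the constant mode (logged).
    """
    diffs = np.abs(np.asarray(pair_diffs, dtype=float))
    if diffs.size < min_pairs:
        log.warning(
            "class %s: only %d analog-pair differences (< %d); falling back to "
            "constant threshold %.2f",
            target_id, diffs.size, min_pairs, fallback,
        )
        return ThresholdProfile(
            target_id=target_id,
            mode=ThresholdMode.CONSTANT,
            threshold=fallback,
            iqr=iqr,
            category=category,
            n_pairs=int(diffs.size),
        )
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return ThresholdProfile(
        target_id=target_id,
        mode=ThresholdMode.CLASS_DEPENDENT,
        threshold=mean + 2.0 * sd,
        iqr=iqr,
        category=category,
        pairdiff_mean=mean,
        pairdiff_sd=sd,
        n_pairs=int(diffs.size),
    )


def constant_threshold(
    value: float = DEFAULT_CONSTANT_THRESHOLD, target_id: str = ""
) -> ThresholdProfile:
    if not value > 0:
        raise ValueError(f"threshold must be positive, got {value}")
    return ThresholdProfile(
        target_id=target_id, mode=ThresholdMode.CONSTANT, threshold=value
    )


def build_profile(
    target_id: str,
    pkis: Sequence[float],
    pair_diffs: Sequence[float],
    min_pairs: int = DEFAULT_MIN_PAIRS,
    fallback: float = DEFAULT_CONSTANT_THRESHOLD,
) -> ThresholdProfile:
    """Full class-dependent profile: IQR category plus mean+2sd threshold.

    CAT1 classes keep their statistics but are marked excluded from cliff
    analysis (``profile.excluded``).
    """
    iqr, cat = iqr_category(pkis)
    profile = class_threshold(
        pair_diffs, min_pairs=min_pairs, fallback=fallback,
        target_id=target_id, iqr=iqr, category=cat,
    )
    return profile


def profile_report(profiles: Sequence[ThresholdProfile]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "target_id": p.target_id,
                "iqr": p.iqr,
                "category": p.category.value if p.category else None,
                "pairdiff_mean": p.pairdiff_mean,
                "pairdiff_sd": p.pairdiff_sd,
                "n_pairs": p.n_pairs,
                "threshold": p.threshold,
                "mode": p.mode.value,
            }
            for p in profiles
        ]
    )
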