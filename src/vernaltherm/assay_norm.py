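"""Expression and ChIP ratio normalization.

Expression readouts are normalized to a reference gene; ChIP enrichment is a
double ratio (mark/H3 at the target locus over mark/H3 at an internal control
locus), which cancels immunoprecipitation efficiency and input scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

__all__ = [
    "ExpressionMeasurement",
    "ChipMeasurement",
    "ProfileComparison",
    "normalized_expression",
    "chip_double_ratio",
    "profile_comparison",
]


@dataclass(frozen=True)
class ExpressionMeasurement:
    sample_id: str
    target_gene: str
    target_quantity: float
    reference_quantity: float
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        if self.target_quantity <= 0 or self.reference_quantity <= 0:
            raise ContractError("quantities must be strictly positive")


@dataclass(frozen=True)
class ChipMeasurement:
    """Relative recoveries at one primer-pair position across the target locus."""

    sample_id: str
    primer_pair_id: str
    k27_flc: float
    h3_flc: float
    k27_stm: float
    h3_stm: float

    def __post_init__(self) -> None:
        for name in ("k27_flc", "h3_flc", "k27_stm", "h3_stm"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ProfileComparison:
    """Paired per-primer comparison of two ChIP profiles."""

    primer_pairs: tuple[str, ...]
    ratios_a: np.ndarray
    ratios_b: np.ndarray
    differences: np.ndarray
    statistic: float
    pvalue: float
    n_positive: int
    n_negative: int


def normalized_expression(m: ExpressionMeasurement) -> float:
    """Target quantity relative to the reference gene (dimensionless ratio)."""
    return m.target_quantity / m.reference_quantity


def chip_double_ratio(m: ChipMeasurement) -> float:
    """(mark/H3 at target) over (mark/H3 at control locus)."""
    return (m.k27_flc / m.h3_flc) / (m.k27_stm / m.h3_stm)


def profile_comparison(cond_a, cond_b) -> ProfileComparison:
    """Compare two conditions' ChIP profiles paired by primer pair.

    Differences are double ratios of condition A minus condition B at each
    primer position; the Wilcoxon signed-rank statistic and p-value are
    delegated to :func:`scipy.stats.wilcoxon`.
    """
    a = {m.primer_pair_id: m for m in cond_a}
    b = {m.primer_pair_id: m for m in cond_b}
    if set(a) != set(b):
        raise ContractError(
            f"primer-pair sets differ: {sorted(set(a) ^ set(b))} unmatched"
        )
    if len(a) < 2:
        raise ContractError("need >= 2 primer pairs for a paired comparison")
    pairs = tuple(sorted(a))
    ra = np.array([chip_double_ratio(a[p]) for p in pairs])
    rb = np.array([chip_double_ratio(b[p]) for p in pairs])
    diff = ra - rb
    if np.allclose(diff, 0.0):
        statistic, pvalue = 0.0, 1.0
    else:
        statistic, pvalue = stats.wilcoxon(ra, rb, zero_method="wilcox")
    return ProfileComparison(
        primer_pairs=pairs,
        ratios_a=ra,
        ratios_b=rb,
        differences=diff,
        statistic=float(statistic),
        pvalue=float(pvalue),
        n_positive=int((diff > 0).sum()),
        n_negative=int((diff < 0).sum()),
    )
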