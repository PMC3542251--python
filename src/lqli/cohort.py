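"""Cohort-level summaries: pattern frequencies, dual-marker concordance
and chance-corrected interobserver agreement (Cohen's kappa).

Percentages are rounded to the nearest integer, half away from zero; the
rounding rule is applied uniformly and documented because published
frequency tables and prose occasionally disagree at the rounding boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "pattern_frequencies",
    "concordance",
    "cohen_kappa",
    "mean_pairwise_kappa",
]

PATTERNS = (1, 2, 3)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class CohortTable:
    """Per-patient pattern calls, optionally for two markers and several
    raters; backed by a DataFrame with a ``patient_id`` column."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "patient_id" not in self.data.columns:
            raise ValueError("cohort table requires a patient_id column")
        if self.data["patient_id"].duplicated().any():
            raise ValueError("patient ids must be unique")
        for col in self.data.columns:
            if col.startswith("pattern") or col.startswith("rater"):
                vals = self.data[col].dropna()
                if not vals.isin(PATTERNS).all():
                    raise ValueError(f"column {col} contains values outside {{1,2,3}}")

    @classmethod
    def read_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def rater_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("rater")]


def pattern_frequencies(calls) -> dict:
    """Counts and integer percentages per pattern.

    Counts sum exactly to n; percentages are nearest-integer (half away
    from zero) and therefore sum to 100 +- 1.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("pattern_frequencies needs a non-empty list")
    n = len(calls)
    counts = {p: sum(1 for c in calls if c == p) for p in PATTERNS}
    percents = {p: _round_half_away(100.0 * counts[p] / n) for p in PATTERNS}
    return {"n": n, "counts": counts, "percents": percents}


def concordance(a, b) -> dict:
    """Agreement between two pattern vectors (e.g. two markers).

    Returns the concordant count and integer percentage plus a
    cross-table of the off-diagonal (discordant) pairs keyed ``(a, b)``.
    """
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError("pattern vectors must have equal length")
    if not a:
        raise ValueError("concordance needs non-empty vectors")
    n = len(a)
    n_conc = sum(1 for x, y in zip(a, b) if x == y)
    table: dict[tuple, int] = {}
    for x, y in zip(a, b):
        if x != y:
            table[(x, y)] = table.get((x, y), 0) + 1
    return {
        "n": n,
        "n_concordant": n_conc,
        "pct_concordant": _round_half_away(100.0 * n_conc / n),
        "n_discordant": n - n_conc,
        "pct_discordant": _round_half_away(100.0 * (n - n_conc) / n),
        "discordance_table": table,
    }


def cohen_kappa(a, b) -> float:
    """Cohen's kappa between two categorical raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the marginal products.  The degenerate
    case p_e = 1 (both raters constant on the same single category,
    hence p_o = 1) is defined as kappa = 1.
    """
    a, b = np.asarray(list(a)), np.asarray(list(b))
    if a.shape != b.shape or a.size == 0:
        raise ValueError("rater vectors must be non-empty and of equal length")
    n = a.size
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if abs(1.0 - p_e) < 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def mean_pairwise_kappa(calls_by_rater: dict) -> float:
    """Multi-rater agreement pooled as the mean of all pairwise kappas."""
    raters = sorted(calls_by_rater)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    kappas = [
        cohen_kappa(calls_by_rater[r1], calls_by_rater[r2])
        for r1, r2 in itertools.combinations(raters, 2)
    ]
    return float(np.mean(kappas))
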