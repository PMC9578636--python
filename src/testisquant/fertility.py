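"""Per-male fertility classification from daily offspring counts.

Categories follow the standard assay thresholds: a male siring more than
30 offspring in 24 h is Fertile, one siring none is Infertile, and
anything in between is Subfertile. The printed rule leaves a count of
exactly 30 unassigned ("more than 30" vs "less than 30"); this package
classifies exactly 30 as Subfertile (the conservative reading) and exposes
the boundary as a parameter.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["CATEGORIES", "classify_fertility", "fertility_rate"]

CATEGORIES = ("Fertile", "Subfertile", "Infertile")
DEFAULT_FERTILE_BOUNDARY = 30  # strictly more than this => Fertile


def classify_fertility(
    offspring_per_day: int,
    fertile_boundary: int = DEFAULT_FERTILE_BOUNDARY,
) -> str:
    """Classify one male: 0 -> Infertile, 1..boundary -> Subfertile,
    > boundary -> Fertile."""
    if isinstance(offspring_per_day, (bool, float)) or not isinstance(
            offspring_per_day, (int, np.integer)):
        raise ValueError(
            f"offspring count must be a non-negative integer, "
            f"got {offspring_per_day!r}")
    n = int(offspring_per_day)
    if n < 0:
        raise ValueError(f"offspring count must be >= 0, got {n}")
    if n == 0:
        return "Infertile"
    if n > fertile_boundary:
        return "Fertile"
    return "Subfertile"


def fertility_rate(
    records: pd.DataFrame,
    genotype: str,
    fertile_boundary: int = DEFAULT_FERTILE_BOUNDARY,
) -> dict:
    """Percentage of a genotype's males in each fertility category.

    ``records`` needs ``genotype`` and ``offspring_per_day`` columns.
    Returns ``{"genotype", "n", "Fertile", "Subfertile", "Infertile"}``
    with percentages that sum to 100 up to rounding.
    """
    sub = records[records["genotype"] == genotype]
    if len(sub) == 0:
        raise ValueError(f"no records for genotype {genotype!r}")
    cats = [classify_fertility(int(c), fertile_boundary)
            for c in sub["offspring_per_day"]]
    n = len(cats)
    out = {"genotype": genotype, "n": n}
    for cat in CATEGORIES:
        out[cat] = 100.0 * sum(c == cat for c in cats) / n
    return out
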