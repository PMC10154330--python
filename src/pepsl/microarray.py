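"""Duplicate-spot QC and labeling for peptide microarray intensities.

Each printed peptide appears as a duplicate spot pair.  Pairs whose
spot-to-spot deviation exceeds a tolerance are zeroed; surviving pairs are
collapsed to their mean.  Binary binding labels are assigned to the top
fraction of peptides ranked by collapsed intensity, and the right-skewed
intensity scale is log10-transformed before use as a regression response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpotPair:
    """One peptide's duplicate-spot intensities (median foreground, a.u.)."""

    id: str
    intensity_a: float
    intensity_b: float

    def __post_init__(self) -> None:
        if self.intensity_a < 0 or self.intensity_b < 0:
            raise ValueError(f"spot pair {self.id!r}: negative intensity")


def spot_deviation_pct(a: float, b: float) -> float:
    """Spot-to-spot deviation as percent of the pair mean; 0 for two zeros."""
    mean = 0.5 * (a + b)
    if mean == 0:
        return 0.0
    return abs(a - b) / mean * 100.0


def collapse_duplicate_spots(
    pairs: Sequence[SpotPair], max_deviation_pct: float = 40.0
) -> pd.DataFrame:
    """Collapse duplicate spots to their mean, zeroing discordant pairs.

    A pair with deviation strictly greater than ``max_deviation_pct`` is set
    to 0 and flagged (the tolerated maximum itself is kept).  Returns a
    DataFrame indexed by peptide id with columns ``intensity`` and
    ``zeroed``.
    """
    rows = {}
    for p in pairs:
        if p.id in rows:
            raise ValueError(f"duplicate peptide id {p.id!r} in spot table")
        dev = spot_deviation_pct(p.intensity_a, p.intensity_b)
        zeroed = dev > max_deviation_pct
        rows[p.id] = {
            "intensity": 0.0 if zeroed else 0.5 * (p.intensity_a + p.intensity_b),
            "zeroed": zeroed,
        }
    if not rows:
        raise ValueError("no spot pairs provided")
    return pd.DataFrame.from_dict(rows, orient="index")


def read_spot_pairs(source) -> list[SpotPair]:
    """CSV with columns id, intensity_a, intensity_b -> list of SpotPair."""
    df = pd.read_csv(source)
    missing = {"id", "intensity_a", "intensity_b"} - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing column(s): {sorted(missing)}")
    if df[["intensity_a", "intensity_b"]].isna().any().any():
        bad = df.loc[df[["intensity_a", "intensity_b"]].isna().any(axis=1), "id"]
        raise ValueError(f"missing replicate intensity for id(s): {list(bad)[:10]}")
    return [
        SpotPair(str(r.id), float(r.intensity_a), float(r.intensity_b))
        for r in df.itertuples(index=False)
    ]


def label_top_fraction(intensities: pd.Series, fraction: float = 0.2) -> pd.Series:
    """Label the top ``fraction`` of peptides by intensity as positive (1).

    Exactly ``floor(fraction * n)`` peptides are labeled positive; ties at
    the cutoff are broken by stable input order (earlier rows win).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(intensities)
    if n == 0:
        raise ValueError("empty intensity table")
    k = int(np.floor(fraction * n))
    if k == 0:
        logger.warning("fraction %.3f of n=%d yields zero positives", fraction, n)
    order = np.argsort(-intensities.to_numpy(), kind="stable")
    labels = np.zeros(n, dtype=int)
    labels[order[:k]] = 1
    return pd.Series(labels, index=intensities.index, name="label")


def transform_response(intensities, offset: float = 1.0) -> np.ndarray:
    """log10(intensity + offset) response transform; zeroed spots map to 0
    under the default offset of 1."""
    x = np.asarray(intensities, dtype=float)
    if (x < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    return np.log10(x + offset)
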