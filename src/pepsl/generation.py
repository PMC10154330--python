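"""Candidate peptide generation and multi-property screening.

Two generators: uniform random peptides (each letter at 5%) and sampling
from a position-dependent amino-acid frequency matrix (PFM) built from
training peptides grouped into intensity bins.  Generated candidates are
screened through the three fitted property models (binding regression,
penetration and toxicity classification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import (
    AMINO_ACIDS, DescriptorSpec, PeptideRecord, compute_descriptor_matrix,
)

logger = logging.getLogger(__name__)

_AA = np.array(list(AMINO_ACIDS))


def generate_uniform_peptides(
    count: int, length_range: tuple[int, int] = (7, 12), seed: int = 0,
) -> list[str]:
    """Random peptides with every letter at probability 0.05 and lengths
    uniform over ``length_range`` (inclusive)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    if lo < 7:
        logger.warning("lengths below 7 cannot be featurized at lag 6")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=count)
    return ["".join(rng.choice(_AA, size=L)) for L in lengths]


@dataclass
class PositionFrequencyMatrix:
    """Per intensity bin: position x 20 amino-acid probabilities.

    ``probs[b]`` is a (max position, 20) array for bin b; rows for positions
    unsupported in that bin (no training peptide that long) are NaN.
    ``bin_edges`` are the equal-width (or quantile) intensity bin edges.
    """

    probs: list[np.ndarray]
    bin_edges: np.ndarray
    counts: list[int]

    @property
    def n_bins(self) -> int:
        return len(self.probs)

    def supported_length(self, bin_index: int) -> int:
        p = self.probs[bin_index]
        ok = ~np.isnan(p).any(axis=1)
        return int(ok.sum())


def build_pfm(sequences, responses, n_bins: int = 8,
              binning: str = "width") -> PositionFrequencyMatrix:
    """Group peptides into intensity bins and count per-position letter
    frequencies.

    Variable-length peptides contribute to positions up to their own length;
    no padding symbol enters the matrix.
    """
    sequences = list(sequences)
    responses = np.asarray(responses, dtype=float)
    if len(sequences) == 0:
        raise ValueError("empty peptide set")
    if len(sequences) != len(responses):
        raise ValueError("sequences and responses differ in length")
    if binning == "width":
        edges = np.linspace(responses.min(), responses.max(), n_bins + 1)
    elif binning == "quantile":
        edges = np.quantile(responses, np.linspace(0, 1, n_bins + 1))
    else:
        raise ValueError(f"unknown binning {binning!r}")
    bin_of = np.clip(np.digitize(responses, edges[1:-1]), 0, n_bins - 1)
    probs, counts = [], []
    for b in range(n_bins):
        members = [sequences[i] for i in np.flatnonzero(bin_of == b)]
        counts.append(len(members))
        if not members:
            probs.append(np.full((0, 20), np.nan))
            continue
        maxlen = max(len(s) for s in members)
        cnt = np.zeros((maxlen, 20))
        for s in members:
            for pos, a in enumerate(s):
                cnt[pos, AMINO_ACIDS.index(a)] += 1
        tot = cnt.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            probs.append(np.where(tot > 0, cnt / np.maximum(tot, 1), np.nan))
    return PositionFrequencyMatrix(probs=probs, bin_edges=edges, counts=counts)


def sample_pfm_peptides(
    pfm: PositionFrequencyMatrix, bin_index: int, count: int,
    length: int, seed: int = 0,
) -> list[str]:
    """Sample peptides position-independently from a bin's per-position
    letter distributions."""
    if pfm.counts[bin_index] == 0:
        raise ValueError(f"bin {bin_index} is empty")
    if length > pfm.supported_length(bin_index):
        raise ValueError(
            f"length {length} unsupported in bin {bin_index} "
            f"(max {pfm.supported_length(bin_index)})"
        )
    rng = np.random.default_rng(seed)
    p = pfm.probs[bin_index][:length]
    out = []
    for _ in range(count):
        out.append("".join(rng.choice(_AA, p=row) for row in p))
    return out


def screen_candidates(
    sequences, melanin_model, cpp_model, tox_model,
    spec: DescriptorSpec | None = None,
) -> pd.DataFrame:
    """Predict the three engineered properties for candidate sequences.

    Melanin binding is the regression prediction on the percent scale,
    capped at 100 (and floored at 0); the two classifications use each
    model's stored max-F1 threshold.
    """
    spec = spec or DescriptorSpec()
    records = []
    for i, s in enumerate(sequences):
        rec = PeptideRecord(id=f"cand{i + 1}", sequence=s)
        if rec.length < spec.min_length:
            raise ValueError(
                f"candidate {rec.id} ({s!r}) shorter than the minimum "
                f"analyzable length {spec.min_length}"
            )
        records.append(rec)
    mat = compute_descriptor_matrix(records, spec).values
    binding = np.clip(melanin_model.predict(mat), 0.0, 100.0)
    return pd.DataFrame({
        "sequence": list(sequences),
        "melanin_binding_pct": binding,
        "cell_penetrating": cpp_model.predict_label(mat),
        "toxic": tox_model.predict_label(mat),
    }, index=[r.id for r in records])
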