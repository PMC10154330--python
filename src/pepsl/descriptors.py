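"""Peptide sequence parsing and physicochemical descriptor computation.

Turns amino-acid sequences into the numeric variable families used as
machine-learning input throughout the package:

* global physicochemical variables (length, molecular weight, net charge,
  isoelectric point, residue-class compositions, GRAVY, aliphatic index),
* amino-acid composition,
* composition/transition/distribution (CTD) over seven 3-group partitions,
* Moreau–Broto / Moran / Geary autocorrelation up to a lag,
* the 343-dimensional conjoint-triad counts,
* quasi-sequence-order (QSO) with sequence-order coupling numbers,
* pseudo- and amphiphilic pseudo-amino-acid composition (PAAC/APAAC).

All descriptors are deterministic functions of the sequence and a
:class:`DescriptorSpec`; recomputation is bit-identical.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

WATER_MASS = 18.0153

#: Average (isotope-abundance weighted) residue masses in Da.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Kyte–Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Hopp–Woods hydrophilicity.
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}

# pKa sets for Henderson–Hasselbalch charge summation. Keys: termini plus the
# ionizable side chains.  EMBOSS values as used by the EMBOSS `charge`/`iep`
# programs.
PKA_SCALES: dict[str, dict[str, float]] = {
    "EMBOSS": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
}

_POSITIVE_SIDECHAINS = ("K", "R", "H")
_NEGATIVE_SIDECHAINS = ("D", "E", "C", "Y")

# Residue classes (EMBOSS pepstats conventions).
RESIDUE_CLASSES = {
    "tiny": set("ACGST"),
    "small": set("ACDGNPSTV"),
    "aliphatic": set("AILV"),
    "aromatic": set("FHWY"),
    "polar": set("DEHKNQRSTY"),
    "nonpolar": set("ACFGILMPVWY"),
    "charged": set("DEHKR"),
    "basic": set("HKR"),
    "acidic": set("DE"),
}

# CTD: seven physicochemical properties, each partitioning the alphabet into
# three groups (PROFEAT / protr partitions).
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdwvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "PKQEND", "MRSTHY"),
}

# Conjoint-triad residue classification (7 classes by dipole / side-chain
# volume).
CONJOINT_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

DESCRIPTOR_FAMILIES = (
    "global-physicochemical",
    "composition-transition-distribution",
    "autocorrelation",
    "conjoint-triad",
    "quasi-sequence-order",
    "pseudo-AA-composition",
    "amphiphilic-pseudo-AA-composition",
)


class SequenceValidationError(ValueError):
    """A peptide sequence failed alphabet/length validation."""


@dataclass(frozen=True)
class PeptideRecord:
    """A validated peptide with optional response value and class label."""

    id: str
    sequence: str
    response: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - _AA_SET)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-canonical letter(s) {''.join(bad)!r} "
                f"in sequence {self.sequence!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DescriptorSpec:
    """Configuration of the descriptor computation.

    Parameters
    ----------
    families
        Descriptor families to compute (subset of ``DESCRIPTOR_FAMILIES``).
    lag
        Maximum lag for autocorrelation, sequence-order coupling and the
        PAAC/APAAC tiers.  The minimum analyzable sequence length is
        ``lag + 1``.
    pKa_scale
        Named pKa set for charge and isoelectric-point computation.
    pH_for_charge
        pH at which the global net-charge variable is evaluated.
    """

    families: tuple[str, ...] = DESCRIPTOR_FAMILIES
    lag: int = 6
    pKa_scale: str = "EMBOSS"
    pH_for_charge: float = 7.0

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        unknown = set(self.families) - set(DESCRIPTOR_FAMILIES)
        if unknown:
            raise ValueError(f"unknown descriptor families: {sorted(unknown)}")
        if self.pKa_scale not in PKA_SCALES:
            raise ValueError(f"unknown pKa scale {self.pKa_scale!r}")
        object.__setattr__(self, "families", tuple(self.families))

    @property
    def min_length(self) -> int:
        return self.lag + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "families": list(self.families),
                "lag": self.lag,
                "pKa_scale": self.pKa_scale,
                "pH_for_charge": self.pH_for_charge,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DescriptorSpec":
        d = json.loads(text)
        return cls(
            families=tuple(d["families"]),
            lag=int(d["lag"]),
            pKa_scale=d["pKa_scale"],
            pH_for_charge=float(d["pH_for_charge"]),
        )


@dataclass
class DescriptorMatrix:
    """Peptides × named numeric variables, with provenance."""

    values: pd.DataFrame
    spec: DescriptorSpec

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="id")


# ---------------------------------------------------------------------------
# parsing


def parse_peptides(source, fmt: str | None = None) -> list[PeptideRecord]:
    """Read peptides from CSV (columns id, sequence, [response], [label]) or
    FASTA.

    ``source`` may be a path or a file-like object.  ``fmt`` forces the
    format; otherwise it is inferred from the filename extension (default
    CSV).
    """
    if fmt is None:
        name = getattr(source, "name", str(source))
        fmt = "fasta" if str(name).lower().endswith((".fa", ".fasta", ".faa")) else "csv"
    if fmt == "fasta":
        from Bio import SeqIO

        handle = open(source) if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__") else source
        try:
            records = [
                PeptideRecord(id=rec.id, sequence=str(rec.seq).upper())
                for rec in SeqIO.parse(handle, "fasta")
            ]
        finally:
            if handle is not source:
                handle.close()
    elif fmt == "csv":
        df = pd.read_csv(source, dtype={"id": str, "sequence": str})
        if "sequence" not in df.columns:
            raise ValueError("CSV input must contain a 'sequence' column")
        if "id" not in df.columns:
            df["id"] = [f"p{i + 1}" for i in range(len(df))]
        records = []
        for _, row in df.iterrows():
            records.append(
                PeptideRecord(
                    id=str(row["id"]),
                    sequence=str(row["sequence"]).strip().upper(),
                    response=float(row["response"]) if "response" in df.columns and pd.notna(row["response"]) else None,
                    label=int(row["label"]) if "label" in df.columns and pd.notna(row["label"]) else None,
                )
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not records:
        raise ValueError("input contains no peptide records")
    return records


def partition_by_length(
    records: Sequence[PeptideRecord], min_length: int
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Split records into (analyzable, too-short); logs a warning for the
    excluded ones."""
    ok = [r for r in records if r.length >= min_length]
    short = [r for r in records if r.length < min_length]
    if short:
        logger.warning(
            "excluded %d peptide(s) shorter than the minimum analyzable "
            "length %d: %s",
            len(short), min_length, ", ".join(r.id for r in short[:10]),
        )
    return ok, short


# ---------------------------------------------------------------------------
# scalar physicochemical quantities


def _resolve_scale(scale) -> dict[str, float]:
    if isinstance(scale, str):
        try:
            return PKA_SCALES[scale]
        except KeyError:
            raise ValueError(f"unknown pKa scale {scale!r}") from None
    return dict(scale)


def net_charge(sequence: str, pH: float = 7.0, scale="EMBOSS") -> float:
    """Signed net charge by Henderson–Hasselbalch summation.

    Sums fractional positive charges over the N-terminus and K/R/H side
    chains and fractional negative charges over the C-terminus and D/E/C/Y
    side chains, each ``1 / (1 + 10^(±(pH − pKa)))``.
    """
    pka = _resolve_scale(scale)
    counts = {a: sequence.count(a) for a in set(sequence)}
    pos = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    for aa in _POSITIVE_SIDECHAINS:
        n = counts.get(aa, 0)
        if n:
            pos += n / (1.0 + 10.0 ** (pH - pka[aa]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for aa in _NEGATIVE_SIDECHAINS:
        n = counts.get(aa, 0)
        if n:
            neg += n / (1.0 + 10.0 ** (pka[aa] - pH))
    return pos - neg


def isoelectric_point(sequence: str, scale="EMBOSS", tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    c_lo = net_charge(sequence, lo, scale)
    c_hi = net_charge(sequence, hi, scale)
    if c_lo < 0 or c_hi > 0:
        raise ValueError(
            f"net charge of {sequence!r} has no sign change on pH [0, 14]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, scale)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight(sequence: str) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    return sum(RESIDUE_MASS[a] for a in sequence) + WATER_MASS


def aa_class_composition(sequence: str) -> dict[str, float]:
    """Percentage of residues in each physicochemical class."""
    n = len(sequence)
    return {
        cls: 100.0 * sum(1 for a in sequence if a in members) / n
        for cls, members in RESIDUE_CLASSES.items()
    }


def gravy(sequence: str) -> float:
    """Grand average of hydropathy (mean Kyte–Doolittle)."""
    return sum(KYTE_DOOLITTLE[a] for a in sequence) / len(sequence)


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index from A/V/I/L mole fractions."""
    n = len(sequence)
    fa = sequence.count("A") / n
    fv = sequence.count("V") / n
    fil = (sequence.count("I") + sequence.count("L")) / n
    return 100.0 * (fa + 2.9 * fv + 3.9 * fil)


# ---------------------------------------------------------------------------
# descriptor families


def _zscore_scale(scale: Mapping[str, float]) -> dict[str, float]:
    vals = np.array([scale[a] for a in AMINO_ACIDS])
    mu, sd = vals.mean(), vals.std()  # population SD over the 20 letters
    return {a: (scale[a] - mu) / sd for a in AMINO_ACIDS}

_NORM_SCALES = {
    "hydropathy": _zscore_scale(KYTE_DOOLITTLE),
    "hydrophilicity": _zscore_scale(HOPP_WOODS),
    "mass": _zscore_scale(RESIDUE_MASS),
}

# Residue-pair distance matrix for QSO: squared Euclidean distance in the
# z-normalized (hydropathy, hydrophilicity, mass) property space.
_DIST2 = np.zeros((20, 20))
for _i, _a in enumerate(AMINO_ACIDS):
    for _j, _b in enumerate(AMINO_ACIDS):
        _DIST2[_i, _j] = sum(
            (s[_a] - s[_b]) ** 2 for s in _NORM_SCALES.values()
        )


def aa_composition(sequence: str) -> dict[str, float]:
    n = len(sequence)
    return {f"AAC.{a}": sequence.count(a) / n for a in AMINO_ACIDS}


def ctd_descriptors(sequence: str) -> dict[str, float]:
    """Composition, transition and distribution over the 3-group partitions."""
    out: dict[str, float] = {}
    L = len(sequence)
    for prop, groups in CTD_GROUPS.items():
        gmap = {}
        for gi, letters in enumerate(groups, start=1):
            for a in letters:
                gmap[a] = gi
        enc = [gmap[a] for a in sequence]
        # composition
        for gi in (1, 2, 3):
            out[f"CTDC.{prop}.G{gi}"] = enc.count(gi) / L
        # transition (unordered adjacent pairs between distinct groups)
        pairs = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
        for x, y in zip(enc, enc[1:]):
            if x != y:
                pairs[(min(x, y), max(x, y))] += 1
        denom = max(L - 1, 1)
        for (x, y), c in pairs.items():
            out[f"CTDT.{prop}.G{x}{y}"] = c / denom
        # distribution: relative positions (%) of the 1st, 25%, 50%, 75% and
        # last residue of each group
        for gi in (1, 2, 3):
            positions = [i + 1 for i, g in enumerate(enc) if g == gi]
            for q, tag in zip((0.0, 0.25, 0.5, 0.75, 1.0),
                              ("first", "25", "50", "75", "100")):
                if not positions:
                    val = 0.0
                else:
                    idx = max(1, math.ceil(q * len(positions)))
                    val = positions[idx - 1] / L * 100.0
                out[f"CTDD.{prop}.G{gi}.{tag}"] = val
    return out


def conjoint_triad(sequence: str) -> dict[str, float]:
    """343-dimensional conjoint-triad counts (7-class encoding)."""
    cmap = {}
    for ci, letters in enumerate(CONJOINT_CLASSES, start=1):
        for a in letters:
            cmap[a] = ci
    counts = {}
    for i in range(1, 8):
        for j in range(1, 8):
            for k in range(1, 8):
                counts[f"CT.{i}{j}{k}"] = 0
    enc = [cmap[a] for a in sequence]
    for x, y, z in zip(enc, enc[1:], enc[2:]):
        counts[f"CT.{x}{y}{z}"] += 1
    return {k: float(v) for k, v in counts.items()}


def autocorrelation(sequence: str, lag: int) -> dict[str, float]:
    """Normalized Moreau–Broto, Moran and Geary autocorrelation."""
    out: dict[str, float] = {}
    L = len(sequence)
    for sname, scale in _NORM_SCALES.items():
        p = np.array([scale[a] for a in sequence])
        pbar = p.mean()
        dev = p - pbar
        ss = float(dev @ dev)
        for d in range(1, lag + 1):
            head, tail = p[: L - d], p[d:]
            nd = L - d
            out[f"MoreauBroto.{sname}.lag{d}"] = float(head @ tail) / nd
            moran_den = ss / L
            out[f"Moran.{sname}.lag{d}"] = (
                float((head - pbar) @ (tail - pbar)) / nd / moran_den
                if moran_den > 0 else 0.0
            )
            geary_den = ss / (L - 1) if L > 1 else 0.0
            out[f"Geary.{sname}.lag{d}"] = (
                float(((head - tail) ** 2).sum()) / (2 * nd) / geary_den
                if geary_den > 0 else 0.0
            )
    return out


def sequence_order_coupling(sequence: str, lag: int) -> list[float]:
    """tau_d = sum_i d(s_i, s_{i+d})^2 for d = 1..lag."""
    enc = [_AA_INDEX[a] for a in sequence]
    taus = []
    for d in range(1, lag + 1):
        taus.append(float(sum(_DIST2[i, j] for i, j in zip(enc, enc[d:]))))
    return taus


def qso_descriptors(sequence: str, lag: int, weight: float = 0.1) -> dict[str, float]:
    taus = sequence_order_coupling(sequence, lag)
    out = {f"SOCN.lag{d}": t for d, t in enumerate(taus, start=1)}
    counts = {a: float(sequence.count(a)) for a in AMINO_ACIDS}
    denom = sum(counts.values()) + weight * sum(taus)
    for a in AMINO_ACIDS:
        out[f"QSO.{a}"] = counts[a] / denom
    for d, t in enumerate(taus, start=1):
        out[f"QSO.tau{d}"] = weight * t / denom
    return out


def _paac_theta(sequence: str, lag: int, scales) -> list[float]:
    L = len(sequence)
    thetas = []
    for d in range(1, lag + 1):
        s = 0.0
        for i in range(L - d):
            a, b = sequence[i], sequence[i + d]
            s += sum((sc[b] - sc[a]) ** 2 for sc in scales) / len(scales)
        thetas.append(s / (L - d))
    return thetas


def paac_descriptors(sequence: str, lag: int, weight: float = 0.05) -> dict[str, float]:
    """Pseudo-amino-acid composition (Chou), tiers up to ``lag``."""
    scales = list(_NORM_SCALES.values())
    thetas = _paac_theta(sequence, lag, scales)
    counts = {a: float(sequence.count(a)) for a in AMINO_ACIDS}
    denom = sum(counts.values()) + weight * sum(thetas)
    out = {f"PAAC.{a}": counts[a] / denom for a in AMINO_ACIDS}
    for d, th in enumerate(thetas, start=1):
        out[f"PAAC.lambda{d}"] = weight * th / denom
    return out


def apaac_descriptors(sequence: str, lag: int, weight: float = 0.05) -> dict[str, float]:
    """Amphiphilic PAAC: separate hydropathy and hydrophilicity correlations."""
    L = len(sequence)
    taus: list[tuple[str, int, float]] = []
    for sname in ("hydropathy", "hydrophilicity"):
        sc = _NORM_SCALES[sname]
        for d in range(1, lag + 1):
            s = sum(sc[sequence[i]] * sc[sequence[i + d]] for i in range(L - d))
            taus.append((sname, d, s / (L - d)))
    counts = {a: float(sequence.count(a)) for a in AMINO_ACIDS}
    denom = sum(counts.values()) + weight * sum(abs(t) for _, _, t in taus)
    out = {f"APAAC.{a}": counts[a] / denom for a in AMINO_ACIDS}
    for sname, d, t in taus:
        out[f"APAAC.{sname}.lambda{d}"] = weight * t / denom
    return out


def global_descriptors(sequence: str, spec: DescriptorSpec) -> dict[str, float]:
    out = {
        "global.length": float(len(sequence)),
        "global.mw": molecular_weight(sequence),
        "global.net_charge": net_charge(sequence, spec.pH_for_charge, spec.pKa_scale),
        "global.pI": isoelectric_point(sequence, spec.pKa_scale),
        "global.gravy": gravy(sequence),
        "global.aliphatic_index": aliphatic_index(sequence),
    }
    for cls, pct in aa_class_composition(sequence).items():
        out[f"global.pct_{cls}"] = pct
    return out


_FAMILY_FUNCS = {
    "global-physicochemical": lambda seq, spec: {
        **global_descriptors(seq, spec), **aa_composition(seq)
    },
    "composition-transition-distribution": lambda seq, spec: ctd_descriptors(seq),
    "autocorrelation": lambda seq, spec: autocorrelation(seq, spec.lag),
    "conjoint-triad": lambda seq, spec: conjoint_triad(seq),
    "quasi-sequence-order": lambda seq, spec: qso_descriptors(seq, spec.lag),
    "pseudo-AA-composition": lambda seq, spec: paac_descriptors(seq, spec.lag),
    "amphiphilic-pseudo-AA-composition": lambda seq, spec: apaac_descriptors(seq, spec.lag),
}


def compute_descriptor_matrix(
    records: Sequence[PeptideRecord], spec: DescriptorSpec | None = None
) -> DescriptorMatrix:
    """Compute the configured descriptor families for every record.

    Raises
    ------
    SequenceValidationError
        If any sequence is shorter than ``spec.min_length`` (use
        :func:`partition_by_length` beforehand to exclude such records).
    """
    spec = spec or DescriptorSpec()
    too_short = [r.id for r in records if r.length < spec.min_length]
    if too_short:
        raise SequenceValidationError(
            f"sequences shorter than the minimum analyzable length "
            f"{spec.min_length}: {', '.join(too_short[:10])}"
        )
    rows = []
    for rec in records:
        row: dict[str, float] = {}
        for fam in spec.families:
            row.update(_FAMILY_FUNCS[fam](rec.sequence, spec))
        rows.append(row)
    df = pd.DataFrame(rows, index=[r.id for r in records])
    return DescriptorMatrix(values=df, spec=spec)
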