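"""Stateless per-window sequence encoders: EAAC, EGAAC, DDE and pKa.

All encoders consume a single :class:`~malosite.sequence_io.PeptideWindow`
and emit a named real-valued feature vector. Pad positions (``X``) are
excluded from every count and denominator: padding carries no
compositional signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from malosite.sequence_io import AMINO_ACIDS, PAD, PeptideWindow

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Five physicochemical residue groups partitioning the 20-residue alphabet:
#: aliphatic, aromatic, positively charged, negatively charged, neutral.
#: G belongs to the aliphatic group only.
EGAAC_GROUPS: dict[str, str] = {
    "g1.aliphatic": "GAVLMI",
    "g2.aromatic": "FYW",
    "g3.positive": "KRH",
    "g4.negative": "DE",
    "g5.neutral": "STCPNQ",
}


@dataclass(frozen=True)
class EncoderOutput:
    """A named feature vector produced by one encoder on one window."""

    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.values):
            raise ValueError("feature_names and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("encoder output contains NaN/Inf")


@dataclass(frozen=True)
class CodonTable:
    """Sense-codon multiplicities of the standard genetic code (61 total)."""

    codons_per_residue: dict[str, int] = field(
        default_factory=lambda: {
            "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
            "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
            "T": 4, "V": 4, "W": 1, "Y": 2,
        }
    )

    def __post_init__(self) -> None:
        if set(self.codons_per_residue) != set(AMINO_ACIDS):
            raise ValueError("codon table must cover exactly the 20 residues")
        if sum(self.codons_per_residue.values()) != self.total_codons:
            raise ValueError("codon counts must sum to 61 sense codons")

    @property
    def total_codons(self) -> int:
        return 61


#: Per-residue pKa values. Residues with an ionizable side chain carry its
#: pKa; the rest carry the mean of their free-amino-acid alpha-amino and
#: alpha-carboxyl pKa values (CRC/Lehninger tables), so every residue
#: contributes a value on the same 0-14 scale.
_DEFAULT_PKA: dict[str, float] = {
    "D": 3.65, "E": 4.25, "H": 6.00, "C": 8.18, "Y": 10.07, "K": 10.53,
    "R": 12.48,
    "A": 6.02, "G": 5.97, "V": 5.97, "L": 5.98, "I": 6.02, "M": 5.75,
    "F": 5.48, "W": 5.89, "S": 5.68, "T": 5.87, "N": 5.41, "Q": 5.65,
    "P": 6.48,
}


@dataclass(frozen=True)
class PkaTable:
    """Map residue -> pKa (negative log of the dissociation constant)."""

    pka_per_residue: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PKA))
    version: str = "side-chain+alpha-mean v1"

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.pka_per_residue)
        if missing:
            raise ValueError(f"pKa table missing residues: {sorted(missing)}")
        for aa, v in self.pka_per_residue.items():
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa for {aa} out of (0, 14): {v}")


def _subwindow_freqs(residues: str, starts: range, length: int) -> np.ndarray:
    """Per-subwindow residue frequencies, (n_subwindows, 20).

    Each subwindow is normalized by its non-pad length; an all-pad
    subwindow contributes a zero row.
    """
    rows = np.zeros((len(starts), 20))
    for k, s in enumerate(starts):
        sub = residues[s:s + length]
        npad = sum(1 for r in sub if r != PAD)
        if npad == 0:
            logger.warning("subwindow at %d is all-pad; zero row emitted", s)
            continue
        for r in sub:
            if r != PAD:
                rows[k, AA_INDEX[r]] += 1.0
        rows[k] /= npad
    return rows


def encode_eaac(
    window: PeptideWindow,
    subwindow_length: int = 5,
    stride: int = 1,
    collapse: str = "mean",
) -> EncoderOutput:
    """Enhanced amino-acid composition over sliding subwindows.

    For each subwindow, the frequency of each residue type is its count
    divided by the subwindow's non-pad length. With ``collapse="mean"``
    (default) the per-subwindow frequencies are averaged into a 20-vector;
    ``collapse="concat"`` keeps every subwindow (20 x n_subwindows values).
    """
    if subwindow_length > window.length:
        raise ValueError("subwindow_length exceeds window length")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = range(0, window.length - subwindow_length + 1, stride)
    rows = _subwindow_freqs(window.residues, starts, subwindow_length)
    if collapse == "mean":
        names = tuple(f"EAAC:{aa}" for aa in AMINO_ACIDS)
        return EncoderOutput(names, rows.mean(axis=0))
    if collapse == "concat":
        names = tuple(
            f"EAAC:win{k}:{aa}" for k in range(len(starts)) for aa in AMINO_ACIDS
        )
        return EncoderOutput(names, rows.ravel())
    raise ValueError(f"unknown collapse mode {collapse!r}")


def encode_egaac(
    window: PeptideWindow,
    subwindow_length: int = 5,
    stride: int = 3,
    pad_to_fit: bool = True,
) -> EncoderOutput:
    """Enhanced grouped amino-acid composition over strided subwindows.

    Residues are pooled into five physicochemical groups
    (:data:`EGAAC_GROUPS`); each subwindow placement yields five group
    frequencies normalized by non-pad length. With the defaults on a
    25-mer (length 5, stride 3, right-padding the final placement) there
    are 9 placements, giving a 45-length vector.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    residues = window.residues
    if pad_to_fit:
        starts = range(0, window.length, stride)
        residues = residues + PAD * subwindow_length
    else:
        starts = range(0, window.length - subwindow_length + 1, stride)
    group_of = {
        aa: gi for gi, members in enumerate(EGAAC_GROUPS.values()) for aa in members
    }
    values = np.zeros(len(starts) * 5)
    names = []
    for k, s in enumerate(starts):
        sub = residues[s:s + subwindow_length]
        npad = sum(1 for r in sub if r != PAD)
        counts = np.zeros(5)
        for r in sub:
            if r != PAD:
                counts[group_of[r]] += 1.0
        if npad > 0:
            counts /= npad
        else:
            logger.warning("EGAAC placement at %d is all-pad; zero block", s)
        values[k * 5:(k + 1) * 5] = counts
        names.extend(f"EGAAC:win{k}:{g}" for g in EGAAC_GROUPS)
    return EncoderOutput(tuple(names), values)


def encode_dde(window: PeptideWindow, codons: CodonTable | None = None) -> EncoderOutput:
    """Dipeptide deviation from expected mean, 400 values ordered (m, n).

    Observed overlapping dipeptide frequencies DC(m,n) = H_mn / (H - 1),
    with H the number of non-pad residues, are standardized against the
    codon-usage expectation TM(m,n) = (C_m / 61)(C_n / 61) with variance
    TV = TM (1 - TM) / (H - 1):  DDE = (DC - TM) / sqrt(TV).
    """
    codons = codons or CodonTable()
    seq = [r for r in window.residues if r != PAD]
    h = len(seq)
    if h < 2:
        raise ValueError("DDE requires at least 2 non-pad residues")
    dc = np.zeros((20, 20))
    for a, b in zip(window.residues, window.residues[1:]):
        if a != PAD and b != PAD:
            dc[AA_INDEX[a], AA_INDEX[b]] += 1.0
    dc /= h - 1
    c = np.array([codons.codons_per_residue[aa] for aa in AMINO_ACIDS], dtype=float)
    c /= codons.total_codons
    tm = np.outer(c, c)
    tv = tm * (1.0 - tm) / (h - 1)
    dde = (dc - tm) / np.sqrt(tv)
    names = tuple(f"DDE:{m}{n}" for m in AMINO_ACIDS for n in AMINO_ACIDS)
    return EncoderOutput(names, dde.ravel())


def encode_pka(
    window: PeptideWindow,
    table: PkaTable | None = None,
    aggregate: str = "mean",
) -> EncoderOutput:
    """Single pKa feature: aggregate of per-residue pKa over non-pad positions."""
    table = table or PkaTable()
    vals = [table.pka_per_residue[r] for r in window.residues if r != PAD]
    if not vals:
        raise ValueError("all-pad window has no pKa")
    if aggregate == "mean":
        v = math.fsum(vals) / len(vals)
    elif aggregate == "sum":
        v = math.fsum(vals)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return EncoderOutput((f"PKA:{aggregate}",), np.array([v]))


#: Registry of the stateless encoders by canonical name. Corpus-fitted
#: encoders (TF-IDF, TF-CRF, PSSM) live in :mod:`malosite.corpus_encoders`.
STATELESS_ENCODERS = {
    "EAAC": encode_eaac,
    "EGAAC": encode_egaac,
    "DDE": encode_dde,
    "PKA": encode_pka,
}
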