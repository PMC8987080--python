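"""Corpus-fitted encoders: TF-IDF, TF-CRF and PSSM.

These encoders follow a strict fit/transform contract: fitting reads
training windows (and labels, where the weighting is class-aware), while
transforming reads only the residues of the window being encoded. In a
cross-validation loop the fit step must see training folds only.

Terms are the 20 single amino acids; each peptide window plays the role of
a document. Pad positions are excluded from all counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from malosite.encoders import AA_INDEX, EncoderOutput
from malosite.sequence_io import AMINO_ACIDS, PAD, PeptideWindow, SiteDataset

logger = logging.getLogger(__name__)

UNIFORM_BACKGROUND: dict[str, float] = {aa: 0.05 for aa in AMINO_ACIDS}


# ---------------------------------------------------------------------------
# TF-IDF


@dataclass(frozen=True)
class IdfWeights:
    """Inverse-document-frequency table learned from a training corpus."""

    idf_per_term: dict[str, float]
    corpus_size: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.idf_per_term.values()):
            raise ValueError("IDF weights must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"idf_per_term": self.idf_per_term, "corpus_size": self.corpus_size},
                indent=2, sort_keys=True,
            ) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "IdfWeights":
        d = json.loads(Path(path).read_text())
        return cls(idf_per_term=d["idf_per_term"], corpus_size=d["corpus_size"])


def fit_tfidf(train: SiteDataset) -> IdfWeights:
    """Learn IDF(t) = ln(|D| / DF(t)) from window-level presence counts.

    DF(t) counts training windows containing residue t at least once. A
    term absent from the whole corpus (DF = 0) gets IDF = ln(|D| / 1), the
    add-one fallback, with a logged notice.
    """
    n = len(train)
    if n == 0:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    df = dict.fromkeys(AMINO_ACIDS, 0)
    for w in train:
        for aa in set(w.residues) - {PAD}:
            df[aa] += 1
    idf = {}
    for aa in AMINO_ACIDS:
        if df[aa] == 0:
            logger.info("term %s absent from corpus; IDF via add-one", aa)
        idf[aa] = math.log(n / max(df[aa], 1))
    return IdfWeights(idf_per_term=idf, corpus_size=n)


def transform_tfidf(window: PeptideWindow, weights: IdfWeights) -> EncoderOutput:
    """TF-IDF(t, d) = TF(t, d) x IDF(t); 20 values, one per residue type."""
    npad = window.non_pad_count()
    values = np.zeros(20)
    for r in window.residues:
        if r != PAD:
            values[AA_INDEX[r]] += 1.0
    if npad:
        values /= npad
    values *= np.array([weights.idf_per_term[aa] for aa in AMINO_ACIDS])
    return EncoderOutput(tuple(f"TFIDF:{aa}" for aa in AMINO_ACIDS), values)


# ---------------------------------------------------------------------------
# TF-CRF


def crf_value(
    n_in_class_with_term: int,
    n_in_class: int,
    n_out_class_with_term: int,
    n_out_class: int,
    smoothing: float = 1.0,
) -> float:
    """Category relevancy factor: positiveRF / negativeRF.

    positiveRF is the smoothed fraction of in-class windows containing the
    term; negativeRF the same on the out-class windows. Laplace smoothing
    ``s`` keeps the ratio finite and strictly positive:
    ``(count + s) / (total + 2 s)``.
    """
    if n_in_class == 0 and n_out_class == 0:
        raise ValueError("both class sizes are zero")
    if not (0 <= n_in_class_with_term <= n_in_class):
        raise ValueError("in-class counts inconsistent")
    if not (0 <= n_out_class_with_term <= n_out_class):
        raise ValueError("out-class counts inconsistent")
    s = smoothing
    pos_rf = (n_in_class_with_term + s) / (n_in_class + 2 * s)
    neg_rf = (n_out_class_with_term + s) / (n_out_class + 2 * s)
    return pos_rf / neg_rf


@dataclass(frozen=True)
class CrfWeights:
    """crfValue per (residue, class), with the smoothing used to fit it."""

    crf_per_term_class: dict[tuple[str, str], float]
    smoothing: float
    class_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for k, v in self.crf_per_term_class.items():
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"crfValue for {k} not positive finite: {v}")

    def to_json(self, path: str | Path) -> None:
        flat = {f"{t}|{c}": v for (t, c), v in self.crf_per_term_class.items()}
        Path(path).write_text(
            json.dumps(
                {"crf": flat, "smoothing": self.smoothing, "class_sizes": self.class_sizes},
                indent=2, sort_keys=True,
            ) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CrfWeights":
        d = json.loads(Path(path).read_text())
        crf = {tuple(k.split("|")): v for k, v in d["crf"].items()}
        return cls(crf_per_term_class=crf, smoothing=d["smoothing"],  # type: ignore[arg-type]
                   class_sizes=d["class_sizes"])


def fit_tfcrf(train: SiteDataset, smoothing: float = 1.0) -> CrfWeights:
    """Learn crfValue(t, c) for every residue and class from presence counts."""
    labels = set(train.labels())
    if len(labels) < 2:
        raise ValueError("TF-CRF requires at least two classes in the corpus")
    class_sizes = train.class_counts
    presence: dict[str, dict[str, int]] = {c: dict.fromkeys(AMINO_ACIDS, 0) for c in labels}
    for w in train:
        for aa in set(w.residues) - {PAD}:
            presence[w.label][aa] += 1
    crf = {}
    for c in labels:
        n_in = class_sizes[c]
        n_out = sum(v for k, v in class_sizes.items() if k != c)
        for aa in AMINO_ACIDS:
            a_in = presence[c][aa]
            a_out = sum(presence[k][aa] for k in labels if k != c)
            crf[(aa, c)] = crf_value(a_in, n_in, a_out, n_out, smoothing)
    return CrfWeights(crf_per_term_class=crf, smoothing=smoothing, class_sizes=class_sizes)


def transform_tfcrf(
    window: PeptideWindow,
    weights: CrfWeights,
    reference_class: str = "positive",
) -> EncoderOutput:
    """Class-blind TF-CRF weights, L2-normalized over the 20 terms.

    The raw weight of term t is ``log(max(tf, eps) * crfValue(t, ref))``
    with ``eps = 1 / (2 L)`` guarding zero term frequencies, then the
    vector is divided by its Euclidean norm. The class-conditional
    crfValue of a fixed reference class (default positive) is used for
    every window, since the true class is unknown at inference.
    """
    L = window.length
    eps = 1.0 / (2 * L)
    npad = window.non_pad_count()
    counts = np.zeros(20)
    for r in window.residues:
        if r != PAD:
            counts[AA_INDEX[r]] += 1.0
    tf = counts / npad if npad else counts
    raw = np.array([
        math.log(max(tf[i], eps) * weights.crf_per_term_class[(aa, reference_class)])
        for i, aa in enumerate(AMINO_ACIDS)
    ])
    norm = float(np.linalg.norm(raw))
    if norm == 0.0:
        logger.warning("all-zero raw TF-CRF weights; emitting zero vector")
        values = raw
    else:
        values = raw / norm
    return EncoderOutput(tuple(f"TFCRF:{aa}" for aa in AMINO_ACIDS), values)


# ---------------------------------------------------------------------------
# PSSM


@dataclass(frozen=True)
class PssmModel:
    """Per-position log2 odds of residue occurrence vs a background model."""

    log_odds: np.ndarray  # L x 20
    background: dict[str, float] = field(default_factory=lambda: dict(UNIFORM_BACKGROUND))
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 20:
            raise ValueError("log_odds must be L x 20")
        b = np.array([self.background[aa] for aa in AMINO_ACIDS])
        probs = (2.0 ** self.log_odds) * b
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PSSM probability rows must sum to 1")

    @property
    def window_length(self) -> int:
        return self.log_odds.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.log_odds, columns=list(AMINO_ACIDS),
            index=pd.RangeIndex(1, self.window_length + 1, name="position"),
        ).to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path,
        background: dict[str, float] | None = None,
        pseudo_count: float = 1.0,
    ) -> "PssmModel":
        """Load an externally computed profile matrix (L rows x 20 named columns)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df[list(AMINO_ACIDS)]
        return cls(log_odds=df.to_numpy(float),
                   background=background or dict(UNIFORM_BACKGROUND),
                   pseudo_count=pseudo_count)


def fit_pssm(
    train_positive: SiteDataset,
    background: dict[str, float] | None = None,
    pseudo_count: float = 1.0,
) -> PssmModel:
    """Estimate a position-specific scoring matrix from positive windows.

    Per position i and residue j, the occurrence probability is the
    pseudo-count-smoothed empirical frequency
    ``M_ij = (count_ij + pc * b_j) / (n_eff_i + pc)`` with pad positions
    excluded, and the score is ``log2(M_ij / b_j)``.
    """
    if len(train_positive) == 0:
        raise ValueError("cannot fit a PSSM on an empty positive set")
    background = background or dict(UNIFORM_BACKGROUND)
    L = train_positive.window_length
    b = np.array([background[aa] for aa in AMINO_ACIDS])
    counts = np.zeros((L, 20))
    n_eff = np.zeros(L)
    for w in train_positive:
        for i, r in enumerate(w.residues):
            if r != PAD:
                counts[i, AA_INDEX[r]] += 1.0
                n_eff[i] += 1.0
    m = (counts + pseudo_count * b) / (n_eff[:, None] + pseudo_count)
    return PssmModel(log_odds=np.log2(m / b), background=background,
                     pseudo_count=pseudo_count)


def transform_pssm(
    window: PeptideWindow,
    model: PssmModel,
    mode: str = "composition400",
) -> EncoderOutput:
    """Score a window against a PSSM.

    ``composition400``: for each residue type r and matrix column j, sum
    the log-odds ``log_odds[i, j]`` over the positions i where the window
    carries r — a 400-length residue-grouped profile composition.
    ``flattenLx20``: the L x 20 per-position score matrix with row i
    masked to the residue the window carries there, flattened row-major
    (pad rows stay zero).
    """
    if window.length != model.window_length:
        raise ValueError(
            f"window length {window.length} != PSSM length {model.window_length}"
        )
    if mode == "composition400":
        out = np.zeros((20, 20))
        for i, r in enumerate(window.residues):
            if r != PAD:
                out[AA_INDEX[r]] += model.log_odds[i]
        names = tuple(f"PSSM:{r}:{j}" for r in AMINO_ACIDS for j in AMINO_ACIDS)
        return EncoderOutput(names, out.ravel())
    if mode == "flattenLx20":
        out = np.zeros((model.window_length, 20))
        for i, r in enumerate(window.residues):
            if r != PAD:
                j = AA_INDEX[r]
                out[i, j] = model.log_odds[i, j]
        names = tuple(
            f"PSSM:pos{i + 1}:{j}" for i in range(model.window_length) for j in AMINO_ACIDS
        )
        return EncoderOutput(names, out.ravel())
    raise ValueError(f"unknown PSSM mode {mode!r}")
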