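"""Dataset-level featurization: encoder configs and a fit/transform extractor.

Binds the per-window encoders into a single object with a train-only fit
step (needed by TF-IDF, TF-CRF and the PSSM) and a class-blind transform,
so cross-validation folds can encode without label leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from malosite import corpus_encoders as ce
from malosite import encoders as enc
from malosite.preprocess_select import FeatureMatrix, combine_features
from malosite.sequence_io import PeptideWindow, SiteDataset

#: Canonical encoder names accepted by :class:`FeatureExtractor`.
ENCODER_NAMES = ("EAAC", "EGAAC", "DDE", "PKA", "TFIDF", "TFCRF", "PSSM")

#: The feature combinations studied with the pipeline: grouped amino-acid
#: composition plus the two term-weighting schemes; composition plus pKa,
#: profile and class-aware weighting; and the union of the two.
NAMED_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "combo1": ("TFCRF", "EGAAC", "TFIDF"),
    "combo2": ("EAAC", "PKA", "PSSM", "TFCRF"),
    "combo3": ("EAAC", "PKA", "PSSM", "TFCRF", "EGAAC"),
    "all": ENCODER_NAMES,
}


@dataclass(frozen=True)
class EncoderConfig:
    """One encoder by canonical name plus its keyword parameters."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ENCODER_NAMES:
            raise ValueError(f"unknown encoder {self.name!r}; known: {ENCODER_NAMES}")


def _as_config(spec: "str | EncoderConfig") -> EncoderConfig:
    return spec if isinstance(spec, EncoderConfig) else EncoderConfig(spec)


class FeatureExtractor:
    """Fit corpus-dependent encoders on training windows, transform any windows.

    Parameters
    ----------
    encoders:
        Encoder names or :class:`EncoderConfig` objects. Stateless encoders
        (EAAC, EGAAC, DDE, PKA) need no fitting; TFIDF/TFCRF/PSSM learn
        their weights from the training corpus (TFCRF from its labels,
        PSSM from its positive windows only).
    """

    def __init__(self, encoders: Sequence["str | EncoderConfig"] = ("EAAC",)):
        self.configs = [_as_config(e) for e in encoders]
        if not self.configs:
            raise ValueError("at least one encoder required")
        self.idf_: ce.IdfWeights | None = None
        self.crf_: ce.CrfWeights | None = None
        self.pssm_: ce.PssmModel | None = None
        self._fitted = False

    @property
    def encoder_names(self) -> list[str]:
        return [c.name for c in self.configs]

    def fit(self, train: SiteDataset) -> "FeatureExtractor":
        names = set(self.encoder_names)
        if "TFIDF" in names:
            self.idf_ = ce.fit_tfidf(train)
        if "TFCRF" in names:
            cfg = next(c for c in self.configs if c.name == "TFCRF")
            self.crf_ = ce.fit_tfcrf(
                train, smoothing=cfg.params.get("smoothing", 1.0)
            )
        if "PSSM" in names:
            cfg = next(c for c in self.configs if c.name == "PSSM")
            positives = SiteDataset([w for w in train if w.label == "positive"])
            self.pssm_ = ce.fit_pssm(
                positives,
                background=cfg.params.get("background"),
                pseudo_count=cfg.params.get("pseudo_count", 1.0),
            )
        self._fitted = True
        return self

    def _encode_window(self, cfg: EncoderConfig, w: PeptideWindow) -> enc.EncoderOutput:
        p = dict(cfg.params)
        if cfg.name == "EAAC":
            return enc.encode_eaac(w, **p)
        if cfg.name == "EGAAC":
            return enc.encode_egaac(w, **p)
        if cfg.name == "DDE":
            return enc.encode_dde(w)
        if cfg.name == "PKA":
            return enc.encode_pka(w, aggregate=p.get("aggregate", "mean"))
        if cfg.name == "TFIDF":
            assert self.idf_ is not None
            return ce.transform_tfidf(w, self.idf_)
        if cfg.name == "TFCRF":
            assert self.crf_ is not None
            return ce.transform_tfcrf(
                w, self.crf_, reference_class=p.get("reference_class", "positive")
            )
        assert self.pssm_ is not None
        return ce.transform_pssm(w, self.pssm_, mode=p.get("mode", "composition400"))

    def transform(self, data: SiteDataset) -> FeatureMatrix:
        """Encode every window; columns are namespaced by encoder."""
        if not self._fitted:
            raise RuntimeError("FeatureExtractor.transform called before fit")
        if len(data) == 0:
            raise ValueError("cannot transform an empty dataset")
        row_ids = [f"{i}:{w.protein_id or 'win'}" for i, w in enumerate(data)]
        labels = data.labels()
        parts = []
        for cfg in self.configs:
            outs = [self._encode_window(cfg, w) for w in data]
            names = outs[0].feature_names
            values = np.vstack([o.values for o in outs])
            parts.append(
                FeatureMatrix(
                    row_ids=row_ids,
                    feature_names=list(names),
                    values=values,
                    labels=labels,
                )
            )
        return combine_features(parts)

    def fit_transform(self, train: SiteDataset) -> FeatureMatrix:
        return self.fit(train).transform(train)
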