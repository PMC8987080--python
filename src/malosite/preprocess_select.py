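"""Feature-matrix assembly, z-score normalization and Fisher-score selection.

The feature matrix keeps encoder-namespaced column names so that any
selected subset can be traced back to the encoder and residue/position it
came from. Normalization and selection both follow a fit-on-train /
transform-anywhere contract for leak-free cross-validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """Rows = peptide windows, columns = named real-valued features."""

    row_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = pd.Index(self.feature_names)
            raise ValueError(
                f"duplicate feature names: {sorted(set(dupes[dupes.duplicated()]))[:5]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")
        if self.labels is not None and len(self.labels) != len(self.row_ids):
            raise ValueError("labels length mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_names)

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            row_ids=list(self.row_ids),
            feature_names=list(names),
            values=self.values[:, idx],
            labels=list(self.labels) if self.labels is not None else None,
        )

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            row_ids=[self.row_ids[i] for i in indices],
            feature_names=list(self.feature_names),
            values=self.values[list(indices)],
            labels=[self.labels[i] for i in indices] if self.labels is not None else None,
        )


def combine_features(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of encoder outputs over the same rows."""
    if not parts:
        raise ValueError("no parts to combine")
    first = parts[0]
    for p in parts[1:]:
        if p.row_ids != first.row_ids:
            raise ValueError("row ids differ between feature parts")
        if p.labels != first.labels:
            raise ValueError("labels differ between feature parts")
    names: list[str] = []
    for p in parts:
        names.extend(p.feature_names)
    return FeatureMatrix(
        row_ids=list(first.row_ids),
        feature_names=names,
        values=np.hstack([p.values for p in parts]),
        labels=list(first.labels) if first.labels is not None else None,
    )


@dataclass(frozen=True)
class ScalerState:
    """Per-feature mean and population standard deviation."""

    mean_per_feature: np.ndarray
    sd_per_feature: np.ndarray

    def __post_init__(self) -> None:
        if self.mean_per_feature.shape != self.sd_per_feature.shape:
            raise ValueError("mean/sd length mismatch")
        if np.any(self.sd_per_feature < 0):
            raise ValueError("negative standard deviation")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"mean": self.mean_per_feature.tolist(), "sd": self.sd_per_feature.tolist()},
                indent=2,
            ) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean"], float), np.asarray(d["sd"], float))


def zscore_fit(train: FeatureMatrix) -> ScalerState:
    """Fit z = (x - mu) / sigma, sigma the population (divide-by-n) sd."""
    if train.n_rows == 0:
        raise ValueError("cannot fit scaler on empty matrix")
    return ScalerState(
        mean_per_feature=train.values.mean(axis=0),
        sd_per_feature=train.values.std(axis=0, ddof=0),
    )


def zscore_transform(m: FeatureMatrix, s: ScalerState) -> FeatureMatrix:
    """Standardize columns; constant columns (sigma = 0) map to exactly 0."""
    if len(s.mean_per_feature) != m.n_features:
        raise ValueError("scaler dimensionality mismatch")
    sd = np.where(s.sd_per_feature == 0.0, 1.0, s.sd_per_feature)
    z = (m.values - s.mean_per_feature) / sd
    z[:, s.sd_per_feature == 0.0] = 0.0
    return FeatureMatrix(
        row_ids=list(m.row_ids),
        feature_names=list(m.feature_names),
        values=z,
        labels=list(m.labels) if m.labels is not None else None,
    )


def zscore_inverse(m: FeatureMatrix, s: ScalerState) -> FeatureMatrix:
    """Undo :func:`zscore_transform` (constant columns return to their mean)."""
    sd = np.where(s.sd_per_feature == 0.0, 0.0, s.sd_per_feature)
    return FeatureMatrix(
        row_ids=list(m.row_ids),
        feature_names=list(m.feature_names),
        values=m.values * sd + s.mean_per_feature,
        labels=list(m.labels) if m.labels is not None else None,
    )


@dataclass
class FScoreRanking:
    """Per-feature Fisher scores with a descending-order ranking and mask."""

    feature_names: list[str]
    score_per_feature: np.ndarray
    order: list[int] = field(default_factory=list)
    selected_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.order:
            # descending by score; ties broken by feature name for stability
            self.order = sorted(
                range(len(self.feature_names)),
                key=lambda i: (-self.score_per_feature[i], self.feature_names[i]),
            )
        if self.selected_mask is None:
            self.selected_mask = np.ones(len(self.feature_names), dtype=bool)

    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]

    def selected_names(self) -> list[str]:
        """Selected features in ranking order."""
        assert self.selected_mask is not None
        return [self.feature_names[i] for i in self.order if self.selected_mask[i]]

    def to_tsv(self, path: str | Path) -> None:
        assert self.selected_mask is not None
        rank_of = {i: r for r, i in enumerate(self.order, start=1)}
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "score": self.score_per_feature,
                "rank": [rank_of[i] for i in range(len(self.feature_names))],
                "selected": self.selected_mask.astype(int),
            }
        ).sort_values("rank")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def fscore(m: FeatureMatrix) -> FScoreRanking:
    """Fisher score of every feature: between-class over within-class spread.

    For feature i with classes k of size ``n_k``,

        F(i) = sum_k n_k (xbar_i^k - xbar_i)^2
               / sum_k [1 / (n_k - 1)] sum_j (x_{j,i}^k - xbar_i^k)^2

    A feature separating classes with zero within-class variance gets the
    ``+inf`` sentinel (ranked first); a constant feature scores 0.
    """
    if m.labels is None:
        raise ValueError("fscore requires labels")
    classes = sorted(set(m.labels))
    if len(classes) < 2:
        raise ValueError("fscore requires at least two classes")
    y = np.asarray(m.labels)
    x = m.values
    overall = x.mean(axis=0)
    num = np.zeros(m.n_features)
    den = np.zeros(m.n_features)
    for c in classes:
        rows = x[y == c]
        n_k = len(rows)
        if n_k < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        mean_k = rows.mean(axis=0)
        num += n_k * (mean_k - overall) ** 2
        den += ((rows - mean_k) ** 2).sum(axis=0) / (n_k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(den == 0) & (num > 0)] = math.inf
    scores[(den == 0) & (num <= 0)] = 0.0
    return FScoreRanking(feature_names=list(m.feature_names), score_per_feature=scores)


def select_top_fraction(r: FScoreRanking, fraction: float = 0.8) -> FScoreRanking:
    """Keep the ceil(fraction * n) highest-scoring features."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = math.ceil(fraction * len(r.feature_names))
    mask = np.zeros(len(r.feature_names), dtype=bool)
    mask[r.order[:n_keep]] = True
    return FScoreRanking(
        feature_names=list(r.feature_names),
        score_per_feature=r.score_per_feature.copy(),
        order=list(r.order),
        selected_mask=mask,
    )
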