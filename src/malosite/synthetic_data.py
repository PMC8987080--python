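"""Synthetic lysine-site window generator with positional enrichment.

Real malonylation datasets show residues that are significantly enriched
or depleted at specific offsets (roughly -12..+12) around the modified
lysine. The generator emulates exactly that structure: windows of odd
length with a fixed ``K`` center, residues drawn independently per
position from a background composition, and class-dependent log-odds
shifts applied to chosen (offset, residue) pairs in the positive class.

It is a test harness for the pipeline, not a statistical model of
malonylation biology: positions are independent (no residue coupling) and
shift magnitudes are free parameters, not estimates from real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from malosite.sequence_io import AMINO_ACIDS, PeptideWindow, SiteDataset

#: Amino-acid composition of a UniProt/Swiss-Prot-like proteome, an
#: alternative to the uniform background for more realistic windows.
UNIPROT_LIKE_FREQS: dict[str, float] = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class EnrichmentProfile:
    """Class-dependent positional residue enrichment around the center.

    Parameters
    ----------
    background_freqs:
        Per-residue probabilities used at every non-center position
        (uniform 0.05 by default). Must sum to 1.
    enriched:
        ``(offset, residue, shift)`` triples; ``offset`` is relative to
        the center lysine, ``shift`` a log-odds increment applied to that
        residue's probability at that offset in the positive class
        (negative shifts deplete).
    label_gap:
        Scale factor on all shifts for the positive class; the negative
        class always samples the plain background. ``label_gap=0`` makes
        the classes exchangeable.
    """

    background_freqs: dict[str, float] = field(
        default_factory=lambda: {aa: 0.05 for aa in AMINO_ACIDS}
    )
    enriched: tuple[tuple[int, str, float], ...] = ()
    label_gap: float = 1.0

    def __post_init__(self) -> None:
        if set(self.background_freqs) != set(AMINO_ACIDS):
            raise ValueError("background must cover exactly the 20 residues")
        total = sum(self.background_freqs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if any(v <= 0 for v in self.background_freqs.values()):
            raise ValueError("background frequencies must be strictly positive")
        for off, aa, _ in self.enriched:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown residue {aa!r} in enrichment")
            if off == 0:
                raise ValueError("offset 0 is the fixed K center")

    def position_distributions(
        self, window_length: int, positive: bool
    ) -> np.ndarray:
        """Per-position residue distributions, (L, 20); center row is one-hot K."""
        half = (window_length - 1) // 2
        base = np.array([self.background_freqs[aa] for aa in AMINO_ACIDS])
        dist = np.tile(base, (window_length, 1))
        if positive:
            logits = np.log(dist)
            for off, aa, shift in self.enriched:
                if abs(off) > half:
                    raise ValueError(
                        f"offset {off} outside half-window {half}"
                    )
                logits[half + off, AMINO_ACIDS.index(aa)] += shift * self.label_gap
            dist = np.exp(logits)
            dist /= dist.sum(axis=1, keepdims=True)
        center = np.zeros(20)
        center[AMINO_ACIDS.index("K")] = 1.0
        dist[half] = center
        return dist

    @classmethod
    def from_file(cls, path: str | Path) -> "EnrichmentProfile":
        """Load a profile from YAML or JSON."""
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(
            background_freqs=d.get(
                "background_freqs", {aa: 0.05 for aa in AMINO_ACIDS}
            ),
            enriched=tuple(
                (int(e["offset"]), str(e["residue"]), float(e["shift"]))
                for e in d.get("enriched", [])
            ),
            label_gap=float(d.get("label_gap", 1.0)),
        )


def null_profile() -> EnrichmentProfile:
    """Uniform background, no enrichment: classes are exchangeable."""
    return EnrichmentProfile()


def strong_profile() -> EnrichmentProfile:
    """A strongly separable benchmark condition.

    Eight (offset, residue) pairs flanking the center carry a log-odds
    shift of +3.5 (raising a uniform 5% background to ~64% occupancy in
    positives) and two pairs are depleted at -2.5, mimicking a clean
    experimental motif. The Bayes-optimal AUROC of this condition is
    ~0.997 (the positive-class motif-hit count ~ Bin(8, 0.64) barely
    overlaps the negative ~ Bin(8, 0.05)), leaving headroom for encoder
    and classifier loss while staying clearly separable.
    """
    return EnrichmentProfile(
        enriched=(
            (-4, "V", 3.5),
            (-3, "L", 3.5),
            (-2, "D", 3.5),
            (-1, "G", 3.5),
            (1, "E", 3.5),
            (2, "R", 3.5),
            (3, "Y", 3.5),
            (4, "F", 3.5),
            (-5, "K", -2.5),
            (5, "S", -2.5),
        )
    )


def generate(
    n_pos: int,
    n_neg: int,
    profile: EnrichmentProfile | None = None,
    window_length: int = 25,
    seed: int = 0,
) -> SiteDataset:
    """Sample a labeled dataset of K-centered windows.

    Positives are drawn from the profile's shifted per-position
    distributions, negatives from the plain background; rows are
    independent and the draw is deterministic under ``seed``.
    """
    if window_length % 2 == 0 or window_length < 3:
        raise ValueError("window_length must be odd and >= 3")
    profile = profile or null_profile()
    rng = np.random.default_rng(seed)
    residues = np.array(list(AMINO_ACIDS))
    windows: list[PeptideWindow] = []
    for label, n, positive in (("positive", n_pos, True), ("negative", n_neg, False)):
        dist = profile.position_distributions(window_length, positive)
        # one multinomial draw per position column, n rows at once
        cols = np.empty((n, window_length), dtype="<U1")
        for i in range(window_length):
            cols[:, i] = rng.choice(residues, size=n, p=dist[i])
        for k in range(n):
            windows.append(
                PeptideWindow(
                    residues="".join(cols[k]),
                    label=label,  # type: ignore[arg-type]
                    protein_id=f"syn_{label[:3]}_{k}",
                )
            )
    return SiteDataset(windows)


def positional_frequency_table(data: SiteDataset) -> pd.DataFrame:
    """Empirical per-position, per-class residue frequencies.

    Returns a DataFrame indexed by (class, offset-from-center) with one
    column per residue; each row sums to 1 over the residues observed
    (pad excluded).
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    L = data.window_length
    half = (L - 1) // 2
    classes = sorted(data.class_counts)
    counts = {c: np.zeros((L, 20)) for c in classes}
    for w in data:
        for i, r in enumerate(w.residues):
            if r != "X":
                counts[w.label][i, AMINO_ACIDS.index(r)] += 1.0
    rows = []
    index = []
    for c in classes:
        mat = counts[c]
        sums = mat.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        freq = mat / sums
        for i in range(L):
            rows.append(freq[i])
            index.append((c, i - half))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["class", "offset"]),
        columns=list(AMINO_ACIDS),
    )
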