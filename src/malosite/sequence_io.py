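"""Reading, windowing and representing lysine-site peptide datasets.

Proteins are read from FASTA; candidate modification sites are represented
as fixed-length odd windows centered on the target residue (lysine, ``K``).
Windows that run over a protein terminus are filled with the pad symbol
``X`` so that every window in a dataset has identical length and the
center stays at index ``(L - 1) // 2``.

Coordinate convention: site positions are 1-based in all files (the usual
biology convention); everything in memory is 0-based.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Pad symbol used for positions beyond a protein terminus and for
#: non-standard residues. Excluded from every frequency denominator.
PAD: str = "X"

ALPHABET = set(AMINO_ACIDS) | {PAD}

Label = Literal["positive", "negative", "unknown"]


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length residue window centered on a candidate site.

    Parameters
    ----------
    residues:
        String of odd length over the 20-residue alphabet plus pad ``X``.
    label:
        ``"positive"``, ``"negative"`` or ``"unknown"``.
    protein_id:
        Identifier of the source protein (or the window record itself).
    site_position:
        1-based position of the central residue in the source protein,
        when known.
    """

    residues: str
    label: Label = "unknown"
    protein_id: str = ""
    site_position: int | None = None

    def __post_init__(self) -> None:
        if len(self.residues) % 2 == 0 or len(self.residues) < 3:
            raise ValueError(
                f"window length must be odd and >= 3, got {len(self.residues)}"
            )
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(f"invalid residues in window: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def center_index(self) -> int:
        return (len(self.residues) - 1) // 2

    @property
    def center_residue(self) -> str:
        return self.residues[self.center_index]

    def non_pad_count(self) -> int:
        return sum(1 for r in self.residues if r != PAD)


@dataclass
class SiteDataset:
    """An ordered collection of equal-length labeled peptide windows."""

    windows: list[PeptideWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {w.length for w in self.windows}
        if len(lengths) > 1:
            raise ValueError(f"windows have mixed lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[PeptideWindow]:
        return iter(self.windows)

    @property
    def window_length(self) -> int:
        if not self.windows:
            raise ValueError("empty dataset has no window length")
        return self.windows[0].length

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(w.label for w in self.windows))

    def subset(self, indices: Sequence[int]) -> "SiteDataset":
        return SiteDataset([self.windows[i] for i in indices])

    def labels(self) -> list[str]:
        return [w.label for w in self.windows]


def _sanitize(seq: str, record_id: str) -> str:
    """Uppercase and map non-standard residues (B, Z, U, O, J, *, ...) to pad."""
    seq = seq.upper()
    out = []
    mapped = set()
    for ch in seq:
        if ch in ALPHABET:
            out.append(ch)
        else:
            mapped.add(ch)
            out.append(PAD)
    if mapped:
        logger.warning(
            "record %s: mapped non-standard characters %s to '%s'",
            record_id, sorted(mapped), PAD,
        )
    return "".join(out)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Sequences are uppercased; characters outside the 20-residue alphabet
    are mapped to ``X`` with a logged warning. An empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        # reject leading junk before the first header, naming the line
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected '>' header, got {line.strip()!r}"
                )
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _sanitize(str(rec.seq), rec.id)))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Write windows as FASTA, LF line endings, 60-column wrap.

    The header encodes provenance as ``protein_id|pos<site>|<label>`` so a
    round trip through :func:`load_window_fasta` is lossless.
    """
    records = []
    for i, w in enumerate(windows):
        pos = w.site_position if w.site_position is not None else 0
        name = w.protein_id or f"win{i}"
        records.append(
            SeqRecord(Seq(w.residues), id=f"{name}|pos{pos}|{w.label}", description="")
        )
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def extract_windows(
    protein: tuple[str, str],
    window_length: int = 25,
    center_residue: str = "K",
    pad: str = PAD,
) -> list[PeptideWindow]:
    """Cut one window per occurrence of ``center_residue`` in a protein.

    Windows overhanging a terminus are left/right-filled with ``pad`` so
    all windows share ``window_length`` with the center at ``(L - 1) // 2``.
    A protein with no center residue yields an empty list.
    """
    if window_length % 2 == 0 or window_length < 3:
        raise ValueError(f"window_length must be odd and >= 3, got {window_length}")
    pid, seq = protein
    half = (window_length - 1) // 2
    out = []
    for i, ch in enumerate(seq):
        if ch != center_residue:
            continue
        lo, hi = i - half, i + half + 1
        chunk = seq[max(lo, 0):hi]
        left = pad * max(-lo, 0)
        right = pad * max(hi - len(seq), 0)
        out.append(
            PeptideWindow(
                residues=left + chunk + right,
                protein_id=pid,
                site_position=i + 1,
            )
        )
    return out


def load_window_fasta(
    path: str | Path, label: Label, window_length: int
) -> list[PeptideWindow]:
    """Load pre-cut fixed-length windows from one FASTA file."""
    records = read_fasta(path)
    bad = [rid for rid, seq in records if len(seq) != window_length]
    if bad:
        raise ValueError(
            f"{path}: records not of length {window_length}: {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    windows = []
    for rid, seq in records:
        pid, pos = rid, None
        parts = rid.split("|")
        if len(parts) >= 2 and parts[1].startswith("pos"):
            pid = parts[0]
            try:
                pos = int(parts[1][3:]) or None
            except ValueError:
                pos = None
        windows.append(
            PeptideWindow(residues=seq, label=label, protein_id=pid, site_position=pos)
        )
    dupes = [r for r, c in Counter(w.residues for w in windows).items() if c > 1]
    if dupes:
        logger.info("%s: %d duplicate window sequences retained", path, len(dupes))
    return windows


def load_labeled_windows(
    pos_path: str | Path,
    neg_path: str | Path,
    window_length: int = 25,
    dialect: Literal["windows", "sites"] = "windows",
    site_table: str | Path | None = None,
) -> SiteDataset:
    """Build a labeled :class:`SiteDataset` from per-class files.

    Two input dialects are supported:

    - ``"windows"`` (default): ``pos_path`` and ``neg_path`` are FASTA
      files of pre-cut windows of ``window_length``.
    - ``"sites"``: ``pos_path`` is a protein FASTA and ``site_table`` a TSV
      with header ``protein_id\tposition\tlabel`` (1-based positions);
      ``neg_path`` is ignored.
    """
    if dialect == "windows":
        windows = load_window_fasta(pos_path, "positive", window_length)
        windows += load_window_fasta(neg_path, "negative", window_length)
        return SiteDataset(windows)
    if dialect != "sites":
        raise ValueError(f"unknown dialect {dialect!r}")
    if site_table is None:
        raise ValueError("dialect='sites' requires site_table")
    proteins = dict(read_fasta(pos_path))
    windows = []
    with open(site_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "position", "label"]:
            raise ValueError(f"{site_table}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            pid, pos_s, label = line.rstrip("\n").split("\t")[:3]
            if pid not in proteins:
                raise ValueError(f"{site_table}: line {lineno}: unknown protein {pid!r}")
            if label not in ("positive", "negative", "unknown"):
                raise ValueError(f"{site_table}: line {lineno}: bad label {label!r}")
            pos = int(pos_s)  # 1-based
            seq = proteins[pid]
            if not (1 <= pos <= len(seq)) or seq[pos - 1] != "K":
                raise ValueError(
                    f"{site_table}: line {lineno}: position {pos} of {pid} is not a K"
                )
            half = (window_length - 1) // 2
            i = pos - 1
            lo, hi = i - half, i + half + 1
            chunk = seq[max(lo, 0):hi]
            residues = PAD * max(-lo, 0) + chunk + PAD * max(hi - len(seq), 0)
            windows.append(
                PeptideWindow(residues=residues, label=label,  # type: ignore[arg-type]
                              protein_id=pid, site_position=pos)
            )
    return SiteDataset(windows)
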