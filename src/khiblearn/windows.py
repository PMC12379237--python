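"""Peptide-window construction and dataset assembly for Khib site prediction.

Modified-lysine predictors operate on fixed-length peptides centred on a
candidate lysine: a window of ``2*flank + 1`` residues (default flank 21,
window length 43) cut from the parent protein, padded with ``"X"`` where the
window runs past a terminus.  This module reads proteins (FASTA) and site
annotation tables (TSV), extracts positive and candidate-negative windows,
removes redundancy by greedy identity clustering (a CD-HIT-style procedure at
a 40 % identity threshold), balances the two classes by cluster
representatives, and produces reproducible train/test and cross-validation
partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
#: ambiguous / non-standard one-letter codes mapped to the padding symbol
NONSTANDARD = {"B", "Z", "U", "O", "J"}

DEFAULT_FLANK = 21
DEFAULT_IDENTITY = 0.4
DEFAULT_SEED = 42


def _clean_sequence(sequence: str, accession: str) -> str:
    seq = sequence.upper()
    if not seq or any(c.isspace() for c in seq):
        raise ValueError(f"{accession}: sequence must be non-empty without whitespace")
    bad = sorted(set(seq) & NONSTANDARD)
    if bad:
        logger.warning("%s: mapping non-standard residues %s to %r", accession, bad, PAD)
        seq = "".join(PAD if c in NONSTANDARD else c for c in seq)
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession.

    Non-standard residues (B, Z, U, O, J) are mapped to the padding symbol
    with a logged warning; other letters are kept verbatim.
    """

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_sequence(self.sequence, self.accession))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A 1-based residue position on a protein with a class label."""

    accession: str
    position: int
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.accession}: position must be >= 1, got {self.position}")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be 'positive' or 'negative', got {self.label!r}")


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length lysine-centred peptide.

    ``sequence`` has length ``2*flank + 1`` over the 20 amino-acid letters
    plus the padding symbol ``"X"``, which may occur only as a contiguous
    prefix and/or suffix.
    """

    sequence: str
    flank: int
    label: str = "unknown"  # positive | negative | unknown
    source: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.flank + 1:
            raise ValueError(
                f"window length {len(self.sequence)} != 2*flank+1 = {2 * self.flank + 1}"
            )
        if self.label not in ("positive", "negative", "unknown"):
            raise ValueError(f"invalid label {self.label!r}")
        core = self.sequence.strip(PAD)
        if PAD in core:
            raise ValueError("padding 'X' must be a contiguous prefix and/or suffix")

    @property
    def centre(self) -> str:
        return self.sequence[self.flank]

    def depadded(self) -> str:
        return self.sequence.strip(PAD)


@dataclass
class ClusterSet:
    """A partition of window indices into identity clusters."""

    clusters: list[list[int]]
    representatives: list[int]
    identity_threshold: float

    def __post_init__(self) -> None:
        for rep, members in zip(self.representatives, self.clusters):
            if rep not in members:
                raise ValueError("every representative must belong to its cluster")

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class DatasetSplit:
    """A stratified train/test partition plus CV fold ids for the training part.

    ``fold_assignments`` is aligned with ``train_indices`` and holds fold ids
    in ``1..n_folds``.
    """

    train_indices: np.ndarray
    test_indices: np.ndarray
    fold_assignments: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_window(
    protein: ProteinRecord,
    position: int,
    flank: int = DEFAULT_FLANK,
    label: str = "unknown",
    strict: bool = True,
) -> PeptideWindow:
    """Cut the closed interval [position-flank, position+flank] from a protein.

    Out-of-range positions are replaced by the padding symbol ``"X"``.  In
    strict mode the central residue must be a lysine.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"{protein.accession}: position {position} out of range 1..{len(seq)}"
        )
    if strict and seq[position - 1] != "K":
        raise ValueError(
            f"{protein.accession} position {position}: central residue "
            f"{seq[position - 1]!r} is not K (strict mode)"
        )
    chars = []
    for i in range(position - flank, position + flank + 1):
        chars.append(seq[i - 1] if 1 <= i <= len(seq) else PAD)
    return PeptideWindow("".join(chars), flank, label, (protein.accession, position))


def enumerate_negative_windows(
    protein: ProteinRecord,
    positive_positions: set[int],
    flank: int = DEFAULT_FLANK,
) -> list[PeptideWindow]:
    """One negative window per lysine not listed as a modified site.

    Windows are returned in ascending position order.
    """
    out = []
    for i, res in enumerate(protein.sequence, start=1):
        if res == "K" and i not in positive_positions:
            out.append(extract_window(protein, i, flank, label="negative"))
    return out


# ---------------------------------------------------------------------------
# greedy identity clustering
# ---------------------------------------------------------------------------

def window_identity(a: str, b: str) -> float:
    """Fraction of matching non-pad positions between two equal-length windows.

    matches / union where matches counts positions with the same non-"X"
    residue in both windows and union counts positions where at least one
    window has a non-"X" residue.  Padding never counts as a match.
    """
    if len(a) != len(b):
        raise ValueError("windows must have equal length")
    matches = union = 0
    for x, y in zip(a, b):
        if x != PAD or y != PAD:
            union += 1
            if x == y and x != PAD:
                matches += 1
    return matches / union if union else 0.0


def _canonical_order(windows: list[PeptideWindow]) -> list[int]:
    def key(i: int):
        w = windows[i]
        acc, pos = w.source if w.source is not None else ("", 0)
        return (w.sequence, acc, pos)

    return sorted(range(len(windows)), key=key)


def greedy_cluster(
    windows: list[PeptideWindow],
    identity_threshold: float = DEFAULT_IDENTITY,
    canonicalize: bool = True,
) -> ClusterSet:
    """Greedy incremental clustering of equal-length windows.

    Windows are processed in canonical order (sequence, accession, position)
    unless ``canonicalize=False``, in which case input order is used.  A
    window joins the first existing cluster whose representative shares
    identity strictly above the threshold (exact duplicates always merge);
    otherwise it founds a new cluster and becomes its representative.
    """
    if not windows:
        return ClusterSet([], [], identity_threshold)
    lengths = {len(w.sequence) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")

    order = _canonical_order(windows) if canonicalize else list(range(len(windows)))

    L = lengths.pop()
    mat = np.frombuffer(
        "".join(windows[i].sequence for i in order).encode("ascii"), dtype="S1"
    ).reshape(len(order), L)
    pad = np.bytes_(PAD)

    clusters: list[list[int]] = []
    reps: list[int] = []
    rep_rows: list[np.ndarray] = []
    for r, idx in enumerate(order):
        row = mat[r]
        joined = False
        if rep_rows:
            R = np.stack(rep_rows)
            non_pad_row = row != pad
            non_pad_rep = R != pad
            matches = ((R == row) & non_pad_rep & non_pad_row).sum(axis=1)
            union = (non_pad_rep | non_pad_row).sum(axis=1)
            with np.errstate(invalid="ignore"):
                ident = np.where(union > 0, matches / np.maximum(union, 1), 0.0)
            hits = np.nonzero((ident > identity_threshold) | (ident == 1.0))[0]
            if hits.size:
                clusters[hits[0]].append(idx)
                joined = True
        if not joined:
            clusters.append([idx])
            reps.append(idx)
            rep_rows.append(row)
    return ClusterSet(clusters, reps, identity_threshold)


# ---------------------------------------------------------------------------
# class balancing and splitting
# ---------------------------------------------------------------------------

def balance_and_split(
    pos_windows: list[PeptideWindow],
    pos_clusters: ClusterSet,
    neg_windows: list[PeptideWindow],
    neg_clusters: ClusterSet,
    test_fraction: float = 0.1,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
) -> tuple[list[PeptideWindow], DatasetSplit]:
    """Balance classes by cluster representatives and split reproducibly.

    Takes one representative per positive cluster, samples (without
    replacement, seeded) an equal number of negative cluster representatives,
    and emits a stratified train/test split plus stratified fold ids on the
    training part.  The selected windows are returned in canonical order so
    the result does not depend on input ordering.
    """
    n_pos, n_neg = len(pos_clusters), len(neg_clusters)
    if n_neg < n_pos:
        raise ValueError(
            f"insufficient negative clusters: {n_neg} negative < {n_pos} positive"
        )
    pos_reps = [pos_windows[i] for i in pos_clusters.representatives]
    neg_reps = [neg_windows[i] for i in neg_clusters.representatives]
    # canonical order before seeded sampling => order-independence
    pos_reps = [pos_reps[i] for i in _canonical_order(pos_reps)]
    neg_reps = [neg_reps[i] for i in _canonical_order(neg_reps)]

    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_neg, size=n_pos, replace=False)
    neg_sel = [neg_reps[i] for i in sorted(chosen)]

    selected = [
        PeptideWindow(w.sequence, w.flank, "positive", w.source) for w in pos_reps
    ] + [PeptideWindow(w.sequence, w.flank, "negative", w.source) for w in neg_sel]
    labels = np.array([1] * n_pos + [0] * n_pos)

    idx = np.arange(len(selected))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.zeros(len(train_idx), dtype=int)
    for fold_id, (_, val) in enumerate(
        skf.split(np.zeros(len(train_idx)), labels[train_idx]), start=1
    ):
        folds[val] = fold_id
    return selected, DatasetSplit(train_idx, test_idx, folds, seed)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(proteins: list[ProteinRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_site_table(path) -> list[SiteAnnotation]:
    """Read a TSV of sites.  Required columns: accession, position, label."""
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    return [
        SiteAnnotation(str(r.accession), int(r.position), str(r.label))
        for r in df.itertuples()
    ]


def write_site_table(sites: list[SiteAnnotation], path) -> None:
    pd.DataFrame(
        [(s.accession, s.position, s.label) for s in sites],
        columns=["accession", "position", "label"],
    ).to_csv(path, sep="\t", index=False)


def windows_to_frame(windows: list[PeptideWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        acc, pos = w.source if w.source is not None else ("", -1)
        rows.append((acc, pos, w.flank, w.label, w.sequence))
    return pd.DataFrame(rows, columns=["accession", "position", "flank", "label", "sequence"])


def write_windows_tsv(windows: list[PeptideWindow], path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)


def read_windows_tsv(path) -> list[PeptideWindow]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideWindow(r.sequence, int(r.flank), r.label, (str(r.accession), int(r.position)))
        for r in df.itertuples()
    ]


def write_windows_fasta(windows: list[PeptideWindow], path) -> None:
    records = []
    for w in windows:
        acc, pos = w.source if w.source is not None else ("window", 0)
        records.append(
            SeqRecord(Seq(w.sequence), id=f"{acc}_{pos}_{w.label}", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def build_windows(
    proteins: list[ProteinRecord],
    sites: list[SiteAnnotation],
    flank: int = DEFAULT_FLANK,
    strict: bool = True,
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Positive windows from the site table; negatives from all other lysines.

    If the table contains explicit negative rows, those are used as the
    negative pool instead of enumerating unannotated lysines.
    """
    by_acc = {p.accession: p for p in proteins}
    pos, explicit_neg = [], []
    pos_positions: dict[str, set[int]] = {}
    for s in sites:
        if s.accession not in by_acc:
            raise KeyError(f"site references unknown accession {s.accession!r}")
        w = extract_window(by_acc[s.accession], s.position, flank, s.label, strict=strict)
        if s.label == "positive":
            pos.append(w)
            pos_positions.setdefault(s.accession, set()).add(s.position)
        else:
            explicit_neg.append(w)
    if explicit_neg:
        return pos, explicit_neg
    neg = []
    for p in proteins:
        neg.extend(enumerate_negative_windows(p, pos_positions.get(p.accession, set()), flank))
    return pos, neg
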