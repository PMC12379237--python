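"""Numeric feature encoders for peptide windows.

Three feature families are produced, mirroring the hybrid representation used
for Khib site prediction:

* **CTD** — Composition/Transition/Distribution descriptors over seven
  three-group physicochemical partitions of the amino-acid alphabet
  (Dubchak-style).  21 + 21 + 105 = 147 features per window.
* **AAindex** — position-specific encoding: each residue is mapped to its
  value on each of 20 property scales, giving ``20 * L`` features
  (860 for the default 43-residue window).
* **Embeddings** — per-residue vectors mean-pooled over the window, produced
  by any provider implementing :class:`EmbeddingProvider`.  The built-in
  :class:`HashingEmbedder` is fully offline and deterministic; an external
  protein-language-model embedder (e.g. a 480-dimensional ESM-2 layer) can be
  plugged in through the same interface.

Padding ``"X"`` is excluded from CTD counts and pooling and contributes zeros
to the AAindex encoding; CTD denominators use the de-padded length.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .aaindex_scales import AA_ORDER, DEFAULT_SCALES
from .windows import PAD, PeptideWindow

_AA_SET = frozenset(AA_ORDER)


# ---------------------------------------------------------------------------
# CTD attribute groupings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeGrouping:
    """A named partition of the 20 standard residues into three groups."""

    name: str
    groups: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ValueError("exactly 3 groups required")
        union = set().union(*self.groups)
        total = sum(len(g) for g in self.groups)
        if union != _AA_SET or total != 20:
            raise ValueError(f"groups of {self.name!r} must partition the 20 residues")

    def group_of(self, residue: str) -> int:
        """1-based group index of a residue."""
        for i, g in enumerate(self.groups, start=1):
            if residue in g:
                return i
        raise KeyError(f"residue {residue!r} not in grouping {self.name!r}")


def _grouping(name: str, g1: str, g2: str, g3: str) -> AttributeGrouping:
    return AttributeGrouping(name, (frozenset(g1), frozenset(g2), frozenset(g3)))


#: The seven canonical three-group partitions (Dubchak-style).  The
#: hydrophobicity partition is polar / neutral / hydrophobic.
DEFAULT_GROUPINGS: tuple[AttributeGrouping, ...] = (
    _grouping("hydrophobicity", "RKEDQN", "GASTPHY", "CLVIMFW"),
    _grouping("vdw_volume", "GASTPDC", "NVEQIL", "MHKFRYW"),
    _grouping("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    _grouping("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    _grouping("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    _grouping("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    _grouping("solvent_accessibility", "ALFCGIVW", "RKQEND", "MSPTHY"),
)


def _as_string(window) -> str:
    return window.sequence if isinstance(window, PeptideWindow) else str(window)


def _depad(window) -> str:
    seq = _as_string(window).strip(PAD)
    if PAD in seq:
        raise ValueError("padding 'X' must be contiguous prefix/suffix")
    return seq


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# CTD descriptors
# ---------------------------------------------------------------------------

def ctd_composition(window, grouping: AttributeGrouping) -> np.ndarray:
    """Per-group residue fraction; three values summing to 1."""
    seq = _depad(window)
    if not seq:
        raise ValueError("window is all padding")
    counts = np.zeros(3)
    for res in seq:
        counts[grouping.group_of(res) - 1] += 1
    return counts / len(seq)


def ctd_transition(
    window,
    grouping: AttributeGrouping,
    mode: str = "symmetric",
    pair: tuple[int, int] | None = None,
) -> np.ndarray | float:
    """Adjacent-pair group-transition frequencies.

    ``symmetric`` returns three values for the unordered pairs (1,2), (1,3),
    (2,3): the count of adjacent residue pairs whose members lie in the two
    groups, in either order, divided by L'-1 (L' = de-padded length).
    ``directional`` returns the ordered count for the requested 1-based
    ``pair=(i, j)`` divided by L'-1, reproducing the ordered-pair convention
    of the printed worked example.
    """
    seq = _depad(window)
    if len(seq) < 2:
        raise ValueError("need at least 2 non-pad residues for transitions")
    g = [grouping.group_of(r) for r in seq]
    denom = len(seq) - 1
    if mode == "directional":
        if pair is None:
            raise ValueError("directional mode requires pair=(i, j)")
        i, j = pair
        return sum(1 for a, b in zip(g, g[1:]) if a == i and b == j) / denom
    if mode != "symmetric":
        raise ValueError(f"unknown mode {mode!r}")
    out = np.zeros(3)
    pairs = [(1, 2), (1, 3), (2, 3)]
    for a, b in zip(g, g[1:]):
        if a != b:
            out[pairs.index((min(a, b), max(a, b)))] += 1
    return out / denom


def ctd_distribution(window, grouping: AttributeGrouping) -> np.ndarray:
    """Relative positions (x100) of the 1st/25%/50%/75%/last group occurrences.

    The p-th percentile occurrence index is round-half-up(p*n) clamped to
    [1, n] for a group with n occurrences; an absent group yields five zeros.
    Positions are 1-based within the de-padded window of length L', and each
    value is 100 * position / L'.
    """
    seq = _depad(window)
    if not seq:
        raise ValueError("window is all padding")
    L = len(seq)
    positions: list[list[int]] = [[], [], []]
    for pos, res in enumerate(seq, start=1):
        positions[grouping.group_of(res) - 1].append(pos)
    out = np.zeros(15)
    for gi, occ in enumerate(positions):
        n = len(occ)
        if n == 0:
            continue
        for pi, p in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
            k = 1 if p == 0.0 else min(max(_round_half_up(p * n), 1), n)
            out[gi * 5 + pi] = 100.0 * occ[k - 1] / L
    return out


def ctd_encode(
    window, groupings: Sequence[AttributeGrouping] = DEFAULT_GROUPINGS
) -> np.ndarray:
    """Full 147-dim CTD vector: C (7x3) + symmetric T (7x3) + D (7x15)."""
    if len(groupings) != 7:
        raise ValueError(f"expected 7 groupings, got {len(groupings)}")
    c = np.concatenate([ctd_composition(window, g) for g in groupings])
    t = np.concatenate([ctd_transition(window, g) for g in groupings])
    d = np.concatenate([ctd_distribution(window, g) for g in groupings])
    return np.concatenate([c, t, d])


def ctd_feature_names(
    groupings: Sequence[AttributeGrouping] = DEFAULT_GROUPINGS,
) -> list[str]:
    names = []
    for g in groupings:
        names += [f"ctd_C_{g.name}_g{i}" for i in (1, 2, 3)]
    for g in groupings:
        names += [f"ctd_T_{g.name}_p{i}{j}" for i, j in ((1, 2), (1, 3), (2, 3))]
    for g in groupings:
        for gi in (1, 2, 3):
            names += [
                f"ctd_D_{g.name}_g{gi}_{q}" for q in ("first", "q25", "q50", "q75", "last")
            ]
    return names


# ---------------------------------------------------------------------------
# AAindex encoding
# ---------------------------------------------------------------------------

@dataclass
class AAIndexTable:
    """An ordered set of named property scales over the 20 standard residues."""

    scales: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, values in self.scales.items():
            missing = _AA_SET - set(values)
            if missing:
                raise ValueError(f"scale {name!r} missing residues {sorted(missing)}")

    @property
    def names(self) -> list[str]:
        return list(self.scales)

    def __len__(self) -> int:
        return len(self.scales)

    def value(self, name: str, residue: str) -> float:
        try:
            return self.scales[name][residue]
        except KeyError:
            raise KeyError(f"scale {name!r} has no value for residue {residue!r}") from None


def default_aaindex_table() -> AAIndexTable:
    return AAIndexTable({k: dict(v) for k, v in DEFAULT_SCALES.items()})


def read_aaindex_table(path) -> AAIndexTable:
    """Read a delimited scale table: one row per scale, columns = residues.

    Expected header: ``index`` followed by the 20 one-letter residue codes
    (any order).  Tab- or comma-separated.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.set_index(df.columns[0])
    return AAIndexTable({str(idx): {str(c): float(v) for c, v in row.items()} for idx, row in df.iterrows()})


def aaindex_encode(window, table: AAIndexTable | None = None) -> np.ndarray:
    """Position-major L x 20 encoding; pad positions contribute zeros."""
    table = table or default_aaindex_table()
    seq = _as_string(window)
    k = len(table)
    out = np.zeros(len(seq) * k)
    for pos, res in enumerate(seq):
        if res == PAD:
            continue
        for si, name in enumerate(table.names):
            out[pos * k + si] = table.value(name, res)
    return out


def aaindex_feature_names(length: int, table: AAIndexTable | None = None) -> list[str]:
    table = table or default_aaindex_table()
    return [
        f"aaidx_p{pos:02d}_{name}"
        for pos in range(1, length + 1)
        for name in table.names
    ]


# ---------------------------------------------------------------------------
# embedding providers
# ---------------------------------------------------------------------------

class EmbeddingProvider(Protocol):
    """Adapter contract for per-residue embedders.

    ``dim`` is the fixed output dimension; ``embed_residues`` returns one
    vector per non-pad residue of the window.
    """

    dim: int

    def embed_residues(self, depadded: str) -> np.ndarray:  # (L', dim)
        ...


class HashingEmbedder:
    """Deterministic offline residue embedder.

    Each residue's vector is the mean of unit-variance Gaussian vectors keyed
    by stable hashes of (a) the residue letter and (b) its local context
    trigram.  Context trigrams are position-independent and self-padded at
    the sequence edges, so a homopolymer yields identical residue vectors.
    The embedding is a fixed random feature map: it carries composition and
    local-context information, is bit-reproducible across runs and platforms,
    and requires no model weights.
    """

    def __init__(self, dim: int = 480):
        self.dim = dim
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dim)
            self._cache[token] = vec
        return vec

    def embed_residues(self, depadded: str) -> np.ndarray:
        n = len(depadded)
        out = np.empty((n, self.dim))
        for i, res in enumerate(depadded):
            left = depadded[i - 1] if i > 0 else res
            right = depadded[i + 1] if i < n - 1 else res
            trigram = left + res + right
            out[i] = 0.5 * (self._token_vector("r:" + res) + self._token_vector("k3:" + trigram))
        return out


def embed(windows: Iterable, provider: EmbeddingProvider | None = None) -> np.ndarray:
    """Mean-pooled per-window embeddings (pad positions excluded)."""
    provider = provider or HashingEmbedder()
    rows = []
    for w in windows:
        seq = _depad(w)
        if not seq:
            raise ValueError("window is all padding")
        residue_vectors = provider.embed_residues(seq)
        if residue_vectors.shape[1] != provider.dim:
            raise ValueError(
                f"provider returned dimension {residue_vectors.shape[1]}, declared {provider.dim}"
            )
        rows.append(residue_vectors.mean(axis=0))
    return np.asarray(rows)


def embedding_feature_names(dim: int) -> list[str]:
    return [f"esm_{i:04d}" for i in range(dim)]


# ---------------------------------------------------------------------------
# feature blocks and assembly
# ---------------------------------------------------------------------------

CATEGORIES = ("esm", "ctd", "aaidx")


@dataclass
class FeatureBlock:
    """A named, category-tagged block of per-sample feature vectors."""

    category: str
    names: list[str]
    values: np.ndarray  # (n_samples, n_features)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique within a block")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values shape does not match names")


@dataclass
class FeatureMatrix:
    """Samples x category-tagged features, with labels.

    ``X`` is a DataFrame whose column names carry the category prefix
    (``esm_``, ``ctd_``, ``aaidx_``); ``y`` holds 0/1 labels.
    """

    X: pd.DataFrame
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.y) != len(self.X):
            raise ValueError("labels and rows disagree")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(len(self.X))]
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def categories(self) -> list[str]:
        return [c.split("_", 1)[0] for c in self.X.columns]

    def subset_rows(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix(
            self.X.iloc[idx].reset_index(drop=True),
            self.y[idx],
            [self.sample_ids[i] for i in idx],
        )


def assemble_features(
    blocks: Sequence[FeatureBlock],
    labels,
    sample_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Column-wise concatenation of blocks covering the same samples in order."""
    if not blocks:
        raise ValueError("no blocks given")
    n = blocks[0].values.shape[0]
    for b in blocks:
        if b.values.shape[0] != n:
            raise ValueError("blocks cover different numbers of samples")
    names = [nm for b in blocks for nm in b.names]
    values = np.hstack([b.values for b in blocks])
    X = pd.DataFrame(values, columns=names)
    return FeatureMatrix(X, np.asarray(labels), sample_ids or [])


def encode_windows(
    windows: Sequence[PeptideWindow],
    blocks: Sequence[str] = ("esm", "ctd", "aaidx"),
    provider: EmbeddingProvider | None = None,
    table: AAIndexTable | None = None,
    groupings: Sequence[AttributeGrouping] = DEFAULT_GROUPINGS,
) -> FeatureMatrix:
    """Encode windows into the hybrid feature matrix.

    With the defaults (flank 21, 480-dim provider, 20 scales) the result has
    480 + 147 + 860 = 1487 columns in esm, ctd, aaidx order.
    """
    if not windows:
        raise ValueError("no windows to encode")
    built: list[FeatureBlock] = []
    for cat in blocks:
        if cat == "esm":
            provider = provider or HashingEmbedder()
            vals = embed(windows, provider)
            built.append(FeatureBlock("esm", embedding_feature_names(provider.dim), vals))
        elif cat == "ctd":
            vals = np.asarray([ctd_encode(w, groupings) for w in windows])
            built.append(FeatureBlock("ctd", ctd_feature_names(groupings), vals))
        elif cat == "aaidx":
            tab = table or default_aaindex_table()
            vals = np.asarray([aaindex_encode(w, tab) for w in windows])
            L = len(windows[0].sequence)
            built.append(FeatureBlock("aaidx", aaindex_feature_names(L, tab), vals))
        else:
            raise ValueError(f"unknown block {cat!r}")
    labels = np.array([1 if w.label == "positive" else 0 for w in windows])
    ids = [
        f"{w.source[0]}_{w.source[1]}" if w.source else f"s{i}"
        for i, w in enumerate(windows)
    ]
    return assemble_features(built, labels, ids)


# ---------------------------------------------------------------------------
# feature matrix I/O
# ---------------------------------------------------------------------------

def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    df = fm.X.copy()
    df.insert(0, "label", fm.y)
    df.insert(0, "sample_id", fm.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    ids = df.pop("sample_id").astype(str).tolist()
    y = df.pop("label").to_numpy()
    return FeatureMatrix(df, y, ids)
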