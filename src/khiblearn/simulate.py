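"""Synthetic peptide and proteome generation with planted motif signal.

The generator emulates balanced Khib window datasets: negatives are drawn
i.i.d. from a background residue distribution (uniform over the 20 standard
residues by default; a natural-abundance option is available) with a fixed
central lysine, and positives additionally receive position-specific
frequency shifts ("effects").  Species presets encode the qualitative motif
story observed around real Khib sites — upstream lysine enrichment whose
maximum matches the reported species values (human 14.5 %, parasite 13.5 %,
plant 12.7 %), glutamate enrichment, and proline/serine/arginine depletion —
with magnitudes decaying linearly away from the central residue.  Depletion
magnitudes are capped below the uniform background frequency of 1/20 so every
per-position distribution stays valid.

The generator produces either labelled windows directly or whole synthetic
proteomes (FASTA + site table) whose implanted positive windows round-trip
exactly through :mod:`khiblearn.windows`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .windows import DEFAULT_FLANK, PeptideWindow, ProteinRecord, SiteAnnotation

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: approximate natural residue abundances (vertebrate proteomes), normalised
NATURAL_ABUNDANCE = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033, "Q": 0.037,
    "E": 0.058, "G": 0.074, "H": 0.029, "I": 0.038, "L": 0.076, "K": 0.072,
    "M": 0.018, "F": 0.040, "P": 0.050, "S": 0.081, "T": 0.062, "W": 0.013,
    "Y": 0.033, "V": 0.068,
}


@dataclass(frozen=True)
class Effect:
    """A frequency delta for one residue at one offset from the central K."""

    offset: int
    residue: str
    delta: float

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("offset 0 is the central lysine; effects must have offset != 0")
        if self.residue not in AA20:
            raise ValueError(f"unknown residue {self.residue!r}")


def _linear_effects(residue: str, offsets, hi: float, lo: float) -> list[Effect]:
    offsets = list(offsets)
    span = max(len(offsets) - 1, 1)
    return [
        Effect(o, residue, hi + (lo - hi) * i / span) for i, o in enumerate(offsets)
    ]


def preset_effects(name: str) -> list[Effect]:
    """Planted effects for the species presets.

    All presets share upstream K enrichment (maximum at offset -1, linear
    decay to 0.05 at offset -8; the maxima are the reported species values)
    and proline depletion near the centre.  The parasite preset adds alanine
    enrichment and serine depletion; the plant preset strengthens glutamate
    enrichment and adds arginine depletion.  ``null`` plants nothing.
    """
    if name == "null":
        return []
    down8 = range(-1, -9, -1)
    p_dep = [Effect(o, "P", -0.030) for o in (-3, -2, -1, 1, 2, 3)]
    if name == "human":
        return (
            _linear_effects("K", down8, 0.145, 0.05)
            + _linear_effects("E", range(1, 7), 0.08, 0.04)
            + p_dep
        )
    if name == "parasite":
        return (
            _linear_effects("K", down8, 0.135, 0.05)
            + _linear_effects("A", range(1, 6), 0.06, 0.04)
            + _linear_effects("E", range(1, 4), 0.035, 0.030)
            + [Effect(o, "S", -0.035) for o in range(-6, 0)]
            + p_dep
        )
    if name == "plant":
        return (
            _linear_effects("K", down8, 0.127, 0.05)
            + _linear_effects("E", range(1, 7), 0.10, 0.05)
            + [Effect(o, "R", -0.035) for o in range(-6, 0)]
            + p_dep
        )
    raise ValueError(f"unknown preset {name!r}; use human, parasite, plant or null")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    ``background`` maps residues to frequencies (defaults to uniform 1/20);
    ``effects`` are applied on top of the background for the positive class
    only.  ``preset`` fills ``effects`` when they are not given explicitly.
    """

    n_pos: int = 2000
    n_neg: int = 2000
    flank: int = DEFAULT_FLANK
    background: dict[str, float] | None = None
    effects: list[Effect] = field(default_factory=list)
    preset: str | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.preset is not None and not self.effects:
            self.effects = preset_effects(self.preset)
        for e in self.effects:
            if abs(e.offset) > self.flank:
                raise ValueError(f"effect offset {e.offset} outside flank {self.flank}")

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1 / 20)
        vec = np.array([self.background[aa] for aa in AA20], dtype=float)
        return vec / vec.sum()


def position_distributions(config: SyntheticConfig) -> dict[int, np.ndarray]:
    """Per-offset residue distributions of the positive class.

    At each affected offset the planted residues take frequency
    background + delta exactly, and the remaining residues are rescaled
    proportionally so the distribution sums to 1.  A delta driving any
    frequency negative raises.
    """
    base = config.background_vector()
    by_offset: dict[int, dict[int, float]] = {}
    for e in config.effects:
        by_offset.setdefault(e.offset, {})
        idx = AA20.index(e.residue)
        by_offset[e.offset][idx] = by_offset[e.offset].get(idx, 0.0) + e.delta
    out: dict[int, np.ndarray] = {}
    for offset, deltas in by_offset.items():
        vec = base.copy()
        affected = np.array(sorted(deltas))
        old_mass = vec[affected].sum()
        for idx, d in deltas.items():
            vec[idx] += d
        if (vec[affected] < 0).any():
            bad = [AA20[i] for i in affected if vec[i] < 0]
            raise ValueError(
                f"effects at offset {offset} drive frequencies negative for {bad}"
            )
        new_mass = vec[affected].sum()
        if new_mass > 1:
            raise ValueError(f"effects at offset {offset} exceed unit mass")
        others = np.setdiff1d(np.arange(20), affected)
        scale = (1 - new_mass) / (1 - old_mass)
        vec[others] *= scale
        out[offset] = vec
    return out


def _sample_columns(rng, n, dist_by_offset, base, flank) -> np.ndarray:
    """Sample an (n, 2*flank+1) residue-index matrix; centre fixed to K."""
    L = 2 * flank + 1
    mat = np.empty((n, L), dtype=np.int64)
    k_idx = AA20.index("K")
    for col in range(L):
        offset = col - flank
        if offset == 0:
            mat[:, col] = k_idx
            continue
        p = dist_by_offset.get(offset, base)
        mat[:, col] = rng.choice(20, size=n, p=p)
    return mat


def generate_windows(config: SyntheticConfig) -> list[PeptideWindow]:
    """Labelled positive+negative windows under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    base = config.background_vector()
    dists = position_distributions(config)
    pos_mat = _sample_columns(rng, config.n_pos, dists, base, config.flank)
    neg_mat = _sample_columns(rng, config.n_neg, {}, base, config.flank)
    out = []
    for i, row in enumerate(pos_mat):
        seq = "".join(AA20[j] for j in row)
        out.append(PeptideWindow(seq, config.flank, "positive", ("SIMPOS", i + 1)))
    for i, row in enumerate(neg_mat):
        seq = "".join(AA20[j] for j in row)
        out.append(PeptideWindow(seq, config.flank, "negative", ("SIMNEG", i + 1)))
    return out


def generate_proteome(
    config: SyntheticConfig,
    n_proteins: int = 10,
    protein_length: int = 200,
    sites_per_protein: int = 3,
) -> tuple[list[ProteinRecord], list[SiteAnnotation], list[PeptideWindow]]:
    """Random proteins with implanted positive-site contexts.

    Each protein is drawn from the background and receives
    ``sites_per_protein`` non-overlapping positive windows (full flank inside
    the protein, so no padding); the site table records their central K
    positions.  All other lysines are implicit negatives.  Returns the
    proteins, the positive-site annotations, and the implanted windows in
    table order (extract_window on each table row reproduces them exactly).
    """
    L = 2 * config.flank + 1
    if protein_length < L:
        raise ValueError(f"protein_length must be >= window length {L}")
    if sites_per_protein * L > protein_length:
        raise ValueError("proteins too short for non-overlapping implants")
    rng = np.random.default_rng(config.seed)
    base = config.background_vector()
    dists = position_distributions(config)

    proteins, sites, implanted = [], [], []
    for pi in range(n_proteins):
        acc = f"SYN{pi:04d}"
        seq = list("".join(AA20[j] for j in rng.choice(20, size=protein_length, p=base)))
        # non-overlapping implant slots: pack windows left to right with
        # random extra left-shifts drawn from the available slack
        slack = protein_length - sites_per_protein * L
        extras = np.sort(rng.integers(0, slack + 1, size=sites_per_protein))
        centres = [int(j * L + extras[j] + config.flank + 1) for j in range(sites_per_protein)]
        win_mat = _sample_columns(rng, len(centres), dists, base, config.flank)
        for c, row in zip(centres, win_mat):
            wseq = "".join(AA20[j] for j in row)
            seq[c - config.flank - 1 : c + config.flank] = wseq
            sites.append(SiteAnnotation(acc, c, "positive"))
            implanted.append(PeptideWindow(wseq, config.flank, "positive", (acc, c)))
        proteins.append(ProteinRecord(acc, "".join(seq)))
    return proteins, sites, implanted
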