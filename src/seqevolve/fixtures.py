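"""Synthetic structures, annotations and sequences for self-contained runs.

Every other module is testable without downloading a single structure:
idealized helices and antiparallel sheet pairs provide plausible CA/CB/
side-chain-centroid geometry, native-like biased sequences, and jittered
"homolog" families that stand in for a non-redundant reference library.
The geometry is intentionally ideal — these fixtures exercise distance
binning, burial counting and structural alignment, not protein physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import DegenerateInputError
from .rng import make_rng
from .structio import AMINO_ACIDS, Residue, Structure, read_frequency_table

# ---------------------------------------------------------------------------
# Amino-acid frequency table
# ---------------------------------------------------------------------------


@dataclass
class AAFrequencyTable:
    """Background amino-acid probabilities (defaults: Swiss-Prot statistics)."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(AMINO_ACIDS):
            raise ValueError("frequency table must cover the 20 amino acids")
        total = sum(self.freq.values())
        if any(v <= 0 for v in self.freq.values()):
            raise ValueError("frequencies must be strictly positive")
        if abs(total - 1.0) > 1e-9:
            self.freq = {aa: v / total for aa, v in self.freq.items()}

    def probs(self) -> np.ndarray:
        """Probabilities ordered as :data:`structio.AMINO_ACIDS`."""
        return np.array([self.freq[aa] for aa in AMINO_ACIDS], dtype=float)

    def biased(self, boost: dict[str, float]) -> "AAFrequencyTable":
        """A new table with selected amino acids up-weighted and renormalized."""
        f = {aa: v * boost.get(aa, 1.0) for aa, v in self.freq.items()}
        return AAFrequencyTable(f)

    @classmethod
    def from_tsv(cls, text: str) -> "AAFrequencyTable":
        return cls(read_frequency_table(text))

    @classmethod
    def default(cls) -> "AAFrequencyTable":
        text = (resources.files("seqevolve.data") / "swissprot_freq.tsv"
                ).read_text()
        return cls.from_tsv(text)


_DEFAULT_TABLE: AAFrequencyTable | None = None


def default_frequency_table() -> AAFrequencyTable:
    """Cached bundled Swiss-Prot table."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AAFrequencyTable.default()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# Sequence generators
# ---------------------------------------------------------------------------

def random_sequence(length: int, table: AAFrequencyTable,
                    rng: np.random.Generator) -> str:
    """i.i.d. draws from the frequency table using the shared MT19937 stream."""
    if length < 1:
        raise DegenerateInputError("sequence length must be >= 1")
    cum = np.cumsum(table.probs())
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(length), side="right")
    return "".join(AMINO_ACIDS[i] for i in idx)


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Fisher-Yates permutation; preserves the residue multiset exactly."""
    if len(seq) < 2:
        raise DegenerateInputError("cannot shuffle a sequence shorter than 2")
    chars = list(seq)
    for i in range(len(chars) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        chars[i], chars[j] = chars[j], chars[i]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

#: Distance (A) of the side-chain centroid beyond CB along the outward
#: direction, roughly tracking side-chain size. Glycine has no side chain.
SC_EXTENT = {
    "G": 0.0, "A": 0.8, "S": 0.9, "C": 1.0, "T": 1.0, "V": 1.0, "P": 1.0,
    "D": 1.2, "N": 1.2, "I": 1.3, "L": 1.3, "E": 1.5, "Q": 1.5, "M": 1.6,
    "H": 1.6, "K": 1.8, "F": 1.9, "Y": 2.1, "R": 2.2, "W": 2.5,
}

CB_BOND = 1.53  # A, CA-CB bond length

HELIX_BOOST = {"A": 4.0, "L": 4.0, "E": 3.0, "K": 3.0}
STRAND_BOOST = {"V": 4.0, "I": 4.0, "T": 3.0, "Y": 3.0}


def _build_structure(sid: str, seq: str, ca: np.ndarray, out_dir: np.ndarray,
                     ss: str) -> Structure:
    """Assemble residues placing CB and centroid along per-residue outward axes."""
    residues = []
    for i, aa in enumerate(seq):
        c = ca[i]
        if aa == "G":
            cb = c.copy()
            sc = c.copy()
        else:
            d = out_dir[i] / np.linalg.norm(out_dir[i])
            cb = c + CB_BOND * d
            sc = cb + SC_EXTENT[aa] * d
        residues.append(Residue(index=i + 1, aa=aa, ca=c, cb=cb,
                                sc_centroid=sc, ss=ss[i]))
    return Structure(id=sid, residues=residues)


# ---------------------------------------------------------------------------
# Fixture structures
# ---------------------------------------------------------------------------

def make_helix(n_res: int, seed: int) -> tuple[Structure, str]:
    """Ideal alpha-helix with a helix-biased native sequence.

    CA trace: rise 1.5 A/residue, radius 2.3 A, 100 deg twist per residue;
    CB points radially outward at 1.53 A; the side-chain centroid sits
    0.8-2.5 A beyond CB depending on residue type. Secondary structure is H
    throughout. The native sequence is enriched in A/L/E/K and drawn from
    the seeded MT19937 stream.
    """
    if n_res < 10:
        raise DegenerateInputError("helix fixtures need >= 10 residues")
    rng = make_rng(seed)
    table = default_frequency_table().biased(HELIX_BOOST)
    seq = random_sequence(n_res, table, rng)

    theta = np.deg2rad(100.0) * np.arange(n_res)
    ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                   1.5 * np.arange(n_res)], axis=1)
    outward = np.stack([np.cos(theta), np.sin(theta),
                        np.zeros(n_res)], axis=1)
    st = _build_structure(f"helix{n_res}s{seed}", seq, ca, outward,
                          "H" * n_res)
    return st, seq


def make_sheet_pair(n_res_per_strand: int, seed: int) -> tuple[Structure, str]:
    """Two antiparallel strands joined by a short turn, strand-biased sequence.

    Strands run 4.8 A apart with a 3.3 A rise per residue; the two turn
    residues are labelled C, strand residues E. The geometry is seed-free;
    only the sequence is drawn from the seed.
    """
    n = n_res_per_strand
    if n < 5:
        raise DegenerateInputError("sheet fixtures need >= 5 residues/strand")
    rng = make_rng(seed)
    table = default_frequency_table().biased(STRAND_BOOST)
    L = 2 * n + 2
    seq = random_sequence(L, table, rng)

    rise, sep = 3.3, 4.8
    z_top = rise * (n - 1)
    ca, outward = [], []
    for i in range(n):  # strand 1, going up in z
        ca.append([0.0, 0.4 * (-1) ** i, rise * i])
        outward.append([0.0, (-1) ** i, 0.0])
    for x in (1.1, 3.7):  # turn
        ca.append([x, 2.4, z_top + 1.5])
        outward.append([0.0, 1.0, 0.3])
    for j in range(n):  # strand 2, antiparallel (z decreasing)
        zi = n - 1 - j
        ca.append([sep, 0.4 * (-1) ** zi, rise * zi])
        outward.append([0.0, (-1) ** zi, 0.0])
    ss = "E" * n + "CC" + "E" * n
    st = _build_structure(f"sheet{n}s{seed}", seq, np.array(ca),
                          np.array(outward), ss)
    return st, seq


def jitter_structure(structure: Structure, sigma: float,
                     rng: np.random.Generator, new_id: str | None = None
                     ) -> Structure:
    """Copy with isotropic Gaussian noise (std ``sigma`` A) on every coordinate."""
    residues = []
    for r in structure.residues:
        ca = r.ca + sigma * rng.standard_normal(3)
        if r.aa == "G":
            cb, sc = ca.copy(), ca.copy()
        else:
            cb = r.cb + sigma * rng.standard_normal(3)
            sc = r.sc_centroid + sigma * rng.standard_normal(3)
        residues.append(Residue(index=r.index, aa=r.aa, ca=ca, cb=cb,
                                sc_centroid=sc, ss=r.ss))
    return Structure(id=new_id or structure.id + "_jit", residues=residues)


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    table: AAFrequencyTable | None = None) -> str:
    """Point-mutate a fraction ``rate`` of positions (background-distributed)."""
    table = table or default_frequency_table()
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    repl = random_sequence(len(chars), table, rng)
    for i in np.where(hit)[0]:
        chars[i] = repl[i]
    return "".join(chars)


def make_library(n_structures: int, seed: int,
                 sigma: float = 0.3) -> list[tuple[Structure, str]]:
    """Mixed reference set of perturbed helices and sheet pairs.

    Serves both as the derivation set for the statistical potentials and as
    an alignment library for profile building. Lengths cycle deterministically
    so the set spans a range of chain lengths.
    """
    if n_structures < 2:
        raise DegenerateInputError("library needs >= 2 structures")
    out = []
    helix_lengths = [30, 42, 54, 66]
    strand_sizes = [6, 8, 10, 12]
    rng = make_rng(seed)
    for k in range(n_structures):
        sub = seed * 1009 + k  # distinct fixture seeds, < 2**31 for small seed
        if k % 2 == 0:
            st, seq = make_helix(helix_lengths[(k // 2) % 4], sub)
        else:
            st, seq = make_sheet_pair(strand_sizes[(k // 2) % 4], sub)
        st = jitter_structure(st, sigma, rng, new_id=f"lib{k:03d}")
        out.append((st, seq))
    return out


def make_homologs(structure: Structure, native: str, n: int, seed: int,
                  sigma: float = 0.3, mutation_rate: float = 0.3
                  ) -> list[tuple[Structure, str]]:
    """Jittered copies of a structure carrying mutated copies of its sequence.

    Emulates a family of structural analogs with related but diverged
    sequences — the situation a structure-based profile is built from.
    """
    rng = make_rng(seed)
    out = []
    for k in range(n):
        st = jitter_structure(structure, sigma, rng,
                              new_id=f"{structure.id}_hom{k}")
        seq = mutate_sequence(native, mutation_rate, rng)
        out.append((st, seq))
    return out
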