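"""Structure-conditioned pseudo-energy terms.

Three families of terms, all derived from a user-supplied reference set of
structures with native sequences by log-odds counting with +1 pseudocounts
(small reference sets must never yield infinities):

* a residue burial potential over a 7-state CB-neighbour-count alphabet
  (neighbours = other CB atoms within 14 A, states = equal-frequency bins
  of the reference set's counts);
* secondary-structure preferences over the 7 STRIDE states;
* a distance-dependent pairwise contact potential with the DFIRE
  distance-scaled ideal-gas reference state (exponent alpha = 1.61,
  reference distance 14.5 A), evaluated separately for CA atoms and for
  side-chain centroids.

Raw pseudo-energies grow with chain length; a fitted linear transform in L
removes that trend so scores are comparable across protein lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConsistencyError, DerivationError
from .structio import AA_INDEX, SS_INDEX, SS_STATES, Structure

N_AA = 20

# ---------------------------------------------------------------------------
# Burial potential (CB-14-7 alphabet)
# ---------------------------------------------------------------------------


@dataclass
class BurialModel:
    """7-state burial alphabet and its per-state amino-acid pseudo-energies."""

    radius: float = 14.0
    n_states: int = 7
    bin_edges: np.ndarray = field(default_factory=lambda: np.arange(1, 7.0))
    table: np.ndarray = field(default_factory=lambda: np.zeros((7, N_AA)))

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.table = np.asarray(self.table, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("burial bin edges must be strictly increasing")
        if not np.isfinite(self.table).all():
            raise ValueError("burial table has non-finite entries")


def burial_counts(structure: Structure, radius: float = 14.0) -> np.ndarray:
    """Number of other residues with CB within ``radius`` of each CB."""
    cb = structure.cb_coords()
    d = squareform(pdist(cb))
    np.fill_diagonal(d, np.inf)
    return (d < radius).sum(axis=1)


def burial_states(structure: Structure, model: BurialModel) -> np.ndarray:
    """Discretized burial state (0..n_states-1) for every residue."""
    counts = burial_counts(structure, model.radius)
    return np.digitize(counts, model.bin_edges)


def _log_odds(counts: np.ndarray, aa_freq: np.ndarray) -> np.ndarray:
    """-ln[(N(s,a)+1) / (N(s) f(a)+1)] with +1 pseudocounts."""
    n_state = counts.sum(axis=1, keepdims=True)
    return -np.log((counts + 1.0) / (n_state * aa_freq[None, :] + 1.0))


def _refset_aa_freq(refset) -> np.ndarray:
    tally = np.zeros(N_AA)
    for _, seq in refset:
        for aa in seq:
            tally[AA_INDEX[aa]] += 1
    if tally.sum() == 0:
        raise DerivationError("reference set has no sequences")
    return tally / tally.sum()


def derive_burial(refset, radius: float = 14.0,
                  n_states: int = 7) -> BurialModel:
    """Fit the burial alphabet and table from (structure, sequence) pairs.

    Bin edges are the equal-frequency quantile boundaries of the pooled
    neighbour counts; the table is the pseudocounted log-odds of seeing
    amino acid a in burial state s versus the background frequency f(a).
    """
    refset = list(refset)
    if len(refset) < 2:
        raise DerivationError("need at least 2 reference structures")
    all_counts = np.concatenate(
        [burial_counts(st, radius) for st, _ in refset])
    qs = np.arange(1, n_states) / n_states
    edges = np.quantile(all_counts, qs)
    for i in range(1, len(edges)):  # force strict monotonicity
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + 1e-6
    model = BurialModel(radius=radius, n_states=n_states, bin_edges=edges,
                        table=np.zeros((n_states, N_AA)))

    counts = np.zeros((n_states, N_AA))
    for st, seq in refset:
        states = burial_states(st, model)
        for s, aa in zip(states, seq):
            counts[s, AA_INDEX[aa]] += 1
    model.table = _log_odds(counts, _refset_aa_freq(refset))
    return model


def evaluate_burial(seq: str, structure: Structure,
                    model: BurialModel) -> float:
    """Sum of per-residue burial pseudo-energies (lower = more native-like)."""
    states = burial_states(structure, model)
    if len(seq) != len(states):
        raise ConsistencyError("sequence/structure length mismatch")
    aa_idx = np.fromiter((AA_INDEX[a] for a in seq), int, len(seq))
    return float(model.table[states, aa_idx].sum())


# ---------------------------------------------------------------------------
# Secondary-structure preferences
# ---------------------------------------------------------------------------

@dataclass
class SSModel:
    """Pseudo-energies of each amino acid in each of the 7 STRIDE states."""

    table: np.ndarray = field(
        default_factory=lambda: np.zeros((len(SS_STATES), N_AA)))

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if not np.isfinite(self.table).all():
            raise ValueError("SS table has non-finite entries")


def derive_ss(refset) -> SSModel:
    """Log-odds table of amino acids in STRIDE states over the reference set."""
    refset = list(refset)
    if len(refset) < 2:
        raise DerivationError("need at least 2 reference structures")
    counts = np.zeros((len(SS_STATES), N_AA))
    for st, seq in refset:
        if len(seq) != len(st):
            raise ConsistencyError("reference sequence/structure mismatch")
        for s, aa in zip(st.ss, seq):
            counts[SS_INDEX[s], AA_INDEX[aa]] += 1
    return SSModel(table=_log_odds(counts, _refset_aa_freq(refset)))


def evaluate_ss(seq: str, ss, model: SSModel) -> float:
    """Sum over positions of table(ss_i, aa_i)."""
    ss = list(ss)
    if len(seq) != len(ss):
        raise ConsistencyError("sequence/SS length mismatch")
    total = 0.0
    for aa, s in zip(seq, ss):
        total += model.table[SS_INDEX[s], AA_INDEX[aa]]
    return float(total)


# ---------------------------------------------------------------------------
# Distance-dependent contact potential (DFIRE reference state)
# ---------------------------------------------------------------------------

@dataclass
class ContactModel:
    """Pairwise distance-binned potential for one atom flavour (CA or SC)."""

    atom_mode: str = "CA"
    r_cut: float = 14.5
    alpha: float = 1.61
    bin_width: float = 0.5
    min_seq_sep: int = 2
    counts: np.ndarray | None = None
    energies: np.ndarray = field(default_factory=lambda: np.zeros((N_AA, N_AA, 29)))

    @property
    def n_bins(self) -> int:
        return self.energies.shape[2]

    def __post_init__(self) -> None:
        if self.atom_mode not in ("CA", "SC"):
            raise ValueError("atom_mode must be 'CA' or 'SC'")
        self.energies = np.asarray(self.energies, dtype=float)
        if not np.isfinite(self.energies).all():
            raise ValueError("contact energies have non-finite entries")


def _mode_coords(structure: Structure, atom_mode: str) -> np.ndarray:
    return (structure.ca_coords() if atom_mode == "CA"
            else structure.sc_coords())


def contact_pairs(structure: Structure, model: ContactModel
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(i, j, bin) arrays of residue pairs within the cutoff, i < j.

    Only pairs with sequence separation |i-j| >= min_seq_sep count; the bin
    index is floor(d / bin_width).
    """
    coords = _mode_coords(structure, model.atom_mode)
    n = len(coords)
    d = squareform(pdist(coords))
    ii, jj = np.triu_indices(n, k=model.min_seq_sep)
    dd = d[ii, jj]
    keep = dd < model.r_cut
    bins = np.minimum((dd[keep] / model.bin_width).astype(int),
                      model.n_bins - 1)
    return ii[keep], jj[keep], bins


def derive_contact(refset, atom_mode: str = "CA", bin_width: float = 0.5,
                   min_seq_sep: int = 2, r_cut: float = 14.5,
                   alpha: float = 1.61) -> ContactModel:
    """DFIRE-style potential from observed pair-distance counts.

    energy(a,b,k) = -ln[ N(a,b,k) / ((r_k/r_ref)^alpha N(a,b,ref)) ] with
    +1 pseudocounts on every count, r_k the bin midpoint and the reference
    bin the last one below r_cut; energy is identically 0 at and beyond the
    reference distance. Counts are accumulated symmetrically in (a,b).
    """
    refset = list(refset)
    if len(refset) < 2:
        raise DerivationError("need at least 2 reference structures")
    n_bins = int(round(r_cut / bin_width))
    model = ContactModel(atom_mode=atom_mode, r_cut=r_cut, alpha=alpha,
                         bin_width=bin_width, min_seq_sep=min_seq_sep,
                         energies=np.zeros((N_AA, N_AA, n_bins)))
    counts = np.zeros((N_AA, N_AA, n_bins))
    for st, seq in refset:
        aa_idx = np.fromiter((AA_INDEX[a] for a in seq), int, len(seq))
        ii, jj, bins = contact_pairs(st, model)
        for i, j, k in zip(aa_idx[ii], aa_idx[jj], bins):
            counts[i, j, k] += 1
            counts[j, i, k] += 1

    nc = counts + 1.0
    r_mid = (np.arange(n_bins) + 0.5) * bin_width
    r_ref = r_mid[-1]
    scale = (r_mid / r_ref) ** alpha
    energies = -np.log(nc / (scale[None, None, :] * nc[:, :, -1:]))
    energies[:, :, -1] = 0.0
    model.counts = counts
    model.energies = energies
    return model


def evaluate_contact(seq: str, structure: Structure,
                     model: ContactModel) -> float:
    """Sum of pair energies over contacts below the reference distance."""
    if len(seq) != len(structure):
        raise ConsistencyError("sequence/structure length mismatch")
    aa_idx = np.fromiter((AA_INDEX[a] for a in seq), int, len(seq))
    ii, jj, bins = contact_pairs(structure, model)
    return float(model.energies[aa_idx[ii], aa_idx[jj], bins].sum())


# ---------------------------------------------------------------------------
# Length-independence transform
# ---------------------------------------------------------------------------

@dataclass
class LengthTransform:
    """Linear trend of a raw term in chain length L, subtracted on use."""

    slope: float = 0.0
    intercept: float = 0.0

    def apply(self, raw: float, length: int) -> float:
        return raw - (self.slope * length + self.intercept)


def fit_length_transform(term_fn, structures, rng,
                         n_random: int = 200, table=None) -> LengthTransform:
    """Regress the mean random-sequence raw energy on chain length.

    ``term_fn(seq, structure) -> float``; ``structures`` must span at least
    three distinct lengths. After the transform, the expected raw score of a
    random sequence is ~0 at every length.
    """
    from .fixtures import default_frequency_table, random_sequence

    structures = list(structures)
    lengths = np.array([len(s) for s in structures], dtype=float)
    if len(set(lengths)) < 3:
        raise DerivationError("need >= 3 distinct chain lengths")
    table = table or default_frequency_table()
    means = []
    for st in structures:
        vals = [term_fn(random_sequence(len(st), table, rng), st)
                for _ in range(n_random)]
        means.append(float(np.mean(vals)))
    slope, intercept = np.polyfit(lengths, np.array(means), 1)
    return LengthTransform(slope=float(slope), intercept=float(intercept))
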