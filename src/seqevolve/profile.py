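"""Structure-based sequence profiles from TM-score structural alignments.

A target backbone is aligned against every member of a structure library
with a TM-align-style heuristic (gapless-threading and secondary-structure
seeds, then iterative superposition / dynamic-programming refinement).
Analogs whose alignment reaches a TM-score of at least 0.4 — the accepted
significance threshold for shared topology — contribute their aligned
residues to an L x 7 position-specific frequency matrix over reduced
amino-acid classes. The reduced 7-class alphabet (small polar, large polar,
negative, positive, hydrophobic, aromatic, histidine) trades residue detail
for signal-to-noise in low-homology profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConsistencyError, DegenerateInputError
from .structio import AA_INDEX, AMINO_ACIDS, Structure

logger = logging.getLogger("seqevolve")

# ---------------------------------------------------------------------------
# Reduced amino-acid classes
# ---------------------------------------------------------------------------

CLASS_NAMES = ["small_polar", "large_polar", "negative", "positive",
               "hydrophobic", "aromatic", "histidine"]

_DEFAULT_CLASSES = {
    "small_polar": "GSTC",
    "large_polar": "NQ",
    "negative": "DE",
    "positive": "KR",
    "hydrophobic": "AVLIMP",
    "aromatic": "FWY",
    "histidine": "H",
}


@dataclass
class ClassMap:
    """Total, single-valued map from the 20 amino acids to 7 classes."""

    mapping: dict[str, str] = field(default_factory=lambda: {
        aa: cls for cls, members in _DEFAULT_CLASSES.items() for aa in members
    })

    def __post_init__(self) -> None:
        if set(self.mapping) != set(AMINO_ACIDS):
            raise ValueError("class map must cover exactly the 20 amino acids")
        if set(self.mapping.values()) - set(CLASS_NAMES):
            raise ValueError("class map uses unknown class names")
        if self.mapping["H"] != "histidine":
            raise ValueError("histidine must map to its own class")
        self._index = {cls: k for k, cls in enumerate(CLASS_NAMES)}
        self.aa_class_idx = np.array(
            [self._index[self.mapping[aa]] for aa in AMINO_ACIDS])

    @property
    def n_classes(self) -> int:
        return len(CLASS_NAMES)

    def class_of(self, aa: str) -> str:
        return self.mapping[aa]

    def index_of(self, aa: str) -> int:
        return int(self.aa_class_idx[AA_INDEX[aa]])

    def class_background(self, freq_table) -> np.ndarray:
        """Class frequencies implied by an amino-acid frequency table."""
        bg = np.zeros(self.n_classes)
        for aa, p in freq_table.freq.items():
            bg[self.index_of(aa)] += p
        return bg


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(coords_a: np.ndarray, coords_b: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping ``coords_b`` onto ``coords_a``.

    Returns (rotation R, translation t, rmsd); apply as ``b @ R.T + t``.
    The rotation is proper (det +1). Requires at least 3 non-collinear pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise DegenerateInputError("superposition needs >= 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9:  # rank < 2: collinear or coincident points
        raise DegenerateInputError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ca - r @ cb
    moved = b @ r.T + t
    rmsd = float(np.sqrt(((moved - a) ** 2).sum(axis=1).mean()))
    return r, t, rmsd


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(length: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 A."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


@dataclass
class Alignment:
    """Sequential residue correspondence between a target and an analog."""

    pairs: list[tuple[int, int]]
    tm_score: float          # normalized by the target length
    rmsd: float              # CA RMSD over the aligned pairs
    tm_by_analog: float = 0.0  # same alignment normalized by the analog length

    def __post_init__(self) -> None:
        ii = [p[0] for p in self.pairs]
        jj = [p[1] for p in self.pairs]
        if any(np.diff(ii) <= 0) or any(np.diff(jj) <= 0):
            raise ConsistencyError("alignment pairs must be strictly increasing")


def _tm_sum(d: np.ndarray, d0: float) -> float:
    return float((1.0 / (1.0 + (d / d0) ** 2)).sum())


def tm_score(pairs, coords_a: np.ndarray, coords_b: np.ndarray,
             l_target: int) -> float:
    """TM-score of an alignment, maximized over rigid superpositions.

    Follows the reference search strategy: superpose on fragments of the
    aligned pairs at several lengths and offsets, then iteratively
    re-superpose on the close pairs only, keeping the best score seen.
    """
    pairs = list(pairs)
    if not pairs:
        raise DegenerateInputError("empty alignment")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    a = np.asarray(coords_a, dtype=float)[ia]
    b = np.asarray(coords_b, dtype=float)[ib]
    n = len(pairs)
    d0 = tm_d0(l_target)
    if n < 3:
        # too few pairs for a fit: best case distances cannot beat n/L anyway
        return min(1.0, n / l_target)

    best = 0.0
    frag_lengths = sorted({n, max(n // 2, 3), max(n // 4, 3), min(4, n)},
                          reverse=True)
    for lf in frag_lengths:
        step = max(1, lf // 2)
        for start in range(0, n - lf + 1, step):
            sel = np.zeros(n, dtype=bool)
            sel[start:start + lf] = True
            for _ in range(20):
                try:
                    r, t, _ = superpose(a[sel], b[sel])
                except DegenerateInputError:
                    break
                d = np.linalg.norm(b @ r.T + t - a, axis=1)
                best = max(best, _tm_sum(d, d0) / l_target)
                d_cut = d0
                new_sel = d < d_cut
                while new_sel.sum() < 3 and d_cut < 8.0 * d0:
                    d_cut += 0.5
                    new_sel = d < d_cut
                if new_sel.sum() < 3 or np.array_equal(new_sel, sel):
                    break
                sel = new_sel
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# Structural aligner (TM-align-style heuristic)
# ---------------------------------------------------------------------------

GAP_PENALTY = -0.6


def _nw_semiglobal(score: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Sequential alignment maximizing the score sum, free end gaps.

    Vectorized Needleman-Wunsch: the within-row horizontal recursion is
    folded into a running-maximum scan, so each row is O(n) numpy work.
    """
    m, n = score.shape
    h = np.zeros((m + 1, n + 1))
    jj = np.arange(n + 1)
    for i in range(1, m + 1):
        x = np.empty(n + 1)
        x[0] = 0.0
        x[1:] = np.maximum(h[i - 1, :-1] + score[i - 1], h[i - 1, 1:] + gap)
        h[i] = np.maximum.accumulate(x - gap * jj) + gap * jj
        h[i, 0] = 0.0

    # start from the best cell on the bottom row / right column
    bi = int(np.argmax(h[m, :]))
    bj = int(np.argmax(h[:, n]))
    if h[m, bi] >= h[bj, n]:
        i, j = m, bi
    else:
        i, j = bj, n
    pairs: list[tuple[int, int]] = []
    tol = 1e-6
    while i > 0 and j > 0:
        v = h[i, j]
        if abs(v - (h[i - 1, j - 1] + score[i - 1, j - 1])) < tol:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif abs(v - (h[i - 1, j] + gap)) < tol:
            i -= 1
        elif abs(v - (h[i, j - 1] + gap)) < tol:
            j -= 1
        elif abs(v) < tol:
            break
        else:  # pragma: no cover - defensive
            break
    pairs.reverse()
    return pairs


def _threading_seeds(la: int, lb: int, ca_a: np.ndarray, ca_b: np.ndarray,
                     d0: float, top: int = 3) -> list[list[tuple[int, int]]]:
    """Best gapless offsets, ranked by TM-sum after one superposition."""
    min_overlap = max(5, min(la, lb) // 2)
    scored = []
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        i0 = max(0, off)
        j0 = i0 - off
        ln = min(la - i0, lb - j0)
        if ln < min_overlap:
            continue
        ia = np.arange(i0, i0 + ln)
        ib = np.arange(j0, j0 + ln)
        try:
            r, t, _ = superpose(ca_a[ia], ca_b[ib])
        except DegenerateInputError:
            continue
        d = np.linalg.norm(ca_b[ib] @ r.T + t - ca_a[ia], axis=1)
        scored.append((_tm_sum(d, d0), off, ia, ib))
    scored.sort(key=lambda x: (-x[0], x[1]))
    return [list(zip(ia.tolist(), ib.tolist()))
            for _, _, ia, ib in scored[:top]]


def _ss_elements(ss: str) -> list[tuple[str, int, int]]:
    """Runs of H or E of length >= 3 as (type, start, end-exclusive)."""
    out = []
    i = 0
    while i < len(ss):
        if ss[i] in "HE":
            j = i
            while j < len(ss) and ss[j] == ss[i]:
                j += 1
            if j - i >= 3:
                out.append((ss[i], i, j))
            i = j
        else:
            i += 1
    return out


def _ss_seed(target: Structure, analog: Structure) -> list[tuple[int, int]]:
    """Pair residues of order-matched secondary-structure elements."""
    ea, eb = _ss_elements(target.ss), _ss_elements(analog.ss)
    if not ea or not eb:
        return []
    # monotone DP matching elements of equal type, reward = overlapped length
    na, nb = len(ea), len(eb)
    dp = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            match = 0.0
            if ea[i - 1][0] == eb[j - 1][0]:
                match = min(ea[i - 1][2] - ea[i - 1][1],
                            eb[j - 1][2] - eb[j - 1][1])
            dp[i, j] = max(dp[i - 1, j - 1] + match, dp[i - 1, j], dp[i, j - 1])
    pairs: list[tuple[int, int]] = []
    i, j = na, nb
    while i > 0 and j > 0:
        match = 0.0
        if ea[i - 1][0] == eb[j - 1][0]:
            match = min(ea[i - 1][2] - ea[i - 1][1],
                        eb[j - 1][2] - eb[j - 1][1])
        if dp[i, j] == dp[i - 1, j - 1] + match and match > 0:
            ta, tb = ea[i - 1], eb[j - 1]
            ln = int(match)
            for k in range(ln):
                pairs.append((ta[1] + k, tb[1] + k))
            i, j = i - 1, j - 1
        elif dp[i, j] == dp[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.sort()
    # enforce strict monotonicity in both indices
    mono: list[tuple[int, int]] = []
    for p in pairs:
        if not mono or (p[0] > mono[-1][0] and p[1] > mono[-1][1]):
            mono.append(p)
    return mono


def align_structures(target: Structure, analog: Structure,
                     gap_penalty: float = GAP_PENALTY,
                     max_iter: int = 30) -> Alignment:
    """Sequential structure alignment maximizing the target-normalized TM-score.

    Seeds from gapless threading and secondary-structure-element matching
    are refined by alternating Kabsch superposition on the current pairs
    with dynamic programming on the TM-style proximity matrix
    1/(1+(d_ij/d0)^2). Deterministic given its inputs.
    """
    if len(target) < 10 or len(analog) < 10:
        raise DegenerateInputError("alignment needs chains of >= 10 residues")
    ca_a = target.ca_coords()
    ca_b = analog.ca_coords()
    la, lb = len(target), len(analog)
    d0 = tm_d0(la)

    seeds = _threading_seeds(la, lb, ca_a, ca_b, d0)
    ss_seed = _ss_seed(target, analog)
    if len(ss_seed) >= 3:
        seeds.append(ss_seed)

    best_pairs: list[tuple[int, int]] = []
    best_quick = -1.0
    for seed in seeds:
        pairs = seed
        prev: list[tuple[int, int]] | None = None
        for _ in range(max_iter):
            if len(pairs) < 3:
                break
            ia = np.array([p[0] for p in pairs])
            ib = np.array([p[1] for p in pairs])
            try:
                r, t, _ = superpose(ca_a[ia], ca_b[ib])
            except DegenerateInputError:
                break
            moved = ca_b @ r.T + t
            dmat = cdist(ca_a, moved)
            smat = 1.0 / (1.0 + (dmat / d0) ** 2)
            new_pairs = _nw_semiglobal(smat, gap_penalty)
            if len(new_pairs) < 3:
                break
            quick = float(smat[tuple(np.array(new_pairs).T)].sum())
            if quick > best_quick:
                best_quick = quick
                best_pairs = new_pairs
            if prev is not None and new_pairs == prev:
                break
            prev, pairs = pairs, new_pairs

    if len(best_pairs) < 3:
        # pathological geometry: fall back to the best raw seed
        best_pairs = max(seeds, key=len) if seeds else []
    if len(best_pairs) < 3:
        raise DegenerateInputError("no seed alignment could be built")

    tm_t = tm_score(best_pairs, ca_a, ca_b, la)
    tm_a = tm_score(best_pairs, ca_a, ca_b, lb)
    ia = np.array([p[0] for p in best_pairs])
    ib = np.array([p[1] for p in best_pairs])
    _, _, rmsd = superpose(ca_a[ia], ca_b[ib])
    return Alignment(pairs=best_pairs, tm_score=tm_t, rmsd=rmsd,
                     tm_by_analog=tm_a)


# ---------------------------------------------------------------------------
# Profile construction and scoring
# ---------------------------------------------------------------------------

TM_THRESHOLD = 0.4
ROW_PSEUDOCOUNT = 0.5


@dataclass
class Profile:
    """L x 7 class-frequency matrix with per-position contributor counts."""

    freqs: np.ndarray
    n_contributors: np.ndarray
    background: np.ndarray
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def log_ratio(self) -> np.ndarray:
        """ln(row frequency / background), the per-position scoring table."""
        return np.log(self.freqs / self.background[None, :])


def background_profile(length: int, background: np.ndarray) -> Profile:
    """Uninformative profile whose every row equals the class background."""
    freqs = np.tile(background / background.sum(), (length, 1))
    return Profile(freqs=freqs, n_contributors=np.zeros(length, dtype=int),
                   background=background)


def build_profile(target: Structure, library, threshold: float = TM_THRESHOLD,
                  class_map: ClassMap | None = None,
                  freq_table=None, alignments=None) -> Profile:
    """Accumulate aligned analog residues into a position-class count matrix.

    Only analogs whose target-normalized TM-score is >= ``threshold``
    (inclusive) contribute; the target's own sequence never does. Rows are
    normalized with +0.5 pseudocounts per class; the background is the class
    distribution implied by the amino-acid frequency table. ``alignments``
    may supply precomputed alignments (same order as ``library``).
    """
    from .fixtures import default_frequency_table

    library = list(library)
    if not library:
        raise DegenerateInputError("profile library is empty")
    class_map = class_map or ClassMap()
    freq_table = freq_table or default_frequency_table()
    background = class_map.class_background(freq_table)

    counts = np.zeros((len(target), class_map.n_classes))
    n_used = 0
    for k, (analog, seq) in enumerate(library):
        aln = alignments[k] if alignments is not None \
            else align_structures(target, analog)
        logger.info("analog %s: TM-score %.3f (%d pairs, rmsd %.2f)",
                    analog.id, aln.tm_score, len(aln.pairs), aln.rmsd)
        if aln.tm_score < threshold:
            continue
        n_used += 1
        for i, j in aln.pairs:
            counts[i, class_map.index_of(seq[j])] += 1
    if n_used == 0:
        logger.warning("no analog reached TM-score %.2f; "
                       "returning background profile", threshold)
        return background_profile(len(target), background)

    n_contrib = counts.sum(axis=1)
    freqs = ((counts + ROW_PSEUDOCOUNT)
             / (n_contrib + ROW_PSEUDOCOUNT * class_map.n_classes)[:, None])
    return Profile(freqs=freqs, n_contributors=n_contrib.astype(int),
                   background=background)


def evaluate_profile(seq: str, profile: Profile,
                     class_map: ClassMap | None = None) -> float:
    """Sum of per-position log-ratios ln[p_i(class)/bg(class)]; higher = better."""
    class_map = class_map or ClassMap()
    if len(seq) != profile.length:
        raise ConsistencyError("sequence/profile length mismatch")
    lr = profile.log_ratio()
    idx = class_map.aa_class_idx[
        np.fromiter((AA_INDEX[a] for a in seq), int, len(seq))]
    return float(lr[np.arange(len(seq)), idx].sum())
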