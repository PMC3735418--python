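"""Anti-grouping restraint: penalize short-range same-class clustering.

Sequence optimizers driven by structure-conditioned potentials tend to tile
helices with runs of alanine and strands with runs of isoleucine/valine.
This term measures, per reduced amino-acid class, how many near-neighbour
position pairs share that class, compares the count with its exact
expectation and variance under random permutation of the fixed sequence
composition, and charges the positive z-scores:

    penalty = sum_c max(0, (O_c - E_c) / sqrt(V_c))

Only excess clustering is penalized — dispersion below expectation is not
an artifact. With the default window (adjacent positions only) and a class
with n of L positions, E_c = n(n-1)/L; the variance follows from exact
combinatorics of overlapping pair events, so no Monte Carlo is needed, and
classes whose count is deterministic under the null (V_c = 0) contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .profile import ClassMap


def _pair_set_geometry(length: int, window: int) -> tuple[int, int, int]:
    """Counts of (pairs M, unordered pair-pairs sharing one index A2, disjoint D2).

    The pair set S holds all index pairs (i, j), i < j, with j - i <= window.
    Two distinct pairs can share at most one index, so the second moment of
    the same-class pair count only needs M, A2 and D2.
    """
    deg = np.zeros(length, dtype=np.int64)
    m = 0
    for w in range(1, window + 1):
        k = max(length - w, 0)
        m += k
        deg[:k] += 1
        deg[w:w + k] += 1
    a2 = int((deg * (deg - 1) // 2).sum())
    d2 = m * (m - 1) // 2 - a2
    return m, a2, d2


def null_moments(length: int, n_c: int, window: int = 1
                 ) -> tuple[float, float]:
    """Exact mean and variance of the same-class pair count.

    Null model: uniformly random permutation of a fixed composition with
    ``n_c`` members of the class among ``length`` positions.
    """
    m, a2, d2 = _pair_set_geometry(length, window)
    lf = float(length)
    p2 = n_c * (n_c - 1) / (lf * (lf - 1)) if length >= 2 else 0.0
    p3 = (n_c * (n_c - 1) * (n_c - 2)
          / (lf * (lf - 1) * (lf - 2))) if length >= 3 else 0.0
    p4 = (n_c * (n_c - 1) * (n_c - 2) * (n_c - 3)
          / (lf * (lf - 1) * (lf - 2) * (lf - 3))) if length >= 4 else 0.0
    mean = m * p2
    second = m * p2 + 2 * a2 * p3 + 2 * d2 * p4
    var = max(second - mean * mean, 0.0)
    return mean, var


def null_moments_table(length: int, window: int = 1) -> np.ndarray:
    """(length+1) x 2 array of (mean, variance) for every class size n_c.

    Precomputed once per structure so the annealer's incremental updates
    stay O(1) per mutation.
    """
    out = np.empty((length + 1, 2))
    for n in range(length + 1):
        out[n] = null_moments(length, n, window)
    return out


@dataclass
class ClusterStat:
    """Observed/expected same-class pair counts and the resulting penalty."""

    classes: list[str]
    observed: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    z: np.ndarray

    @property
    def penalty(self) -> float:
        return float(np.maximum(self.z, 0.0).sum())


def observed_pairs(class_idx: np.ndarray, n_classes: int,
                   window: int = 1) -> np.ndarray:
    """Per-class count of same-class pairs within the window."""
    obs = np.zeros(n_classes)
    for w in range(1, window + 1):
        same = class_idx[:-w] == class_idx[w:]
        if same.any():
            np.add.at(obs, class_idx[:-w][same], 1)
    return obs


def cluster_statistics(seq: str, class_map: ClassMap | None = None,
                       window: int = 1) -> ClusterStat:
    """Full per-class clustering statistics for a sequence."""
    if len(seq) < 3:
        raise DegenerateInputError("clustering statistic needs L >= 3")
    class_map = class_map or ClassMap()
    from .structio import AA_INDEX

    idx = class_map.aa_class_idx[
        np.fromiter((AA_INDEX[a] for a in seq), int, len(seq))]
    ncl = class_map.n_classes
    obs = observed_pairs(idx, ncl, window)
    comp = np.bincount(idx, minlength=ncl)
    exp = np.zeros(ncl)
    var = np.zeros(ncl)
    for c in range(ncl):
        exp[c], var[c] = null_moments(len(seq), int(comp[c]), window)
    z = np.zeros(ncl)
    active = var > 1e-12
    z[active] = (obs[active] - exp[active]) / np.sqrt(var[active])
    from .profile import CLASS_NAMES

    return ClusterStat(classes=list(CLASS_NAMES), observed=obs,
                       expected=exp, variance=var, z=z)


def clustering_penalty(seq: str, class_map: ClassMap | None = None,
                       window: int = 1) -> float:
    """Sum over classes of the positive part of the clustering z-score."""
    return cluster_statistics(seq, class_map, window).penalty
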