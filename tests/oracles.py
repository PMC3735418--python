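"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the library's own vectorized code
paths: neighbour counts and pair tallies are explicit Python loops over
raw coordinates, the clustering null is estimated by Monte Carlo
permutation, and the toy design problem is solved by exhaustive
enumeration from the model tables directly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from seqevolve.structio import AA_INDEX, SS_INDEX


def brute_neighbor_counts(structure, radius: float) -> list[int]:
    """CB-within-radius neighbour counts by explicit pairwise loops."""
    cb = structure.cb_coords()
    n = len(cb)
    counts = []
    for i in range(n):
        c = 0
        for j in range(n):
            if i == j:
                continue
            d = math.dist(cb[i], cb[j])
            if d < radius:
                c += 1
        counts.append(c)
    return counts


def brute_burial_table(refset, model) -> np.ndarray:
    """Recount the burial state/amino-acid table and rebuild the log-odds."""
    counts = np.zeros((model.n_states, 20))
    aa_tally = np.zeros(20)
    for st, seq in refset:
        ncounts = brute_neighbor_counts(st, model.radius)
        for c, aa in zip(ncounts, seq):
            state = 0
            for e in model.bin_edges:
                if c >= e:
                    state += 1
            counts[state, AA_INDEX[aa]] += 1
            aa_tally[AA_INDEX[aa]] += 1
    freq = aa_tally / aa_tally.sum()
    table = np.empty_like(counts)
    for s in range(model.n_states):
        ns = counts[s].sum()
        for a in range(20):
            table[s, a] = -math.log((counts[s, a] + 1.0)
                                    / (ns * freq[a] + 1.0))
    return table


def brute_ss_table(refset) -> np.ndarray:
    counts = np.zeros((7, 20))
    aa_tally = np.zeros(20)
    for st, seq in refset:
        for s, aa in zip(st.ss, seq):
            counts[SS_INDEX[s], AA_INDEX[aa]] += 1
            aa_tally[AA_INDEX[aa]] += 1
    freq = aa_tally / aa_tally.sum()
    table = np.empty_like(counts)
    for s in range(7):
        ns = counts[s].sum()
        for a in range(20):
            table[s, a] = -math.log((counts[s, a] + 1.0)
                                    / (ns * freq[a] + 1.0))
    return table


def brute_contact_counts(refset, atom_mode: str, r_cut: float,
                         bin_width: float, min_seq_sep: int) -> np.ndarray:
    """O(L^2) pair tally of distance-binned amino-acid contacts."""
    n_bins = int(round(r_cut / bin_width))
    counts = np.zeros((20, 20, n_bins))
    for st, seq in refset:
        coords = (st.ca_coords() if atom_mode == "CA" else st.sc_coords())
        L = len(coords)
        for i in range(L):
            for j in range(i + min_seq_sep, L):
                d = math.dist(coords[i], coords[j])
                if d >= r_cut:
                    continue
                k = min(int(d / bin_width), n_bins - 1)
                a, b = AA_INDEX[seq[i]], AA_INDEX[seq[j]]
                counts[a, b, k] += 1
                counts[b, a, k] += 1
    return counts


def dfire_energies_from_counts(counts: np.ndarray, alpha: float,
                               bin_width: float) -> np.ndarray:
    """Rebuild the DFIRE energies from a count tensor, loop by loop."""
    n_bins = counts.shape[2]
    out = np.zeros_like(counts)
    r_ref = (n_bins - 0.5) * bin_width
    for a in range(20):
        for b in range(20):
            nref = counts[a, b, n_bins - 1] + 1.0
            for k in range(n_bins - 1):
                r = (k + 0.5) * bin_width
                out[a, b, k] = -math.log(
                    (counts[a, b, k] + 1.0) / ((r / r_ref) ** alpha * nref))
    return out


def permutation_penalty(seq: str, class_map, n_perm: int,
                        rng: np.random.Generator,
                        window: int = 1) -> tuple[float, np.ndarray, np.ndarray]:
    """Clustering penalty with E_c and V_c estimated by Monte Carlo.

    Returns (penalty, empirical means, empirical variances).
    """
    idx = np.array([class_map.index_of(a) for a in seq])
    ncl = class_map.n_classes

    def same_class_pairs(x):
        obs = np.zeros(ncl)
        for w in range(1, window + 1):
            for i in range(len(x) - w):
                if x[i] == x[i + w]:
                    obs[x[i]] += 1
        return obs

    obs = same_class_pairs(idx)
    samples = np.empty((n_perm, ncl))
    for t in range(n_perm):
        samples[t] = same_class_pairs(rng.permutation(idx))
    means = samples.mean(axis=0)
    variances = samples.var(axis=0)
    penalty = 0.0
    for c in range(ncl):
        if variances[c] > 1e-12:
            penalty += max(0.0, (obs[c] - means[c]) / math.sqrt(variances[c]))
    return penalty, means, variances


def enumerate_max_fitness(structure, model, alphabet: str) -> float:
    """Exhaustive maximum of the combined fitness over a reduced alphabet.

    Works from the model's tables directly (vectorized over all sequences)
    rather than through the package's evaluation path.
    """
    from seqevolve.antigroup import null_moments

    L = len(structure)
    letters = np.array([AA_INDEX[a] for a in alphabet])
    combos = np.array(list(itertools.product(range(len(alphabet)), repeat=L)))
    seqs = letters[combos]                       # (N, L) amino-acid indices
    n = len(seqs)

    states = brute_neighbor_counts(structure, model.burial.radius)
    states = np.digitize(states, model.burial.bin_edges)
    ss_idx = np.array([SS_INDEX[s] for s in structure.ss])

    raw = {}
    raw["burial"] = model.burial.table[states[None, :],
                                       seqs].sum(axis=1)
    raw["ss"] = model.ss.table[ss_idx[None, :], seqs].sum(axis=1)

    for name, cm in (("contact_ca", model.contact_ca),
                     ("contact_sc", model.contact_sc)):
        coords = (structure.ca_coords() if cm.atom_mode == "CA"
                  else structure.sc_coords())
        total = np.zeros(n)
        for i in range(L):
            for j in range(i + cm.min_seq_sep, L):
                d = math.dist(coords[i], coords[j])
                if d >= cm.r_cut:
                    continue
                k = min(int(d / cm.bin_width), cm.n_bins - 1)
                total += cm.energies[seqs[:, i], seqs[:, j], k]
        lt = model.length_ca if name == "contact_ca" else model.length_sc
        raw[name] = total - (lt.slope * L + lt.intercept)

    lr = model.profile.log_ratio()
    cls = model.class_map.aa_class_idx[seqs]     # (N, L)
    raw["profile"] = lr[np.arange(L)[None, :], cls].sum(axis=1)

    penalty = np.zeros(n)
    moments = [null_moments(L, k, model.antigroup_window)
               for k in range(L + 1)]
    for c in range(model.class_map.n_classes):
        is_c = cls == c
        n_c = is_c.sum(axis=1)
        obs = np.zeros(n)
        for w in range(1, model.antigroup_window + 1):
            obs += (is_c[:, :-w] & is_c[:, w:]).sum(axis=1)
        mean = np.array([moments[k][0] for k in n_c])
        var = np.array([moments[k][1] for k in n_c])
        ok = var > 1e-12
        z = np.zeros(n)
        z[ok] = (obs[ok] - mean[ok]) / np.sqrt(var[ok])
        penalty += np.maximum(z, 0.0)
    raw["antigroup"] = penalty

    from seqevolve.fitness import TERMS
    fit = np.ones(n)
    for k, t in enumerate(TERMS):
        nz = model.normalizers[t]
        fit += model.weights[k] * nz.orientation * (raw[t] - nz.mu) / nz.sigma
    return float(fit.max())
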