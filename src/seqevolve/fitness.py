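"""Combined fitness: normalized terms, calibrated weights, incremental moves.

The six raw terms (burial, secondary structure, CA contacts, side-chain
contacts, profile, anti-grouping) live on incompatible scales, so each is
z-normalized against random background sequences drawn for the target
structure, with its sign oriented so that larger means more native-like.
The combined score is

    fitness = 1 + sum_t w_t * z_t(seq),   w_t >= 0, sum_t w_t = 1,

so a random sequence scores ~1.0 by construction and evolved sequences
climb above it. Weights are calibrated on native-versus-decoy sequence
sets by maximizing the average native-decoy z-gap.

:class:`FitnessState` provides the O(neighbourhood) single-mutation update
the annealer's inner loop depends on; it must agree with full
re-evaluation to 1e-9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import antigroup as ag
from . import potentials as pot
from . import profile as prof
from .errors import CalibrationError, ConsistencyError
from .structio import AA_INDEX, AMINO_ACIDS, SS_INDEX, Structure

logger = logging.getLogger("seqevolve")

TERMS = ["burial", "ss", "contact_ca", "contact_sc", "profile", "antigroup"]

#: +1 if larger raw values are more native-like, else -1. Energies and the
#: clustering penalty decrease for good sequences; the profile log-ratio grows.
ORIENTATION = {"burial": -1.0, "ss": -1.0, "contact_ca": -1.0,
               "contact_sc": -1.0, "profile": 1.0, "antigroup": -1.0}


@dataclass
class TermNormalizer:
    """Random-sequence mean/SD of a raw term on one target, plus orientation."""

    mu: float
    sigma: float
    orientation: float

    def normalize(self, raw: float) -> float:
        return self.orientation * (raw - self.mu) / self.sigma


@dataclass
class EnergyModel:
    """Everything needed to score a sequence on a fixed backbone."""

    burial: pot.BurialModel
    ss: pot.SSModel
    contact_ca: pot.ContactModel
    contact_sc: pot.ContactModel
    profile: prof.Profile
    class_map: prof.ClassMap
    freq_table: object  # AAFrequencyTable
    length_ca: pot.LengthTransform = field(default_factory=pot.LengthTransform)
    length_sc: pot.LengthTransform = field(default_factory=pot.LengthTransform)
    normalizers: dict[str, TermNormalizer] | None = None
    weights: np.ndarray = field(
        default_factory=lambda: np.full(len(TERMS), 1.0 / len(TERMS)))
    antigroup_window: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(TERMS),) or (self.weights < 0).any():
            raise ValueError("weights must be 6 non-negative values")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def calibrated(self) -> bool:
        return self.normalizers is not None


def _aa_array(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[a] for a in seq), np.int64, len(seq))


class StructureContext:
    """Precomputed per-structure lookups shared by all sequence evaluations."""

    def __init__(self, structure: Structure, model: EnergyModel):
        self.structure = structure
        self.length = len(structure)
        self.burial_state = pot.burial_states(structure, model.burial)
        self.ss_idx = np.fromiter((SS_INDEX[s] for s in structure.ss),
                                  np.int64, self.length)
        if model.profile.length != self.length:
            raise ConsistencyError("profile length does not match structure")
        self.log_ratio = model.profile.log_ratio()
        self.aa_class = model.class_map.aa_class_idx

        self.pairs = {}
        self.neighbors = {}
        for name, cm in (("contact_ca", model.contact_ca),
                         ("contact_sc", model.contact_sc)):
            ii, jj, bins = pot.contact_pairs(structure, cm)
            self.pairs[name] = (ii, jj, bins)
            nb_idx = [[] for _ in range(self.length)]
            nb_bin = [[] for _ in range(self.length)]
            for i, j, b in zip(ii, jj, bins):
                nb_idx[i].append(j)
                nb_bin[i].append(b)
                nb_idx[j].append(i)
                nb_bin[j].append(b)
            self.neighbors[name] = (
                [np.array(v, dtype=np.int64) for v in nb_idx],
                [np.array(v, dtype=np.int64) for v in nb_bin])
        # constant offsets from the length-independence transforms
        self.offsets = {
            "contact_ca": model.length_ca.slope * self.length
            + model.length_ca.intercept,
            "contact_sc": model.length_sc.slope * self.length
            + model.length_sc.intercept,
        }
        self.ag_moments = ag.null_moments_table(self.length,
                                                model.antigroup_window)


def raw_terms(seq: str, structure: Structure, model: EnergyModel,
              context: StructureContext | None = None) -> dict[str, float]:
    """All six raw term values (length transforms applied to the contacts)."""
    ctx = context or StructureContext(structure, model)
    if len(seq) != ctx.length:
        raise ConsistencyError("sequence/structure length mismatch")
    aa = _aa_array(seq)
    out = {
        "burial": float(model.burial.table[ctx.burial_state, aa].sum()),
        "ss": float(model.ss.table[ctx.ss_idx, aa].sum()),
        "profile": float(
            ctx.log_ratio[np.arange(ctx.length), ctx.aa_class[aa]].sum()),
        "antigroup": ag.clustering_penalty(seq, model.class_map,
                                           model.antigroup_window),
    }
    for name, cm in (("contact_ca", model.contact_ca),
                     ("contact_sc", model.contact_sc)):
        ii, jj, bins = ctx.pairs[name]
        raw = float(cm.energies[aa[ii], aa[jj], bins].sum())
        out[name] = raw - ctx.offsets[name]
    return out


def calibrate_normalizers(structure: Structure, model: EnergyModel,
                          n_random: int = 200, rng=None
                          ) -> dict[str, TermNormalizer]:
    """Per-term mean/SD over random background sequences on this target."""
    from .fixtures import random_sequence
    from .rng import make_rng

    if n_random < 30:
        raise CalibrationError("need at least 30 random sequences")
    rng = rng if rng is not None else make_rng()
    ctx = StructureContext(structure, model)
    samples = {t: np.empty(n_random) for t in TERMS}
    for k in range(n_random):
        seq = random_sequence(ctx.length, model.freq_table, rng)
        raws = raw_terms(seq, structure, model, ctx)
        for t in TERMS:
            samples[t][k] = raws[t]
    normalizers = {}
    for t in TERMS:
        mu = float(samples[t].mean())
        sigma = float(samples[t].std(ddof=1))
        if sigma <= 1e-12:
            raise CalibrationError(
                f"term {t!r} is degenerate on this structure (SD = 0)")
        normalizers[t] = TermNormalizer(mu=mu, sigma=sigma,
                                        orientation=ORIENTATION[t])
    return normalizers


def fitness(seq: str, structure: Structure, model: EnergyModel,
            context: StructureContext | None = None) -> float:
    """Combined score; ~1.0 for random sequences, larger = more native-like."""
    if not model.calibrated:
        raise CalibrationError("model has no normalizers; calibrate first")
    raws = raw_terms(seq, structure, model, context)
    z = np.array([model.normalizers[t].normalize(raws[t]) for t in TERMS])
    return float(1.0 + model.weights @ z)


# ---------------------------------------------------------------------------
# Incremental evaluation (the annealer's inner loop)
# ---------------------------------------------------------------------------

class FitnessState:
    """Mutable sequence state with O(neighbourhood) single-mutation updates."""

    def __init__(self, seq: str, structure: Structure, model: EnergyModel,
                 context: StructureContext | None = None):
        if not model.calibrated:
            raise CalibrationError("model has no normalizers; calibrate first")
        self.model = model
        self.ctx = context or StructureContext(structure, model)
        self.structure = structure
        self._scale = np.array(
            [model.weights[k] * ORIENTATION[t] / model.normalizers[t].sigma
             for k, t in enumerate(TERMS)])
        self.reset(seq)

    def reset(self, seq: str) -> None:
        """Full recomputation from a sequence string."""
        self.aa = _aa_array(seq)
        self.raws = raw_terms(seq, self.structure, self.model, self.ctx)
        m, cm = self.model, self.model.class_map
        self.cls = cm.aa_class_idx[self.aa].copy()
        self.comp = np.bincount(self.cls, minlength=cm.n_classes).astype(np.int64)
        self.obs = ag.observed_pairs(self.cls, cm.n_classes,
                                     m.antigroup_window)

    @property
    def sequence(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.aa)

    @property
    def fitness(self) -> float:
        z = np.array([self.model.normalizers[t].normalize(self.raws[t])
                      for t in TERMS])
        return float(1.0 + self.model.weights @ z)

    # -- antigroup helpers ------------------------------------------------

    def _class_z(self, c: int, obs_c: float, n_c: int) -> float:
        mean, var = self.ctx.ag_moments[n_c]
        if var <= 1e-12:
            return 0.0
        return (obs_c - mean) / np.sqrt(var)

    def _antigroup_delta(self, pos: int, new_cls: int
                         ) -> tuple[float, np.ndarray, np.ndarray]:
        old_cls = int(self.cls[pos])
        if new_cls == old_cls:
            return 0.0, self.obs, self.comp
        w = self.model.antigroup_window
        obs = self.obs.copy()
        for d in range(1, w + 1):
            for q in (pos - d, pos + d):
                if 0 <= q < self.ctx.length:
                    qc = int(self.cls[q])
                    if qc == old_cls:
                        obs[old_cls] -= 1
                    if qc == new_cls:
                        obs[new_cls] += 1
        comp = self.comp.copy()
        comp[old_cls] -= 1
        comp[new_cls] += 1
        delta = 0.0
        for c in (old_cls, new_cls):
            z_old = self._class_z(c, self.obs[c], int(self.comp[c]))
            z_new = self._class_z(c, obs[c], int(comp[c]))
            delta += max(0.0, z_new) - max(0.0, z_old)
        return delta, obs, comp

    # -- mutation interface -----------------------------------------------

    def term_deltas(self, pos: int, new_aa: int) -> np.ndarray:
        """Per-term raw deltas for substituting ``new_aa`` at ``pos``."""
        old_aa = int(self.aa[pos])
        m, ctx = self.model, self.ctx
        d = np.zeros(len(TERMS))
        d[0] = (m.burial.table[ctx.burial_state[pos], new_aa]
                - m.burial.table[ctx.burial_state[pos], old_aa])
        d[1] = (m.ss.table[ctx.ss_idx[pos], new_aa]
                - m.ss.table[ctx.ss_idx[pos], old_aa])
        for k, name in ((2, "contact_ca"), (3, "contact_sc")):
            cm = m.contact_ca if name == "contact_ca" else m.contact_sc
            nb_idx, nb_bin = ctx.neighbors[name]
            idx, bins = nb_idx[pos], nb_bin[pos]
            if len(idx):
                other = self.aa[idx]
                d[k] = float((cm.energies[new_aa, other, bins]
                              - cm.energies[old_aa, other, bins]).sum())
        new_cls = int(ctx.aa_class[new_aa])
        d[4] = ctx.log_ratio[pos, new_cls] - ctx.log_ratio[pos, self.cls[pos]]
        d[5], self._pending_obs, self._pending_comp = \
            self._antigroup_delta(pos, new_cls)
        return d

    def delta_fitness(self, pos: int, new_aa: int) -> float:
        """Fitness change of a single substitution, without applying it."""
        return float(self._scale @ self.term_deltas(pos, new_aa))

    def apply_deltas(self, pos: int, new_aa: int, deltas: np.ndarray) -> None:
        """Commit a substitution using deltas from :meth:`term_deltas`.

        Must follow the ``term_deltas`` call for the same (pos, new_aa): the
        pending clustering bookkeeping is reused.
        """
        for k, t in enumerate(TERMS):
            self.raws[t] += deltas[k]
        self.aa[pos] = new_aa
        self.cls[pos] = self.ctx.aa_class[new_aa]
        self.obs = self._pending_obs
        self.comp = self._pending_comp

    def apply(self, pos: int, new_aa: int) -> None:
        """Commit the substitution at ``pos`` (recomputes its deltas)."""
        self.apply_deltas(pos, new_aa, self.term_deltas(pos, new_aa))


# ---------------------------------------------------------------------------
# Weight calibration
# ---------------------------------------------------------------------------

def _z_vector(seq, structure, model, ctx) -> np.ndarray:
    raws = raw_terms(seq, structure, model, ctx)
    return np.array([model.normalizers[t].normalize(raws[t]) for t in TERMS])


def _gap_objective(w: np.ndarray, cases_z) -> float:
    total = 0.0
    for zn, zd in cases_z:
        fn = float(w @ zn)
        fd = zd @ w
        sd = float(fd.std())
        total += (fn - float(fd.mean())) / (sd + 1e-9)
    return total / len(cases_z)


def calibrate_weights(cases) -> np.ndarray:
    """Optimize term weights on native-versus-decoy discrimination.

    ``cases``: sequence of (model, structure, native_seq, decoy_seqs) with
    calibrated models. The objective is the mean over cases of the z-gap
    between the native fitness and the decoy fitness distribution, maximized
    over the probability simplex by projected coordinate ascent from the
    uniform start. Deterministic given its inputs.
    """
    cases = list(cases)
    if len(cases) < 5:
        raise CalibrationError("weight calibration needs >= 5 cases")
    cases_z = []
    for model, structure, native, decoys in cases:
        if len(decoys) < 10:
            raise CalibrationError("each case needs >= 10 decoys")
        ctx = StructureContext(structure, model)
        zn = _z_vector(native, structure, model, ctx)
        zd = np.stack([_z_vector(s, structure, model, ctx) for s in decoys])
        cases_z.append((zn, zd))

    return optimize_weights(cases_z)


def optimize_weights(cases_z) -> np.ndarray:
    """Projected coordinate ascent of the native-decoy z-gap on the simplex.

    ``cases_z``: list of (native z-vector, decoy z-matrix) pairs. Starts
    from uniform weights; if no move improves the objective, uniform is
    returned with a warning.
    """
    nt = len(TERMS)
    w = np.full(nt, 1.0 / nt)
    best = _gap_objective(w, cases_z)
    start = best
    for step in (0.2, 0.1, 0.05, 0.02, 0.01):
        improved = True
        while improved:
            improved = False
            for t in range(nt):
                for sign in (1.0, -1.0):
                    cand = w.copy()
                    cand[t] = max(0.0, cand[t] + sign * step)
                    s = cand.sum()
                    if s <= 0:
                        continue
                    cand /= s
                    val = _gap_objective(cand, cases_z)
                    if val > best + 1e-12:
                        w, best = cand, val
                        improved = True
    if best <= start + 1e-12:
        logger.warning("no feasible improvement; returning uniform weights")
        return np.full(nt, 1.0 / nt)
    return w


# ---------------------------------------------------------------------------
# Model assembly and serialization
# ---------------------------------------------------------------------------

def build_energy_model(target: Structure, refset, freq_table=None,
                       class_map: prof.ClassMap | None = None,
                       profile_threshold: float = prof.TM_THRESHOLD,
                       fit_length: bool = True, rng=None,
                       n_random_length: int = 50) -> EnergyModel:
    """Derive every table from a reference set and build the target's profile.

    ``refset`` is a list of (Structure, native sequence) pairs; it acts both
    as the derivation set for the statistical potentials and as the
    alignment library for the profile.
    """
    from .fixtures import default_frequency_table
    from .rng import make_rng

    freq_table = freq_table or default_frequency_table()
    class_map = class_map or prof.ClassMap()
    rng = rng if rng is not None else make_rng()

    burial = pot.derive_burial(refset)
    ss = pot.derive_ss(refset)
    c_ca = pot.derive_contact(refset, atom_mode="CA")
    c_sc = pot.derive_contact(refset, atom_mode="SC")
    profile = prof.build_profile(target, refset, threshold=profile_threshold,
                                 class_map=class_map, freq_table=freq_table)

    length_ca = pot.LengthTransform()
    length_sc = pot.LengthTransform()
    structures = [st for st, _ in refset]
    if fit_length and len({len(s) for s in structures}) >= 3:
        length_ca = pot.fit_length_transform(
            lambda s, st: pot.evaluate_contact(s, st, c_ca), structures,
            rng, n_random=n_random_length, table=freq_table)
        length_sc = pot.fit_length_transform(
            lambda s, st: pot.evaluate_contact(s, st, c_sc), structures,
            rng, n_random=n_random_length, table=freq_table)

    return EnergyModel(burial=burial, ss=ss, contact_ca=c_ca, contact_sc=c_sc,
                       profile=profile, class_map=class_map,
                       freq_table=freq_table, length_ca=length_ca,
                       length_sc=length_sc)


MODEL_FORMAT_VERSION = 1


def save_model(model: EnergyModel, path) -> None:
    """Serialize an EnergyModel to a single sectioned, versioned text file."""
    lines = [f"#SEQEVOLVE-MODEL v{MODEL_FORMAT_VERSION}"]

    def section(name: str, array: np.ndarray) -> None:
        arr = np.asarray(array, dtype=float)
        lines.append(f"#SECTION {name} shape={','.join(map(str, arr.shape))}")
        for row in arr.reshape(-1, arr.shape[-1]):
            lines.append("\t".join(repr(float(v)) for v in row))

    meta = {
        "burial_radius": model.burial.radius,
        "burial_states": model.burial.n_states,
        "contact_r_cut": model.contact_ca.r_cut,
        "contact_alpha": model.contact_ca.alpha,
        "contact_bin_width": model.contact_ca.bin_width,
        "contact_min_seq_sep": model.contact_ca.min_seq_sep,
        "antigroup_window": model.antigroup_window,
        "length_ca_slope": model.length_ca.slope,
        "length_ca_intercept": model.length_ca.intercept,
        "length_sc_slope": model.length_sc.slope,
        "length_sc_intercept": model.length_sc.intercept,
    }
    lines.append("#SECTION meta")
    for k, v in meta.items():
        lines.append(f"{k}\t{v!r}")
    lines.append("#SECTION class_map")
    for aa in AMINO_ACIDS:
        lines.append(f"{aa}\t{model.class_map.mapping[aa]}")
    lines.append("#SECTION freq_table")
    for aa in AMINO_ACIDS:
        lines.append(f"{aa}\t{model.freq_table.freq[aa]!r}")
    section("burial_edges", model.burial.bin_edges[None, :])
    section("burial_table", model.burial.table)
    section("ss_table", model.ss.table)
    section("contact_ca", model.contact_ca.energies)
    section("contact_sc", model.contact_sc.energies)
    section("profile_freqs", model.profile.freqs)
    section("profile_background", model.profile.background[None, :])
    section("profile_contributors",
            model.profile.n_contributors.astype(float)[None, :])
    section("weights", model.weights[None, :])
    if model.normalizers is not None:
        lines.append("#SECTION normalizers")
        for t in TERMS:
            n = model.normalizers[t]
            lines.append(f"{t}\t{n.mu!r}\t{n.sigma!r}\t{n.orientation!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> EnergyModel:
    """Inverse of :func:`save_model`."""
    from .fixtures import AAFrequencyTable

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#SEQEVOLVE-MODEL v"):
        raise ConsistencyError("not a model file")
    sections: dict[str, list[str]] = {}
    current = None
    for line in lines[1:]:
        if line.startswith("#SECTION"):
            parts = line.split()
            current = parts[1]
            sections[current] = []
            if len(parts) > 2 and parts[2].startswith("shape="):
                sections[current + "@shape"] = [parts[2][6:]]
        elif current is not None:
            sections[current].append(line)

    def array(name: str) -> np.ndarray:
        rows = [[float(v) for v in ln.split("\t")] for ln in sections[name]]
        arr = np.array(rows)
        shape = tuple(int(x) for x in sections[name + "@shape"][0].split(","))
        return arr.reshape(shape)

    meta = {}
    for ln in sections["meta"]:
        k, v = ln.split("\t")
        meta[k] = float(v)
    mapping = dict(ln.split("\t") for ln in sections["class_map"])
    freq = {k: float(v) for k, v in
            (ln.split("\t") for ln in sections["freq_table"])}

    burial = pot.BurialModel(radius=meta["burial_radius"],
                             n_states=int(meta["burial_states"]),
                             bin_edges=array("burial_edges")[0],
                             table=array("burial_table"))
    ss = pot.SSModel(table=array("ss_table"))
    kw = dict(r_cut=meta["contact_r_cut"], alpha=meta["contact_alpha"],
              bin_width=meta["contact_bin_width"],
              min_seq_sep=int(meta["contact_min_seq_sep"]))
    c_ca = pot.ContactModel(atom_mode="CA", energies=array("contact_ca"), **kw)
    c_sc = pot.ContactModel(atom_mode="SC", energies=array("contact_sc"), **kw)
    profile = prof.Profile(
        freqs=array("profile_freqs"),
        n_contributors=array("profile_contributors")[0].astype(int),
        background=array("profile_background")[0])
    normalizers = None
    if "normalizers" in sections:
        normalizers = {}
        for ln in sections["normalizers"]:
            t, mu, sigma, orient = ln.split("\t")
            normalizers[t] = TermNormalizer(float(mu), float(sigma),
                                            float(orient))
    return EnergyModel(
        burial=burial, ss=ss, contact_ca=c_ca, contact_sc=c_sc,
        profile=profile, class_map=prof.ClassMap(mapping=mapping),
        freq_table=AAFrequencyTable(freq),
        length_ca=pot.LengthTransform(meta["length_ca_slope"],
                                      meta["length_ca_intercept"]),
        length_sc=pot.LengthTransform(meta["length_sc_slope"],
                                      meta["length_sc_intercept"]),
        normalizers=normalizers,
        weights=array("weights")[0],
        antigroup_window=int(meta["antigroup_window"]))
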