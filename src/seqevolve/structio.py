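"""Reading and writing the standard formats the tool touches.

Single-chain PDB structures (via gemmi), STRIDE secondary-structure output
(ASG records), FASTA sequences, profile tables, amino-acid frequency
tables, and tab-separated annealing trajectories.

Conventions for imperfect input:

* residues lacking a CA atom are dropped with a logged warning;
* a missing CB on a non-glycine residue is rebuilt from N/CA/C with ideal
  tetrahedral geometry, so the burial term stays defined;
* altLoc duplicates keep the highest-occupancy atom (ties: first in file);
* HETATM records and waters are ignored, only the first MODEL is read;
* residues are re-indexed 1..L in file order, original numbering is only
  reported in log messages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (
    AmbiguityError,
    ConsistencyError,
    DegenerateInputError,
    FormatError,
)

logger = logging.getLogger("seqevolve")

# ---------------------------------------------------------------------------
# Alphabets
# ---------------------------------------------------------------------------

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "C", "PYL": "K",
}

#: 7-state secondary-structure alphabet (STRIDE convention).
SS_STATES = "HGIEBTC"
SS_INDEX = {s: i for i, s in enumerate(SS_STATES)}

MIN_CHAIN_LENGTH = 10

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One residue of a single-chain structure.

    ``cb`` equals ``ca`` for glycine; ``sc_centroid`` is the unweighted mean
    of the side-chain heavy atoms (CB and beyond) and also falls back to
    ``ca`` when no side-chain atom is resolved.
    """

    index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray
    sc_centroid: np.ndarray
    ss: str = "C"


@dataclass
class Structure:
    """An ordered single-chain backbone with per-residue annotations."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ss(self) -> str:
        return "".join(r.ss for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def cb_coords(self) -> np.ndarray:
        return np.array([r.cb for r in self.residues], dtype=float)

    def sc_coords(self) -> np.ndarray:
        return np.array([r.sc_centroid for r in self.residues], dtype=float)

    def set_ss(self, labels) -> None:
        """Attach secondary-structure labels, one per residue."""
        labels = list(labels)
        if len(labels) != len(self.residues):
            raise ConsistencyError(
                f"{len(labels)} SS labels for {len(self.residues)} residues"
            )
        for r, s in zip(self.residues, labels):
            r.ss = s if s in SS_INDEX else "C"

    def validate(self) -> None:
        if len(self.residues) < MIN_CHAIN_LENGTH:
            raise DegenerateInputError(
                f"chain of {len(self.residues)} residues is shorter than "
                f"{MIN_CHAIN_LENGTH}"
            )
        for k, r in enumerate(self.residues, start=1):
            if r.index != k:
                raise ConsistencyError("residues are not indexed 1..L")
            if not (np.isfinite(r.ca).all() and np.isfinite(r.cb).all()
                    and np.isfinite(r.sc_centroid).all()):
                raise ConsistencyError(f"non-finite coordinates at residue {k}")


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB position from backbone N/CA/C with ideal tetrahedral geometry.

    Standard construction used in backbone-only modelling: an orthogonal
    frame from the N-CA and CA-C bonds; the fixed coefficients place CB at
    ~1.53 A from CA with canonical bond angles.
    """
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec + ca


def _pick_altloc(atoms) -> dict:
    """Highest-occupancy atom per atom name; ties resolved by file order."""
    chosen: dict = {}
    for atom in atoms:
        name = atom.name
        if name not in chosen or atom.occ > chosen[name].occ:
            chosen[name] = atom
    return chosen


def read_structure(pdb_text: str, chain_id: str | None = None) -> Structure:
    """Parse a single-chain protein structure from PDB-format text.

    Raises :class:`FormatError` when no ATOM records are present,
    :class:`AmbiguityError` when several chains exist and no ``chain_id``
    selects one, and :class:`DegenerateInputError` for chains shorter than
    10 residues.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise FormatError("no ATOM records found in PDB input")
    model = st[0]  # first MODEL only

    chains = [ch for ch in model if any(res.het_flag == "A" for res in ch)]
    if not chains:
        raise FormatError("no ATOM records found in PDB input")
    if chain_id is not None:
        chains = [ch for ch in chains if ch.name == chain_id]
        if not chains:
            raise FormatError(f"chain {chain_id!r} not present")
    if len(chains) > 1:
        names = ", ".join(ch.name for ch in chains)
        raise AmbiguityError(f"multiple chains ({names}); pass chain_id")
    chain = chains[0]

    residues: list[Residue] = []
    for res in chain:
        if res.het_flag != "A":
            if res.name not in THREE_TO_ONE:
                continue  # HETATM ligand/water
        aa = THREE_TO_ONE.get(res.name)
        if aa is None:
            logger.warning("skipping non-standard residue %s %s",
                           res.name, res.seqid)
            continue
        atoms = _pick_altloc(res)
        if "CA" not in atoms:
            logger.warning("residue %s %s has no CA atom; dropped",
                           res.name, res.seqid)
            continue
        ca = np.array(atoms["CA"].pos.tolist(), dtype=float)

        if aa == "G":
            cb = ca.copy()
            sc = ca.copy()
        else:
            if "CB" in atoms:
                cb = np.array(atoms["CB"].pos.tolist(), dtype=float)
            elif "N" in atoms and "C" in atoms:
                cb = ideal_cb(
                    np.array(atoms["N"].pos.tolist(), dtype=float), ca,
                    np.array(atoms["C"].pos.tolist(), dtype=float))
                logger.warning("rebuilt CB for %s %s from backbone",
                               res.name, res.seqid)
            else:
                cb = ca.copy()
            side = [np.array(a.pos.tolist(), dtype=float)
                    for name, a in atoms.items()
                    if name not in _BACKBONE and not a.is_hydrogen()]
            sc = np.mean(side, axis=0) if side else ca.copy()

        residues.append(Residue(index=len(residues) + 1, aa=aa,
                                ca=ca, cb=cb, sc_centroid=sc))

    if len(residues) < MIN_CHAIN_LENGTH:
        raise DegenerateInputError(
            f"chain {chain.name!r} has {len(residues)} usable residues "
            f"(< {MIN_CHAIN_LENGTH})")

    out = Structure(id=st.name or "structure", residues=residues)
    _warn_chain_breaks(out)
    return out


def _warn_chain_breaks(structure: Structure) -> None:
    ca = structure.ca_coords()
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    bad = np.where((d <= 2.5) | (d >= 4.5))[0]
    for i in bad:
        logger.warning("CA(%d)-CA(%d) distance %.2f A suggests a chain break",
                       i + 1, i + 2, d[i])


def write_pdb(structure: Structure) -> str:
    """Minimal PDB text carrying CA, CB and the side-chain centroid.

    The centroid itself is not a PDB atom, so a pseudo CG atom is placed at
    ``2*sc_centroid - cb``; re-reading then recovers the centroid exactly as
    the mean of the side-chain atoms {CB, CG}. Glycine writes CA only.
    """
    one_to_three = {v: k for k, v in THREE_TO_ONE.items() if len(k) == 3}
    lines = []
    serial = 1
    for r in structure.residues:
        resname = one_to_three[r.aa]
        atom_list = [("CA", r.ca)]
        if r.aa != "G":
            atom_list.append(("CB", r.cb))
            atom_list.append(("CG", 2.0 * r.sc_centroid - r.cb))
        for name, pos in atom_list:
            name_field = f" {name:<3}"
            lines.append(
                f"ATOM  {serial:>5} {name_field} {resname} A{r.index:>4}"
                f"    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"  1.00  0.00           C")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# STRIDE input
# ---------------------------------------------------------------------------

def parse_stride(stride_text: str) -> list[str]:
    """Secondary-structure labels from STRIDE output (ASG records).

    One label per ASG record in file order. STRIDE's one-letter codes map
    onto the 7-state alphabet {H,G,I,E,B,T,C}; ``b`` means bridge (B) and
    any other unknown or lower-case code maps to coil (C).
    """
    labels = []
    for line in stride_text.splitlines():
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"malformed ASG record: {line!r}")
        code = fields[5]
        if code == "b":
            code = "B"
        labels.append(code if code in SS_INDEX else "C")
    if not labels:
        raise FormatError("no ASG records found in STRIDE input")
    return labels


def write_stride(structure: Structure) -> str:
    """STRIDE-style ASG records for a structure's SS labels (fixture aid)."""
    names = {"H": "AlphaHelix", "G": "310Helix", "I": "PiHelix",
             "E": "Strand", "B": "Bridge", "T": "Turn", "C": "Coil"}
    one_to_three = {v: k for k, v in THREE_TO_ONE.items() if len(k) == 3}
    lines = []
    for r in structure.residues:
        lines.append(
            f"ASG  {one_to_three[r.aa]} A {r.index:>4} {r.index:>4}    "
            f"{r.ss}    {names[r.ss]:<11}   360.00    360.00       0.0")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sequence / profile / frequency-table I/O
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ConsistencyError("sequences differ in length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def write_fasta(sequence: str, header: str) -> str:
    body = "\n".join(sequence[i:i + 60] for i in range(0, len(sequence), 60))
    return f">{header}\n{body}\n"


def read_fasta(text: str) -> tuple[str, str]:
    """First record of a FASTA file as (header, sequence)."""
    header = None
    seq: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                break
            header = line[1:].strip()
        elif header is not None:
            seq.append(line.strip())
    if header is None or not seq:
        raise FormatError("no FASTA record found")
    return header, "".join(seq)


def write_profile_tsv(freqs: np.ndarray, class_names: list[str]) -> str:
    """Profile matrix as TSV: a header row of class names, one row per position."""
    lines = ["\t".join(class_names)]
    for row in np.asarray(freqs, dtype=float):
        lines.append("\t".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def read_profile_tsv(text: str) -> tuple[list[str], np.ndarray]:
    """Parse a profile TSV back into (class names, L x n_classes matrix)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty profile file")
    names = lines[0].split("\t")
    try:
        rows = [[float(v) for v in ln.split("\t")] for ln in lines[1:]]
    except ValueError as exc:
        raise FormatError(f"non-numeric profile entry: {exc}") from exc
    mat = np.array(rows, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(names):
        raise FormatError("profile rows do not match header width")
    return names, mat


def read_frequency_table(text: str) -> dict[str, float]:
    """20-row TSV (aa, weight) -> normalized frequency map."""
    freq: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[0] not in AA_INDEX:
            raise FormatError(f"bad frequency-table line: {line!r}")
        freq[parts[0]] = float(parts[1])
    if set(freq) != set(AMINO_ACIDS):
        missing = sorted(set(AMINO_ACIDS) - set(freq))
        raise FormatError(f"frequency table missing amino acids: {missing}")
    total = sum(freq.values())
    if total <= 0:
        raise FormatError("frequency table sums to zero")
    return {aa: v / total for aa, v in freq.items()}


# ---------------------------------------------------------------------------
# Run outputs
# ---------------------------------------------------------------------------

TRAJECTORY_HEADER = "# step temperature fitness identity"


def write_outputs(sequence: str, trajectory, fasta_path, traj_path, *,
                  structure_id: str, seed: int, final_fitness: float) -> None:
    """Write the evolved sequence (FASTA) and the annealing trajectory (TSV).

    Deterministic byte-for-byte for identical in-memory inputs; trajectory
    columns are step, temperature, fitness and identity-to-native.
    """
    if not trajectory:
        raise ValueError("trajectory must be non-empty")
    header = f"{structure_id} seed={seed} fitness={final_fitness:.6f}"
    try:
        with open(fasta_path, "w") as fh:
            fh.write(write_fasta(sequence, header))
        with open(traj_path, "w") as fh:
            fh.write(TRAJECTORY_HEADER + "\n")
            for rec in trajectory:
                fh.write(f"{rec.step}\t{rec.temperature:.6f}\t"
                         f"{rec.fitness:.6f}\t{rec.identity:.6f}\n")
    except OSError as exc:
        raise OSError(f"cannot write output file: {exc}") from exc
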