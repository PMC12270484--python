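"""Soft-contact featurization of threaded protein-DNA sequence pairs.

The contact weight between an interface amino acid i and nucleotide j is a
tanh switching function of their bead distance,

    Θ(r) = 0.5 · tanh(κ(r − r_min)) · tanh(κ(r_max − r)) + 0.5,

with κ = 0.7 Å⁻¹, r_min = −8 Å, r_max = 8 Å by default, so Θ(8 Å) = 0.5 and
Θ decays smoothly beyond the 8 Å contact cutoff. The feature vector φ of a
sequence pair threaded onto a fixed structure accumulates Θ weights into a
20×4 (amino acid × nucleotide) contact-count matrix; binding energies are
linear in φ (see :mod:`ideadna.optimize`).

Threading keeps the structure rigid: only residue identities change, never
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabets import (AA_ALPHABET, N_AA, N_FEATURES, N_NT, NT_ALPHABET,
                        aa_codes, nt_codes, reverse_complement)
from .structio import FORWARD, REVERSE, CoarseGrainedComplex, InterfaceSelection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of the tanh switching function (Å, Å⁻¹)."""

    kappa: float = 0.7
    r_min: float = -8.0
    r_max: float = 8.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.r_min >= self.r_max:
            raise ValueError("r_min must be below r_max")


DEFAULT_SWITCH = SwitchParams()


def theta(r, params: SwitchParams = DEFAULT_SWITCH):
    """Soft contact weight in [0, 1] for distance(s) ``r`` in Å."""
    r = np.asarray(r, dtype=float)
    w = 0.5 * (np.tanh(params.kappa * (r - params.r_min))
               * np.tanh(params.kappa * (params.r_max - r))) + 0.5
    return w if w.ndim else float(w)


def pair_weights(cplx: CoarseGrainedComplex, interface: InterfaceSelection,
                 params: SwitchParams = DEFAULT_SWITCH) -> np.ndarray:
    """Θ weight for every interface (protein, DNA) bead pair."""
    if interface.n_pairs == 0:
        return np.zeros(0)
    pc = cplx.protein_coords[interface.pairs[:, 0]]
    dc = cplx.dna_coords[interface.pairs[:, 1]]
    return theta(np.linalg.norm(pc - dc, axis=1), params)


def _check_lengths(cplx, protein_seq, dna_seq):
    if len(protein_seq) != len(cplx.protein_beads):
        chains = sorted({b.chain for b in cplx.protein_beads})
        raise ValueError(
            f"protein sequence length {len(protein_seq)} does not match the "
            f"{len(cplx.protein_beads)} beads of protein chain(s) {chains}")
    if len(dna_seq) != len(cplx.dna_beads):
        chains = sorted({b.chain for b in cplx.dna_beads})
        raise ValueError(
            f"DNA sequence length {len(dna_seq)} does not match the "
            f"{len(cplx.dna_beads)} beads of DNA chain(s) {chains}")


def compute_phi(cplx: CoarseGrainedComplex, interface: InterfaceSelection,
                protein_seq: str, dna_seq: str,
                params: SwitchParams = DEFAULT_SWITCH) -> np.ndarray:
    """φ matrix (20×4) of one threaded sequence pair.

    ``protein_seq``/``dna_seq`` are full-length over the complex's beads (all
    protein chains concatenated; forward then reverse DNA strand). Entry
    (a, n) sums the Θ weights of interface pairs whose threaded types are
    (a, n).
    """
    _check_lengths(cplx, protein_seq, dna_seq)
    phi = np.zeros((N_AA, N_NT))
    if interface.n_pairs == 0:
        return phi
    w = pair_weights(cplx, interface, params)
    a = aa_codes(protein_seq)[interface.pairs[:, 0]]
    n = nt_codes(dna_seq)[interface.pairs[:, 1]]
    np.add.at(phi, (a, n), w)
    return phi


def phi_batch(cplx: CoarseGrainedComplex, interface: InterfaceSelection,
              protein_codes: np.ndarray, dna_codes: np.ndarray,
              params: SwitchParams = DEFAULT_SWITCH) -> np.ndarray:
    """Flattened φ vectors, one row per sequence pair.

    ``protein_codes``/``dna_codes`` are integer-coded arrays of shape
    (m, n_protein_beads) and (m, n_dna_beads).
    """
    m = protein_codes.shape[0]
    out = np.zeros((m, N_FEATURES))
    if interface.n_pairs == 0:
        return out
    w = pair_weights(cplx, interface, params)
    flat = (protein_codes[:, interface.pairs[:, 0]] * N_NT
            + dna_codes[:, interface.pairs[:, 1]])
    np.add.at(out, (np.arange(m)[:, None], flat), w[None, :])
    return out


@dataclass
class DecoySet:
    """Randomized interface sequences emulating weak (decoy) binders."""

    dna_decoys: list[str]
    protein_decoys: list[str]
    seed: int
    protein_positions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    dna_positions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


def generate_decoys(native_protein: str, native_dna: str,
                    interface: InterfaceSelection,
                    n_dna: int = 1000, n_protein: int = 10000,
                    seed: int = 0, mode: str = "iid") -> DecoySet:
    """Randomize interface positions of the native sequences.

    DNA and protein decoys form separate sets: each DNA decoy keeps the
    native protein and redraws every interface DNA position; protein decoys
    mirror this. ``mode='iid'`` draws i.i.d. uniform letters; ``'shuffle'``
    permutes the native interface letters (composition-preserving).
    """
    if n_dna < 1 or n_protein < 1:
        raise ValueError("decoy counts must be >= 1")
    if len(interface.protein_index_set) == 0 and len(interface.dna_index_set) == 0:
        raise ValueError("nothing to randomize: empty interface")

    rng = np.random.default_rng(seed)

    def randomize(native: str, positions: np.ndarray, alphabet: str, n: int) -> list[str]:
        base = np.array(list(native))
        out = []
        k = len(positions)
        for _ in range(n):
            s = base.copy()
            if k:
                if mode == "iid":
                    s[positions] = np.array(list(alphabet))[rng.integers(len(alphabet), size=k)]
                elif mode == "shuffle":
                    s[positions] = s[positions][rng.permutation(k)]
                else:
                    raise ValueError(f"unknown decoy mode {mode!r}")
            out.append("".join(s))
        return out

    return DecoySet(
        dna_decoys=randomize(native_dna, interface.dna_index_set, NT_ALPHABET, n_dna),
        protein_decoys=randomize(native_protein, interface.protein_index_set,
                                 AA_ALPHABET, n_protein),
        seed=int(seed),
        protein_positions=interface.protein_index_set.copy(),
        dna_positions=interface.dna_index_set.copy(),
    )


def write_decoys_fasta(decoys: DecoySet, path, which: str = "dna") -> None:
    seqs = decoys.dna_decoys if which == "dna" else decoys.protein_decoys
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">decoy_{which}_{i} seed={decoys.seed}\n{s}\n")


# ---------------------------------------------------------------------------
# Strand-selection threading


@dataclass
class ThreadingResult:
    """Candidate full-length DNA sequence assignments for one target."""

    candidates: list[tuple[str, str]]  # (strand label, full dna sequence)
    chosen_strand: str | None          # None when orientation is unknown
    identities: dict[str, float]


def _thread_onto(cplx: CoarseGrainedComplex, strand: str, target: str) -> str:
    seq = list(cplx.dna_sequence)
    for pos_in_strand, bead_idx in enumerate(cplx.strand_indices(strand)):
        seq[bead_idx] = target[pos_in_strand]
    return "".join(seq)


def thread_dna(cplx: CoarseGrainedComplex, interface: InterfaceSelection,
               target_dna: str, orientation_known: bool = True) -> ThreadingResult:
    """Decide which native strand a 5'→3' target sequence replaces.

    Sequence identity of the target against each strand's native sequence
    (full strand) selects the strand to replace; ties break to the forward
    strand with a warning. With ``orientation_known=False`` both threadings
    are returned and the caller should score each and keep the lower
    (stronger) predicted energy.
    """
    target = target_dna.upper()
    strands = [FORWARD] + ([REVERSE] if len(cplx.strand_indices(REVERSE)) else [])
    lengths = {s: len(cplx.strand_indices(s)) for s in strands}
    matching = [s for s in strands if lengths[s] == len(target)]
    if not matching:
        raise ValueError(
            f"target length {len(target)} matches no strand (lengths {lengths})")

    identities = {}
    for s in matching:
        native = cplx.strand_sequence(s)
        identities[s] = sum(a == b for a, b in zip(target, native)) / len(target)

    if not orientation_known and len(matching) > 1:
        return ThreadingResult(
            candidates=[(s, _thread_onto(cplx, s, target)) for s in matching],
            chosen_strand=None, identities=identities)

    best = max(identities.values())
    tied = [s for s in matching if identities[s] == best]
    if len(tied) > 1:
        logger.warning("target matches both strands equally (identity %.3f); "
                       "defaulting to the forward strand", best)
    chosen = FORWARD if FORWARD in tied else tied[0]
    return ThreadingResult(candidates=[(chosen, _thread_onto(cplx, chosen, target))],
                           chosen_strand=chosen, identities=identities)
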