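"""Synthetic fixtures: toy complexes, planted energy matrices, affinity
tables, and genomes with ground-truth binding sites.

Everything here is generated from a seed, so tests and benchmarks need no
external structures or assay downloads. The scenarios emulate only the
contact-count statistics that the energy model sees — not real protein-DNA
geometry.

The planted-parameter scenario works as follows. A toy complex is built with
an exactly controlled number of protein-DNA contacts (a "star" geometry:
each contacting protein bead sits within the 8 Å cutoff of one or two
adjacent DNA beads and outside 10 Å of everything else). A ground-truth
interaction matrix γ* is drawn at random, and "evolved" strong-binder
sequences are sampled from per-position conditional Boltzmann distributions
under γ* — DNA varied with the protein fixed and vice versa, mirroring the
two decoy ensembles used in training. In the linear-response regime this
makes the gap statistics satisfy A ≈ β·B·γ*, so gap optimization is a
consistent estimator of the planted matrix; a lone deterministic-minimum
native carries far less graded information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import (AA_ALPHABET, N_AA, N_NT, NT_ALPHABET, NT_NAMES,
                        ONE_TO_THREE, aa_codes, nt_codes, reverse_complement)
from .featurize import (DEFAULT_SWITCH, DecoySet, SwitchParams, generate_decoys,
                        pair_weights, phi_batch)
from .genomescan import _strand_profile, proximal_strand
from .optimize import (EnergyModel, GapStatistics, compute_gap_statistics,
                       kd_from_ddg, predict_energy, solve_gamma)
from .structio import (FORWARD, REVERSE, CoarseGrainedComplex, DnaBead,
                       InterfaceSelection, ProteinBead, extract_interface,
                       select_dna_representative)

#: DNA bead spacing along the helix axis stand-in (Å).
DNA_SPACING = 12.0
#: Offset of the decoy P pseudo-atom from the C5 position (Å).
P_OFFSET = np.array([0.0, 0.0, 8.0])


def random_gamma(seed: int | np.random.Generator) -> np.ndarray:
    """Unit-norm random 20×4 planted interaction matrix."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = rng.normal(size=(N_AA, N_NT))
    return g / np.linalg.norm(g)


def _round3(x: np.ndarray) -> np.ndarray:
    # PDB coordinates carry 3 decimals; rounding here makes the PDB
    # round trip exact.
    return np.round(x, 3)


def make_toy_complex(n_protein: int, n_dna: int, n_contacts: int, seed: int = 0,
                     double_stranded: bool = False,
                     protein_seq: str | None = None,
                     dna_seq: str | None = None
                     ) -> tuple[CoarseGrainedComplex, InterfaceSelection]:
    """Toy complex with exactly ``n_contacts`` cross pairs under 8 Å.

    DNA C5 pseudo-atoms lie on a line with 12 Å spacing; contacting protein
    beads are placed 4.5-7.5 Å from one DNA bead (or near the midpoint of an
    adjacent pair when ``n_contacts > n_protein``), offset into the z ≤ 0
    half-space so that the P pseudo-atoms (offset +8 Å in z) lose the
    representative-atom vote and C5 is selected. Remaining protein beads are
    parked far away. ``n_dna`` counts nucleotides per strand;
    ``double_stranded`` adds a contact-free complementary strand 20 Å off
    the interface.
    """
    if n_contacts > 2 * n_protein:
        raise ValueError("at most 2 contacts per protein bead are constructible")
    if n_contacts > 0 and n_dna < 1:
        raise ValueError("contacts require DNA beads")
    if n_contacts > n_protein and n_dna < 2:
        raise ValueError("double contacts require at least two DNA beads")

    rng = np.random.default_rng(seed)
    protein_seq = protein_seq or "".join(
        AA_ALPHABET[i] for i in rng.integers(N_AA, size=n_protein))
    dna_seq = dna_seq or "".join(
        NT_ALPHABET[i] for i in rng.integers(N_NT, size=n_dna))
    if len(protein_seq) != n_protein or len(dna_seq) != n_dna:
        raise ValueError("sequence lengths disagree with bead counts")

    dna_xyz = np.column_stack([DNA_SPACING * np.arange(n_dna),
                               np.zeros(n_dna), np.zeros(n_dna)])

    def yz_offset(radius):
        phi = rng.uniform(np.pi, 2 * np.pi)  # z <= 0 half-plane
        return np.array([0.0, radius * np.cos(phi), radius * np.sin(phi)])

    n_double = max(0, n_contacts - n_protein)
    n_single = n_contacts - 2 * n_double
    prot_xyz = np.zeros((n_protein, 3))
    dna_targets = rng.permutation(n_dna)
    t = 0
    for p in range(n_protein):
        if p < n_double:
            j = p % (n_dna - 1)
            prot_xyz[p] = dna_xyz[j] + np.array([DNA_SPACING / 2, 0, 0]) \
                + yz_offset(rng.uniform(1.0, 5.0))
        elif p < n_double + n_single:
            j = int(dna_targets[t % n_dna]); t += 1
            prot_xyz[p] = dna_xyz[j] + yz_offset(rng.uniform(4.5, 7.5))
        else:  # spectator bead, outside every shell
            prot_xyz[p] = np.array([DNA_SPACING * (p % n_dna if n_dna else 0),
                                    -60.0 - 15.0 * (p // max(n_dna, 1)), 0.0])

    protein_beads = [ProteinBead("A", str(i + 1), aa, _round3(prot_xyz[i]))
                     for i, aa in enumerate(protein_seq)]
    dna_beads = [DnaBead("B", FORWARD, i, str(i + 1), "D" + nt,
                         c5=_round3(dna_xyz[i]),
                         p=_round3(dna_xyz[i] + P_OFFSET))
                 for i, nt in enumerate(dna_seq)]
    if double_stranded:
        rc = reverse_complement(dna_seq)
        for k, nt in enumerate(rc):
            xyz = np.array([DNA_SPACING * (n_dna - 1 - k), 20.0, 0.0])
            dna_beads.append(DnaBead("C", REVERSE, k, str(k + 1), "D" + nt,
                                     c5=_round3(xyz),
                                     p=_round3(xyz + P_OFFSET)))

    cplx = CoarseGrainedComplex(protein_beads, dna_beads,
                                source_id=f"toy-{seed}")
    select_dna_representative(cplx)
    interface = extract_interface(cplx)
    return cplx, interface


def write_pdb(cplx: CoarseGrainedComplex, path) -> None:
    """Write the toy complex as minimal legal ATOM records (synthetic)."""
    serial = 1
    lines = []

    def atom(name, res, chain, resnum, xyz, element):
        nonlocal serial
        padded = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {serial:5d} {padded}{'':1s}{res:>3s} {chain}{int(resnum):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")
        serial += 1

    for b in cplx.protein_beads:
        atom("CA", ONE_TO_THREE[b.aa], b.chain, b.label, b.xyz, "C")
    for b in cplx.dna_beads:
        if b.c5 is not None:
            atom("C5", b.nuc, b.chain, b.label, b.c5, "C")
        if b.p is not None:
            atom("P", b.nuc, b.chain, b.label, b.p, "P")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")


# ---------------------------------------------------------------------------
# Planted-parameter scenarios


def _conditional_fields(cplx, interface, gamma_star, params=DEFAULT_SWITCH):
    """Per-position single-site energy fields given the partner sequence."""
    w = pair_weights(cplx, interface, params)
    aa = aa_codes(cplx.protein_sequence)
    nt = nt_codes(cplx.dna_sequence)
    prot_field = np.zeros((len(aa), N_AA))
    dna_field = np.zeros((len(nt), N_NT))
    for (pi, dj), th in zip(interface.pairs, w):
        prot_field[pi] += th * gamma_star[:, nt[dj]]
        dna_field[dj] += th * gamma_star[aa[pi], :]
    return prot_field, dna_field


def _gibbs_sample(field_mat: np.ndarray, beta: float, m: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw m sequences from independent per-position Boltzmann weights."""
    logits = -beta * field_mat
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    cum = p.cumsum(axis=1)
    u = rng.random((m, field_mat.shape[0]))
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2)


@dataclass
class PlantedScenario:
    """A reproducible synthetic training/evaluation setup."""

    seed: int
    gamma_star: np.ndarray
    cplx: CoarseGrainedComplex
    interface: InterfaceSelection
    native_protein: str
    native_dna: str
    strong_protein_seqs: list[str]   # varied protein, native DNA
    strong_dna_seqs: list[str]       # varied DNA, native protein
    selection_strength: float
    switch: SwitchParams = DEFAULT_SWITCH
    geometry: dict = field(default_factory=dict)

    def strong_phis(self) -> np.ndarray:
        nat_aa = aa_codes(self.native_protein)[None, :]
        nat_nt = nt_codes(self.native_dna)[None, :]
        phis_dna = phi_batch(
            self.cplx, self.interface,
            np.repeat(nat_aa, len(self.strong_dna_seqs), axis=0),
            np.array([nt_codes(s) for s in self.strong_dna_seqs]), self.switch)
        phis_prot = phi_batch(
            self.cplx, self.interface,
            np.array([aa_codes(s) for s in self.strong_protein_seqs]),
            np.repeat(nat_nt, len(self.strong_protein_seqs), axis=0), self.switch)
        return np.vstack([phis_dna, phis_prot])

    def decoy_phis(self, decoys: DecoySet) -> np.ndarray:
        nat_aa = aa_codes(self.native_protein)[None, :]
        nat_nt = nt_codes(self.native_dna)[None, :]
        phis_dna = phi_batch(
            self.cplx, self.interface,
            np.repeat(nat_aa, len(decoys.dna_decoys), axis=0),
            np.array([nt_codes(s) for s in decoys.dna_decoys]), self.switch)
        phis_prot = phi_batch(
            self.cplx, self.interface,
            np.array([aa_codes(s) for s in decoys.protein_decoys]),
            np.repeat(nat_nt, len(decoys.protein_decoys), axis=0), self.switch)
        return np.vstack([phis_dna, phis_prot])


def planted_scenario(seed: int, n_protein: int = 30, n_dna: int = 16,
                     n_contacts: int = 40, selection_strength: float = 2.0,
                     n_strong_dna: int = 200, n_strong_protein: int = 2000,
                     double_stranded: bool = False) -> PlantedScenario:
    """Build a toy complex whose sequences evolved under a planted γ*.

    The native pair is one conditional-Boltzmann draw at the given selection
    strength; the strong-binder ensembles are further draws from the two
    conditional ensembles (1:10 DNA:protein, mirroring the decoy ratio).
    """
    rng = np.random.default_rng(seed)
    gamma_star = random_gamma(rng)
    cplx, interface = make_toy_complex(n_protein, n_dna, n_contacts,
                                       seed=int(rng.integers(2**31)),
                                       double_stranded=double_stranded)

    # native: protein conditioned on the random DNA, then DNA re-conditioned
    prot_field, _ = _conditional_fields(cplx, interface, gamma_star)
    nat_aa = _gibbs_sample(prot_field, selection_strength, 1, rng)[0]
    for bead, code in zip(cplx.protein_beads, nat_aa):
        bead.aa = AA_ALPHABET[code]
    _, dna_field = _conditional_fields(cplx, interface, gamma_star)
    nat_nt = _gibbs_sample(dna_field, selection_strength, 1, rng)[0]
    for bead, code in zip(cplx.dna_beads, nat_nt):
        bead.nuc = "D" + NT_ALPHABET[code]

    prot_field, dna_field = _conditional_fields(cplx, interface, gamma_star)
    strong_dna = ["".join(NT_ALPHABET[c] for c in row)
                  for row in _gibbs_sample(dna_field, selection_strength,
                                           n_strong_dna, rng)]
    strong_prot = ["".join(AA_ALPHABET[c] for c in row)
                   for row in _gibbs_sample(prot_field, selection_strength,
                                            n_strong_protein, rng)]

    return PlantedScenario(
        seed=seed, gamma_star=gamma_star, cplx=cplx, interface=interface,
        native_protein=cplx.protein_sequence, native_dna=cplx.dna_sequence,
        strong_protein_seqs=strong_prot, strong_dna_seqs=strong_dna,
        selection_strength=selection_strength,
        geometry={"n_protein": n_protein, "n_dna": n_dna,
                  "n_contacts": n_contacts})


def train_planted(scenario: PlantedScenario, n_dna_decoys: int = 1000,
                  n_protein_decoys: int = 10000, seed: int = 0,
                  n_modes: int | None = None) -> tuple[EnergyModel, GapStatistics]:
    """Gap-optimize γ on a planted scenario (pooled decoy statistics)."""
    decoys = generate_decoys(scenario.native_protein, scenario.native_dna,
                             scenario.interface, n_dna=n_dna_decoys,
                             n_protein=n_protein_decoys, seed=seed)
    stats = compute_gap_statistics(scenario.strong_phis(),
                                   scenario.decoy_phis(decoys))
    model = solve_gamma(stats, n_modes=n_modes)
    model.metadata.update(scenario.geometry, scenario_seed=scenario.seed,
                          decoy_seed=seed)
    return model, stats


# ---------------------------------------------------------------------------
# Affinity tables and synthetic genomes


def sample_affinities(cplx: CoarseGrainedComplex, interface: InterfaceSelection,
                      gamma_star: np.ndarray, sequences=None,
                      n_random: int | None = None, noise_sd: float = 0.0,
                      seed: int = 0,
                      params: SwitchParams = DEFAULT_SWITCH) -> pd.DataFrame:
    """Synthetic affinity table: ΔΔG = E(threaded | γ*) + Gaussian noise.

    Targets are w-mers for the proximal strand; the Kd-ratio column inverts
    ΔΔG = RT·ln(ΔKd), so both encodings of the same measurement are present
    (emulating MITOMI/SELEX-style tables).
    """
    rng = np.random.default_rng(seed)
    model = EnergyModel(gamma=gamma_star, provenance="planted")
    strand = proximal_strand(cplx, interface)
    w = len(cplx.strand_indices(strand))
    if sequences is None:
        if n_random is None:
            raise ValueError("provide sequences or n_random")
        sequences = ["".join(NT_ALPHABET[i] for i in rng.integers(N_NT, size=w))
                     for _ in range(n_random)]
    M, const, _ = _strand_profile(model, cplx, interface, strand, params)
    ddg = np.array([const + sum(M[k, "ATCG".index(c)] for k, c in enumerate(s))
                    for s in sequences])
    ddg = ddg + rng.normal(0.0, noise_sd, size=len(ddg)) if noise_sd > 0 else ddg
    return pd.DataFrame({"sequence": list(sequences), "ddg": ddg,
                         "kd_ratio": kd_from_ddg(ddg), "units": "kcal/mol"})


def strongest_wmer(model: EnergyModel, cplx: CoarseGrainedComplex,
                   interface: InterfaceSelection,
                   params: SwitchParams = DEFAULT_SWITCH,
                   exhaustive_max_w: int = 8) -> tuple[str, float]:
    """Lowest-energy w-mer for the threading strand under ``model``.

    Exhaustive over all 4^w w-mers for w ≤ ``exhaustive_max_w``, otherwise a
    per-position greedy argmin (exact here, since threading energies are
    additive over window positions).
    """
    strand = proximal_strand(cplx, interface)
    w = len(cplx.strand_indices(strand))
    M, const, _ = _strand_profile(model, cplx, interface, strand, params)
    if w <= exhaustive_max_w:
        total = np.zeros(4 ** w)
        for k in range(w):
            digits = (np.arange(4 ** w) // (4 ** (w - 1 - k))) % 4
            total += M[k, digits]
        best = int(np.argmin(total))
        letters = [NT_ALPHABET[(best // (4 ** (w - 1 - k))) % 4] for k in range(w)]
        return "".join(letters), float(const + total[best])
    codes = M.argmin(axis=1)
    return ("".join(NT_ALPHABET[c] for c in codes),
            float(const + M[np.arange(w), codes].sum()))


def make_synthetic_genome(length: int, motif: str, n_insertions: int,
                          seed: int = 0, gc: float = 0.5
                          ) -> tuple[str, list[tuple[int, int]]]:
    """Uniform-background genome with non-overlapping planted motifs.

    Returns the sequence and truth intervals ``[pos, pos+1)`` marking the
    scan position of each planted w-mer (0-based, half-open) — the
    single-position resolution at which an isolated motif is detectable.
    """
    w = len(motif)
    if length < w * max(n_insertions, 1):
        raise ValueError("genome too short for the requested insertions")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    genome = np.array(list(NT_ALPHABET))[rng.choice(N_NT, size=length, p=p)]

    positions: list[int] = []
    guard = 0
    while len(positions) < n_insertions:
        pos = int(rng.integers(0, length - w + 1))
        if all(abs(pos - q) >= w for q in positions):
            positions.append(pos)
        guard += 1
        if guard > 100000:
            raise RuntimeError("could not place non-overlapping insertions")
    for pos in positions:
        genome[pos:pos + w] = list(motif)
    return "".join(genome), [(pos, pos + 1) for pos in sorted(positions)]


def write_truth_bed(intervals, path, contig: str = "synth") -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{contig}\t{s}\t{e}\tplanted\n")
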