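"""Coarse-graining of protein-DNA complex structures.

Reduces a PDB/mmCIF structure to one bead per residue: the Cα atom for each
amino acid, and for each nucleotide either the base C5 atom or the backbone
phosphate P, whichever atom kind lies more often near the protein Cα atoms
(summed pair counts within 8, 9 and 10 Å; ties prefer the base-proximal C5,
which carries base identity). The binding interface is the set of beads with
at least one cross-molecule partner within a hard distance cutoff (8 Å by
default); the soft contact weight applied on top of interface pairs lives in
:mod:`ideadna.featurize`.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .alphabets import NT_NAMES, THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Atom names accepted for the base-carbon representative.
C5_NAMES = ("C5", "C5'")
P_NAME = "P"

FORWARD = "forward"
REVERSE = "reverse"

#: Default mapping for modified residues; user-extensible via ``res_map``.
DEFAULT_RES_MAP: dict[str, str] = {
    "5CM": "DC",   # 5-methyl-cytosine
    "MSE": "MET",  # selenomethionine
}


@dataclass
class ProteinBead:
    chain: str
    label: str          # author residue number, insertion code appended
    aa: str             # one-letter type
    xyz: np.ndarray

    def __eq__(self, other):
        return (
            isinstance(other, ProteinBead)
            and (self.chain, self.label, self.aa) == (other.chain, other.label, other.aa)
            and np.allclose(self.xyz, other.xyz, atol=1e-6)
        )


@dataclass
class DnaBead:
    chain: str
    strand: str         # FORWARD or REVERSE
    index: int          # consecutive 0-based position within the strand, 5'->3'
    label: str
    nuc: str            # residue name in {DA, DT, DC, DG}
    kind: str | None = None          # resolved representative atom kind
    xyz: np.ndarray | None = None    # resolved representative coordinate
    c5: np.ndarray | None = field(default=None, repr=False)
    p: np.ndarray | None = field(default=None, repr=False)

    def __eq__(self, other):
        if not isinstance(other, DnaBead):
            return NotImplemented
        same = (self.chain, self.strand, self.index, self.nuc, self.kind) == (
            other.chain, other.strand, other.index, other.nuc, other.kind)
        if not same:
            return False
        if self.xyz is None or other.xyz is None:
            return self.xyz is None and other.xyz is None
        return np.allclose(self.xyz, other.xyz, atol=1e-6)


@dataclass
class CoarseGrainedComplex:
    """One-bead-per-residue representation of a protein-DNA complex."""

    protein_beads: list[ProteinBead]
    dna_beads: list[DnaBead]
    source_id: str = ""
    atom_kind: str | None = None  # set by select_dna_representative

    @property
    def protein_sequence(self) -> str:
        return "".join(b.aa for b in self.protein_beads)

    @property
    def dna_sequence(self) -> str:
        """All DNA bead letters in bead order (forward strand then reverse)."""
        return "".join(b.nuc[1] for b in self.dna_beads)

    def strand_indices(self, strand: str) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.dna_beads) if b.strand == strand],
                        dtype=np.int64)

    def strand_sequence(self, strand: str) -> str:
        return "".join(self.dna_beads[i].nuc[1] for i in self.strand_indices(strand))

    @property
    def protein_coords(self) -> np.ndarray:
        return np.array([b.xyz for b in self.protein_beads], dtype=float)

    @property
    def dna_coords(self) -> np.ndarray:
        if self.atom_kind is None:
            raise ValueError("representative atom kind not resolved; "
                             "call select_dna_representative first")
        return np.array([b.xyz for b in self.dna_beads], dtype=float)


@dataclass
class InterfaceSelection:
    """Beads with >=1 cross-molecule partner within ``cutoff`` Å.

    ``pairs`` lists every (protein bead index, DNA bead index) pair within
    the cutoff; the index sets are its projections.
    """

    protein_index_set: np.ndarray
    dna_index_set: np.ndarray
    cutoff: float
    pairs: np.ndarray  # shape (m, 2)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _read_structure(source) -> gemmi.Structure:
    text = None
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        return gemmi.read_structure(str(source))
    if isinstance(source, str):
        text = source
    elif hasattr(source, "read"):
        text = source.read()
    if text is None:
        raise ValueError(f"cannot interpret structure source {source!r}")
    if text.lstrip().startswith("data_"):
        doc = gemmi.cif.read_string(text)
        return gemmi.make_structure_from_block(doc.sole_block())
    return gemmi.read_pdb_string(text)


def _first_atom(residue: gemmi.Residue, names: tuple[str, ...]) -> np.ndarray | None:
    # first alternate location wins
    for atom in residue:
        if atom.name in names:
            return np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
    return None


def parse_complex(source, res_map: dict[str, str] | None = None) -> CoarseGrainedComplex:
    """Parse a PDB/mmCIF structure (path, text, or file object) into beads.

    Both candidate DNA atom kinds (C5 and P) are retained on each bead until
    :func:`select_dna_representative` resolves the representative kind.
    Residues lacking the relevant atom are skipped with a warning; hetero
    residues, waters, and unknown residue names not covered by ``res_map``
    raise unless mapped.
    """
    mapping = dict(DEFAULT_RES_MAP)
    if res_map:
        mapping.update(res_map)

    st = _read_structure(source)
    st.setup_entities()
    model = st[0]

    protein_beads: list[ProteinBead] = []
    dna_chain_names: list[str] = []
    dna_by_chain: dict[str, list[DnaBead]] = {}

    for chain in model:
        for residue in chain:
            name = residue.name.strip().upper()
            if name in ("HOH", "WAT"):
                continue
            name = mapping.get(name, name)
            if name != residue.name.strip().upper():
                logger.warning("mapped modified residue %s -> %s in chain %s",
                               residue.name, name, chain.name)
            label = f"{residue.seqid.num}{residue.seqid.icode}".strip()
            if name in THREE_TO_ONE:
                ca = _first_atom(residue, ("CA",))
                if ca is None:
                    logger.warning("residue %s %s/%s lacks a CA atom; skipped",
                                   residue.name, chain.name, label)
                    continue
                protein_beads.append(ProteinBead(chain.name, label, THREE_TO_ONE[name], ca))
            elif name in NT_NAMES:
                c5 = _first_atom(residue, C5_NAMES)
                p = _first_atom(residue, (P_NAME,))
                if c5 is None and p is None:
                    logger.warning("nucleotide %s %s/%s lacks both C5 and P; skipped",
                                   residue.name, chain.name, label)
                    continue
                bead = DnaBead(chain.name, FORWARD, 0, label, name, c5=c5, p=p)
                dna_by_chain.setdefault(chain.name, []).append(bead)
                if chain.name not in dna_chain_names:
                    dna_chain_names.append(chain.name)
            elif residue.het_flag == "H":
                continue
            else:
                raise ValueError(
                    f"unknown residue name {residue.name!r} in chain {chain.name}; "
                    "supply a res_map entry to resolve it")

    if not protein_beads:
        raise ValueError("no protein")
    if not dna_by_chain:
        raise ValueError("no DNA")
    if len(dna_chain_names) > 2:
        raise ValueError(f"more than two DNA chains ({dna_chain_names}); "
                         "split the structure into one duplex")

    dna_beads: list[DnaBead] = []
    for strand, chain_name in zip((FORWARD, REVERSE), dna_chain_names):
        for i, bead in enumerate(dna_by_chain[chain_name]):
            bead.strand = strand
            bead.index = i
            dna_beads.append(bead)

    return CoarseGrainedComplex(protein_beads, dna_beads, source_id=st.name or "")


def _pair_count_sums(dna_xyz: np.ndarray, ca_xyz: np.ndarray,
                     cutoffs=(8.0, 9.0, 10.0)) -> int:
    if len(dna_xyz) == 0 or len(ca_xyz) == 0:
        return 0
    d = np.linalg.norm(dna_xyz[:, None, :] - ca_xyz[None, :, :], axis=-1)
    return int(sum((d <= c).sum() for c in cutoffs))


def select_dna_representative(cplx: CoarseGrainedComplex) -> str:
    """Resolve the DNA representative atom kind (C5 vs P) in place.

    For each kind, DNA-atom/Cα pairs within 8, 9 and 10 Å are counted and the
    three counts summed; the kind with the larger sum wins (tie -> C5). The
    complex's DNA beads are rewritten to the winning kind; beads lacking that
    atom are dropped with a warning.
    """
    ca = cplx.protein_coords
    c5_xyz = np.array([b.c5 for b in cplx.dna_beads if b.c5 is not None], dtype=float)
    p_xyz = np.array([b.p for b in cplx.dna_beads if b.p is not None], dtype=float)
    if len(c5_xyz) == 0 and len(p_xyz) == 0:
        raise ValueError("no candidate DNA representative atoms present")

    c5_count = _pair_count_sums(c5_xyz.reshape(-1, 3), ca)
    p_count = _pair_count_sums(p_xyz.reshape(-1, 3), ca)
    if c5_count == p_count:
        logger.info("atom-kind occurrence tie (C5=%d, P=%d); preferring C5",
                    c5_count, p_count)
        kind = "C5"
    else:
        kind = "C5" if c5_count > p_count else "P"

    kept: list[DnaBead] = []
    for bead in cplx.dna_beads:
        coord = bead.c5 if kind == "C5" else bead.p
        if coord is None:
            logger.warning("nucleotide %s %s/%s lacks the representative %s atom; dropped",
                           bead.nuc, bead.chain, bead.label, kind)
            continue
        bead.kind = kind
        bead.xyz = coord
        kept.append(bead)
    # re-number per strand so indices stay consecutive
    for strand in (FORWARD, REVERSE):
        for i, bead in enumerate(b for b in kept if b.strand == strand):
            bead.index = i
    cplx.dna_beads = kept
    cplx.atom_kind = kind
    return kind


def extract_interface(cplx: CoarseGrainedComplex, cutoff: float = 8.0) -> InterfaceSelection:
    """Return beads with >=1 cross-molecule partner within ``cutoff`` Å."""
    d = np.linalg.norm(cplx.protein_coords[:, None, :] - cplx.dna_coords[None, :, :],
                       axis=-1)
    pi, di = np.nonzero(d <= cutoff)
    pairs = np.column_stack([pi, di]).astype(np.int64)
    if len(pairs) == 0:
        logger.warning("empty protein-DNA interface at cutoff %.2f Å", cutoff)
    return InterfaceSelection(
        protein_index_set=np.unique(pi),
        dna_index_set=np.unique(di),
        cutoff=float(cutoff),
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# TSV round trip

_TSV_COLUMNS = ["molecule", "chain", "strand", "index", "label", "type",
                "atom_kind", "x", "y", "z"]


def write_complex_tsv(cplx: CoarseGrainedComplex, path) -> None:
    rows = []
    for i, b in enumerate(cplx.protein_beads):
        rows.append(("protein", b.chain, ".", i, b.label, b.aa, "CA",
                     b.xyz[0], b.xyz[1], b.xyz[2]))
    for b in cplx.dna_beads:
        if b.xyz is None:
            raise ValueError("cannot serialize unresolved DNA beads; "
                             "call select_dna_representative first")
        rows.append(("dna", b.chain, b.strand, b.index, b.label, b.nuc, b.kind,
                     b.xyz[0], b.xyz[1], b.xyz[2]))
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_complex_tsv(path, source_id: str = "") -> CoarseGrainedComplex:
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "chain": str})
    protein, dna = [], []
    kind = None
    for row in df.itertuples(index=False):
        xyz = np.array([row.x, row.y, row.z], dtype=float)
        if row.molecule == "protein":
            protein.append(ProteinBead(row.chain, str(row.label), row.type, xyz))
        else:
            kind = row.atom_kind
            dna.append(DnaBead(row.chain, row.strand, int(row.index), str(row.label),
                               row.type, kind=kind, xyz=xyz,
                               c5=xyz if kind == "C5" else None,
                               p=xyz if kind == "P" else None))
    return CoarseGrainedComplex(protein, dna, source_id=source_id, atom_kind=kind)
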