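"""Sequence, alignment and structure I/O plus dataset-preparation utilities.

FASTA and aligned FASTA go through Biopython's :mod:`Bio.SeqIO`; macromolecular
structures (PDB / mmCIF) go through :mod:`gemmi`.  The redundancy filter is a
deliberately simple greedy identity-clustering stand-in for CD-HIT: sequences
are sorted by length and each joins the first cluster whose representative it
matches at or above the identity threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import (
    AA_THREE_TO_ONE,
    DNA_RESIDUES,
    GAP,
    NUCLEOTIDE_RESIDUES,
    PROTEIN_RESIDUES,
    RNA_RESIDUES,
    WATER_RESIDUES,
)
from .errors import FormatError, InputError

BINDING_CLASSES = ("rna", "dna", "protein", "reference")
TAXON_GROUPS = ("virus", "bacteria", "archaea", "eukaryota")


@dataclass
class SequenceRecord:
    """One ungapped protein sequence with optional dataset tags."""

    id: str
    sequence: str
    binding_class: str | None = None
    taxon_group: str | None = None

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        if GAP in self.sequence or "." in self.sequence:
            raise FormatError(f"record {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MSA:
    """Aligned FASTA rows of equal length over the AA alphabet plus '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise FormatError("alignment with no rows")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise FormatError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, expected {width}"
                )
        self.rows = [r.upper().replace(".", GAP) for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def gap_fraction(self) -> np.ndarray:
        """Per-column fraction of rows carrying a gap."""
        mat = np.array([list(r) for r in self.rows])
        return (mat == GAP).mean(axis=0)

    def column(self, c: int) -> list[str]:
        return [row[c] for row in self.rows]

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _parse_tags(description: str) -> dict:
    tags = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, val = token.partition("=")
            if key in ("binding_class", "class"):
                tags["binding_class"] = val
            elif key in ("taxon", "taxon_group"):
                tags["taxon_group"] = val
    return tags


def read_fasta(path) -> list[SequenceRecord]:
    """Read ungapped protein sequences; header tags ``class=``/``taxon=`` are kept."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = _parse_tags(rec.description)
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), **tags))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path) -> None:
    seqs = []
    for r in records:
        desc = []
        if r.binding_class:
            desc.append(f"binding_class={r.binding_class}")
        if r.taxon_group:
            desc.append(f"taxon={r.taxon_group}")
        seqs.append(SeqRecord(Seq(r.sequence), id=r.id, description=" ".join(desc)))
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(path) -> MSA:
    """Read an aligned FASTA into an :class:`MSA` (gap character ``-``)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: row {rec.id!r} has an empty sequence")
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not rows:
        raise FormatError(f"{path}: no alignment rows found")
    try:
        return MSA(ids, rows)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_alignment(msa: MSA, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(msa.ids, msa.rows)),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray


@dataclass
class Residue:
    seq_index: int          # 0-based internal index
    name: str               # PDB residue name (e.g. ALA, A, DG)
    atoms: list[Atom]
    label: str = ""         # author residue number, label only

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    polymer_type: str       # protein | rna | dna | other
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        if not self.residues:
            return np.empty((0, 3))
        return np.vstack([r.coords() for r in self.residues])

    def atom_residue_index(self) -> np.ndarray:
        """Residue index (0-based within the chain) of every atom, in order."""
        return np.concatenate(
            [np.full(len(r.atoms), i) for i, r in enumerate(self.residues)]
        ) if self.residues else np.empty(0, dtype=int)

    def sequence(self) -> str:
        """One-letter sequence for protein chains (X for unknowns)."""
        return "".join(AA_THREE_TO_ONE.get(r.name, "X") for r in self.residues)


@dataclass
class StructureModel:
    model_index: int
    chains: list[Chain]
    name: str = ""

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise InputError(f"chain {chain_id!r} not found in structure {self.name!r}")

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_type == "protein"]

    def nucleic_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_type in ("rna", "dna")]


def _classify_chain(residue_names: list[str], residues: list[Residue]) -> str:
    """Polymer type from residue vocabulary; RNA requires O2' in >=50% of nucleotides."""
    n_protein = sum(name in PROTEIN_RESIDUES for name in residue_names)
    n_nuc = sum(name in NUCLEOTIDE_RESIDUES for name in residue_names)
    total = len(residue_names)
    if total == 0:
        return "other"
    if n_protein and n_nuc:
        return "other"
    if n_protein == total:
        return "protein"
    if n_nuc == total:
        with_o2 = sum(
            any(a.name == "O2'" for a in res.atoms)
            for res, name in zip(residues, residue_names)
        )
        if with_o2 >= 0.5 * n_nuc:
            return "rna"
        # fall back to the residue-name vocabulary when O2' is entirely absent
        if all(name in DNA_RESIDUES for name in residue_names):
            return "dna"
        if all(name in RNA_RESIDUES for name in residue_names):
            return "rna"
        return "dna"
    return "other"


def read_structure(path) -> StructureModel:
    """Parse a PDB/mmCIF file: first model only, waters and ligands excluded,
    hydrogens dropped, highest-occupancy altloc kept, chains typed by vocabulary."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse structure ({exc})") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: structure contains no models")
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    model = st[0]

    chains = []
    for gchain in model:
        residues, names = [], []
        for idx, gres in enumerate(gchain):
            name = gres.name.strip()
            if name in WATER_RESIDUES:
                continue
            if name not in PROTEIN_RESIDUES and name not in NUCLEOTIDE_RESIDUES:
                continue  # heteroatoms / ligands are excluded from chains
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in gres
            ]
            if not atoms:
                continue
            residues.append(Residue(len(residues), name, atoms, label=str(gres.seqid.num)))
            names.append(name)
        if not residues:
            continue
        ptype = _classify_chain(names, residues)
        if ptype == "other":
            warnings.warn(
                f"{path.name}: chain {gchain.name} has mixed/unknown residue vocabulary; "
                "flagged 'other'",
                stacklevel=2,
            )
        chains.append(Chain(gchain.name, ptype, residues))
    if not chains:
        raise FormatError(f"{path}: no polymer chains found")
    return StructureModel(model_index=1, chains=chains, name=path.stem)


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM records, one MODEL) for a StructureModel."""
    lines = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            resnum = res.seq_index + 1
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:>3s} {chain.chain_id}"
                    f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Redundancy filtering (CD-HIT stand-in)
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of matched residues under a match=1/mismatch=0/gap=0 global
    alignment, divided by the shorter sequence length."""
    if aligner is None:
        aligner = _make_aligner()
    matches = aligner.score(a, b)
    return matches / min(len(a), len(b))


def greedy_redundancy_filter(records, identity_threshold: float = 0.9) -> list[SequenceRecord]:
    """Greedy incremental clustering by pairwise identity; returns representatives.

    Records are sorted by length (descending, input order breaking ties); each
    record joins the first cluster whose representative it matches at
    ``>= identity_threshold``, otherwise it founds a new cluster.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise InputError("identity_threshold must be in (0.5, 1.0]")
    if not records:
        return []
    aligner = _make_aligner()
    ordered = sorted(records, key=lambda r: -len(r.sequence))
    representatives: list[SequenceRecord] = []
    for rec in ordered:
        for rep in representatives:
            if pairwise_identity(rec.sequence, rep.sequence, aligner) >= identity_threshold:
                break
        else:
            representatives.append(rec)
    return representatives
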