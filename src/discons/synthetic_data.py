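"""Synthetic data with planted ground truth.

Every generator is a pure function of its spec and seed.  MSAs are built
block-wise with planted conservation categories; toy protein-nucleic
complexes are built with an exactly known interface; sequence sets are
composed to hit a target disorder fraction under the shipped predictor.  The
geometry is deliberately unphysical (pseudo-atoms on simple lattices): the
point is exact, testable truth, not realistic folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_ONE_TO_THREE, AMINO_ACIDS, GAP
from .disorder import (
    DISORDERED_COMPOSITION,
    ORDERED_COMPOSITION,
    DisorderProfile,
    sample_composition,
)
from .errors import InputError
from .io_formats import MSA, Atom, Chain, Residue, SequenceRecord, StructureModel

PLANTED_CATEGORIES = ("constrained", "flexible", "non_conserved", "structured")
#: Residues with low background frequency -> near-maximal JSD when invariant.
RARE_RESIDUES = ("W", "C", "M", "H")
DISORDERED_SCORE = 0.9
ORDERED_SCORE = 0.1
#: Planted contacts sit at 4.0 +- 0.3 A, safely inside the 5 A rule.
CONTACT_RADIUS = 4.0


# ---------------------------------------------------------------------------
# Planted MSAs
# ---------------------------------------------------------------------------

@dataclass
class MSABlock:
    length: int
    category: str            # planted category, or any category with gap_rate >= 0.3
    gap_rate: float = 0.0

    def __post_init__(self):
        if self.length < 1:
            raise InputError("block length must be >= 1")
        if self.category not in PLANTED_CATEGORIES:
            raise InputError(f"unknown planted category {self.category!r}")
        if not 0.0 <= self.gap_rate <= 1.0:
            raise InputError("gap_rate must be in [0, 1]")

    @property
    def planted_label(self) -> str:
        return "unclassified" if self.gap_rate >= 0.30 else self.category


@dataclass
class MSASpec:
    n_rows: int
    blocks: list[MSABlock]
    seed: int = 0

    def __post_init__(self):
        self.blocks = [b if isinstance(b, MSABlock) else MSABlock(*b) for b in self.blocks]
        if self.n_rows < 2:
            raise InputError("an alignment needs at least 2 rows")
        if not self.blocks:
            raise InputError("spec needs at least one block")


def _uniform_column(rng: np.random.Generator, n_rows: int) -> list[str]:
    """A column whose residue composition is as uniform as n_rows allows.

    Balanced sampling (every amino acid equally often, remainder drawn without
    replacement) keeps the column distribution at the uniform background, so a
    low sequence-conservation score is guaranteed rather than merely likely.
    """
    pool = list(AMINO_ACIDS) * (n_rows // 20)
    remainder = n_rows % 20
    if remainder:
        pool += list(rng.choice(list(AMINO_ACIDS), size=remainder, replace=False))
    rng.shuffle(pool)
    return pool


def _gap_count(rate: float, n_rows: int) -> int:
    """Deterministic per-column gap count honouring the 30% classification filter."""
    if rate >= 0.30:
        return max(int(np.ceil(rate * n_rows)), int(np.ceil(0.30 * n_rows)))
    return int(np.floor(rate * n_rows))


def generate_msa(spec: MSASpec):
    """Build (MSA, planted truth per column, per-row disorder profiles).

    Constrained blocks carry one invariant rare residue per column and
    all-row disorder; flexible blocks uniform residues and all-row disorder;
    non-conserved blocks give 30% of the rows disorder; structured blocks are
    ordered everywhere.  Gaps are planted at an exact per-column count so the
    30% filter outcome is part of the truth.
    """
    rng = np.random.default_rng(spec.seed)
    n_rows = spec.n_rows
    aa = list(AMINO_ACIDS)
    columns: list[list[str]] = []
    col_scores: list[np.ndarray] = []
    truth: list[str] = []

    for block in spec.blocks:
        if block.category == "non_conserved":
            n_dis = int(np.floor(0.3 * n_rows))
            if n_dis < 1 or n_dis / n_rows >= 0.5:
                raise InputError(
                    f"non_conserved block impossible with n_rows={n_rows}: "
                    "needs 0 < disordered rows < half"
                )
            dis_rows = rng.choice(n_rows, size=n_dis, replace=False)
        for _ in range(block.length):
            if block.category == "constrained":
                residues = [rng.choice(RARE_RESIDUES)] * n_rows
                scores = np.full(n_rows, DISORDERED_SCORE)
            elif block.category == "flexible":
                residues = _uniform_column(rng, n_rows)
                scores = np.full(n_rows, DISORDERED_SCORE)
            elif block.category == "non_conserved":
                residues = _uniform_column(rng, n_rows)
                scores = np.full(n_rows, ORDERED_SCORE)
                scores[dis_rows] = DISORDERED_SCORE
            else:  # structured
                residues = _uniform_column(rng, n_rows)
                scores = np.full(n_rows, ORDERED_SCORE)
            n_gaps = _gap_count(block.gap_rate, n_rows)
            if n_gaps:
                for r in rng.choice(n_rows, size=n_gaps, replace=False):
                    residues[r] = GAP
            columns.append(residues)
            col_scores.append(scores)
            truth.append(block.planted_label)

    rows = ["".join(col[r] for col in columns) for r in range(n_rows)]
    # guard: a fully-gapped row carries no sequence; force one column back
    for r, row in enumerate(rows):
        if set(row) == {GAP}:
            columns[0][r] = rng.choice(aa)
            rows[r] = "".join(col[r] for col in columns)

    score_matrix = np.column_stack(col_scores)
    profiles = []
    for r in range(n_rows):
        mask = np.array([c != GAP for c in rows[r]])
        profiles.append(DisorderProfile(f"row{r}", score_matrix[r][mask],
                                        predictor_name="planted"))
    msa = MSA([f"row{r}" for r in range(n_rows)], rows)
    return msa, truth, profiles


# ---------------------------------------------------------------------------
# Planted protein-nucleic complexes
# ---------------------------------------------------------------------------

@dataclass
class ComplexSpec:
    protein_length: int
    rna_length: int
    planted_interface: set[int] = field(default_factory=set)
    contact_atoms_per_residue: int = 6
    seed: int = 0
    residue_names: list[str] | None = None   # one-letter codes, optional
    decoy_protein_chain: bool = False

    def __post_init__(self):
        self.planted_interface = set(int(i) for i in self.planted_interface)
        if self.protein_length < 1 or self.rna_length < 1:
            raise InputError("chains must have at least one residue")
        if self.planted_interface and max(self.planted_interface) >= self.protein_length:
            raise InputError("planted interface index beyond protein length")
        if self.planted_interface and min(self.planted_interface) < 0:
            raise InputError("planted interface indices must be >= 0")
        if len(self.planted_interface) > self.rna_length:
            raise InputError(
                "geometric infeasibility: more planted residues than nucleotides"
            )
        if self.contact_atoms_per_residue < 1:
            raise InputError("contact_atoms_per_residue must be >= 1")
        if self.residue_names is not None and len(self.residue_names) != self.protein_length:
            raise InputError("residue_names must match protein_length")


def _protein_residue(i: int, name3: str, arm_atoms: list[Atom]) -> Residue:
    x = 3.8 * i
    atoms = [
        Atom("N", "N", np.array([x, 0.0, 0.0])),
        Atom("CA", "C", np.array([x + 1.2, 0.8, 0.0])),
        Atom("C", "C", np.array([x + 2.4, 0.0, 0.0])),
        Atom("O", "O", np.array([x + 2.4, -1.2, 0.0])),
        Atom("CB", "C", np.array([x + 1.2, 2.0, 0.0])),
    ]
    return Residue(i, name3, atoms + arm_atoms)


def _rna_residue(j: int, name: str) -> Residue:
    x = 7.0 * j
    return Residue(j, name, [
        Atom("P", "P", np.array([x, 30.0, 0.0])),
        Atom("C1'", "C", np.array([x, 31.5, 1.0])),
        Atom("O2'", "O", np.array([x, 31.5, 2.5])),
        Atom("N1", "N", np.array([x, 33.0, 0.0])),
    ])


def generate_complex(spec: ComplexSpec):
    """Build a toy protein(A)-RNA(B) complex with an exactly planted interface.

    Each planted protein residue receives ``contact_atoms_per_residue``
    pseudo side-chain atoms, each within 4.5 A of exactly one RNA phosphate
    (and > 5 A from every other RNA atom), so its atom-pair count under the
    5 A rule equals the planted count.  All other protein atoms stay > 8 A
    from the RNA.  Returns (StructureModel, truth dict).
    """
    rng = np.random.default_rng(spec.seed)
    planted = sorted(spec.planted_interface)
    if planted:
        step = spec.rna_length / len(planted)
        targets = {res: int(np.floor(k * step)) for k, res in enumerate(planted)}
    else:
        targets = {}

    prot_residues = []
    names = spec.residue_names or ["A"] * spec.protein_length
    for i in range(spec.protein_length):
        arm = []
        if i in targets:
            centre = np.array([7.0 * targets[i], 30.0 - CONTACT_RADIUS, 0.0])
            for k in range(spec.contact_atoms_per_residue):
                offset = rng.uniform(-0.3, 0.3, size=3) * np.array([1, 1, 1])
                offset /= max(1.0, np.linalg.norm(offset) / 0.3)
                arm.append(Atom(f"X{k + 1}", "C", centre + offset))
        name3 = AA_ONE_TO_THREE.get(names[i].upper(), "ALA")
        prot_residues.append(_protein_residue(i, name3, arm))

    rna_names = rng.choice(["A", "C", "G", "U"], size=spec.rna_length)
    rna_residues = [_rna_residue(j, rna_names[j]) for j in range(spec.rna_length)]

    chains = [Chain("A", "protein", prot_residues), Chain("B", "rna", rna_residues)]
    if spec.decoy_protein_chain:
        decoy = [
            Residue(i, "GLY", [
                Atom("N", "N", np.array([3.8 * i, -200.0, 0.0])),
                Atom("CA", "C", np.array([3.8 * i + 1.2, -199.2, 0.0])),
                Atom("C", "C", np.array([3.8 * i + 2.4, -200.0, 0.0])),
                Atom("O", "O", np.array([3.8 * i + 2.4, -201.2, 0.0])),
            ])
            for i in range(10)
        ]
        chains.append(Chain("C", "protein", decoy))

    truth = {
        "interface_residues": set(planted),
        "pairs_per_residue": {i: spec.contact_atoms_per_residue for i in planted},
    }
    return StructureModel(1, chains, name=f"synthetic_complex_seed{spec.seed}"), truth


# ---------------------------------------------------------------------------
# Sequence sets with a target disorder fraction
# ---------------------------------------------------------------------------

def generate_sequence_set(n: int, target_disorder_fraction: float, length: int = 150,
                          seed: int = 0, binding_class=None, taxon_group=None
                          ) -> list[SequenceRecord]:
    """Sequences with one disordered-composition segment of the target size.

    A contiguous charge/Pro/Gly-rich segment of ``round(target * length)``
    residues is placed at a random offset inside an otherwise
    hydrophobic-core-like sequence, so the shipped predictor scores roughly
    the target fraction of residues as disordered.
    """
    if not 0.0 <= target_disorder_fraction <= 1.0:
        raise InputError("target fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(round(target_disorder_fraction * length))
    records = []
    for i in range(n):
        core = sample_composition(ORDERED_COMPOSITION, length - k, rng)
        idr = sample_composition(DISORDERED_COMPOSITION, k, rng)
        start = int(rng.integers(0, length - k + 1)) if k < length else 0
        seq = core[:start] + idr + core[start:]
        records.append(SequenceRecord(f"syn{i:04d}", seq,
                                      binding_class=binding_class, taxon_group=taxon_group))
    return records


# ---------------------------------------------------------------------------
# Complex datasets with coupled disorder / interface size / composition
# ---------------------------------------------------------------------------

#: Arg/Lys-enriched composition used for planted interface residues.
INTERFACE_COMPOSITION = {
    "R": 0.25, "K": 0.20, "G": 0.10, "S": 0.10, "N": 0.08, "A": 0.08,
    "Q": 0.06, "H": 0.05, "T": 0.05, "E": 0.03,
}


def generate_complex_dataset(n: int, seed: int = 0, protein_length: int = 100,
                             rna_length: int = 50):
    """Toy complexes where disorder content drives interface size and the
    planted interface residues are Arg/Lys-enriched.

    The chain-A sequence carries a contiguous disordered-composition segment
    sized to the planted disorder fraction (so the shipped predictor also sees
    the disorder), with interface positions re-drawn from an Arg/Lys-rich
    composition.  Returns a list of dicts with the structure, its planted
    truth, the planted disorder profile of chain A and the planted fraction.
    """
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n):
        dis_frac = float(rng.uniform(0.05, 0.55))
        n_iface = max(1, int(round(protein_length * (0.05 + 0.4 * dis_frac))))
        n_iface = min(n_iface, rna_length, protein_length)
        planted = set(rng.choice(protein_length, size=n_iface, replace=False).tolist())
        n_dis = int(round(dis_frac * protein_length))
        start = int(rng.integers(0, protein_length - n_dis + 1)) if n_dis else 0
        names = []
        for pos in range(protein_length):
            if pos in planted:
                comp = INTERFACE_COMPOSITION
            elif start <= pos < start + n_dis:
                comp = DISORDERED_COMPOSITION
            else:
                comp = ORDERED_COMPOSITION
            names.append(sample_composition(comp, 1, rng))
        scores = np.full(protein_length, ORDERED_SCORE)
        if n_dis:
            scores[start:start + n_dis] = DISORDERED_SCORE
        spec = ComplexSpec(
            protein_length=protein_length, rna_length=rna_length,
            planted_interface=planted, contact_atoms_per_residue=6,
            seed=int(rng.integers(0, 2**31 - 1)), residue_names=names,
        )
        structure, truth = generate_complex(spec)
        items.append({
            "structure": structure,
            "truth": truth,
            "profile": DisorderProfile(f"complex{i:03d}_A", scores, predictor_name="planted"),
            "disorder_fraction": float((scores >= 0.5).mean()),
        })
    return items


# ---------------------------------------------------------------------------
# Ideal backbones (helices, extended chains) for geometry tests
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF atom placement: position d with given internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    nrm = np.cross(ab, bc)
    nrm /= np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    d2 = bond * np.array([-np.cos(angle), np.sin(angle) * np.cos(dihedral),
                          np.sin(angle) * np.sin(dihedral)])
    rot = np.column_stack([bc, m, nrm])
    return c + rot @ d2


def build_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0,
                   chain_id: str = "A", residue_name: str = "ALA",
                   offset=(0.0, 0.0, 0.0)) -> Chain:
    """Ideal poly-residue backbone (N, CA, C, O) with uniform (phi, psi)."""
    if n_res < 2:
        raise InputError("need at least 2 residues")
    offset = np.asarray(offset, dtype=float)
    N = [np.array([0.0, 0.0, 0.0])]
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    CA = [N[0] + np.array([_BOND["N-CA"], 0.0, 0.0])]
    C = [CA[0] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    O = []
    for i in range(1, n_res):
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1], _BOND["C-N"], _ANGLE["CA-C-N"], psi))
        CA.append(_place(CA[i - 1], C[i - 1], N[i], _BOND["N-CA"], _ANGLE["C-N-CA"], omega))
        C.append(_place(C[i - 1], N[i], CA[i], _BOND["CA-C"], _ANGLE["N-CA-C"], phi))
        O.append(_place(N[i], CA[i - 1], C[i - 1], _BOND["C-O"], _ANGLE["CA-C-O"], 180.0))
    # carbonyl O of the last residue, relative to its own N
    O.append(_place(N[-1], CA[-1], C[-1], _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0))
    residues = []
    for i in range(n_res):
        atoms = [
            Atom("N", "N", N[i] + offset),
            Atom("CA", "C", CA[i] + offset),
            Atom("C", "C", C[i] + offset),
            Atom("O", "O", O[i] + offset),
        ]
        residues.append(Residue(i, residue_name, atoms))
    return Chain(chain_id, "protein", residues)


def ideal_alpha_helix(n_res: int = 20, chain_id: str = "A", offset=(0, 0, 0)) -> Chain:
    return build_backbone(n_res, phi=-57.0, psi=-47.0, chain_id=chain_id, offset=offset)


def extended_chain(n_res: int = 20, chain_id: str = "A", offset=(0, 0, 0)) -> Chain:
    return build_backbone(n_res, phi=-140.0, psi=135.0, chain_id=chain_id, offset=offset)
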