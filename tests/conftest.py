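import numpy as np
import pytest

from discons.io_formats import SequenceRecord, write_fasta
from discons.synthetic_data import ComplexSpec, MSABlock, MSASpec, generate_complex, generate_msa

def _pdb_atom(serial, name, resname, chain, resnum, x, y, z, element):
    return (f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")


def make_multi_model_pdb() -> str:
    lines = []
    for model in (1, 2, 3):
        lines.append(f"MODEL     {model}")
        serial = 1
        for resnum in (1, 2):
            shift = 10.0 * (model - 1)
            base = 3.8 * resnum + shift
            for name, element, dx in (("N", "N", 0.0), ("CA", "C", 1.2),
                                      ("C", "C", 2.4), ("O", "O", 2.4)):
                lines.append(_pdb_atom(serial, name, "ALA", "A", resnum, base + dx,
                                       0.0, 0.0, element))
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_protein_rna_pdb(with_water: bool = False) -> str:
    """Two chains: a 3-residue protein (A) and a 2-nucleotide RNA (B)."""
    lines = []
    serial = 1
    for resnum in (1, 2, 3):
        x = 3.8 * resnum
        for name, element, dx, dy in (("N", "N", 0, 0), ("CA", "C", 1.2, 0.8),
                                      ("C", "C", 2.4, 0), ("O", "O", 2.4, -1.2)):
            lines.append(_pdb_atom(serial, name, "GLY", "A", resnum, x + dx, dy, 0, element))
            serial += 1
    lines.append("TER")
    for resnum in (1, 2):
        x = 7.0 * resnum
        for name, element, dy in (("P", "P", 30.0), ("C1'", "C", 31.5),
                                  ("O2'", "O", 32.5), ("N1", "N", 33.0)):
            lines.append(_pdb_atom(serial, name, "U", "B", resnum, x, dy, 0, element))
            serial += 1
    lines.append("TER")
    if with_water:
        for resnum in (1, 2, 3):
            lines.append(_pdb_atom(serial, "O", "HOH", "W", resnum, 50.0 + resnum, 0, 0, "O"))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        write_fasta([SequenceRecord(rid, seq) for rid, seq in records], path)
        return path
    return _write


@pytest.fixture
def four_block_msa():
    """20-row noise-free MSA with one 25-column block per planted category."""
    spec = MSASpec(
        n_rows=20,
        blocks=[MSABlock(25, cat) for cat in
                ("constrained", "flexible", "non_conserved", "structured")],
        seed=7,
    )
    return generate_msa(spec)


@pytest.fixture
def planted_complex():
    spec = ComplexSpec(protein_length=30, rna_length=20, planted_interface={3, 4, 5},
                       contact_atoms_per_residue=6, seed=1)
    return generate_complex(spec)


def brute_force_pair_counts(structure, protein_chain, partner_chain, cutoff=5.0):
    """All-pairs O(n*m) interface oracle: per-residue atom-pair counts."""
    prot = structure.chain(protein_chain)
    part = structure.chain(partner_chain)
    counts = np.zeros(len(prot), dtype=int)
    partner_coords = part.coords()
    for i, res in enumerate(prot.residues):
        for atom in res.atoms:
            d = np.linalg.norm(partner_coords - atom.xyz, axis=1)
            counts[i] += int((d <= cutoff).sum())
    return counts
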