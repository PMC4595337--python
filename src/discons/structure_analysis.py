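"""Structure geometry: interfaces, partners, surface areas, secondary structure.

All distance work uses heavy atoms only.  The protein-nucleic interface rule
follows the contact definition used throughout the analysis: a protein residue
belongs to the interface when it forms at least 5 atom pairs within 5 A of the
nucleic chain.  Buried interface area is (chain SASA + complement SASA -
complex SASA) / 2 from a deterministic Shrake-Rupley calculation, and chains
are placed on the accessibility/interface ("Nussinov") plot with the constant
threshold line of 80 A^2 per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .disorder import DISORDER_THRESHOLD, DisorderProfile
from .errors import InputError
from .io_formats import Chain, StructureModel

CONTACT_DISTANCE = 5.0      # A, inclusive
MIN_ATOM_PAIRS = 5          # atom pairs defining an interface residue
MIN_PARTNER_RESIDUES = 5    # interacting residues defining a chain partner
NUSSINOV_THRESHOLD = 80.0   # A^2/residue level set separating the plot sides
SASA_PROBE = 1.4            # A, water probe
SASA_POINTS = 960           # sphere points per atom

#: Bondi van der Waals radii (A) by element; unlisted elements fall back to 1.7.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}
DEFAULT_RADIUS = 1.70


# ---------------------------------------------------------------------------
# Interfaces and partners
# ---------------------------------------------------------------------------

@dataclass
class InterfaceResult:
    protein_chain_id: str
    partner_chain_id: str
    atom_pair_count: np.ndarray          # per protein residue
    interface_residues: set[int] = field(init=False)

    def __post_init__(self):
        self.atom_pair_count = np.asarray(self.atom_pair_count, dtype=int)
        self.interface_residues = {
            int(i) for i in np.nonzero(self.atom_pair_count >= MIN_ATOM_PAIRS)[0]
        }

    @property
    def n_interface_residues(self) -> int:
        return len(self.interface_residues)

    @property
    def interface_fraction(self) -> float:
        n = len(self.atom_pair_count)
        return self.n_interface_residues / n if n else 0.0


def find_interface_residues(structure: StructureModel, protein_chain: str,
                            partner_chain: str,
                            cutoff: float = CONTACT_DISTANCE) -> InterfaceResult:
    """Count, per protein residue, atom pairs within ``cutoff`` of the partner
    chain; residues with >= 5 pairs form the interface.

    Uses a k-d tree over the partner atoms; results are identical to the
    all-pairs distance matrix (asserted against a brute-force oracle in the
    test suite).
    """
    prot = structure.chain(protein_chain)
    part = structure.chain(partner_chain)
    counts = np.zeros(len(prot), dtype=int)
    if not prot.residues or not part.residues:
        return InterfaceResult(protein_chain, partner_chain, counts)
    tree = cKDTree(part.coords())
    prot_coords = prot.coords()
    per_atom = np.array([len(tree.query_ball_point(x, cutoff)) for x in prot_coords])
    np.add.at(counts, prot.atom_residue_index(), per_atom)
    return InterfaceResult(protein_chain, partner_chain, counts)


def count_partners(structure: StructureModel, chain_id: str,
                   cutoff: float = CONTACT_DISTANCE,
                   min_residues: int = MIN_PARTNER_RESIDUES) -> int:
    """Number of chains that are interaction partners of ``chain_id``.

    A chain B is a partner when at least ``min_residues`` residues of the
    query chain each have at least one atom within ``cutoff`` of any B atom.
    """
    query = structure.chain(chain_id)
    if not query.residues:
        return 0
    qcoords = query.coords()
    qres = query.atom_residue_index()
    n = 0
    for other in structure.chains:
        if other.chain_id == chain_id or not other.residues:
            continue
        tree = cKDTree(other.coords())
        dist, _ = tree.query(qcoords, k=1)
        touching = np.unique(qres[dist <= cutoff])
        if len(touching) >= min_residues:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def atom_radii(elements) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS) for e in elements])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = SASA_PROBE, n_points: int = SASA_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area in A^2."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(coords) == 0:
        return np.zeros(0)
    sphere = _golden_spiral(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    rmax = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax)
                      if j != i]
        if neighbours:
            nb = np.array(neighbours)
            close = np.linalg.norm(coords[nb] - coords[i], axis=1) < expanded[i] + expanded[nb]
            nb = nb[close]
        else:
            nb = np.empty(0, dtype=int)
        if len(nb):
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            accessible = (~buried).sum()
        else:
            accessible = n_points
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible / n_points
    return areas


@dataclass
class SurfaceAreas:
    chain_id: str
    n_residues: int
    sasa_chain: float         # chain alone, A^2
    sasa_complement: float    # all other chains alone, A^2
    sasa_complex: float       # full complex, A^2

    @property
    def interface_area(self) -> float:
        """Buried interface area: (chain + complement - complex) / 2."""
        return 0.5 * (self.sasa_chain + self.sasa_complement - self.sasa_complex)

    @property
    def asa_per_residue(self) -> float:
        return self.sasa_chain / self.n_residues if self.n_residues else 0.0

    @property
    def interface_per_residue(self) -> float:
        return self.interface_area / self.n_residues if self.n_residues else 0.0


def _chain_arrays(chains) -> tuple[np.ndarray, np.ndarray]:
    coords = np.vstack([c.coords() for c in chains])
    elements = [a.element for c in chains for r in c.residues for a in r.atoms]
    return coords, atom_radii(elements)


def compute_surface_areas(structure: StructureModel, chain_id: str,
                          n_points: int = SASA_POINTS) -> SurfaceAreas:
    """SASA of the chain alone, its complement alone, and the full complex."""
    chain = structure.chain(chain_id)
    others = [c for c in structure.chains if c.chain_id != chain_id and c.residues]
    c_coords, c_radii = _chain_arrays([chain])
    sasa_chain = shrake_rupley(c_coords, c_radii, n_points=n_points).sum()
    if not others:
        warnings.warn(f"structure has a single chain {chain_id!r}; interface area is 0",
                      stacklevel=2)
        return SurfaceAreas(chain_id, len(chain), sasa_chain, 0.0, sasa_chain)
    o_coords, o_radii = _chain_arrays(others)
    sasa_complement = shrake_rupley(o_coords, o_radii, n_points=n_points).sum()
    sasa_complex = shrake_rupley(
        np.vstack([c_coords, o_coords]), np.concatenate([c_radii, o_radii]),
        n_points=n_points,
    ).sum()
    return SurfaceAreas(chain_id, len(chain), float(sasa_chain),
                        float(sasa_complement), float(sasa_complex))


@dataclass
class FlexibilityCall:
    asa_per_residue: float
    interface_per_residue: float
    side: str                     # ordered | disordered_folding_upon_binding
    threshold_line: float = NUSSINOV_THRESHOLD


def classify_flexibility(areas: SurfaceAreas,
                         threshold: float = NUSSINOV_THRESHOLD) -> FlexibilityCall:
    """Place a chain on the accessibility/interface plot.

    The threshold line of 80 is read as the level set
    ``asa_per_residue + interface_per_residue = 80``; chains below it are
    called ordered, chains on or above it disordered (folding upon binding).
    """
    total = areas.asa_per_residue + areas.interface_per_residue
    side = "ordered" if total < threshold else "disordered_folding_upon_binding"
    return FlexibilityCall(areas.asa_per_residue, areas.interface_per_residue, side, threshold)


# ---------------------------------------------------------------------------
# Secondary structure (DSSP-style)
# ---------------------------------------------------------------------------

SS_LABELS = ("helix_alpha", "helix_310", "strand", "turn", "unclassified")
_HB_ENERGY_CUTOFF = -0.5        # kcal/mol
_Q_FACTOR = 0.084 * 332.0       # Kabsch-Sander electrostatic prefactor
_PEPTIDE_BOND_MAX = 2.5         # A, C(i-1)-N(i) distance for chain continuity


def _backbone_arrays(chain: Chain):
    names = ("N", "CA", "C", "O")
    n = len(chain)
    coords = {k: np.full((n, 3), np.nan) for k in names}
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            if atom.name in coords and np.isnan(coords[atom.name][i]).any():
                coords[atom.name][i] = atom.xyz
    complete = ~np.any([np.isnan(coords[k]).any(axis=1) for k in names], axis=0)
    return coords, complete


def _hbond_matrix(chain: Chain):
    """hb[i, j]: the C=O of residue i accepts an H bond from the N-H of residue j."""
    bb, complete = _backbone_arrays(chain)
    n = len(chain)
    # reconstruct amide H: 1.01 A from N, opposite the preceding carbonyl O
    H = np.full((n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for j in range(1, n):
        if not (complete[j] and complete[j - 1]):
            continue
        if np.linalg.norm(bb["N"][j] - bb["C"][j - 1]) > _PEPTIDE_BOND_MAX:
            continue  # chain break
        if chain.residues[j].name == "PRO":
            continue  # proline has no amide H
        direction = bb["C"][j - 1] - bb["O"][j - 1]
        H[j] = bb["N"][j] + 1.01 * direction / np.linalg.norm(direction)
        has_h[j] = True
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if not complete[i]:
            continue
        for j in range(n):
            if j == i or j == i + 1 or not has_h[j]:
                continue
            r_on = np.linalg.norm(bb["O"][i] - bb["N"][j])
            r_ch = np.linalg.norm(bb["C"][i] - H[j])
            r_oh = np.linalg.norm(bb["O"][i] - H[j])
            r_cn = np.linalg.norm(bb["C"][i] - bb["N"][j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            energy = _Q_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _HB_ENERGY_CUTOFF:
                hb[i, j] = True
    return hb, complete


def assign_secondary_structure(structure: StructureModel, chain_id: str) -> list[str]:
    """DSSP-style per-residue labels for a protein chain.

    Hydrogen-bond energies use the Kabsch-Sander electrostatic model with the
    amide H rebuilt from the preceding C=O.  Consecutive n-turns yield helices
    (n=4 alpha, n=3 3-10), bridge patterns yield strands, remaining H-bonded
    turns are labelled turn, everything else unclassified.  Residues with an
    incomplete backbone stay unclassified.
    """
    chain = structure.chain(chain_id)
    if chain.polymer_type != "protein":
        raise InputError(f"chain {chain_id!r} is {chain.polymer_type}, not protein")
    n = len(chain)
    hb, complete = _hbond_matrix(chain)

    turn = {3: np.zeros(n, dtype=bool), 4: np.zeros(n, dtype=bool), 5: np.zeros(n, dtype=bool)}
    for m in (3, 4, 5):
        for i in range(n - m):
            if hb[i, i + m]:
                turn[m][i] = True

    labels = np.array(["unclassified"] * n, dtype=object)

    # bridges -> strand
    def _hbond(a, b):
        return 0 <= a < n and 0 <= b < n and hb[a, b]

    strand = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3:
                continue
            parallel = (_hbond(i - 1, j) and _hbond(j, i + 1)) or \
                       (_hbond(j - 1, i) and _hbond(i, j + 1))
            antiparallel = (_hbond(i, j) and _hbond(j, i)) or \
                           (_hbond(i - 1, j + 1) and _hbond(j - 1, i + 1))
            if parallel or antiparallel:
                strand[i] = strand[j] = True
    labels[strand] = "strand"

    # 3-10 helices: two consecutive 3-turns
    for i in range(1, n - 3):
        if turn[3][i] and turn[3][i - 1]:
            labels[i:i + 3] = "helix_310"
    # alpha helices: two consecutive 4-turns (take precedence)
    for i in range(1, n - 4):
        if turn[4][i] and turn[4][i - 1]:
            labels[i:i + 4] = "helix_alpha"

    # H-bonded turns (3-, 4- or 5-turns) not already helix/strand
    in_turn = np.zeros(n, dtype=bool)
    for m in (3, 4, 5):
        for i in np.nonzero(turn[m])[0]:
            in_turn[i + 1:i + m] = True
    for i in range(n):
        if in_turn[i] and labels[i] == "unclassified":
            labels[i] = "turn"

    labels[~complete] = "unclassified"
    return list(labels)


def regular_fraction(labels) -> float:
    """Fraction of residues in regular secondary structure (helices + strands)."""
    if len(labels) == 0:
        return 0.0
    regular = sum(l in ("helix_alpha", "helix_310", "strand") for l in labels)
    return regular / len(labels)


def disordered_region_ss_fractions(labels, profile: DisorderProfile,
                                   threshold: float = DISORDER_THRESHOLD):
    """(helix, strand, regular) fractions over predicted-disordered residues.

    Returns ``(nan, nan, nan)`` when the chain has no disordered residues.
    """
    if len(labels) != len(profile):
        raise InputError("labels and disorder profile cover different lengths")
    mask = profile.scores >= threshold
    n_dis = int(mask.sum())
    if n_dis == 0:
        return (float("nan"),) * 3
    sub = [l for l, m in zip(labels, mask) if m]
    helix = sum(l in ("helix_alpha", "helix_310") for l in sub) / n_dis
    strand = sum(l == "strand" for l in sub) / n_dis
    return helix, strand, helix + strand
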