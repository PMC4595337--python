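"""Per-residue intrinsic-disorder prediction.

The reference predictor follows the pairwise interaction-energy estimation
scheme of IUPred: for each residue the stabilizing energy contributed by its
sequential neighbourhood is estimated from a 20x20 amino-acid interaction
matrix, smoothed along the chain, and mapped through a strictly decreasing
logistic transform onto a disorder probability in [0, 1].  The matrix shipped
here is built from the TOP-IDP order/disorder propensity scale plus a
charge-pair term and the transform is calibrated on synthetic ordered vs
disordered compositions; it reproduces the *shape* of the IUPred algorithm,
not its published parameter values.

Any callable mapping a sequence to a per-residue [0,1] vector can be plugged
in anywhere a predictor is accepted; a windowed TOP-IDP propensity predictor
is provided as a trivial fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, CHARGE, TOP_IDP, UNKNOWN
from .errors import InputError

#: Disorder threshold used throughout: residues scoring >= 0.5 are disordered.
DISORDER_THRESHOLD = 0.5

# Transform parameters fitted once with fit_transform() on the calibration
# compositions below (10 ordered, 10 disordered, length 150, fixed seed), so
# that the logistic separates the two groups at 0.5 with group means near
# 0.25 / 0.75.  See calibrate_default_transform().
DEFAULT_OFFSET = -0.1620520021406792
DEFAULT_STEEPNESS = 4.161326567599224


def _build_energy_matrix() -> np.ndarray:
    """Symmetric 20x20 stabilizing-interaction matrix.

    P[a,b] = mean order propensity of the pair
             + hydrophobic-pair bonus
             - like-charge repulsion / + opposite-charge salt-bridge term.
    Higher values mean a more stabilizing (order-promoting) contact.
    """
    f = np.array([-TOP_IDP[aa] for aa in AMINO_ACIDS])   # order propensity
    q = np.array([CHARGE[aa] for aa in AMINO_ACIDS])
    fpos = np.clip(f, 0.0, None)
    P = 0.5 * (f[:, None] + f[None, :])
    P += 0.4 * fpos[:, None] * fpos[None, :]
    P -= 0.3 * q[:, None] * q[None, :]
    return P


@dataclass
class EnergyPredictorMatrix:
    """Parameters of the pairwise-energy disorder predictor."""

    P: np.ndarray = field(default_factory=_build_energy_matrix)
    window_radius: int = 50
    smooth_radius: int = 10
    offset: float = DEFAULT_OFFSET
    steepness: float = DEFAULT_STEEPNESS

    def __post_init__(self):
        if self.P.shape != (20, 20) or not np.allclose(self.P, self.P.T):
            raise InputError("energy matrix must be a symmetric 20x20 array")

    def transform(self, energy):
        """Strictly decreasing logistic map from stabilizing energy to [0,1]."""
        return 1.0 / (1.0 + np.exp(self.steepness * (np.asarray(energy) - self.offset)))


@dataclass
class DisorderProfile:
    """Per-residue disorder scores in [0,1] for one sequence."""

    sequence_id: str
    scores: np.ndarray
    predictor_name: str = "unknown"
    threshold: float = DISORDER_THRESHOLD

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) == 0:
            raise InputError(f"profile {self.sequence_id!r}: scores must be a non-empty vector")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise InputError(f"profile {self.sequence_id!r}: scores outside [0,1]")

    def __len__(self) -> int:
        return len(self.scores)


def _encode(sequence: str) -> np.ndarray:
    idx = np.empty(len(sequence), dtype=int)
    for i, aa in enumerate(sequence):
        if aa in AA_INDEX:
            idx[i] = AA_INDEX[aa]
        elif aa == UNKNOWN:
            idx[i] = 20
        else:
            raise InputError(f"unknown residue {aa!r} at position {i}")
    return idx


def _moving_mean(values: np.ndarray, radius: int) -> np.ndarray:
    """Mean over a +-radius window, truncated (renormalized) at the ends."""
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(n)
    for k in range(n):
        lo, hi = max(0, k - radius), min(n, k + radius + 1)
        out[k] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


class PairwiseEnergyPredictor:
    """IUPred-style predictor: windowed pairwise energy -> logistic transform."""

    def __init__(self, matrix: EnergyPredictorMatrix | None = None):
        self.matrix = matrix if matrix is not None else EnergyPredictorMatrix()
        self.name = "iupred-like"
        # extend P with an 'X' row/column holding the column means
        P = self.matrix.P
        col_mean = P.mean(axis=0)
        Px = np.empty((21, 21))
        Px[:20, :20] = P
        Px[20, :20] = col_mean
        Px[:20, 20] = col_mean
        Px[20, 20] = col_mean.mean()
        self._P = Px

    def energies(self, sequence: str) -> np.ndarray:
        """Smoothed per-residue stabilizing energies."""
        if not sequence:
            raise InputError("cannot predict disorder for an empty sequence")
        idx = _encode(sequence)
        n = len(idx)
        r = self.matrix.window_radius
        e = np.empty(n)
        for k in range(n):
            lo, hi = max(0, k - r), min(n, k + r + 1)
            window = np.concatenate([idx[lo:k], idx[k + 1:hi]])
            if len(window) == 0:
                e[k] = 0.0
            else:
                e[k] = self._P[idx[k], window].mean()
        return _moving_mean(e, self.matrix.smooth_radius)

    def __call__(self, sequence: str) -> np.ndarray:
        return self.matrix.transform(self.energies(sequence))


class PropensityPredictor:
    """Trivial fallback: windowed TOP-IDP propensity through a logistic map."""

    def __init__(self, radius: int = 10, scale: float = 0.15):
        self.radius = radius
        self.scale = scale
        self.name = "top-idp"
        self._vals = {aa: TOP_IDP[aa] for aa in AMINO_ACIDS}
        self._vals[UNKNOWN] = float(np.mean(list(TOP_IDP.values())))

    def __call__(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise InputError("cannot predict disorder for an empty sequence")
        try:
            raw = np.array([self._vals[aa] for aa in sequence])
        except KeyError as exc:
            raise InputError(f"unknown residue {exc.args[0]!r}") from exc
        smooth = _moving_mean(raw, self.radius)
        return 1.0 / (1.0 + np.exp(-smooth / self.scale))


def predict_disorder(sequence: str, predictor=None, sequence_id: str = "seq") -> DisorderProfile:
    """Run a predictor (default: the IUPred-style reference) over a sequence."""
    if isinstance(sequence, (list, tuple)):
        sequence = "".join(sequence)
    if predictor is None:
        predictor = PairwiseEnergyPredictor()
    scores = np.clip(np.asarray(predictor(sequence), dtype=float), 0.0, 1.0)
    if len(scores) != len(sequence):
        raise InputError("predictor returned a vector of the wrong length")
    name = getattr(predictor, "name", type(predictor).__name__)
    return DisorderProfile(sequence_id, scores, predictor_name=name)


def disorder_fraction(profile: DisorderProfile) -> float:
    """Fraction of residues at or above the profile's disorder threshold."""
    return float((profile.scores >= profile.threshold).mean())


# ---------------------------------------------------------------------------
# Transform calibration
# ---------------------------------------------------------------------------

#: Composition of a folded, hydrophobic-core-like protein.
ORDERED_COMPOSITION = {
    "L": 0.12, "V": 0.10, "I": 0.08, "F": 0.07, "A": 0.12, "G": 0.06,
    "W": 0.03, "Y": 0.05, "M": 0.03, "T": 0.06, "S": 0.05, "C": 0.03,
    "N": 0.04, "Q": 0.03, "D": 0.04, "E": 0.03, "K": 0.03, "R": 0.02,
    "H": 0.01,
}
#: Composition of a charge/Pro/Gly-rich intrinsically disordered region.
DISORDERED_COMPOSITION = {
    "E": 0.15, "K": 0.12, "R": 0.08, "D": 0.10, "S": 0.12, "P": 0.12,
    "G": 0.12, "Q": 0.08, "A": 0.06, "T": 0.05,
}


def sample_composition(composition: dict, length: int, rng: np.random.Generator) -> str:
    letters = list(composition)
    probs = np.array([composition[a] for a in letters], dtype=float)
    probs /= probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def calibration_sequences(n: int = 10, length: int = 150, seed: int = 20151006):
    """Synthetic known-ordered and known-disordered calibration sequences."""
    rng = np.random.default_rng(seed)
    ordered = [sample_composition(ORDERED_COMPOSITION, length, rng) for _ in range(n)]
    disordered = [sample_composition(DISORDERED_COMPOSITION, length, rng) for _ in range(n)]
    return ordered, disordered


def fit_transform(matrix: EnergyPredictorMatrix | None = None,
                  ordered=None, disordered=None) -> tuple[float, float]:
    """Fit (offset, steepness) so the two calibration groups separate at 0.5.

    The offset is the midpoint of the group mean energies and the steepness is
    chosen so the group means map to scores 0.25 and 0.75.
    """
    if matrix is None:
        matrix = EnergyPredictorMatrix()
    if ordered is None or disordered is None:
        ordered, disordered = calibration_sequences()
    pred = PairwiseEnergyPredictor(matrix)
    e_ord = np.mean([pred.energies(s).mean() for s in ordered])
    e_dis = np.mean([pred.energies(s).mean() for s in disordered])
    if e_ord <= e_dis:
        raise InputError("calibration failed: ordered group not more stabilized")
    offset = 0.5 * (e_ord + e_dis)
    steepness = 2.0 * np.log(3.0) / (e_ord - e_dis)
    return float(offset), float(steepness)
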