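"""Column-wise conservation of sequence and of disorder, and classification.

Sequence conservation score (SCS): Jensen-Shannon divergence between each
column's amino-acid distribution and a background distribution (Capra & Singh
scoring), gap-penalized and combined with a length-3 window.  Disorder
conservation score (DCS): fraction of aligned sequences predicted disordered
at the column.  Columns with less than 30% gaps are classified as constrained,
flexible, non-conserved or structured disorder; gappier columns stay
unclassified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX, GAP, UNKNOWN, background_distribution
from .disorder import DISORDER_THRESHOLD, DisorderProfile
from .errors import InputError
from .io_formats import MSA

GAP_FILTER = 0.30          # columns with >= 30% gaps are not classified
WINDOW_WEIGHT = 0.5        # Capra & Singh default combination weight
CATEGORIES = ("constrained", "flexible", "non_conserved", "structured")


@dataclass
class ColumnAnnotation:
    """Scores and category for one alignment column (0-based index)."""

    column_index: int
    scs: float
    dcs: float
    gap_fraction: float
    category: str = "unclassified"

    @property
    def scs_binned(self) -> int:
        return bin_score(self.scs)

    @property
    def dcs_binned(self) -> int:
        return bin_score(self.dcs)


def bin_score(score: float) -> int:
    """Map a [0,1] score onto the 0-9 display scale: floor(score*10), clipped."""
    return min(int(np.floor(score * 10.0)), 9)


def jensen_shannon_divergence(p, q, weight: float = 0.5) -> float:
    """JSD with log base 2 (bounded by 1); symmetric, 0 iff p == q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = weight * p + (1.0 - weight) * q
    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
    return weight * kl(p, m) + (1.0 - weight) * kl(q, m)


def _column_distribution(column: list[str]) -> tuple[np.ndarray, int]:
    """Amino-acid frequency over non-gap rows (X ignored); returns (p, n_nongap)."""
    counts = np.zeros(20)
    n_nongap = 0
    for aa in column:
        if aa == GAP:
            continue
        n_nongap += 1
        if aa == UNKNOWN:
            continue
        try:
            counts[AA_INDEX[aa]] += 1
        except KeyError:
            raise InputError(f"unexpected alignment character {aa!r}") from None
    total = counts.sum()
    p = counts / total if total > 0 else counts
    return p, n_nongap


def sequence_conservation(msa: MSA, background="blosum62", window: int = 3) -> np.ndarray:
    """Per-column SCS: gap-penalized JSD vs background, window-averaged.

    For column c the raw divergence D_c = JSD(p_c, background) is scaled by
    (1 - gap_fraction) and the reported score is
    ``(1-w) * D'_c + w * mean(D' over the window centred at c)`` with w = 0.5
    and the window truncated at the alignment edges.
    """
    if window < 1 or window % 2 == 0:
        raise InputError("window must be a positive odd integer")
    bg = background_distribution(background)
    gaps = msa.gap_fraction
    d = np.zeros(msa.n_cols)
    all_gap = np.zeros(msa.n_cols, dtype=bool)
    for c in range(msa.n_cols):
        p, n_nongap = _column_distribution(msa.column(c))
        if n_nongap == 0 or p.sum() == 0:
            all_gap[c] = n_nongap == 0
            d[c] = 0.0
        else:
            d[c] = jensen_shannon_divergence(p, bg) * (1.0 - gaps[c])
    radius = window // 2
    scs = np.empty(msa.n_cols)
    for c in range(msa.n_cols):
        lo, hi = max(0, c - radius), min(msa.n_cols, c + radius + 1)
        scs[c] = (1.0 - WINDOW_WEIGHT) * d[c] + WINDOW_WEIGHT * d[lo:hi].mean()
    scs[all_gap] = 0.0
    return scs


def map_profile_to_columns(row: str, profile: DisorderProfile, row_id: str = "") -> np.ndarray:
    """Spread an ungapped profile onto alignment columns (NaN at gaps)."""
    ungapped_len = len(row) - row.count(GAP)
    if len(profile) != ungapped_len:
        raise InputError(
            f"row {row_id or profile.sequence_id!r}: profile length {len(profile)} "
            f"does not match ungapped row length {ungapped_len}"
        )
    out = np.full(len(row), np.nan)
    k = 0
    for c, aa in enumerate(row):
        if aa != GAP:
            out[c] = profile.scores[k]
            k += 1
    return out


def disorder_conservation(msa: MSA, profiles: list[DisorderProfile],
                          threshold: float = DISORDER_THRESHOLD) -> np.ndarray:
    """Per-column DCS: fraction of non-gap rows predicted disordered there."""
    if len(profiles) != msa.n_rows:
        raise InputError(
            f"need one disorder profile per alignment row "
            f"({len(profiles)} profiles for {msa.n_rows} rows)"
        )
    mapped = np.vstack([
        map_profile_to_columns(row, prof, row_id=rid)
        for row, prof, rid in zip(msa.rows, profiles, msa.ids)
    ])
    nongap = ~np.isnan(mapped)
    n_nongap = nongap.sum(axis=0)
    disordered = (mapped >= threshold) & nongap
    with np.errstate(invalid="ignore", divide="ignore"):
        dcs = np.where(n_nongap > 0, disordered.sum(axis=0) / np.maximum(n_nongap, 1), 0.0)
    return dcs


def classify_columns(scs: np.ndarray, dcs: np.ndarray, gap_fraction: np.ndarray) -> list[ColumnAnnotation]:
    """Four-way classification of columns passing the 30% gap filter.

    constrained: SCS >= 0.5 and DCS >= 0.5; flexible: SCS < 0.5 and DCS >= 0.5;
    non-conserved: 0 < DCS < 0.5; structured: DCS == 0 (complete lack of
    disorder).  Columns with gap fraction >= 0.30 are unclassified.
    """
    annotations = []
    for c, (s, d, g) in enumerate(zip(scs, dcs, gap_fraction)):
        if g >= GAP_FILTER:
            cat = "unclassified"
        elif d >= 0.5:
            cat = "constrained" if s >= 0.5 else "flexible"
        elif d > 0.0:
            cat = "non_conserved"
        else:
            cat = "structured"
        annotations.append(ColumnAnnotation(c, float(s), float(d), float(g), cat))
    return annotations


def annotate_msa(msa: MSA, profiles: list[DisorderProfile], background="blosum62",
                 window: int = 3) -> list[ColumnAnnotation]:
    """Convenience: SCS + DCS + classification for a whole alignment."""
    scs = sequence_conservation(msa, background=background, window=window)
    dcs = disorder_conservation(msa, profiles)
    return classify_columns(scs, dcs, msa.gap_fraction)


def category_histogram(annotations: list[ColumnAnnotation], subset=None):
    """Category counts and the 10x10 binned (SCS, DCS) matrix.

    Both are restricted to classified columns, intersected with ``subset``
    (a set of column indices) when given.  The matrix is indexed
    ``[scs_binned, dcs_binned]`` and underlies the score-pair heat maps.
    """
    counts = Counter({cat: 0 for cat in CATEGORIES})
    matrix = np.zeros((10, 10), dtype=int)
    for ann in annotations:
        if ann.category == "unclassified":
            continue
        if subset is not None and ann.column_index not in subset:
            continue
        counts[ann.category] += 1
        matrix[ann.scs_binned, ann.dcs_binned] += 1
    return dict(counts), matrix
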