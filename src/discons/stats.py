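"""Statistics over disorder fractions, compositions and conservation scores.

Group tests (Welch t, two-sample Kolmogorov-Smirnov) and correlations
(Pearson, Kendall tau-b) are delegated to scipy; reported p-values are floored
at 2.2e-16, the conventional lowest printed precision, with the raw values
retained.  Composition enrichment is the percent change of a target amino-acid
frequency relative to a background frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alphabet import AMINO_ACIDS
from .conservation import ColumnAnnotation
from .disorder import DISORDER_THRESHOLD, DisorderProfile, disorder_fraction
from .errors import InputError
from .io_formats import MSA

P_FLOOR = 2.2e-16


def composition_enrichment(target_counts: dict, background_counts: dict) -> pd.DataFrame:
    """Per-amino-acid frequency change of a target set vs a background set.

    ``relative_change`` is ``100 * (target_freq - background_freq) /
    background_freq`` (NaN where the background frequency is zero).
    """
    t = np.array([float(target_counts.get(aa, 0)) for aa in AMINO_ACIDS])
    b = np.array([float(background_counts.get(aa, 0)) for aa in AMINO_ACIDS])
    if b.sum() <= 0:
        raise InputError("background counts are empty")
    if t.sum() <= 0:
        raise InputError("target counts are empty")
    tf = t / t.sum()
    bf = b / b.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        change = np.where(bf > 0, 100.0 * (tf - bf) / np.where(bf > 0, bf, 1.0), np.nan)
    return pd.DataFrame(
        {"target_frequency": tf, "background_frequency": bf, "relative_change": change},
        index=list(AMINO_ACIDS),
    )


@dataclass
class GroupComparison:
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    medians: tuple[float, float]
    test: str                  # welch_t | ks
    statistic: float
    p_value: float             # floored at 2.2e-16
    p_value_raw: float


def compare_groups(values_by_group: dict, test: str = "welch_t") -> GroupComparison:
    """Two-sample Welch t-test or Kolmogorov-Smirnov test between two groups."""
    if len(values_by_group) != 2:
        raise InputError("compare_groups expects exactly two groups")
    (name_a, a), (name_b, b) = values_by_group.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 observations")
    if test == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif test == "ks":
        res = sps.ks_2samp(a, b)
    else:
        raise InputError(f"unknown test {test!r}; choose 'welch_t' or 'ks'")
    return GroupComparison(
        groups=(name_a, name_b),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        medians=(float(np.median(a)), float(np.median(b))),
        test=test,
        statistic=float(res.statistic),
        p_value=float(max(res.pvalue, P_FLOOR)),
        p_value_raw=float(res.pvalue),
    )


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson product-moment or Kendall tau-b correlation coefficient.

    Returns NaN when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "kendall":
        return float(sps.kendalltau(x, y, variant="b").statistic)
    raise InputError(f"unknown method {method!r}; choose 'pearson' or 'kendall'")


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (monotone in the raw p-value ranks)."""
    p = np.asarray(p_values, dtype=float)
    return sps.false_discovery_control(p, method="bh")


def per_aa_conservation(annotations: list[ColumnAnnotation], msa: MSA,
                        disordered_columns=None, dcs_threshold: float = DISORDER_THRESHOLD,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Mean SCS per amino acid over occurrences in disordered columns.

    Disordered columns default to those with DCS >= 0.5.  Each amino acid's
    SCS sample (one value per (row, column) occurrence) is compared to the
    pooled occurrences of all other residues by a Welch t-test; the 20 raw
    p-values are BH-corrected and flagged at ``alpha``.
    """
    if disordered_columns is None:
        disordered_columns = {a.column_index for a in annotations if a.dcs >= dcs_threshold}
    else:
        disordered_columns = set(disordered_columns)
    scs_by_col = {a.column_index: a.scs for a in annotations}
    values: dict[str, list[float]] = {aa: [] for aa in AMINO_ACIDS}
    for c in sorted(disordered_columns):
        for aa in msa.column(c):
            if aa in values:
                values[aa].append(scs_by_col[c])
    all_values = np.array([v for vals in values.values() for v in vals])
    if all_values.size == 0:
        return pd.DataFrame(
            columns=["n", "mean_scs", "overall_mean", "statistic", "p_value",
                     "p_adjusted", "significant"],
        )
    overall = float(all_values.mean())
    rows = {}
    for aa in AMINO_ACIDS:
        sample = np.asarray(values[aa])
        rest = np.array([v for other, vals in values.items() if other != aa for v in vals])
        if len(sample) < 2 or len(rest) < 2 or np.ptp(all_values) == 0:
            stat, p = np.nan, np.nan
        else:
            res = sps.ttest_ind(sample, rest, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        rows[aa] = {
            "n": len(sample),
            "mean_scs": float(sample.mean()) if len(sample) else np.nan,
            "overall_mean": overall,
            "statistic": stat,
            "p_value": p,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    tested = table["p_value"].notna()
    adjusted = np.full(len(table), np.nan)
    if tested.any():
        adjusted[tested.to_numpy()] = benjamini_hochberg(table.loc[tested, "p_value"])
    table["p_adjusted"] = adjusted
    table["significant"] = table["p_adjusted"] < alpha
    return table


def disorder_fraction_summary(records, profiles: list[DisorderProfile],
                              group_by: str = "binding_class") -> pd.DataFrame:
    """Distribution summary of disorder fractions per group (class or taxon)."""
    if group_by not in ("binding_class", "taxon_group"):
        raise InputError("group_by must be 'binding_class' or 'taxon_group'")
    if len(records) != len(profiles):
        raise InputError("need one profile per record")
    fracs, groups = [], []
    for rec, prof in zip(records, profiles):
        group = getattr(rec, group_by)
        if group is None:
            continue
        groups.append(group)
        fracs.append(disorder_fraction(prof))
    if not fracs:
        raise InputError(f"no records carry a {group_by} tag")
    df = pd.DataFrame({group_by: groups, "disorder_fraction": fracs})
    summary = df.groupby(group_by)["disorder_fraction"].agg(
        n="count", mean="mean", median="median",
        q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75),
    )
    return summary.reset_index()
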