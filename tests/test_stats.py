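import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import stdtr

from discons.conservation import annotate_msa
from discons.disorder import DisorderProfile, PairwiseEnergyPredictor, predict_disorder
from discons.errors import InputError
from discons.io_formats import MSA
from discons.stats import (
    benjamini_hochberg,
    compare_groups,
    composition_enrichment,
    correlate,
    disorder_fraction_summary,
    per_aa_conservation,
)
from discons.synthetic_data import generate_sequence_set


# -- independent oracles ----------------------------------------------------

def welch_oracle(a, b):
    """Welch t statistic and two-sided p from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stdtr(df, -abs(t))
    return t, p


def ks_oracle(a, b):
    """Two-sample KS statistic by direct ECDF comparison."""
    a, b = np.sort(a), np.sort(b)
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return np.abs(fa - fb).max()


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def kendall_tau_b_oracle(x, y):
    """Tie-corrected tau-b by explicit enumeration of all pairs."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    return (nc - nd) / np.sqrt((n0 - tx) * (n0 - ty))


class TestEnrichment:
    def test_identical_counts_give_zero_change(self):
        counts = {"A": 10, "R": 5, "K": 3}
        table = composition_enrichment(counts, counts)
        np.testing.assert_allclose(table["relative_change"].dropna(), 0.0, atol=1e-12)

    def test_doubled_arginine_is_plus_100(self):
        background = {"A": 80, "R": 10, "K": 10}
        target = {"A": 70, "R": 20, "K": 10}
        table = composition_enrichment(target, background)
        assert table.loc["R", "relative_change"] == pytest.approx(100.0)

    def test_two_letter_toy_hand_arithmetic(self):
        table = composition_enrichment({"A": 30, "R": 70}, {"A": 50, "R": 50})
        assert table.loc["R", "relative_change"] == pytest.approx(40.0)
        assert table.loc["A", "relative_change"] == pytest.approx(-40.0)

    def test_frequencies_sum_to_one_and_absent_background_is_nan(self):
        table = composition_enrichment({"A": 5, "W": 5}, {"A": 10})
        assert table["target_frequency"].sum() == pytest.approx(1.0)
        assert table["background_frequency"].sum() == pytest.approx(1.0)
        assert np.isnan(table.loc["W", "relative_change"])

    def test_empty_counts_rejected(self):
        with pytest.raises(InputError):
            composition_enrichment({"A": 1}, {})


class TestGroupComparisons:
    def test_identical_samples_ks_statistic_zero(self):
        a = list(np.linspace(0, 1, 20))
        comp = compare_groups({"x": a, "y": list(a)}, test="ks")
        assert comp.statistic == pytest.approx(0.0)

    def test_welch_sign_matches_mean_difference(self):
        comp = compare_groups({"low": [1.0, 1.1, 0.9], "high": [5.0, 5.1, 4.9]})
        assert comp.statistic < 0 and comp.p_value < 1e-4

    def test_seeded_normal_shift_strongly_significant(self):
        rng = np.random.default_rng(42)
        a, b = rng.normal(0, 1, 1000), rng.normal(1, 1, 1000)
        comp = compare_groups({"a": a, "b": b}, test="welch_t")
        assert comp.p_value_raw < 1e-10
        assert comp.p_value >= 2.2e-16    # reported value is floored

    @pytest.mark.parametrize("test", ["welch_t", "ks"])
    def test_agrees_with_first_principles_oracle(self, test):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(10, 60))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(10, 60))
            comp = compare_groups({"a": a, "b": b}, test=test)
            if test == "welch_t":
                t, p = welch_oracle(a, b)
                assert comp.statistic == pytest.approx(t, abs=1e-10)
                assert comp.p_value_raw == pytest.approx(p, abs=1e-10)
            else:
                assert comp.statistic == pytest.approx(ks_oracle(a, b), abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})


class TestCorrelate:
    def test_perfect_linear_relationships(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1, "pearson") == pytest.approx(1.0)
        assert correlate(x, 2 * x + 1, "kendall") == pytest.approx(1.0)
        assert correlate(x, -x, "pearson") == pytest.approx(-1.0)
        assert correlate(x, -x, "kendall") == pytest.approx(-1.0)

    def test_tau_b_with_ties_matches_brute_force(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0]
        assert correlate(x, y, "kendall") == pytest.approx(
            kendall_tau_b_oracle(x, y), abs=1e-12
        )

    def test_seeded_random_parity_with_oracles(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            assert correlate(x, y, "pearson") == pytest.approx(
                pearson_oracle(x, y), abs=1e-10)
            assert correlate(x, y, "kendall") == pytest.approx(
                kendall_tau_b_oracle(x, y), abs=1e-10)

    def test_zero_variance_is_missing(self):
        assert np.isnan(correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestBenjaminiHochberg:
    def test_adjusted_values_monotone_in_rank(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0, 1, 20)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestPerAAConservation:
    def test_uniform_scs_yields_equal_means_and_no_flags(self):
        # all columns invariant W: identical SCS everywhere, disorder conserved
        msa = MSA([f"r{i}" for i in range(6)], ["WWWW"] * 6)
        profiles = [DisorderProfile(f"r{i}", [0.9] * 4) for i in range(6)]
        table = per_aa_conservation(annotate_msa(msa, profiles), msa)
        present = table[table["n"] > 0]
        assert (present.index == "W").all()
        assert not table["significant"].fillna(False).any()

    def test_planted_high_scs_arginine_flagged(self):
        # R occupies invariant (high SCS) columns; other residues random columns
        rng = np.random.default_rng(5)
        n_rows, n_cols = 12, 40
        cols = []
        for c in range(n_cols):
            if c < 15:
                cols.append(["R"] * n_rows)
            else:
                cols.append(list(rng.choice(list("ACDEFGHIKLMNPQSTVWY"), size=n_rows)))
        rows = ["".join(col[r] for col in cols) for r in range(n_rows)]
        msa = MSA([f"r{i}" for i in range(n_rows)], rows)
        profiles = [DisorderProfile(f"r{i}", [0.9] * n_cols) for i in range(n_rows)]
        table = per_aa_conservation(annotate_msa(msa, profiles), msa)
        assert table.loc["R", "mean_scs"] > table.loc["R", "overall_mean"]
        assert bool(table.loc["R", "significant"])

    def test_empty_disordered_set_gives_empty_table(self):
        msa = MSA(["a", "b"], ["AC", "AC"])
        profiles = [DisorderProfile(x, [0.1, 0.1]) for x in "ab"]
        table = per_aa_conservation(annotate_msa(msa, profiles), msa)
        assert table.empty


class TestDisorderFractionSummary:
    def test_single_group_mean(self):
        from discons.io_formats import SequenceRecord
        records = [SequenceRecord("a", "AA", binding_class="rna"),
                   SequenceRecord("b", "AA", binding_class="rna")]
        profiles = [DisorderProfile("a", [0.9, 0.1]), DisorderProfile("b", [0.1, 0.1])]
        # fractions 0.5 and 0.0 -> mean 0.25; and the 0.1/0.3 -> 0.2 case
        table = disorder_fraction_summary(records, profiles)
        assert table.loc[0, "mean"] == pytest.approx(0.25)
        profiles2 = [DisorderProfile("a", [0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]),
                     DisorderProfile("b", [0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])]
        table2 = disorder_fraction_summary(records, profiles2)
        assert table2.loc[0, "mean"] == pytest.approx(0.2)

    def test_disjoint_groups_ordered(self):
        from discons.io_formats import SequenceRecord
        records = ([SequenceRecord(f"l{i}", "AA", binding_class="reference") for i in range(3)]
                   + [SequenceRecord(f"h{i}", "AA", binding_class="rna") for i in range(3)])
        profiles = ([DisorderProfile(f"l{i}", [0.1, 0.1]) for i in range(3)]
                    + [DisorderProfile(f"h{i}", [0.9, 0.9]) for i in range(3)])
        table = disorder_fraction_summary(records, profiles).set_index("binding_class")
        assert table.loc["rna", "mean"] > table.loc["reference", "mean"]

    def test_generator_target_recovered(self):
        records = generate_sequence_set(200, target_disorder_fraction=0.30,
                                        length=150, seed=9)
        predictor = PairwiseEnergyPredictor()
        from discons.disorder import disorder_fraction
        fractions = [
            disorder_fraction(predict_disorder(r.sequence, predictor)) for r in records
        ]
        assert np.mean(fractions) == pytest.approx(0.30, abs=0.03)
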