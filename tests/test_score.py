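import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sexcpm import datasets, score
from sexcpm.types import ChromosomeMap, ConsistencyError, CountsMatrix, CpmMatrix

from conftest import cpm_from_frame, random_counts


class TestComputeCpm:
    def test_single_gene_is_one_million(self):
        m = CountsMatrix(pd.DataFrame({"S1": [10]}, index=["g1"]))
        assert score.compute_cpm(m).cpm.iloc[0, 0] == 1e6

    def test_two_gene_proportions(self):
        m = CountsMatrix(pd.DataFrame({"S1": [3, 1]}, index=["g1", "g2"]))
        cpm = score.compute_cpm(m).cpm["S1"]
        assert cpm.tolist() == [750000.0, 250000.0]

    def test_matches_brute_force_on_random_matrix(self):
        m = random_counts(seed=42)
        cpm = score.compute_cpm(m).cpm.to_numpy()
        raw = m.counts.to_numpy().astype(float)
        expected = raw / raw.sum(axis=0, keepdims=True) * 1e6
        np.testing.assert_allclose(cpm, expected, rtol=1e-12)

    def test_zero_library_names_sample(self):
        m = CountsMatrix(pd.DataFrame({"S1": [1], "EMPTY": [0]}, index=["g1"]))
        with pytest.raises(ConsistencyError, match="EMPTY"):
            score.compute_cpm(m)

    def test_summary_rows_optionally_enter_denominator(self, tmp_path):
        counts = pd.DataFrame({"S1": [9]}, index=["g1"])
        summary = pd.DataFrame({"S1": [1]}, index=["__no_feature"])
        m = CountsMatrix(counts, summary)
        assert score.compute_cpm(m).cpm.iloc[0, 0] == 1e6
        assert score.compute_cpm(m, include_summary_in_library=True).cpm.iloc[0, 0] == 9e5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_columns_sum_to_one_million(self, seed):
        cpm = score.compute_cpm(random_counts(seed)).cpm
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 1000))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, seed, factor):
        """Multiplying one sample's counts by a constant leaves its CPM unchanged."""
        m = random_counts(seed)
        scaled = m.counts.copy()
        scaled.iloc[:, 0] *= factor
        a = score.compute_cpm(m).cpm.iloc[:, 0]
        b = score.compute_cpm(CountsMatrix(scaled)).cpm.iloc[:, 0]
        np.testing.assert_allclose(a, b, rtol=1e-9)


def brute_force_discrepant(values, min_fold, min_high_cpm, min_group, eps=0.01):
    """Independent oracle: try every split point of the sorted values."""
    v = sorted(values)
    n = len(v)
    best = None
    for i in range(n - 1):
        gap = v[i + 1] - v[i]
        if best is None or gap > v[best + 1] - v[best]:
            best = i
    low, high = v[: best + 1], v[best + 1 :]
    return (
        len(low) >= min_group
        and len(high) >= min_group
        and high[0] >= min_high_cpm
        and high[0] / max(low[-1], eps) >= min_fold
    )


class TestSelectInformativeGenes:
    def test_reference_genes_all_selected(self, reference, reference_chrom_map):
        cpm, _, _ = reference
        sel = score.select_informative_genes(cpm, reference_chrom_map)
        assert sel.selected_gene_ids == list(datasets.Y_GENES)

    def test_bimodal_gene_selected_with_diagnostics(self):
        values = [0.0, 0.1, 0.7, 143.33, 150.0, 200.33]
        cpm = cpm_from_frame([values], ["DDX3Y"], [f"s{i}" for i in range(6)])
        sel = score.select_informative_genes(cpm, ChromosomeMap({"DDX3Y": "Y"}), min_group=2)
        assert sel.selected_gene_ids == ["DDX3Y"]
        diag = sel.diagnostics.loc["DDX3Y"]
        assert diag["low_max"] == 0.7 and diag["high_min"] == 143.33
        assert diag["n_low"] == 3 and diag["n_high"] == 3

    def test_constant_gene_not_selected(self):
        cpm = cpm_from_frame([[5.0] * 6], ["g"], [f"s{i}" for i in range(6)])
        sel = score.select_informative_genes(cpm, ChromosomeMap({"g": "Y"}))
        assert sel.selected_gene_ids == []

    def test_matches_brute_force_on_synthetic_panel(self):
        """Selection agrees gene-by-gene with an exhaustive split evaluation."""
        rng = np.random.default_rng(7)
        n = 20
        rows, ids, truth = [], [], []
        for i in range(10):  # true informative genes
            low = rng.uniform(0, 0.3, size=10)
            high = rng.uniform(50, 200, size=10)
            rows.append(np.concatenate([low, high]))
            ids.append(f"inf{i}")
            truth.append(f"inf{i}")
        for i in range(69):  # artifact-level noise genes
            rows.append(rng.uniform(0, 0.4, size=n))
            ids.append(f"noise{i}")
        cpm = cpm_from_frame(rows, ids, [f"s{j}" for j in range(n)])
        cm = ChromosomeMap({g: "Y" for g in ids})
        sel = score.select_informative_genes(cpm, cm)
        assert sel.selected_gene_ids == truth
        for gene in ids:
            expected = brute_force_discrepant(
                cpm.cpm.loc[gene], score.DEFAULT_MIN_FOLD, score.DEFAULT_MIN_HIGH_CPM, 2
            )
            assert bool(sel.diagnostics.loc[gene, "selected"]) == expected

    def test_no_target_genes_is_error(self):
        cpm = cpm_from_frame([[1.0] * 4], ["g"], list("abcd"))
        with pytest.raises(ConsistencyError, match="Y"):
            score.select_informative_genes(cpm, ChromosomeMap({"g": "1"}))

    def test_too_few_samples_is_error(self):
        cpm = cpm_from_frame([[1.0, 2.0]], ["g"], ["a", "b"])
        with pytest.raises(ConsistencyError, match="samples"):
            score.select_informative_genes(cpm, ChromosomeMap({"g": "Y"}))


class TestSigmaCpm:
    def test_published_male_row(self, reference):
        cpm, _, _ = reference
        sig = score.sigma_cpm(cpm, list(datasets.Y_GENES))
        assert round(sig["E1-25DA-M"], 2) == 486.84

    def test_all_zero_row(self, reference):
        cpm, _, _ = reference
        sig = score.sigma_cpm(cpm, list(datasets.Y_GENES))
        assert sig["E8-25DC-F"] == 0.0

    def test_empty_gene_list_is_zero_everywhere(self, reference):
        cpm, _, _ = reference
        sig = score.sigma_cpm(cpm, [])
        assert (sig == 0).all() and list(sig.index) == cpm.sample_ids

    def test_unknown_gene_named_in_error(self, reference):
        cpm, _, _ = reference
        with pytest.raises(ConsistencyError, match="NOT_A_GENE"):
            score.sigma_cpm(cpm, ["DDX3Y", "NOT_A_GENE"])


LABEL_RANK = {"female": 0, "undetermined": 1, "male": 2}


class TestClassify:
    @pytest.mark.parametrize(
        "sigma,label",
        [(486.84, "male"), (1.75, "female"), (200.0, "undetermined"),
         (400.0, "undetermined"), (2.0, "undetermined"), (400.01, "male"), (1.99, "female")],
    )
    def test_threshold_boundaries_are_strict(self, sigma, label):
        calls = score.classify(pd.Series([sigma], index=["S"]))
        assert calls.table.loc[0, "label"] == label

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            score.classify(pd.Series([1.0], index=["S"]), male_threshold=2, female_threshold=400)

    @given(
        st.floats(0, 1000, allow_nan=False),
        st.floats(0, 1000, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_sigma(self, a, b):
        """Raising ΣCPM never moves a label from male toward female."""
        lo, hi = sorted([a, b])
        calls = score.classify(pd.Series([lo, hi], index=["lo", "hi"]))
        ranks = [LABEL_RANK[l] for l in calls.table["label"]]
        assert ranks[0] <= ranks[1]


class TestSummarizeGroups:
    def test_reference_group_statistics(self, reference):
        cpm, _, _ = reference
        sig = score.sigma_cpm(cpm, list(datasets.Y_GENES))
        calls = score.classify(sig, n_genes_used=10)
        by_label = {s.label: s for s in score.summarize_groups(calls)}
        male, female = by_label["male"], by_label["female"]
        assert (male.n, round(male.mean, 2), round(male.sd, 2)) == (17, 499.08, 44.74)
        assert (round(male.min, 2), round(male.max, 2)) == (427.29, 573.09)
        assert (female.n, round(female.mean, 2), round(female.max, 2)) == (18, 0.38, 1.75)

    def test_singleton_group_has_no_sd(self):
        calls = score.classify(pd.Series([500.0], index=["S"]), n_genes_used=1)
        (summary,) = score.summarize_groups(calls)
        assert summary.sd is None
        assert summary.mean == summary.min == summary.max == 500.0

    def test_absent_labels_omitted(self):
        calls = score.classify(pd.Series([500.0, 600.0], index=["a", "b"]))
        assert [s.label for s in score.summarize_groups(calls)] == ["male"]
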