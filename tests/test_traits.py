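"""Trait assembly: collapsing, log relative abundance, diversity, PCoA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microscan.traits import (
    RANKS,
    TaxonCountTable,
    assemble_initial_traits,
    collapse_to_level,
    log_relative_abundance,
    parse_lineages,
    pcoa_axes,
    richness,
    shannon_index,
)


def _lineage(rows: dict[str, str]) -> pd.DataFrame:
    return parse_lineages(pd.Series(rows))


@pytest.fixture
def toy_table() -> TaxonCountTable:
    counts = pd.DataFrame(
        {
            "otu1": [5, 2],
            "otu2": [7, 1],
            "otu3": [3, 4],
            "otu4": [2, 8],
        },
        index=["s1", "s2"],
    )
    lineage = _lineage(
        {
            "otu1": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia",
            "otu2": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__",
            "otu3": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__;g__",
            "otu4": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides",
        }
    )
    return TaxonCountTable(counts=counts, lineage=lineage)


class TestCollapse:
    def test_class_counts_are_additive(self, toy_table):
        collapsed = collapse_to_level(toy_table, "class")
        assert collapsed.counts.loc["s1", "Clostridia"] == 5 + 7 + 3
        assert collapsed.counts.loc["s1", "Bacteroidia"] == 2

    def test_incomplete_assignment_excluded_at_family(self, toy_table):
        collapsed = collapse_to_level(toy_table, "family")
        assert set(collapsed.counts.columns) == {
            "Lachnospiraceae", "Ruminococcaceae", "Bacteroidaceae"
        }

    def test_collapsed_depth_never_exceeds_original(self, toy_table):
        for level in ("class", "family"):
            collapsed = collapse_to_level(toy_table, level)
            assert (collapsed.depth <= toy_table.depth).all()
        # nothing unassigned at class level in the toy table: equality
        assert (collapse_to_level(toy_table, "class").depth == toy_table.depth).all()

    def test_unknown_rank_rejected(self, toy_table):
        with pytest.raises(ValueError):
            collapse_to_level(toy_table, "species")


class TestLogRelativeAbundance:
    def test_single_taxon_gives_log_one(self):
        counts = pd.DataFrame({"t": [10, 50]}, index=["s1", "s2"])
        out = log_relative_abundance(counts, pseudocount=0.0)
        assert np.allclose(out, 0.0)

    def test_symmetric_counts_without_pseudocount(self):
        counts = pd.DataFrame({"a": [50], "b": [50]})
        out = log_relative_abundance(counts, pseudocount=0.0)
        assert np.allclose(out, np.log(0.5))

    def test_zero_count_with_pseudocount(self):
        counts = pd.DataFrame({"a": [0], "b": [100]})
        out = log_relative_abundance(counts, pseudocount=0.5)
        assert out.loc[0, "a"] == pytest.approx(np.log(0.5 / 101))

    def test_zero_depth_sample_named_in_error(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [5, 0]}, index=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            log_relative_abundance(counts)

    def test_adjusted_relative_abundances_sum_to_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 200, (5, 8)).astype(float))
        counts.iloc[:, 0] += 1  # keep depths positive
        out = np.exp(log_relative_abundance(counts, pseudocount=0.5))
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_monotone_in_count_at_fixed_depth(self):
        counts = pd.DataFrame({"a": [10], "b": [20], "c": [70]})
        out = log_relative_abundance(counts)
        assert out.loc[0, "a"] < out.loc[0, "b"] < out.loc[0, "c"]


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [([5], 0.0), ([1, 1, 1, 1], 2.0), ([2, 1, 1], 1.5)],
    )
    def test_shannon_known_values(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-12)

    def test_shannon_rejects_empty(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0, 0])

    @given(st.integers(2, 10), st.integers(1, 50))
    @settings(deadline=None, max_examples=40)
    def test_uniform_maximizes_shannon_at_fixed_richness(self, k, scale):
        rng = np.random.default_rng(k * 100 + scale)
        skewed = rng.integers(1, 50, k).astype(float)
        uniform = np.full(k, float(scale))
        assert shannon_index(uniform) >= shannon_index(skewed) - 1e-12
        assert shannon_index(uniform) == pytest.approx(np.log2(k))

    @pytest.mark.parametrize("counts, expected", [([0, 0, 0], 0), ([1, 0, 3], 2)])
    def test_richness(self, counts, expected):
        assert richness(counts) == expected

    def test_richness_invariant_to_extra_reads(self):
        assert richness([1, 0, 3]) == richness([5, 0, 30])


class TestPCoA:
    def test_line_geometry_recovered(self):
        pts = np.array([0.0, 1.0, 3.0, 6.0])
        D = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]), index=list("abcd"), columns=list("abcd"))
        axes = pcoa_axes(D, k=2)
        r = np.corrcoef(axes.iloc[:, 0], pts)[0, 1]
        assert abs(r) > 0.999

    def test_axes_orthogonal_and_eigenvalues_sorted(self, rng):
        X = rng.normal(size=(12, 4))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        axes = pcoa_axes(pd.DataFrame(D), k=4)
        G = axes.to_numpy().T @ axes.to_numpy()
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        eig = axes.attrs["eigenvalues"]
        assert (np.diff(eig) <= 1e-9).all()

    def test_euclidean_distances_reconstructed(self, rng):
        X = rng.normal(size=(10, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        axes = pcoa_axes(pd.DataFrame(D), k=9).to_numpy()
        recon = np.linalg.norm(axes[:, None] - axes[None, :], axis=2)
        assert np.allclose(recon, D, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            pcoa_axes(bad, k=1)

    def test_nonzero_diagonal_rejected(self):
        bad = pd.DataFrame([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            pcoa_axes(bad, k=1)

    def test_all_zero_distances_degenerate(self):
        D = pd.DataFrame(np.zeros((3, 3)))
        axes = pcoa_axes(D, k=2)
        assert np.allclose(axes, 0.0)


class TestAssembly:
    def _counts_table(self, rng, n_classes=10, families_per_class=4, n_samples=8):
        taxa, lineages = [], {}
        for c in range(n_classes):
            for f in range(families_per_class):
                name = f"otu_c{c}_f{f}"
                taxa.append(name)
                lineages[name] = (
                    f"k__Bacteria;p__P{c % 3};c__Class{c};o__Order{c};f__Fam{c}_{f};g__"
                )
        counts = pd.DataFrame(
            rng.integers(1, 100, (n_samples, len(taxa))),
            index=[f"s{i}" for i in range(n_samples)],
            columns=taxa,
        )
        return TaxonCountTable(counts=counts, lineage=_lineage(lineages))

    def _distance(self, rng, n_samples=8):
        X = rng.normal(size=(n_samples, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        return pd.DataFrame(D, index=[f"s{i}" for i in range(n_samples)],
                            columns=[f"s{i}" for i in range(n_samples)])

    def test_expected_trait_count(self, rng):
        table = self._counts_table(rng)
        alpha = pd.DataFrame(
            rng.normal(size=(8, 3)),
            index=table.counts.index, columns=["shannon", "pd", "richness"],
        )
        dms = {"wunifrac": self._distance(rng), "unifrac": self._distance(rng)}
        traits = assemble_initial_traits(table, alpha, dms, n_axes=6)
        # 40 families + 10 classes + 3 alpha + 12 beta axes
        assert traits.shape[1] == 40 + 10 + 3 + 12
        kinds = traits.attrs["trait_metadata"]["kind"].value_counts()
        assert kinds["taxon_family"] == 40
        assert kinds["beta_axis"] == 12

    def test_two_alpha_columns_accepted_with_warning(self, rng):
        table = self._counts_table(rng, n_classes=2, families_per_class=2)
        alpha = pd.DataFrame(rng.normal(size=(8, 2)), index=table.counts.index,
                             columns=["shannon", "richness"])
        with pytest.warns(UserWarning, match="alpha"):
            traits = assemble_initial_traits(table, alpha, None)
        assert "alpha:shannon" in traits.columns

    def test_sample_index_mismatch_rejected(self, rng):
        table = self._counts_table(rng, n_classes=2, families_per_class=2)
        alpha = pd.DataFrame(rng.normal(size=(3, 3)), index=["x1", "x2", "x3"])
        with pytest.raises(ValueError, match="index"):
            assemble_initial_traits(table, alpha, None)

    def test_duplicate_trait_name_rejected(self, rng):
        table = self._counts_table(rng, n_classes=2, families_per_class=2)
        alpha = pd.DataFrame(
            rng.normal(size=(8, 2)), index=table.counts.index,
            columns=["shannon", "shannon"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            with pytest.warns(UserWarning):
                assemble_initial_traits(table, alpha, None)


def test_lineage_parser_strips_prefixes():
    df = _lineage({"t": "k__Bacteria; p__Firmicutes;c__Clostridia"})
    assert df.loc["t", "kingdom"] == "Bacteria"
    assert df.loc["t", "class"] == "Clostridia"
    assert df.loc["t", "family"] == ""
    assert list(df.columns) == RANKS
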