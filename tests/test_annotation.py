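"""Region assignment windows, CGI criteria, categories and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methvc import annotation as ann


@pytest.fixture
def genes():
    # one forward gene with TSS at 100,000 and 3' end at 150,000
    return pd.DataFrame(
        {"gene_id": ["g1"], "chrom": ["chr1"], "strand": ["+"],
         "tss": [100_000], "end": [150_000]}
    )


@pytest.fixture
def genes_minus():
    # reverse-strand gene: TSS 150,000, 3' end 100,000
    return pd.DataFrame(
        {"gene_id": ["g1"], "chrom": ["chr1"], "strand": ["-"],
         "tss": [150_000], "end": [100_000]}
    )


class TestGeneRegions:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (98_000, "distal_promoter"),        # 2 kb upstream
            (100_100, "proximal_promoter"),     # 100 bp downstream of TSS
            (98_500, "proximal_promoter"),      # exactly -1.5 kb: promoter-proximal wins
            (90_000, "distal_promoter"),        # exactly -10 kb
            (89_999, "intergenic"),             # just beyond -10 kb
            (100_500, "proximal_promoter"),     # exactly +500
            (100_501, "gene_body"),
            (150_000, "gene_body"),             # 3' end
            (152_000, "downstream"),
            (155_000, "downstream"),            # exactly +5 kb past end
            (155_001, "intergenic"),
            (200_000, "intergenic"),            # 50 kb away
        ],
    )
    def test_forward_strand_windows(self, genes, pos, expected):
        assert ann.assign_gene_region("chr1", pos, genes) == expected

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (152_000, "distal_promoter"),       # 2 kb upstream of reverse TSS
            (149_900, "proximal_promoter"),
            (120_000, "gene_body"),
            (98_000, "downstream"),
        ],
    )
    def test_reverse_strand_windows(self, genes_minus, pos, expected):
        assert ann.assign_gene_region("chr1", pos, genes_minus) == expected

    def test_nearest_tss_tie_lower_gene_id(self):
        two = pd.DataFrame(
            {"gene_id": ["gB", "gA"], "chrom": ["chr1", "chr1"],
             "strand": ["+", "-"], "tss": [90_000, 110_000],
             "end": [91_000, 105_000]}
        )
        # 100,000 is equidistant from both TSSs; gA (lower id) governs and
        # places the site in its downstream window, while gB would label it
        # intergenic (beyond gB's end + 5 kb).
        assert ann.assign_gene_region("chr1", 100_000, two) == "downstream"

    def test_missing_chromosome_intergenic_with_warning(self, genes):
        with pytest.warns(UserWarning):
            assert ann.assign_gene_region("chr9", 1_000, genes) == "intergenic"


class TestCgiRegions:
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [51_000]})

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (50_500, "island"),
            (50_000, "island"),
            (48_500, "shore"),      # 1,500 bp from the edge
            (49_999, "shore"),
            (53_000, "shore"),      # exactly 2,000 bp from the edge
            (53_001, "shelf"),      # 2,000 < d <= 4,000
            (55_000, "shelf"),      # exactly 4,000 from the edge
            (55_001, "non_cgi"),    # 4,001 bp: beyond the shelf
            (40_000, "non_cgi"),
        ],
    )
    def test_flank_widths(self, pos, expected):
        assert ann.assign_cgi_region("chr1", pos, self.cgis) == expected


class TestCgiCriteria:
    def test_cg_repeat_is_island(self):
        is_cgi, metrics = ann.check_cgi_criteria("CG" * 125)
        assert is_cgi
        assert metrics["gc_fraction"] == 1.0
        assert metrics["obs_exp_cpg"] == pytest.approx(2.0)
        assert metrics["length"] == 250

    def test_at_sequence_fails_gc(self):
        is_cgi, metrics = ann.check_cgi_criteria("A" * 300)
        assert not is_cgi and metrics["gc_fraction"] == 0.0

    def test_short_sequence_fails_length(self):
        is_cgi, _ = ann.check_cgi_criteria("CG" * 75)  # 150 bp
        assert not is_cgi

    def test_strict_thresholds(self):
        # exactly GC = 50% fails the strict inequality
        seq = "CATG" * 100  # length 400, gc 0.5
        is_cgi, metrics = ann.check_cgi_criteria(seq)
        assert metrics["gc_fraction"] == 0.5 and not is_cgi

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            ann.check_cgi_criteria("ACGTN")


class TestCategories:
    def test_threshold_edges(self):
        cat = pd.DataFrame(
            {"site_id": ["a", "b", "c", "d"],
             "h2": [0.5, 0.19, 0.3, np.nan],
             "sd_beta": [0.03, 0.031, 0.02, 0.05],
             "longitudinal_r": [0.5, 0.1, 0.3, 0.2]}
        )
        flags = ann.categorize_sites(cat)
        assert flags.loc[0, "high_h2"]            # h2 >= 0.5 inclusive
        assert not flags.loc[0, "low_h2"]
        assert flags.loc[1, "low_h2"]             # h2 < 0.2
        assert not flags.loc[0, "variable"]       # sd 0.03 strict
        assert flags.loc[1, "variable"]
        assert flags.loc[0, "longitudinally_stable"]   # r >= 0.5
        assert flags.loc[1, "longitudinally_unstable"]
        assert not flags.loc[3, "high_h2"]        # NaN never flagged

    def test_high_low_mutually_exclusive(self):
        rng = np.random.default_rng(0)
        cat = pd.DataFrame({"site_id": [f"s{i}" for i in range(100)],
                            "h2": rng.uniform(0, 1, 100)})
        flags = ann.categorize_sites(cat)
        assert not (flags["high_h2"] & flags["low_h2"]).any()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            ann.categorize_sites(pd.DataFrame({"site_id": ["a"]}))


class TestEnrichment:
    def make_annotation(self, labels):
        return pd.DataFrame(
            {"site_id": [f"s{i}" for i in range(len(labels))],
             "gene_region": pd.Categorical(labels, categories=sorted(set(labels)))}
        )

    def test_identical_proportions_null(self):
        labels = ["a"] * 20 + ["b"] * 20
        annotation = self.make_annotation(labels)
        category = [f"s{i}" for i in range(0, 40, 2)]  # half of each class
        out = ann.enrichment_test(category, annotation["site_id"], annotation)
        assert (out["chi2"].abs() < 1e-10).all()

    def test_hand_computed_table(self):
        # 2x2 table [[20,10],[10,20]]: chi2 = 6.667, p = 0.00983
        labels = ["x"] * 30 + ["y"] * 30
        annotation = self.make_annotation(labels)
        category = [f"s{i}" for i in range(20)] + [f"s{i}" for i in range(30, 40)]
        out = ann.enrichment_test(category, annotation["site_id"], annotation)
        row = out[out["class"] == "x"].iloc[0]
        assert row["chi2"] == pytest.approx(20 / 3, abs=1e-10)
        assert row["p"] == pytest.approx(0.00983, abs=5e-5)
        assert row["direction"] == "enriched"

    def test_matches_brute_force_contingency(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(["a", "b", "c"], size=100)
        annotation = self.make_annotation(list(labels))
        category = list(annotation["site_id"].sample(40, random_state=2))
        out = ann.enrichment_test(category, annotation["site_id"], annotation)
        for _, row in out.iterrows():
            in_cat = annotation["site_id"].isin(category).to_numpy()
            in_cls = (annotation["gene_region"] == row["class"]).to_numpy()
            table = np.array(
                [[(in_cat & in_cls).sum(), (in_cat & ~in_cls).sum()],
                 [(~in_cat & in_cls).sum(), (~in_cat & ~in_cls).sum()]]
            )
            expected = stats.chi2_contingency(table, correction=False)[0]
            assert row["chi2"] == pytest.approx(expected, abs=1e-10)

    def test_bonferroni_family(self):
        # p = 1e-5 < 0.05/117 -> significant; p = 1e-3 is not
        assert 1e-5 < 0.05 / 117
        labels = ["x"] * 30 + ["y"] * 30
        annotation = self.make_annotation(labels)
        category = [f"s{i}" for i in range(25)] + [f"s{i}" for i in range(30, 35)]
        out = ann.enrichment_test(category, annotation["site_id"], annotation,
                                  family_size=117)
        row = out[out["class"] == "x"].iloc[0]
        assert row["significant"] == (row["p"] < 0.05 / 117)

    def test_empty_category_rejected(self):
        annotation = self.make_annotation(["a", "b"])
        with pytest.raises(ValueError):
            ann.enrichment_test([], annotation["site_id"], annotation)

    def test_category_outside_background_rejected(self):
        annotation = self.make_annotation(["a", "b"])
        with pytest.raises(ValueError):
            ann.enrichment_test(["zzz"], annotation["site_id"], annotation)


class TestAnnotateSites:
    def test_exhaustive_exclusive_labels(self):
        from methvc.simulate import simulate_annotation

        sites, genes, cgis = simulate_annotation(200, seed=3)
        out = ann.annotate_sites(sites, genes, cgis)
        assert out["gene_region"].notna().all()
        assert out["cgi_region"].notna().all()
        assert set(out["gene_region"].unique()) <= set(ann.GENE_REGIONS)
        assert set(out["cgi_region"].unique()) <= set(ann.CGI_REGIONS)
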