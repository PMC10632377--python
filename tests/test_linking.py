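"""Regulatory domains, peak filters, region-gene association and enrichment."""

import warnings

from math import comb

import numpy as np
import pandas as pd
import pytest

from chromdyn.clustering import kmeans_cluster
from chromdyn.intervals import GenomicInterval, GenomicIntervalSet
from chromdyn.linking import (
    GeneModel,
    RegulatoryDomain,
    associate_regions,
    build_domains,
    cluster_expression_summary,
    peak_anova,
    read_gene_models,
    read_gmt,
    region_log2fc_filter,
    term_enrichment,
)

from conftest import make_matrix

GENOME = {"chr1": 100_000}


class TestBuildDomains:
    def test_single_plus_gene(self):
        doms = build_domains([GeneModel("g1", "chr1", 50_000, "+")], GENOME)
        d = doms[0]
        assert (d.basal.start, d.basal.end) == (45_000, 51_000)
        assert (d.extended.start, d.extended.end) == (0, 100_000)

    def test_extension_stops_at_neighbor_basal(self):
        genes = [GeneModel("g1", "chr1", 10_000, "+"), GeneModel("g2", "chr1", 20_000, "+")]
        doms = {d.gene_id: d for d in build_domains(genes, GENOME)}
        assert doms["g1"].extended.end == 15_000  # g2's basal left boundary
        assert doms["g2"].extended.start == 11_000  # g1's basal right boundary

    def test_minus_strand_mirrors_basal(self):
        doms = build_domains([GeneModel("g1", "chr1", 50_000, "-")], GENOME)
        assert (doms[0].basal.start, doms[0].basal.end) == (49_000, 55_000)

    def test_extension_capped_at_max_ext(self):
        genome = {"chr1": 5_000_000}
        doms = build_domains([GeneModel("g1", "chr1", 2_500_000, "+")], genome)
        assert doms[0].extended.start == 1_500_000
        assert doms[0].extended.end == 3_500_000

    def test_overlapping_basal_domains_keep_own_basal(self):
        # neighbors 2 kb apart: basal windows overlap, extension never shrinks
        genes = [GeneModel("g1", "chr1", 10_000, "+"), GeneModel("g2", "chr1", 12_000, "+")]
        doms = {d.gene_id: d for d in build_domains(genes, GENOME)}
        assert doms["g1"].extended.end >= doms["g1"].basal.end
        assert doms["g2"].extended.start <= doms["g2"].basal.start

    def test_tss_outside_chromosome_errors(self):
        with pytest.raises(ValueError, match="outside"):
            build_domains([GeneModel("g1", "chr1", 200_000, "+")], GENOME)

    def test_adjacent_extension_boundaries_from_random_layouts(self):
        rng = np.random.default_rng(0)
        tss = np.sort(rng.choice(np.arange(10_000, 90_000), size=12, replace=False))
        genes = [
            GeneModel(f"g{i}", "chr1", int(t), "+" if rng.random() < 0.5 else "-")
            for i, t in enumerate(tss)
        ]
        doms = {d.gene_id: d for d in build_domains(genes, GENOME)}
        ordered = [doms[g.gene_id] for g in genes]  # genes already tss-sorted
        for left, right in zip(ordered, ordered[1:]):
            # extension stops at the neighbor's basal boundary (no shrink below
            # a gene's own basal domain when basal windows already overlap)
            assert left.extended.end <= max(right.basal.start, left.basal.end)
            assert right.extended.start >= min(left.basal.end, right.basal.start)


class TestRegionFilters:
    def _fpkm(self, rows):
        conds = ["invitro", "early", "late"]
        return make_matrix(rows, conditions=conds)

    def test_log2fc_filter_cases(self):
        m = self._fpkm([[1, 4, 1], [1, 1, 1], [0, 3, 0]])
        kept = region_log2fc_filter(m, min_lfc=1.0, pseudocount=1.0)
        # log2(5/2)=1.32 keeps p0; p1 flat; p2 kept via pseudocount log2(4/1)=2
        assert kept == ["p0", "p2"]

    def test_anova_equal_group_means(self):
        m = make_matrix(
            [[1, 2, 1, 2, 1, 2]],
            conditions=["invitro"] * 2 + ["early"] * 2 + ["late"] * 2,
        )
        res = peak_anova(m)
        assert res["F"].iloc[0] == 0 and res["p"].iloc[0] == 1

    def test_anova_zero_within_variance_sentinel(self):
        m = make_matrix(
            [[0, 0, 0, 0, 10, 10]],
            conditions=["invitro"] * 2 + ["early"] * 2 + ["late"] * 2,
        )
        res = peak_anova(m)
        assert res["p"].iloc[0] == 0 and np.isinf(res["F"].iloc[0])

    def test_anova_worked_example(self):
        # groups {1,2,3},{2,3,4},{6,7,8}: SSB=42 (df 2), SSW=6 (df 6) -> F=21
        # p has the closed form (d2/(d2+d1*F))^(d2/2) = (6/48)^3 = 1/512
        m = make_matrix(
            [[1, 2, 3, 2, 3, 4, 6, 7, 8]],
            conditions=["invitro"] * 3 + ["early"] * 3 + ["late"] * 3,
        )
        res = peak_anova(m)
        assert res["F"].iloc[0] == pytest.approx(21.0, abs=1e-9)
        assert res["p"].iloc[0] == pytest.approx(1 / 512, abs=1e-9)


class TestAssociateRegions:
    def test_multi_domain_assignment(self):
        regions = GenomicIntervalSet([GenomicInterval("chr1", 95, 105, id="r1")])
        doms = [
            RegulatoryDomain("g1", GenomicInterval("chr1", 90, 110, id="g1"),
                             GenomicInterval("chr1", 0, 150, id="g1")),
            RegulatoryDomain("g2", GenomicInterval("chr1", 95, 120, id="g2"),
                             GenomicInterval("chr1", 50, 200, id="g2")),
        ]
        pairs = associate_regions(regions, doms)
        assert sorted(pairs["gene_id"]) == ["g1", "g2"]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        regions = GenomicIntervalSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 100, id=f"r{i}")
                for i, s in enumerate(rng.integers(0, 99_000, 200))
            ]
        )
        doms = []
        for i, s in enumerate(rng.integers(0, 95_000, 30)):
            b = GenomicInterval("chr1", int(s), int(s) + 2_000, id=f"g{i}")
            e = GenomicInterval("chr1", max(0, int(s) - 3_000), int(s) + 5_000, id=f"g{i}")
            doms.append(RegulatoryDomain(f"g{i}", b, e))
        pairs = associate_regions(regions, doms)
        got = pairs.groupby("region_id")["gene_id"].apply(sorted).to_dict()
        for r in regions:
            expect = sorted(
                d.gene_id for d in doms
                if d.extended.start <= r.midpoint < d.extended.end
            )
            assert got.get(r.id, []) == expect


class TestExpressionSummary:
    def _clusters(self):
        prof = pd.DataFrame(
            [[-1.0, 1.0, 0.0], [1.0, -1.0, 0.0]],
            index=["pk1", "pk2"],
            columns=["invitro", "early", "late"],
        )
        return kmeans_cluster(prof, k=2, seed=0, n_init=2, compute_silhouette=False)

    def test_single_gene_profile_is_the_median(self):
        clusters = self._clusters()
        expr = make_matrix([[1, 2, 4]], conditions=["invitro", "early", "late"])
        expr.values.index = ["gene1"]
        pairs = pd.DataFrame({"region_id": ["pk1"], "gene_id": ["gene1"]})
        out = cluster_expression_summary(clusters, pairs, expr)
        cl = clusters.labels["pk1"]
        sub = out[(out.cluster == cl)].set_index("condition")
        z = (np.array([1, 2, 4]) - 7 / 3) / np.std([1, 2, 4], ddof=1)
        for cond, zv in zip(["invitro", "early", "late"], z):
            assert sub.loc[cond, "median"] == pytest.approx(zv)
            assert sub.loc[cond, "n"] == 1

    def test_gene_linked_twice_counted_once(self):
        clusters = self._clusters()
        expr = make_matrix([[1, 2, 4]], conditions=["invitro", "early", "late"])
        expr.values.index = ["gene1"]
        pairs = pd.DataFrame(
            {"region_id": ["pk1", "pk2"], "gene_id": ["gene1", "gene1"]}
        )
        out = cluster_expression_summary(clusters, pairs, expr)
        assert out["n"].max() == 1

    def test_empty_cluster_flagged_not_error(self):
        clusters = self._clusters()
        expr = make_matrix([[1, 2, 4]], conditions=["invitro", "early", "late"])
        expr.values.index = ["gene1"]
        pairs = pd.DataFrame({"region_id": [], "gene_id": []})
        out = cluster_expression_summary(clusters, pairs, expr)
        assert out["empty"].all() and out["n"].eq(0).all()


class TestTermEnrichment:
    def _setup(self):
        genome = {"chr1": 1_000}
        # one "domain" covering exactly half the genome -> p_term = 0.5
        doms = [
            RegulatoryDomain(
                "g1",
                GenomicInterval("chr1", 0, 500, id="g1"),
                GenomicInterval("chr1", 0, 500, id="g1"),
            )
        ]
        return genome, doms

    def test_binomial_closed_form(self):
        genome, doms = self._setup()
        regions = GenomicIntervalSet(
            [GenomicInterval("chr1", 10, 20, id="r1"), GenomicInterval("chr1", 30, 40, id="r2")]
        )
        out = term_enrichment(regions, doms, {"T": ["g1"]}, genome)
        assert out.loc[0, "x"] == 2 and out.loc[0, "n"] == 2
        assert out.loc[0, "p_binom"] == pytest.approx(0.25, abs=1e-12)

    def test_binomial_zero_hits_p_one(self):
        genome, doms = self._setup()
        regions = GenomicIntervalSet(
            [GenomicInterval("chr1", 600, 610, id="r1"), GenomicInterval("chr1", 700, 710, id="r2")]
        )
        out = term_enrichment(regions, doms, {"T": ["g1"]}, genome)
        assert out.loc[0, "p_binom"] == pytest.approx(1.0)

    def test_hypergeometric_closed_form(self):
        # population 20 genes, 5 in term, 4 drawn, 3 overlap
        genome = {"chr1": 100_000}
        doms, regions = [], []
        for i in range(20):
            start = i * 1_000
            iv = GenomicInterval("chr1", start, start + 500, id=f"g{i}")
            doms.append(RegulatoryDomain(f"g{i}", iv, iv))
        for i in [0, 1, 2, 10]:  # overlap = 3 with term {g0..g4}
            regions.append(GenomicInterval("chr1", i * 1_000 + 100, i * 1_000 + 200, id=f"r{i}"))
        out = term_enrichment(
            GenomicIntervalSet(regions), doms, {"T": [f"g{i}" for i in range(5)]}, genome
        )
        expect = (comb(5, 3) * comb(15, 1) + comb(5, 4) * comb(15, 0)) / comb(20, 4)
        assert out.loc[0, "p_hyper"] == pytest.approx(expect, abs=1e-12)

    def test_bh_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": 100_000}
        doms = []
        for i in range(50):
            iv = GenomicInterval("chr1", i * 2_000, i * 2_000 + int(rng.integers(200, 1_500)), id=f"g{i}")
            doms.append(RegulatoryDomain(f"g{i}", iv, iv))
        regions = GenomicIntervalSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 50, id=f"r{i}")
                for i, s in enumerate(rng.integers(0, 99_000, 60))
            ]
        )
        sets = {
            f"T{j}": [f"g{i}" for i in rng.choice(50, size=8, replace=False)]
            for j in range(10)
        }
        out = term_enrichment(regions, doms, sets, genome)
        assert (out["q_binom"] >= out["p_binom"] - 1e-12).all()
        srt = out.sort_values("p_binom")
        assert (np.diff(srt["q_binom"]) >= -1e-12).all()

    def test_unknown_gene_term_skipped_with_warning(self):
        genome, doms = self._setup()
        regions = GenomicIntervalSet([GenomicInterval("chr1", 10, 20, id="r1")])
        with pytest.warns(UserWarning, match="skipped"):
            out = term_enrichment(regions, doms, {"BAD": ["nope"], "T": ["g1"]}, genome)
        assert list(out["term"]) == ["T"]


class TestReaders:
    def test_gene_model_roundtrip_and_duplicates(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tchrom\ttss\tstrand\ng1\tchr1\t100\t+\ng2\tchr1\t500\t-\n")
        genes = read_gene_models(p)
        assert [g.gene_id for g in genes] == ["g1", "g2"] and genes[1].strand == "-"
        p.write_text("gene_id\tchrom\ttss\tstrand\ng1\tchr1\t100\t+\ng1\tchr1\t500\t-\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_models(p)

    def test_gmt_parse(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tdesc\tg1\tg2\nT2\tdesc\tg3\n")
        sets = read_gmt(p)
        assert sets == {"T1": ["g1", "g2"], "T2": ["g3"]}
        p.write_text("T1\tonly-description\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(p)
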