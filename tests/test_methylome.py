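"""Methylome statistics: weighted levels, distributions, symmetry, metaplots,
TE enrichment, DMRs, expression coupling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from temeth import methylome
from temeth.calling import MethylomeTable
from temeth.methylome import FeatureSet


def _table(rows):
    df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "context",
                                     "dinuc", "mc", "total",
                                     "opposite_g_fraction", "opposite_cov"])
    return MethylomeTable(df)


def _cg_row(pos, mc, total, strand="+", contig="c"):
    return (contig, pos, strand, "CG", "G", mc, total, 1.0, 10)


class TestGlobalLevels:
    def test_pooled_ratio_not_site_average(self):
        table = _table([_cg_row(3, 3, 10), _cg_row(9, 7, 10)])
        assert methylome.global_levels(table)["CG"] == pytest.approx(0.5)

    def test_zero_coverage_group_is_missing(self):
        table = _table([_cg_row(3, 0, 0)])
        levels = methylome.global_levels(table)
        assert np.isnan(levels["CG"]) and np.isnan(levels["CHH"])

    def test_ch_unions_chg_and_chh(self):
        table = _table([
            ("c", 3, "+", "CHG", "A", 2, 10, 1.0, 5),
            ("c", 8, "+", "CHH", "T", 4, 10, 1.0, 5),
        ])
        levels = methylome.global_levels(table)
        assert levels["CH"] == pytest.approx(0.3)
        assert levels["CA"] == pytest.approx(0.2)
        assert levels["CT"] == pytest.approx(0.4)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            methylome.global_levels(_table([]))

    def test_per_contig_breakdown(self):
        table = _table([_cg_row(3, 9, 10, contig="genome"),
                        _cg_row(3, 1, 10, contig="episome")])
        per = methylome.global_levels(table, by_contig=True)
        assert per.loc["genome", "CG"] == pytest.approx(0.9)
        assert per.loc["episome", "CG"] == pytest.approx(0.1)

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 40)),
                    min_size=1, max_size=30))
    def test_pooled_equals_coverage_weighted_site_mean(self, pairs):
        rows = [_cg_row(2 + 10 * i, min(mc, tot), tot)
                for i, (mc, tot) in enumerate(pairs)]
        table = _table(rows)
        pooled = methylome.global_levels(table)["CG"]
        df = table.table
        weighted = np.average(df["mc"] / df["total"], weights=df["total"])
        assert pooled == pytest.approx(weighted)


class TestSiteLevelDistribution:
    def test_point_mass_at_one(self):
        table = _table([_cg_row(p, 10, 10) for p in range(2, 52, 10)])
        res = methylome.site_level_distribution(table, "CG", min_cov=10)
        assert res["zero_fraction"] == 0.0
        assert res["gt02_fraction"] == 1.0
        assert res["hist"][-1] == res["n_sites"]

    def test_min_cov_boundary_excludes_site(self):
        table = _table([_cg_row(2, 5, 9), _cg_row(12, 5, 10)])
        res = methylome.site_level_distribution(table, "CG", min_cov=10)
        assert res["n_sites"] == 1

    def test_zero_fraction_requires_exact_zero(self):
        table = _table([_cg_row(2, 0, 20), _cg_row(12, 1, 20)])
        res = methylome.site_level_distribution(table, "CG", min_cov=10)
        assert res["zero_fraction"] == 0.5

    def test_simulated_distribution_matches_truth_expectation(
            self, small_methylome):
        """Observed fully-unmethylated fraction agrees with the expectation
        implied by the truth p values, per-site coverage and the
        non-conversion rate."""
        res = small_methylome
        cfg = res["config"]
        df = res["table"].table
        cg = df[(df["contig"] == cfg.main_contig) & (df["context"] == "CG")
                & (df["total"] >= 10)]
        truth = res["truth"].table
        tcg = truth[(truth["contig"] == cfg.main_contig)
                    & (truth["context"] == "CG")]
        lut = {(p, s): v for p, s, v in
               zip(tcg["pos"], tcg["strand"], tcg["p"])}
        p = np.array([lut[(r.pos, r.strand)] for r in cg.itertuples()])
        n = cg["total"].to_numpy()
        expected = np.mean(((1 - p) * (1 - cfg.non_conversion)) ** n)
        observed = (cg["mc"] == 0).mean()
        assert observed == pytest.approx(expected, abs=0.01)
        obs = methylome.site_level_distribution(
            MethylomeTable(df[df["contig"] == cfg.main_contig]), "CG")
        assert obs["gt02_fraction"] > 0.8  # most sites medium-to-high


class TestReadLevels:
    def test_per_read_level_and_min_cg_boundary(self, tmp_path):
        genome = {"chr": "ACGACGACGACGACGT"}
        # 5 CG cytosines on + at 1-based 2,5,8,11,14; read calls C,C,T,C,C
        seq_5cg = "ACGACGATGACGACGT"
        sam = tmp_path / "r.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr\tLN:16\n"
            f"a\t0\tchr\t1\t60\t16M\t*\t0\t0\t{seq_5cg}\t{'I' * 16}\n"
            f"b\t0\tchr\t1\t60\t12M\t*\t0\t0\t{seq_5cg[:12]}\t{'I' * 12}\n")
        levels = methylome.read_level_distribution(str(sam), genome,
                                                   min_cg_per_read=5)
        assert levels.tolist() == [0.8]  # read b covers only 4 CGs


class TestSymmetry:
    def test_identical_strand_levels_give_r_one(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(30):
            mc = int(rng.integers(0, 21))
            rows.append(_cg_row(100 * i + 2, mc, 20, "+"))
            rows.append(_cg_row(100 * i + 3, mc, 20, "-"))
        res = methylome.symmetric_cg_concordance(_table(rows), min_cov=10)
        assert res["n_pairs"] == 30
        assert res["pearson"] == pytest.approx(1.0)

    def test_too_few_pairs_undefined(self):
        rows = [_cg_row(2, 5, 20, "+"), _cg_row(3, 5, 20, "-")]
        res = methylome.symmetric_cg_concordance(_table(rows), min_cov=10)
        assert np.isnan(res["pearson"])


class TestMetaplot:
    @staticmethod
    def _uniform_table(level=0.5, n=2000, total=20):
        mc = int(round(level * total))
        return _table([_cg_row(5 * i + 2, mc, total) for i in range(n)])

    def test_uniform_methylome_gives_flat_profile(self):
        table = self._uniform_table()
        feats = FeatureSet.from_dataframe(pd.DataFrame(
            [("c", 1000, 3000, "+", "gene", "g1", ".", 1.0),
             ("c", 4000, 7000, "+", "gene", "g2", ".", 1.0)],
            columns=["contig", "start", "end", "strand", "kind", "id",
                     "family", "tpm"]))
        prof = methylome.metaplot(table, feats, body_bins=10, flank_bp=500,
                                  flank_bins=5, contexts=("CG",))
        assert np.allclose(prof.mean["CG"], 0.5, atol=1e-9)

    def test_minus_strand_profile_is_flipped(self):
        # genomic gradient: level rises with coordinate
        rows = []
        for i in range(400):
            pos = 10 * i + 2
            level = i / 399
            rows.append(_cg_row(pos, int(round(level * 20)), 20))
        table = _table(rows)
        frame = pd.DataFrame(
            [("c", 500, 3500, s, "gene", f"g{s}", ".", 1.0)
             for s in ("+", "-")],
            columns=["contig", "start", "end", "strand", "kind", "id",
                     "family", "tpm"])
        plus = methylome.metaplot(table, FeatureSet(frame.iloc[[0]]),
                                  body_bins=10, flank_bp=0, flank_bins=0,
                                  contexts=("CG",)).mean["CG"]
        minus = methylome.metaplot(table, FeatureSet(frame.iloc[[1]]),
                                   body_bins=10, flank_bp=0, flank_bins=0,
                                   contexts=("CG",)).mean["CG"]
        assert plus[0] < plus[-1]
        assert minus[0] > minus[-1]
        assert np.allclose(plus, minus[::-1], atol=1e-9)

    def test_te_3prime_bias_rises_toward_tes(self, small_methylome):
        prof = small_methylome["te_profile"]
        body = prof.mean["CH"][prof.flank_bins:prof.flank_bins
                               + prof.body_bins]
        tail = body[-prof.body_bins // 4:]
        head = body[: prof.body_bins // 2]
        assert np.nanmean(tail) > 2.0 * np.nanmean(head)


class TestTE3PrimeEnrichment:
    @staticmethod
    def _te_table(tail_level, rest_level, start=0, end=4000, total=20):
        rows = []
        tail0 = end - (end - start) // 4
        for pos0 in range(start, end, 10):
            level = tail_level if pos0 >= tail0 else rest_level
            rows.append(("c", pos0 + 1, "+", "CHH", "T",
                         int(round(level * total)), total, 1.0, 10))
        return _table(rows)

    @staticmethod
    def _te_features(tpm):
        return FeatureSet.from_dataframe(pd.DataFrame(
            [("c", 0, 4000, "+", "TE", "te1", "fam", tpm)],
            columns=["contig", "start", "end", "strand", "kind", "id",
                     "family", "tpm"]))

    def test_biased_te_enriched(self):
        res = methylome.te_3prime_ch_enrichment(
            self._te_table(0.25, 0.05), self._te_features(2.0))
        assert res["classification"].tolist() == ["enriched"]

    def test_uniform_te_not_enriched(self):
        res = methylome.te_3prime_ch_enrichment(
            self._te_table(0.1, 0.1), self._te_features(2.0))
        assert res["classification"].tolist() == ["not_enriched"]

    def test_low_tpm_excluded_regardless_of_profile(self):
        res = methylome.te_3prime_ch_enrichment(
            self._te_table(0.25, 0.05), self._te_features(0.4))
        assert res["classification"].tolist() == ["insufficient"]


class TestDMR:
    # CG sites on a 150-bp grid, the typical spacing the 300-bp merge gap
    # is meant to bridge (one or two intervening sites)
    SPACING = 150

    @classmethod
    def _binomial_table(cls, p_by_site, total, rng):
        rows = []
        for i, p in enumerate(p_by_site):
            mc = int(rng.binomial(total, p))
            rows.append(_cg_row(cls.SPACING * i + 2, mc, total))
        return _table(rows)

    def test_identical_tables_give_no_dmrs(self):
        rng = np.random.default_rng(5)
        t = self._binomial_table(np.full(200, 0.7), 30, rng)
        assert methylome.find_dmrs(t, t) == []

    def test_planted_region_recovered(self):
        rng = np.random.default_rng(7)
        p_a = np.full(200, 0.7)
        p_b = p_a.copy()
        p_a[90:110] = 0.9
        p_b[90:110] = 0.5
        a = self._binomial_table(p_a, 30, rng)
        b = self._binomial_table(p_b, 30, rng)
        dmrs = methylome.find_dmrs(a, b)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        start_site = (d.start + 1 - 2) // self.SPACING
        end_site = (d.end - 2) // self.SPACING
        assert abs(start_site - 90) <= 2
        assert abs(end_site - 109) <= 2
        assert d.delta == pytest.approx(0.4, abs=0.1)
        assert d.p_value < 1e-10

    def test_null_false_positive_rate_controlled(self):
        """Across replicated null comparisons the region-level false-positive
        rate stays at or below the per-site threshold."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            p = rng.beta(2 * 0.7, 2 * 0.3, size=150)
            a = self._binomial_table(p, 20, rng)
            b = self._binomial_table(p, 20, rng)
            if methylome.find_dmrs(a, b):
                hits += 1
        assert hits <= 2


class TestExpressionCorrelation:
    def test_constant_methylation_undefined(self):
        r, n = methylome.expression_methylation_correlation(
            [0.5] * 10, np.arange(10))
        assert np.isnan(r) and n == 10

    def test_coupled_simulation_positive(self, rng):
        tpm = rng.lognormal(1, 1, size=300)
        levels = 0.5 + 0.3 * (np.argsort(np.argsort(tpm)) / 300) \
            + rng.normal(0, 0.05, 300)
        r, n = methylome.expression_methylation_correlation(levels, tpm)
        assert r > 0.3 and n == 300

    def test_decoupled_simulation_near_zero(self, rng):
        tpm = rng.lognormal(1, 1, size=600)
        levels = rng.uniform(0, 1, size=600)
        r, _ = methylome.expression_methylation_correlation(levels, tpm)
        assert abs(r) < 0.1
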