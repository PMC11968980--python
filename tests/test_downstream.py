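"""Association bookkeeping: thresholds, tallies, overlaps, coloc identities."""

import numpy as np
import pandas as pd
import pytest

import grexcontact as gc


class TestThresholds:
    @pytest.mark.parametrize(
        "n_tests,n_traits,expected",
        [
            (40_749, None, 1.2270e-6),
            (14_471, None, 3.4552e-6),
            (344_814, None, 1.4501e-7),
            (26_138, None, 1.9129e-6),
            (41_086, 4_671, 2.605e-10),
        ],
    )
    def test_published_twas_thresholds(self, n_tests, n_traits, expected):
        spec = gc.bonferroni_thresholds(0.05, n_tests, n_traits)
        assert spec.threshold == pytest.approx(expected, rel=1e-3)

    def test_single_test_keeps_alpha(self):
        assert gc.bonferroni_thresholds(0.05, 1).threshold == 0.05

    def test_monotone_decreasing_in_tests_and_traits(self):
        t = [gc.bonferroni_thresholds(0.05, n).threshold for n in (10, 100, 1000)]
        assert t[0] > t[1] > t[2]
        u = [gc.bonferroni_thresholds(0.05, 100, k).threshold for k in (2, 20, 200)]
        assert u[0] > u[1] > u[2]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            gc.bonferroni_thresholds(0.05, 0)


class TestGrexTraitAssociation:
    def test_null_phenotype_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        n, m = 400, 1000
        grex = pd.DataFrame(rng.normal(size=(n, m)),
                            columns=[f"t{i}" for i in range(m)])
        pheno = rng.normal(size=n)
        out = gc.associate_grex_with_trait(grex, pheno)
        frac = (out["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / m)
        assert abs(frac - 0.05) < 4 * se

    def test_true_signal_has_smallest_p(self):
        rng = np.random.default_rng(1)
        n = 500
        grex = pd.DataFrame(rng.normal(size=(n, 20)),
                            columns=[f"t{i}" for i in range(20)])
        pheno = grex["t7"].to_numpy() + 0.3 * rng.normal(size=n)
        out = gc.associate_grex_with_trait(grex, pheno)
        assert out.loc[out["p"].idxmin(), "transcript_id"] == "t7"

    def test_constant_grex_skipped(self):
        rng = np.random.default_rng(2)
        grex = pd.DataFrame({"t0": np.ones(50), "t1": rng.normal(size=50)})
        out = gc.associate_grex_with_trait(grex, rng.normal(size=50))
        assert bool(out.loc[out["transcript_id"] == "t0", "skipped"].iloc[0])

    def test_binary_phenotype_uses_logistic(self):
        rng = np.random.default_rng(3)
        n = 600
        g = rng.normal(size=n)
        p = 1 / (1 + np.exp(-2 * g))
        y = rng.binomial(1, p)
        grex = pd.DataFrame({"t0": g})
        out = gc.associate_grex_with_trait(grex, y.astype(float))
        assert out["p"].iloc[0] < 1e-6 and out["zscore"].iloc[0] > 0


class TestLocusClassification:
    def _loci(self):
        return pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(4)],
                "chrom": "chr1",
                "start": [0, 100, 200, 300],
                "end": [50, 150, 250, 350],
                "mhc": [False, False, False, True],
            }
        )

    def _hits(self, spans, p=1e-9):
        return pd.DataFrame(
            [{"transcript_id": f"h{i}", "chrom": "chr1", "start": s, "end": e, "p": p}
             for i, (s, e) in enumerate(spans)]
        )

    def test_single_erna_hit_labels_erna_only(self):
        out = gc.classify_gwas_loci(self._loci(), self._hits([(10, 20)]),
                                    self._hits([], ), 1e-6, 1e-7)
        assert out.set_index("locus_id")["label"]["L0"] == "eRNA-only"

    def test_empty_hits_all_neither(self):
        empty = self._hits([])
        out = gc.classify_gwas_loci(self._loci(), empty, empty, 1e-6, 1e-7)
        assert (out["label"] == "neither").all()

    def test_planted_assignment_matches_hand_enumeration(self):
        erna = self._hits([(10, 20), (210, 220)])
        gene = self._hits([(110, 120), (215, 230)])
        out = gc.classify_gwas_loci(self._loci(), erna, gene, 1e-6, 1e-7)
        labels = out.set_index("locus_id")["label"]
        assert labels["L0"] == "eRNA-only"
        assert labels["L1"] == "gene-only"
        assert labels["L2"] == "both"
        assert "L3" not in labels.index  # MHC excluded

    def test_labels_partition_locus_set(self):
        erna = self._hits([(10, 20)])
        gene = self._hits([(110, 120)])
        out = gc.classify_gwas_loci(self._loci(), erna, gene, 1e-6, 1e-7)
        assert len(out) == 3  # non-MHC loci
        assert out["label"].isin(["eRNA-only", "gene-only", "both", "neither"]).all()

    def test_nonsignificant_hits_ignored(self):
        erna = self._hits([(10, 20)], p=1e-3)
        out = gc.classify_gwas_loci(self._loci(), erna, self._hits([]), 1e-6, 1e-7)
        assert (out["label"] == "neither").all()


class TestCausalTallies:
    @pytest.mark.parametrize("n_pass,n_total,pct", [(222, 392, 56.63),
                                                    (14, 109, 12.84),
                                                    (1297, 2755, 47.08)])
    def test_published_causal_fractions(self, n_pass, n_total, pct):
        flags = [True] * n_pass + [False] * (n_total - n_pass)
        out = gc.tally_causal_fraction(flags)
        assert out["fraction_pct_display"] == pytest.approx(pct, abs=0.005)

    def test_zero_passes(self):
        out = gc.tally_causal_fraction([False] * 10)
        assert out["n_causal"] == 0 and out["fraction_pct"] == 0.0

    def test_unique_transcript_count(self):
        out = gc.tally_causal_fraction([True, True, False, True],
                                       ["a", "a", "b", "c"])
        assert out["n_unique_causal_transcripts"] == 2


class TestCausalContacts:
    def _pairs(self, rows):
        df = pd.DataFrame(rows, columns=["upstream_id", "downstream_id", "pair_class"])
        df["grex_up"] = 0.0
        df["grex_down"] = 0.0
        df["distance_bp"] = 10_000
        df["log1p_distance"] = np.log1p(10_000)
        df["contact"] = 2.0
        return gc.PairDataset(df)

    def test_empty_pairs_all_contact_free(self):
        out = gc.intersect_causal_contacts({"e1"}, {"g1"},
                                           self._pairs([("x", "y", "enhancer-gene")]))
        assert out["n_in_contact_pairs"] == 0
        assert out["contact_free_ernas"] == ["e1"]
        assert out["contact_free_genes"] == ["g1"]

    def test_single_contact_pair_found(self):
        out = gc.intersect_causal_contacts({"e1"}, {"g1"},
                                           self._pairs([("e1", "g1", "enhancer-gene")]))
        assert out["in_contact_pairs"] == [("e1", "g1")]

    def test_orientation_agnostic(self):
        out = gc.intersect_causal_contacts({"e1"}, {"g1"},
                                           self._pairs([("g1", "e1", "gene-enhancer")]))
        assert out["in_contact_pairs"] == [("e1", "g1")]

    def test_matches_brute_force_join(self):
        rng = np.random.default_rng(4)
        ernas = [f"e{i}" for i in range(10)]
        genes = [f"g{i}" for i in range(10)]
        rows = []
        seen = set()
        for _ in range(40):
            e, g = rng.choice(ernas), rng.choice(genes)
            if (e, g) in seen:
                continue
            seen.add((e, g))
            rows.append((e, g, "enhancer-gene") if rng.random() < 0.5
                        else (g, e, "gene-enhancer"))
        # dedupe on (up, down)
        uniq = {}
        for r in rows:
            uniq[(r[0], r[1])] = r
        pairs = self._pairs(list(uniq.values()))
        causal_e = set(rng.choice(ernas, 4, replace=False))
        causal_g = set(rng.choice(genes, 4, replace=False))
        out = gc.intersect_causal_contacts(causal_e, causal_g, pairs)
        brute = set()
        for a, b in zip(pairs.table["upstream_id"], pairs.table["downstream_id"]):
            e = a if a in causal_e else b if b in causal_e else None
            g = a if a in causal_g else b if b in causal_g else None
            if e is not None and g is not None:
                brute.add((e, g))
        assert set(out["in_contact_pairs"]) == brute


class TestPeakOverlap:
    def _regions(self, n=4):
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 1000,
                             "end": np.arange(n) * 1000 + 500})

    def test_full_coverage_fraction_one(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        out = gc.peak_overlap_fractions(self._regions(), {"atac": peaks})
        assert out[out["mark"] == "atac"]["fraction"].iloc[0] == 1.0

    def test_empty_peaks_zero(self):
        peaks = pd.DataFrame(columns=["chrom", "start", "end"])
        out = gc.peak_overlap_fractions(self._regions(), {"dnase": peaks})
        assert out[out["mark"] == "dnase"]["n_overlapping"].iloc[0] == 0

    def test_planted_12_of_34_gives_35_pct(self):
        regions = pd.DataFrame({"chrom": "chr1", "start": np.arange(34) * 1000,
                                "end": np.arange(34) * 1000 + 500})
        peaks = pd.DataFrame({"chrom": "chr1", "start": np.arange(12) * 1000 + 100,
                              "end": np.arange(12) * 1000 + 200})
        out = gc.peak_overlap_fractions(regions, {"atac": peaks})
        frac = out[out["mark"] == "atac"]["fraction"].iloc[0]
        assert frac * 100 == pytest.approx(35.29, abs=0.01)

    def test_composite_any_of_marks(self):
        regions = self._regions(3)
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1100]})
        out = gc.peak_overlap_fractions(regions, {"a": a, "b": b})
        assert out[out["mark"] == "any"]["n_overlapping"].iloc[0] == 2


class TestEqtlComparison:
    def _eqtl(self, pairs):
        df = pd.DataFrame(pairs, columns=["transcript_id", "variant_id"])
        df["beta"] = 1.0
        df["p"] = 1e-5
        df["fdr"] = 0.01
        return gc.EqtlSet(df, 0.1)

    def test_identical_sets_jaccard_one(self):
        assert gc.jaccard_index({"a", "b"}, {"a", "b"}) == 1.0

    def test_worked_jaccard(self):
        assert gc.jaccard_index({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_jaccard_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = set(rng.choice(50, rng.integers(1, 20), replace=False))
            b = set(rng.choice(50, rng.integers(1, 20), replace=False))
            j1, j2 = gc.jaccard_index(a, b), gc.jaccard_index(b, a)
            assert j1 == j2 and 0.0 <= j1 <= 1.0
            assert (j1 == 1.0) == (a == b)

    def test_nearest_tss_matches_brute_force(self):
        rng = np.random.default_rng(6)
        variants = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(500)],
            "chrom": rng.choice(["chr1", "chr2"], 500),
            "pos": rng.integers(1, 1_000_000, 500),
        })
        tss = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 80),
                            "tss": rng.integers(1, 1_000_000, 80)})
        got = gc.nearest_tss_distances(variants, tss)
        for i, (c, p) in enumerate(zip(variants["chrom"], variants["pos"])):
            cand = tss[tss["chrom"] == c]["tss"].to_numpy()
            expected = np.abs(cand - p).min() if cand.size else np.inf
            assert got[i] == expected

    def test_full_comparison_medians_and_test(self):
        erna = self._eqtl([("e", f"v{i}") for i in range(50)])
        gene = self._eqtl([("g", f"w{i}") for i in range(50)])
        rng = np.random.default_rng(7)
        variants = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(50)] + [f"w{i}" for i in range(50)],
            "chrom": "chr1",
            # eRNA eQTLs planted distal, gene eQTLs proximal to the lone TSS
            "pos": np.concatenate([500_000 + rng.integers(30_000, 60_000, 50),
                                   500_000 + rng.integers(1_000, 15_000, 50)]),
        })
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [500_000]})
        out = gc.eqtl_set_comparison(erna, gene, variants, tss)
        assert out.jaccard == 0.0
        assert out.median_tss_distance_a > out.median_tss_distance_b
        assert out.mannwhitney_p < 1e-6


class TestColocTally:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["signal_id", "tissue", "eqtl_class", "pp"])

    def test_published_counts_accounting(self):
        out = gc.coloc_identities_from_counts(26_926, 29_669, 8_111)
        assert out["n_exclusive_erna"] == 18_815
        assert out["n_either"] == 48_484
        assert out["percent_increase_over_gene"] == pytest.approx(63.4, abs=0.05)
        assert round(out["percent_increase_over_gene"]) == 63

    def test_all_zero_pp_no_hits(self):
        recs = self._records([("s1", "T1", "eRNA", 0.0), ("s1", "T1", "canonical", 0.0)])
        out = gc.coloc_tally(recs)
        assert out.n_either == 0

    def test_threshold_inclusive_at_exact_07(self):
        recs = self._records([("s1", "T1", "eRNA", 0.7)])
        out = gc.coloc_tally(recs)
        assert out.n_erna_any == 1

    def test_any_tissue_rule(self):
        recs = self._records([("s1", "T1", "eRNA", 0.2), ("s1", "T2", "eRNA", 0.9)])
        assert gc.coloc_tally(recs).n_erna_any == 1

    def test_identities_hold_on_random_input(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(300):
            for tissue in ("T1", "T2"):
                for cls in ("eRNA", "canonical"):
                    if rng.random() < 0.7:
                        rows.append((f"s{i}", tissue, cls, float(rng.random())))
        out = gc.coloc_tally(self._records(rows))
        assert out.n_either == out.n_erna_any + out.n_gene_any - out.n_both
        assert out.n_exclusive_erna + out.n_exclusive_gene + out.n_both == out.n_either

    def test_invalid_pp_rejected(self):
        with pytest.raises(ValueError):
            gc.coloc_tally(self._records([("s1", "T1", "eRNA", 1.2)]))


class TestTranscriptLengths:
    def test_published_length_split(self):
        anns = [gc.TranscriptAnnotation(f"e{i}", "eRNA", "chrS", 0, 500, "+")
                for i in range(13_580)]
        anns += [gc.TranscriptAnnotation(f"l{i}", "eRNA", "chrS", 0, 3_000, "+")
                 for i in range(891)]
        out = gc.classify_transcript_lengths(anns)
        assert out["n_short"] == 13_580
        assert out["pct_short_display"] == 93.84
        assert out["pct_long_display"] == 6.16

    def test_boundary_length_counts_long(self):
        anns = [gc.TranscriptAnnotation("a", "eRNA", "chrS", 0, 2_000, "+")]
        out = gc.classify_transcript_lengths(anns)
        assert out["n_short"] == 0 and out["n_long"] == 1

    def test_strict_inequality(self):
        anns = [gc.TranscriptAnnotation(x, "eRNA", "chrS", 0, n, "+")
                for x, n in (("a", 1), ("b", 2), ("c", 3))]
        out = gc.classify_transcript_lengths(anns, cutoff_bp=2)
        assert out["n_short"] == 1
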