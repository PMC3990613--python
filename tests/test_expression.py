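"""Tag extraction, TPM normalization, filters, matching, classes, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetqtl import expression as expr
from hetqtl import simulate as sim


class TestExtractSignature:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            # 3'-most GATC with >= 13 downstream bases
            ("TTTGATCACGTACGTACGTAC", "GATCACGTACGTACGTA"),
            # no anchor at all
            ("AAACCCGGGTTT", None),
            # signature is exactly the tail of the sequence
            ("GATCAAAAAAAAAAAAA", "GATCAAAAAAAAAAAAA"),
            # 3'-most anchor too close to the end; an earlier one qualifies
            ("GATCCCCCCCCCCCCCCAAGATCTT", "GATCCCCCCCCCCCCCC"),
            # two qualifying anchors: the 3'-most wins
            ("GATCAAAAAAAAAAAAAGATCGGGGGGGGGGGGG", "GATCGGGGGGGGGGGGG"),
        ],
    )
    def test_rule(self, seq, expected):
        assert expr.extract_signature(seq) == expected

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            expr.extract_signature("GATCNNNNNNNNNNNNN")


class TestNormalizeTpm:
    def test_single_count_in_quarter_million_library_is_4_tpm(self):
        counts = pd.DataFrame({"L": [1, 249_999]}, index=["s1", "s2"])
        tpm = expr.normalize_tpm(counts)
        assert tpm.loc["s1", "L"] == pytest.approx(4.0)

    def test_all_zero_row_stays_zero(self, toy_counts):
        counts, meta = toy_counts
        tpm = expr.normalize_tpm(counts, meta)
        assert (tpm.iloc[0] == 0).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_column_sums_conserved(self, seed):
        gen = np.random.default_rng(seed)
        counts = pd.DataFrame(gen.integers(0, 100, size=(50, 5)) + (gen.random((50, 5)) < 0.1))
        counts.iloc[:, 0] += 1  # avoid an all-zero library
        tpm = expr.normalize_tpm(counts)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=0.5)

    def test_declared_total_mismatch_rejected(self, toy_counts):
        counts, meta = toy_counts
        bad = meta.assign(total=counts.sum().to_numpy() + 1)
        with pytest.raises(ValueError, match="declared total"):
            expr.normalize_tpm(counts, bad)


class TestFilters:
    def test_significant_but_unreliable_single_library_signature(self):
        counts = pd.DataFrame(
            {"L1": [1, 0], "L2": [0, 249_999]}, index=["hit", "rest"]
        )
        counts.loc["rest", "L1"] = 249_999
        flags = expr.apply_filters(counts)
        assert bool(flags.loc["hit", "significant"])  # exactly 4 TPM in one library
        assert not bool(flags.loc["hit", "reliable"])

    def test_reliable_but_insignificant(self):
        # 1 tag in a 300,000-tag library is 3.33 TPM: present twice, never >= 4 TPM
        counts = pd.DataFrame({"L1": [1, 299_999], "L2": [1, 299_999]}, index=["s", "big"])
        flags = expr.apply_filters(counts)
        assert bool(flags.loc["s", "reliable"]) and not bool(flags.loc["s", "significant"])

    def test_flags_equal_bruteforce_oracle(self, toy_counts):
        counts, meta = toy_counts
        tpm = expr.normalize_tpm(counts)
        flags = expr.apply_filters(counts, tpm)
        for s in counts.index:
            assert flags.loc[s, "reliable"] == ((counts.loc[s] > 0).sum() >= 2)
            assert flags.loc[s, "significant"] == (tpm.loc[s] >= 4).any()

    def test_raising_threshold_never_increases_significant_count(self, toy_counts):
        counts, _ = toy_counts
        tpm = expr.normalize_tpm(counts)
        n = [( tpm >= thr).any(axis=1).sum() for thr in (1, 4, 10, 100)]
        assert n == sorted(n, reverse=True)


class TestReferenceMatching:
    def test_statuses_equal_double_search_oracle(self, small_reference):
        gen = np.random.default_rng(7)
        sigs = list(small_reference.signatures()["sig_p1"])
        # add decoys that match nothing
        sigs += ["".join(gen.choice(list("ACGT"), 17)) for _ in range(20)]
        status = expr.match_to_references(
            sigs, small_reference.transcripts["P1"], small_reference.transcripts["P2"]
        )
        for s in sigs:
            in1 = any(s in t for t in small_reference.transcripts["P1"].values())
            in2 = any(s in t for t in small_reference.transcripts["P2"].values())
            expected = "both" if in1 and in2 else "P1-only" if in1 else "P2-only" if in2 else "none"
            assert status[s] == expected

    def test_signature_snp_yields_single_parent_match(self, small_reference):
        sigs = small_reference.signatures()
        snp = sigs[sigs["differs"]]
        status = expr.match_to_references(
            list(snp["sig_p1"]),
            small_reference.transcripts["P1"],
            small_reference.transcripts["P2"],
        )
        assert (status == "P1-only").all()

    def test_statuses_partition_all_signatures(self, small_reference):
        sigs = list(small_reference.signatures()["sig_p1"])
        status = expr.match_to_references(
            sigs, small_reference.transcripts["P1"], small_reference.transcripts["P2"]
        )
        assert status.isin(["P1-only", "P2-only", "both", "none"]).all()


def _toy_genome():
    """Hand-built single chromosome: spacer, one + gene, big gap, one - gene."""
    gen = np.random.default_rng(21)
    def rand(n):
        s = "".join(gen.choice(list("ACGT"), n))
        while "GATC" in s:
            i = s.index("GATC")
            s = s[: i + 3] + "A" + s[i + 4 :]
        return s

    tx_a = rand(183) + "GATC" + rand(13)  # 200 bases, anchor at 183
    tx_b = rand(133) + "GATC" + rand(13)  # 150 bases
    spacer1, spacer2, spacer3 = rand(600), rand(700), rand(300)
    chrom = spacer1 + tx_a + spacer2 + expr.reverse_complement(tx_b) + spacer3
    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["c1", "c1"],
            "start": [601, 601 + 200 + 700],
            "end": [600 + 200, 600 + 200 + 700 + 150],
            "strand": ["+", "-"],
        }
    )
    return {"c1": chrom}, genes, tx_a, tx_b, spacer2


class TestPositionalClasses:
    def test_decision_table(self):
        chroms, genes, tx_a, tx_b, spacer2 = _toy_genome()
        pc = expr.PositionalClassifier(chroms, genes)
        # 1: the canonical 3'-anchored signature, sense strand (both strands of genome)
        assert pc.classify(expr.extract_signature(tx_a)) == 1
        assert pc.classify(expr.extract_signature(tx_b)) == 1
        # 2: sense exonic but not the canonical signature
        assert pc.classify(tx_a[50:67]) == 2
        # 3: antisense exonic
        assert pc.classify(expr.reverse_complement(tx_a[50:67])) == 3
        # 6: within 500 bp downstream of gA (+ strand: right of its end)
        assert pc.classify(spacer2[100:117]) == 6
        # 7: intergenic (spacer1 precedes every gene and no downstream window covers it)
        spacer1 = chroms["c1"][:600]
        assert pc.classify(spacer1[50:67]) == 7

    def test_unmatched_signature_is_an_error(self):
        chroms, genes, *_ = _toy_genome()
        pc = expr.PositionalClassifier(chroms, genes)
        with pytest.raises(ValueError, match="no genome match"):
            pc.classify("A" * 17)

    def test_classes_partition_matched_signatures(self, small_reference):
        pc = expr.PositionalClassifier(small_reference.chromosomes["P1"], small_reference.genes)
        classes = [pc.classify(s) for s in small_reference.signatures()["sig_p1"]]
        assert set(classes) <= set(range(1, 8))
        assert all(c == 1 for c in classes)  # canonical signatures are class 1


class TestReplicateMeans:
    def test_zeros_included_mean(self):
        tpm = pd.DataFrame(
            {"a1": [10.0], "a2": [0.0], "a3": [0.0], "a4": [0.0]}, index=["s"]
        )
        meta = pd.DataFrame(
            {"library": ["a1", "a2", "a3", "a4"], "genotype": ["P1"] * 4,
             "tissue": ["leaf"] * 4, "replicate": [1, 2, 3, 4]}
        )
        means = expr.replicate_means(tpm, meta)
        assert means.loc["s", "P1_leaf"] == pytest.approx(2.5)

    def test_single_replicate_group_is_identity(self, toy_counts):
        counts, meta = toy_counts
        tpm = expr.normalize_tpm(counts)
        means = expr.replicate_means(tpm, meta)
        assert np.allclose(means["F1_root"], tpm["L4"])

    def test_group_means_equal_groupby_oracle(self, toy_counts):
        counts, meta = toy_counts
        tpm = expr.normalize_tpm(counts)
        means = expr.replicate_means(tpm, meta)
        for (g, t), grp in meta.groupby(["genotype", "tissue"]):
            expected = tpm[grp["library"]].mean(axis=1)
            assert np.allclose(means[f"{g}_{t}"], expected)

    def test_unknown_library_rejected(self, toy_counts):
        counts, meta = toy_counts
        bad = pd.concat(
            [meta, pd.DataFrame([{"library": "ghost", "genotype": "P1",
                                  "tissue": "leaf", "replicate": 9}])]
        )
        with pytest.raises(ValueError, match="ghost"):
            expr.replicate_means(expr.normalize_tpm(counts), bad)


class TestAbundanceBins:
    @pytest.mark.parametrize(
        "tpm,bin_label",
        [(100.0, "1-100"), (100.5, "101-1000"), (1000.4, "101-1000"),
         (10_001.0, ">10000"), (1.0, "1-100")],
    )
    def test_bin_edges_on_rounded_integers(self, tpm, bin_label):
        bins = expr.abundance_bins(pd.Series([tpm]))
        assert bins[bin_label] == 1 and bins.sum() == 1

    def test_bins_partition_expressed_signatures(self, toy_counts):
        counts, _ = toy_counts
        tpm = expr.normalize_tpm(counts)
        for lib in tpm.columns:
            bins = expr.abundance_bins(tpm[lib])
            rounded = np.floor(tpm[lib] + 0.5)
            assert bins.sum() == (rounded >= 1).sum()


class TestLibrarySummary:
    def test_empty_table_is_all_zero(self):
        counts = pd.DataFrame({"L1": [0, 0], "L2": [1, 1]}, index=["a", "b"])
        meta = pd.DataFrame(
            {"library": ["L1", "L2"], "genotype": ["P1", "P1"],
             "tissue": ["leaf", "root"], "replicate": [1, 1]}
        )
        summary = expr.library_summary(counts, meta)
        leaf = summary.loc[("P1", "leaf")]
        assert leaf["distinct"] == 0 and leaf["reliable"] == 0

    def test_cells_equal_bruteforce_recount(self, toy_counts):
        counts, meta = toy_counts
        tpm = expr.normalize_tpm(counts)
        flags = expr.apply_filters(counts, tpm)
        summary = expr.library_summary(counts, meta)
        for (g, t), grp in meta.groupby(["genotype", "tissue"]):
            libs = grp["library"].to_list()
            distinct = np.mean([(counts[l] > 0).sum() for l in libs])
            rel = np.mean([((counts[l] > 0) & flags["reliable"]).sum() for l in libs])
            both = np.mean(
                [((counts[l] > 0) & flags["reliable"] & flags["significant"]).sum() for l in libs]
            )
            row = summary.loc[(g, t)]
            assert row["distinct"] == pytest.approx(distinct)
            assert row["reliable"] == pytest.approx(rel)
            assert row["reliable_and_significant"] == pytest.approx(both)

    def test_replicated_group_reports_the_replicate_mean(self, toy_counts):
        counts, meta = toy_counts
        summary = expr.library_summary(counts, meta)
        libs = meta[(meta.genotype == "P1") & (meta.tissue == "leaf")]["library"]
        expected = np.mean([counts[l].sum() for l in libs])
        assert summary.loc[("P1", "leaf"), "total_reads"] == pytest.approx(expected)

    def test_gene_and_match_annotations(self, small_reference):
        truth = sim.generate_inheritance_truth(
            small_reference.genes["gene_id"].to_list(), seed=3
        )
        counts, meta, mapping = sim.simulate_tag_libraries(
            small_reference, truth, noise_model="none", n_background=50, seed=4
        )
        status = expr.match_to_references(
            list(counts.index),
            small_reference.transcripts["P1"],
            small_reference.transcripts["P2"],
        )
        summary = expr.library_summary(
            counts, meta, gene_of_signature=mapping, match_status=status
        )
        assert (summary["distinct_genes"] <= len(small_reference.genes)).all()
        assert (summary["pct_match_p1"] <= 100).all()
        assert (summary["pct_match_p1"] > 0).all()
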