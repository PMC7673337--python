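"""Genome filter, cas-hit thresholds, windowing, classification, summary."""

import itertools

import pytest

from spurscan.context import (
    _median_lower,
    classify,
    filter_cas_hits,
    filter_genome,
    interval_distance,
    load_domain_label_map,
    load_subtype_definitions,
    summarize,
    window_cas_genes,
)
from spurscan.errors import ConfigError, InputError
from spurscan.model import (
    Candidate,
    CasHit,
    CasSubtypeDefinition,
    ContextClassification,
    GeneLocus,
)

SUBTYPES = load_subtype_definitions()


def locus(start, end, gene_id="g", genome="G1", length=600_000):
    return GeneLocus(
        genome_accession=genome,
        genome_length=length,
        gene_id=gene_id,
        start=start,
        end=end,
        strand="+",
    )


def hit(gene_id="c", label="cas1", evalue=1e-10, identity=50.0, coverage=0.9):
    return CasHit(
        gene_id=gene_id,
        domain_id="D",
        cas_label=label,
        evalue=evalue,
        identity_pct=identity,
        coverage=coverage,
    )


class TestGenomeFilter:
    def test_just_below_500kb_is_untested(self):
        assert filter_genome(locus(0, 300, length=499_999)) == "untested"

    def test_exactly_500kb_is_tested(self):
        assert filter_genome(locus(0, 300, length=500_000)) == "tested"

    def test_unmapped_candidate_is_untested(self):
        # mirrors a real 864 bp contig: far too short to hold cas genes
        assert filter_genome(None) == "untested"
        assert filter_genome(locus(0, 300, length=864)) == "untested"


class TestCasHitFilter:
    def test_clearing_all_thresholds_is_kept(self):
        assert filter_cas_hits([hit(evalue=1e-6, identity=30, coverage=0.8)])

    def test_evalue_above_threshold_rejected_despite_strong_identity(self):
        assert filter_cas_hits([hit(evalue=1e-4, identity=90, coverage=0.9)]) == []

    def test_thresholds_are_inclusive(self):
        assert filter_cas_hits([hit(evalue=1e-5, identity=25.0, coverage=0.70)])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"evalue": 1.1e-5},
            {"identity": 24.9},
            {"coverage": 0.699},
        ],
    )
    def test_each_threshold_rejects_just_past_the_bound(self, kwargs):
        assert filter_cas_hits([hit(**kwargs)]) == []

    def test_best_hit_per_gene_lowest_evalue_then_highest_identity(self):
        hits = [
            hit("g1", "cas1", evalue=1e-8, identity=40),
            hit("g1", "cas2", evalue=1e-10, identity=30),
            hit("g1", "cas3", evalue=1e-10, identity=60),
        ]
        kept = filter_cas_hits(hits)
        assert len(kept) == 1
        assert kept[0].cas_label == "cas3"


class TestWindowing:
    def test_gene_just_inside_window_included_with_distance(self):
        cand = locus(50_000, 51_000, "cand")
        cas = locus(48_001 - 2_000, 48_001, "cas")  # ends 1,999 bp upstream
        got = window_cas_genes(cand, [(hit("cas"), cas)])
        assert [(g.gene_id, d) for _, g, d in got] == [("cas", 1999)]

    @pytest.mark.parametrize("gap,n", [(10_000, 1), (10_001, 0)])
    def test_window_bound_is_inclusive_at_10kb(self, gap, n):
        cand = locus(50_000, 51_000, "cand")
        cas = locus(51_000 + gap, 52_000 + gap, "cas")
        assert len(window_cas_genes(cand, [(hit("cas"), cas)])) == n

    def test_overlapping_gene_has_distance_zero(self):
        cand = locus(50_000, 51_000, "cand")
        cas = locus(50_500, 52_000, "cas")
        assert window_cas_genes(cand, [(hit("cas"), cas)])[0][2] == 0

    def test_distance_is_symmetric(self):
        a, b = locus(10, 20, "a"), locus(50, 70, "b")
        assert interval_distance(a, b) == interval_distance(b, a) == 30

    def test_widening_window_never_loses_genes(self):
        cand = locus(50_000, 51_000, "cand")
        genes = [
            (hit(f"c{i}"), locus(51_000 + 3_000 * i, 51_500 + 3_000 * i, f"c{i}"))
            for i in range(6)
        ]
        narrow = {g.gene_id for _, g, _ in window_cas_genes(cand, genes, 8_000)}
        wide = {g.gene_id for _, g, _ in window_cas_genes(cand, genes, 14_000)}
        assert narrow <= wide

    def test_cross_genome_comparison_is_an_error(self):
        with pytest.raises(InputError, match="across genomes"):
            interval_distance(locus(0, 10, genome="G1"), locus(0, 10, genome="G2"))


def windowed(labels, distance=1000):
    return [
        (hit(f"g{i}", label), locus(100 + 5000 * i, 600 + 5000 * i, f"g{i}"), distance + i)
        for i, label in enumerate(labels)
    ]


class TestClassify:
    def test_cas1_cas2_rule(self):
        got = classify("P", windowed(["cas1", "cas2", "cas3"]), SUBTYPES)
        assert (got.status, got.rule) == ("pfp", "cas1cas2")
        assert got.n_cas_genes == 3

    def test_complete_cluster_without_cas1_cas2(self):
        iii_b = next(d for d in SUBTYPES if d.subtype == "III-B")
        assert not {"cas1", "cas2"} <= iii_b.required_genes
        got = classify("P", windowed(sorted(iii_b.required_genes)), SUBTYPES)
        assert (got.status, got.rule, got.matched_subtype) == ("pfp", "cluster", "III-B")

    def test_partial_evidence_is_cas_positive_only(self):
        got = classify("P", windowed(["cas3"]), SUBTYPES)
        assert (got.status, got.rule) == ("cas_positive", "none")

    def test_no_windowed_genes_is_negative(self):
        got = classify("P", [], SUBTYPES)
        assert got.status == "negative"
        assert got.distance_to_nearest_cas is None
        assert got.n_cas_genes == 0

    def test_paralogs_count_once_for_completeness(self):
        ii_c = next(d for d in SUBTYPES if d.subtype == "II-C")
        labels = sorted(ii_c.required_genes) + ["cas9"]  # duplicate label
        got = classify("P", windowed(labels), SUBTYPES)
        assert (got.status, got.rule, got.matched_subtype) == ("pfp", "cluster", "II-C")

    def test_order_invariance(self):
        labels = ["cas3", "cas1", "cas2", "cas6"]
        results = {
            (
                classify("P", windowed(list(perm)), SUBTYPES).status,
                classify("P", windowed(list(perm)), SUBTYPES).rule,
            )
            for perm in itertools.permutations(labels)
        }
        assert len(results) == 1

    def test_adding_hits_never_lowers_status_rank(self):
        from spurscan.model import status_rank

        labels = ["cas3", "cas7", "cas1", "cas2"]
        ranks = [
            status_rank(classify("P", windowed(labels[: k + 1]), SUBTYPES).status)
            for k in range(len(labels))
        ]
        assert ranks == sorted(ranks)

    def test_empty_subtype_catalog_is_a_config_error(self):
        with pytest.raises(ConfigError):
            classify("P", windowed(["cas1"]), [])

    def test_distance_is_minimum_over_windowed_genes(self):
        got = classify("P", windowed(["cas1", "cas2"], distance=1999), SUBTYPES)
        assert got.distance_to_nearest_cas == 1999


class TestCatalogs:
    def test_shipped_catalog_covers_labels_in_domain_map(self):
        labels = set(load_domain_label_map().values())
        for d in SUBTYPES:
            assert d.required_genes <= labels


class TestSummarize:
    def test_median_lower_interpolation(self):
        assert _median_lower([5, 1, 9]) == 5
        assert _median_lower([1, 2, 3, 4]) == 2  # lower of the middle pair
        assert _median_lower([]) is None

    def test_empty_inputs_give_zero_report(self):
        report = summarize({}, [])
        block = report["per_approach"]["I"]
        assert block["n_candidates"] == 0
        assert block["pct_pfp_of_tested"] == 0.0
        assert block["median_length_pfp"] is None

    def test_counts_match_a_constructed_truth_table(self):
        cands = [
            Candidate("A1", "I", (), (), 80),
            Candidate("A2", "I", (), (), 100),
            Candidate("A3", "I", (), (), 120),
            Candidate("A4", "I", (), (), 90),
        ]
        cls = {
            "A1": ContextClassification("A1", "pfp", 4, 1000),
            "A2": ContextClassification("A2", "cas_positive", 2, 5000),
            "A3": ContextClassification("A3", "negative", 0, None),
            "A4": ContextClassification("A4", "untested"),
        }
        block = summarize(cls, cands)["per_approach"]["I"]
        assert block["n_candidates"] == 4
        assert block["tested"] == 3
        assert block["by_status"] == {
            "untested": 1,
            "negative": 1,
            "cas_positive": 1,
            "pfp": 1,
        }
        assert block["pct_cas_positive_of_tested"] == pytest.approx(200 / 3)
        assert block["pct_pfp_of_tested"] == pytest.approx(100 / 3)
        assert block["median_length_cas_positive"] == 80  # lower median of 80,100
        assert block["median_length_pfp"] == 80
        assert block["median_distance_to_cas"] == 1000
        assert block["frac_cas_positive_ge3_cas_genes"] == 0.5
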