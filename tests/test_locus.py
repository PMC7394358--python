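"""Locus interpretation: collation, classification, TRD segmentation,
allele/population-state enumeration, and survey summaries."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irscan import (
    GeneAnnotation,
    GenomeRecord,
    InvertedRepeatHit,
    LocusCall,
    UnsegmentableLocusError,
    classify_locus,
    collate_identical_genes,
    combinatorial_states,
    combined_phase_variable_percentage,
    enumerate_alleles,
    format_percent,
    segment_trds,
    summarize_survey,
)
from _util import rand_seq


# -- collation ----------------------------------------------------------------

def test_collation_partitions_by_sequence():
    genes = [("g3", "ACGT"), ("g1", "ACGT"), ("g2", "ACGT"),
             ("g5", "TTTT"), ("g4", "TTTT")]
    groups = collate_identical_genes(genes)
    assert sorted(len(g.gene_ids) for g in groups) == [2, 3]
    assert [g.representative for g in groups] == ["g1", "g4"]
    assert groups[0].gene_ids == ["g1", "g2", "g3"]


def test_collation_all_distinct():
    genes = [(f"g{i}", "ACGT"[: i % 4 + 1] * (i + 1)) for i in range(6)]
    groups = collate_identical_genes(genes)
    assert len(groups) == len({s for _, s in genes})


def test_collation_matches_pairwise_oracle(rng):
    genes = []
    pool = [rand_seq(rng, 30) for _ in range(4)]
    for i in range(10):
        genes.append((f"g{i:02d}", pool[int(rng.integers(0, 4))]))
    groups = collate_identical_genes(genes)
    # O(n^2) string-equality oracle
    for gid_a, seq_a in genes:
        for gid_b, seq_b in genes:
            same_group = any(
                gid_a in g.gene_ids and gid_b in g.gene_ids for g in groups
            )
            assert same_group == (seq_a == seq_b)
    assert sum(len(g.gene_ids) for g in groups) == len(genes)


# -- classification -----------------------------------------------------------

def _mk_hit(ps, pe, length=None):
    length = length or (pe - ps + 1)
    return InvertedRepeatHit("hsdS", 10, 10 + length - 1, "c", ps, pe, length,
                             "downstream", 100)


def test_classify_inverting_with_silent_partner():
    genome = GenomeRecord("c", "A" * 500 + "CAT" + "A" * 497)  # revcomp(ATG)=CAT
    gene = GeneAnnotation("hsdS", "c", 1, 100, "+", "hsdS")
    partner = GeneAnnotation("hsdS2", "c", 401, 600, "-", "hsdS")
    call = classify_locus(gene, [_mk_hit(450, 480)], [gene, partner], genome)
    assert call.category == "inverting"
    assert call.partner_gene_id == "hsdS2"
    # partner first codon on '-' strand = revcomp(genome[598:600]) != ATG here
    assert call.partner_is_silent is True


def test_classify_partner_with_atg_start_not_silent():
    seq = "G" * 200 + "ATG" + "G" * 297
    genome = GenomeRecord("c", seq)
    gene = GeneAnnotation("hsdS", "c", 1, 100, "+", "hsdS")
    partner = GeneAnnotation("hsdS2", "c", 201, 320, "+", "hsdS")
    call = classify_locus(gene, [_mk_hit(250, 280)], [gene, partner], genome)
    assert call.category == "inverting" and call.partner_is_silent is False


def test_classify_incidental_when_partner_unannotated():
    gene = GeneAnnotation("hsdS", "c", 1, 100, "+", "hsdS")
    other = GeneAnnotation("x", "c", 900, 1000, "+", "hypothetical")
    call = classify_locus(gene, [_mk_hit(450, 480)], [gene, other])
    assert call.category == "incidental_ir"
    assert call.partner_gene_id is None


def test_classify_no_ir():
    gene = GeneAnnotation("hsdS", "c", 1, 100, "+", "hsdS")
    call = classify_locus(gene, [], [gene])
    assert call.category == "no_ir" and call.hits == []


def test_classify_missing_labels_degrades_not_crashes(caplog):
    gene = GeneAnnotation("hsdS", "c", 1, 100, "+", "hsdS")
    unlabeled = GeneAnnotation("y", "c", 440, 500, "+")
    call = classify_locus(gene, [_mk_hit(450, 480)], [gene, unlabeled])
    assert call.category == "incidental_ir"


def test_classification_order_independent():
    gene = GeneAnnotation("hsdS", "c", 1, 100, "+", "hsdS")
    anns = [
        GeneAnnotation("a", "c", 300, 400, "+", "hypothetical"),
        GeneAnnotation("b", "c", 440, 520, "-", "hsdS"),
        GeneAnnotation("d", "c", 600, 700, "+", "hsdM"),
    ]
    hits = [_mk_hit(450, 480)]
    fwd = classify_locus(gene, hits, [gene] + anns)
    rev = classify_locus(gene, hits, [gene] + anns[::-1])
    assert (fwd.category, fwd.partner_gene_id) == (rev.category, rev.partner_gene_id)


# -- TRD segmentation ---------------------------------------------------------

def test_segment_trds_interval_arithmetic():
    seg = segment_trds("G" * 600, (1, 30), (301, 350))
    assert seg.trd5 == (31, 300) and seg.trd3 == (351, 600)
    assert seg.trd5[1] - seg.trd5[0] + 1 == 270
    assert seg.trd3[1] - seg.trd3[0] + 1 == 250


def test_segment_trds_empty_trd3_is_error():
    with pytest.raises(UnsegmentableLocusError, match="3'-TRD"):
        segment_trds("G" * 350, (1, 30), (301, 350))


def test_segment_trds_disordered_irs_error():
    with pytest.raises(UnsegmentableLocusError):
        segment_trds("G" * 600, (301, 350), (1, 30))
    with pytest.raises(UnsegmentableLocusError):
        segment_trds("G" * 600, (1, 310), (301, 350))


def test_segment_extract_round_trip():
    gene = "AA" + "C" * 28 + "G" * 270 + "T" * 33 + "A" * 250
    seg = segment_trds(gene, (3, 30), (301, 333))
    t5, t3 = seg.extract(gene)
    assert t5 == "G" * 270 and t3 == "A" * 250


# -- allele / state enumeration ----------------------------------------------

@pytest.mark.parametrize(
    "n5,n3,expected",
    [(2, 2, 4), (1, 1, 1), (13, 16, 208)],
)
def test_enumerate_allele_counts(rng, n5, n3, expected):
    v5 = {"A" * (i + 1) + rand_seq(rng, 25) + "C" * (n5 - i) for i in range(n5)}
    v3 = {"G" * (i + 1) + rand_seq(rng, 30) + "T" * (n3 - i) for i in range(n3)}
    assert len(v5) == n5 and len(v3) == n3
    space = enumerate_alleles(v5, v3)
    assert space.n_alleles == expected
    labels = [a[0] for a in space.alleles]
    assert len(labels) == len(set(labels)) == expected


def test_enumerate_alleles_row_major_labels():
    space = enumerate_alleles({"AA", "CC"}, {"GG", "TT"})
    assert space.alleles == [("A", 0, 0), ("B", 0, 1), ("C", 1, 0), ("D", 1, 1)]


def test_enumerate_alleles_symmetric_under_swap():
    v5, v3 = {"AAA", "CCC", "GGG"}, {"TT", "AA"}
    a = enumerate_alleles(v5, v3)
    b = enumerate_alleles(v3, v5)
    assert a.n_alleles == b.n_alleles == 6
    assert (a.n5, a.n3) == (b.n3, b.n5)


def test_enumerate_alleles_empty_set_errors():
    with pytest.raises(ValueError):
        enumerate_alleles(set(), {"ACGT"})


@pytest.mark.parametrize("m,a,expected", [(2, 4, 16), (0, 1, 1), (3, 6, 48)])
def test_combinatorial_states(m, a, expected):
    assert combinatorial_states(m, a) == expected


def test_combinatorial_states_rejects_bad_input():
    with pytest.raises(ValueError):
        combinatorial_states(-1, 4)
    with pytest.raises(ValueError):
        combinatorial_states(2, 0)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 10), st.integers(1, 100))
def test_combinatorial_states_formula(m, a):
    assert combinatorial_states(m, a) == 2**m * a
    assert combinatorial_states(m + 1, a) == 2 * combinatorial_states(m, a)


# -- summaries ----------------------------------------------------------------

def _call(gid, category, n_hits=0):
    hits = [_mk_hit(450 + i, 480 + i) for i in range(n_hits)]
    return LocusCall(gid, category, hits)


def test_summary_percentage_truncates_not_rounds():
    calls = [_call(f"g{i}", "inverting", 1) for i in range(875)]
    calls += [_call(f"h{i}", "no_ir") for i in range(22107 - 875)]
    s = summarize_survey(calls)
    assert s.total_genes == 22107 and s.inverting == 875
    assert s.percent_inverting == "3.9"  # 3.958... floors to 3.9, not 4.0
    assert abs(s.percent_inverting_raw - 100 * 875 / 22107) < 1e-12


@pytest.mark.parametrize(
    "inverting,total,expected",
    [(0, 10, "0.0"), (5, 428, "1.1"), (1, 232, "0.4")],
)
def test_summary_percentages(inverting, total, expected):
    calls = [_call(f"g{i}", "inverting", 1) for i in range(inverting)]
    calls += [_call(f"h{i}", "no_ir") for i in range(total - inverting)]
    assert summarize_survey(calls).percent_inverting == expected


def test_summary_empty_input_is_all_zero():
    s = summarize_survey([])
    assert (s.total_genes, s.genes_with_ir, s.inverting) == (0, 0, 0)
    assert s.percent_inverting == "0.0"


def test_summary_counts_collated_groups_and_species():
    calls = [
        _call("a1", "inverting", 2),
        _call("a2", "incidental_ir", 1),
        _call("b1", "no_ir"),
    ]
    collation = collate_identical_genes(
        [("a1", "ACGTACGT"), ("a2", "ACGTACGT"), ("b1", "TTTTCCCC")]
    )
    s = summarize_survey(calls, collation,
                         species_by_gene={"a1": "S. suis", "a2": "S. suis",
                                          "b1": "E. coli"})
    assert s.genes_with_ir == 2
    assert s.collated_with_ir == 1
    assert "S. suis\t1 of 2 strains" in s.species_rollup


def test_summary_monotone_in_inverting_count():
    def pct(k, n):
        calls = [_call(f"g{i}", "inverting", 1) for i in range(k)]
        calls += [_call(f"h{i}", "no_ir") for i in range(n - k)]
        return summarize_survey(calls).percent_inverting_raw

    vals = [pct(k, 50) for k in range(0, 51, 5)]
    assert vals == sorted(vals)


def test_combined_percentage_mechanism_sum():
    assert combined_phase_variable_percentage([2.0, 7.9, 3.9]) == 13.8
    assert combined_phase_variable_percentage([0.0]) == 0.0
    assert combined_phase_variable_percentage([50.0, 50.0]) == 100.0


def test_combined_percentage_warns_above_100():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        assert combined_phase_variable_percentage([60.0, 60.0]) == 120.0
        assert any("overlap" in str(w.message) for w in caught)


def test_format_percent_examples():
    assert format_percent(100 * 875 / 22107) == "3.9"
    assert format_percent(100 * 5 / 428) == "1.1"
    assert format_percent(0.0) == "0.0"
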