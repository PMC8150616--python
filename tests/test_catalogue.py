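"""Deduplication, population breakdowns and summary statistics."""

import numpy as np
import pytest

from lcshap.catalogue import (
    count_gene_variants,
    deduplicate,
    length_observation_correlation,
    population_breakdown,
    round_percent,
    summarize,
)
from lcshap.extraction import HaplotypeObservation, extract_observations
from lcshap.formats import SamplePanel
from lcshap.genomic import GenomicInterval, VariantSite
from lcshap.sequences import HaplotypeSequence, build_sequence
from lcshap.simulate import simulate_cohort

from conftest import make_cohort, random_small_config

SPAN = GenomicInterval("chr1", 10, 40)


def _pair(sample, seq, span=SPAN):
    h = HaplotypeSequence(span, seq)
    return (
        [HaplotypeObservation(sample, 0, span, ()), HaplotypeObservation(sample, 1, span, ())],
        [h, h],
    )


def test_identical_observations_collapse():
    obs, seqs = _pair("S01", "ACGT")
    records = deduplicate(obs, seqs)
    assert len(records) == 1
    assert records[0].observations == 2 and records[0].samples == ["S01", "S01"]


def test_het_sample_yields_two_singleton_records():
    span = SPAN
    obs = [
        HaplotypeObservation("S01", 0, span, ((0, 0),)),
        HaplotypeObservation("S01", 1, span, ((0, 1),)),
    ]
    seqs = [HaplotypeSequence(span, "AAAA"), HaplotypeSequence(span, "ACAA")]
    records = deduplicate(obs, seqs)
    assert [r.observations for r in records] == [1, 1]


def test_ids_ordered_by_descending_observations():
    obs1, seqs1 = _pair("S01", "AAAA")
    obs2, seqs2 = _pair("S02", "AAAA")
    obs3, seqs3 = _pair("S03", "CCCC")
    records = deduplicate(obs1 + obs2 + obs3, seqs1 + seqs2 + seqs3)
    assert [r.id for r in records] == ["HAP1", "HAP2"]
    assert records[0].observations == 4 and records[0].sequence == "AAAA"


def test_same_sequence_different_span_stays_distinct():
    obs1, seqs1 = _pair("S01", "ACGT")
    other = GenomicInterval("chr1", 11, 41)
    obs2, seqs2 = _pair("S02", "ACGT", span=other)
    assert len(deduplicate(obs1 + obs2, seqs1 + seqs2)) == 2


def test_dedup_idempotence():
    sim = simulate_cohort(random_small_config(42))
    c = sim.cohort
    obs = extract_observations(c, sim.config.gene)
    seqs = [build_sequence(c.reference, c.region, c.sites, o) for o in obs]
    records = deduplicate(obs, seqs)
    expanded_obs, expanded_seqs = [], []
    for r in records:
        for k, s in enumerate(r.samples):
            expanded_obs.append(HaplotypeObservation(s, k % 2, r.span, ()))
            expanded_seqs.append(r.built)
    again = deduplicate(expanded_obs, expanded_seqs)
    assert [(r.span, r.sequence, r.observations) for r in records] == [
        (r.span, r.sequence, r.observations) for r in again
    ]


def test_population_breakdown_counts_chromosomes():
    panel = SamplePanel({"S01": "LWK"}, {"LWK": "AFR"})
    obs, seqs = _pair("S01", "ACGT")
    (rec,) = population_breakdown(deduplicate(obs, seqs), panel)
    assert rec.pop_counts == {"LWK": 2} and rec.superpop_counts == {"AFR": 2}


def test_population_breakdown_unknown_sample_errors():
    panel = SamplePanel({"S99": "LWK"}, {"LWK": "AFR"})
    obs, seqs = _pair("S01", "ACGT")
    with pytest.raises(ValueError, match="S01"):
        population_breakdown(deduplicate(obs, seqs), panel)


def test_population_breakdown_matches_simulator_truth():
    sim = simulate_cohort(random_small_config(9))
    c = sim.cohort
    obs = extract_observations(c, sim.config.gene)
    seqs = [build_sequence(c.reference, c.region, c.sites, o) for o in obs]
    records = population_breakdown(deduplicate(obs, seqs), sim.panel)
    truth = {(e.start, e.end, e.sequence): e for e in sim.truth.catalogue}
    for r in records:
        e = truth[(r.span.start, r.span.end, r.sequence)]
        expected = {}
        for s in e.samples:
            p = sim.panel.population(s)
            expected[p] = expected.get(p, 0) + 1
        assert r.pop_counts == expected
        assert sum(r.pop_counts.values()) == r.observations
        assert sum(r.superpop_counts.values()) == r.observations


def _records(length_obs):
    out = []
    for k, (length, n) in enumerate(length_obs):
        span = GenomicInterval("chr1", 1, 1)
        from lcshap.catalogue import HaplotypeRecord

        out.append(HaplotypeRecord(f"HAP{k+1}", span, "", length, n))
    return out


def test_summary_single_record():
    s = summarize(_records([(500, 2)]))
    assert s.median_length == 500 and s.total_observations == 2
    assert len(s.bins) == 1 and s.bins[0].percent == 100.0


def test_summary_quartiles_and_iqr():
    s = summarize(_records([(7_588, 1), (7_588, 1), (16_014, 1), (30_729, 1), (30_729, 1)]))
    assert (s.q1, s.median_length, s.q3) == (7_588, 16_014, 30_729)
    assert s.iqr == 23_141


def test_histogram_percent_rounding_half_up():
    assert round_percent(2_132, 3_040) == 70.13
    assert round_percent(1, 8) == 12.5
    assert round_percent(1, 3_040) == 0.03  # 0.0328… rounds down
    assert round_percent(1, 800) == 0.13  # 0.125 rounds half-up, not to even


def test_histogram_conservation_and_percent_recompute():
    rng = np.random.default_rng(4)
    recs = _records([(int(l), int(n)) for l, n in
                     zip(rng.integers(100, 90_000, 40), rng.integers(1, 50, 40))])
    for width in (5_000, 10_000, 25_000):
        s = summarize(recs, bin_width=width)
        assert sum(b.observations for b in s.bins) == s.total_observations
        for b in s.bins:
            assert b.percent == round_percent(b.observations, s.total_observations)
        assert abs(sum(b.percent for b in s.bins) - 100) < 0.05 * len(s.bins)


def test_empty_catalogue_summary_is_defined():
    s = summarize([])
    assert s.distinct_count == 0 and s.total_observations == 0
    assert s.median_length is None and s.bins == []


def test_combined_length_over_distinct_haplotypes():
    s = summarize(_records([(100, 5), (300, 1)]))
    assert s.combined_length == 400  # not observation-weighted


@pytest.mark.parametrize(
    "obs,expected", [((3, 2, 1), -1.0), ((1, 2, 3), 1.0)]
)
def test_length_observation_correlation_signs(obs, expected):
    recs = _records(list(zip((1, 2, 3), obs)))
    assert length_observation_correlation(recs) == pytest.approx(expected)


def test_correlation_degenerate_signalled():
    with pytest.raises(ValueError):
        length_observation_correlation(_records([(1, 2), (2, 2)]))
    with pytest.raises(ValueError):
        length_observation_correlation(_records([(1, 2), (2, 2), (3, 2)]))


def test_count_gene_variants_overlap_rule():
    gene = GenomicInterval("chr1", 40, 60)
    sites = [
        VariantSite("chr1", p, "", r, ("A",) if r != "A" else ("C",))
        for p, r in [(10, "G"), (38, "GTTT"), (45, "G"), (60, "G"), (61, "G")]
    ]
    assert count_gene_variants(sites, gene) == 3  # 38 straddles, 45 and 60 inside
    assert count_gene_variants([], gene) == 0
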