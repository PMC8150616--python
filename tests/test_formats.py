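"""File format round-trips and reader filtering rules."""

import numpy as np
import pytest

from lcshap.formats import (
    read_catalogue,
    read_genotype_region,
    read_panel,
    read_reference_window,
    write_catalogue,
    write_fasta,
    write_panel,
)
from lcshap.genomic import CohortData, GenomicInterval
from lcshap.simulate import simulate_cohort

from conftest import random_small_config


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


def test_panel_round_trip(tmp_path):
    p = tmp_path / "toy.panel"
    write_panel(p, [("HG01", "LWK", "AFR"), ("HG02", "GBR", "EUR")])
    panel = read_panel(p)
    assert panel.population("HG01") == "LWK"
    assert panel.super_population("HG02") == "EUR"
    assert len(panel.samples) == 2


def test_panel_duplicate_sample_rejected(tmp_path):
    p = tmp_path / "dup.panel"
    p.write_text("sample\tpop\tsuper_pop\nA\tLWK\tAFR\nA\tGBR\tEUR\n")
    with pytest.raises(ValueError, match="more than once"):
        read_panel(p)


def test_panel_missing_column_rejected(tmp_path):
    p = tmp_path / "bad.panel"
    p.write_text("sample\tpop\nA\tLWK\n")
    with pytest.raises(ValueError, match="super_pop"):
        read_panel(p)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_reference_window_uppercases_and_slices(tmp_path):
    p = tmp_path / "ref.fa"
    p.write_text(">chr9\nacgtacgtac\n")
    assert read_reference_window(p, GenomicInterval("chr9", 1, 10)) == "ACGTACGTAC"
    assert read_reference_window(p, GenomicInterval("chr9", 3, 6)) == "GTAC"


def test_reference_window_excerpt_contig(tmp_path):
    # samtools-faidx style window record at real-scale coordinates
    p = tmp_path / "win.fa"
    p.write_text(">chr1:1001-1010\nAACCGGTTAA\n")
    assert read_reference_window(p, GenomicInterval("chr1", 1003, 1006)) == "CCGG"
    with pytest.raises(ValueError, match="covering"):
        read_reference_window(p, GenomicInterval("chr1", 999, 1004))


def test_reference_window_out_of_bounds(tmp_path):
    p = tmp_path / "ref.fa"
    p.write_text(">chr9\nACGT\n")
    with pytest.raises(ValueError):
        read_reference_window(p, GenomicInterval("chr9", 2, 9))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def test_vcf_round_trip_on_simulated_cohort(tmp_path):
    sim = simulate_cohort(random_small_config(7))
    paths = sim.write(tmp_path)
    res = read_genotype_region(paths["vcf"], sim.cohort.region)
    assert res.skipped == {}
    assert [s.pos for s in res.sites] == [s.pos for s in sim.cohort.sites]
    assert [s.ref for s in res.sites] == [s.ref for s in sim.cohort.sites]
    assert [s.alts for s in res.sites] == [s.alts for s in sim.cohort.sites]
    assert res.samples == sim.cohort.samples
    gm0, gm1 = sim.cohort.genotypes, res.genotypes
    assert np.array_equal(gm0.allele_a, gm1.allele_a)
    assert np.array_equal(gm0.allele_b, gm1.allele_b)
    assert np.array_equal(gm0.phased, gm1.phased)


def test_vcf_keep_samples_subsets_in_header_order(tmp_path):
    sim = simulate_cohort(random_small_config(8))
    paths = sim.write(tmp_path)
    wanted = {sim.cohort.samples[4], sim.cohort.samples[1]}
    res = read_genotype_region(paths["vcf"], sim.cohort.region, keep_samples=wanted)
    assert res.samples == [s for s in sim.cohort.samples if s in wanted]
    idx = [sim.cohort.samples.index(s) for s in res.samples]
    assert np.array_equal(res.genotypes.allele_a, sim.cohort.genotypes.allele_a[idx])


def _toy_vcf(tmp_path, body, fmt="GT"):
    p = tmp_path / "toy.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        f'##FORMAT=<ID={fmt},Number=1,Type=String,Description="x">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n" + body
    )
    return p


def test_vcf_symbolic_and_no_alt_records_skipped(tmp_path):
    body = (
        "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
        "chr1\t20\t.\tA\t<CN0>\t.\tPASS\t.\tGT\t0/1\n"
        "chr1\t30\t.\tA\t.\t.\tPASS\t.\tGT\t0/0\n"
    )
    res = read_genotype_region(_toy_vcf(tmp_path, body), GenomicInterval("chr1", 1, 100))
    assert [s.pos for s in res.sites] == [10]
    assert res.skipped == {"symbolic_or_non_acgt": 1, "no_alt": 1}


def test_vcf_without_gt_is_an_error(tmp_path):
    p = _toy_vcf(tmp_path, "chr1\t10\t.\tA\tC\t.\tPASS\t.\tDP\t3\n", fmt="DP")
    with pytest.raises(ValueError, match="GT"):
        read_genotype_region(p, GenomicInterval("chr1", 1, 100))


def test_vcf_absent_contig_is_an_error(tmp_path):
    p = _toy_vcf(tmp_path, "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
    with pytest.raises(ValueError, match="absent"):
        read_genotype_region(p, GenomicInterval("chrX", 1, 100))


def test_vcf_region_without_records_is_empty_not_an_error(tmp_path):
    p = _toy_vcf(tmp_path, "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
    res = read_genotype_region(p, GenomicInterval("chr1", 500, 600))
    assert res.sites == [] and res.samples == ["S1"]
    assert res.genotypes.n_sites == 0 and res.genotypes.n_samples == 1


def test_vcf_phase_separators_parsed_but_alleles_identical(tmp_path):
    body = "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\nchr1\t20\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
    res = read_genotype_region(_toy_vcf(tmp_path, body), GenomicInterval("chr1", 1, 100))
    assert res.genotypes.phased[0, 0] and not res.genotypes.phased[0, 1]
    assert res.genotypes.allele_a[0].tolist() == [0, 0]
    assert res.genotypes.allele_b[0].tolist() == [1, 1]


# ---------------------------------------------------------------------------
# catalogue
# ---------------------------------------------------------------------------


def _fixture_catalogue(sim):
    from lcshap.catalogue import deduplicate, population_breakdown
    from lcshap.extraction import extract_observations
    from lcshap.sequences import build_sequence

    c = sim.cohort
    obs = extract_observations(c, sim.config.gene)
    seqs = [build_sequence(c.reference, c.region, c.sites, o) for o in obs]
    records = deduplicate(obs, seqs)
    return population_breakdown(records, sim.panel)


def test_catalogue_write_read_round_trip(tmp_path, regression_sim):
    records = _fixture_catalogue(regression_sim)
    fa, meta = tmp_path / "h.fasta", tmp_path / "h.tsv"
    write_catalogue(records, fa, meta)
    back = read_catalogue(fa, meta)
    assert len(back) == len(records)
    for r0, r1 in zip(records, back):
        assert (r0.id, r0.span, r0.sequence, r0.length, r0.observations) == (
            r1.id, r1.span, r1.sequence, r1.length, r1.observations
        )
        assert r0.pop_counts == r1.pop_counts
        assert r0.superpop_counts == r1.superpop_counts


def test_empty_catalogue_writes_valid_files(tmp_path):
    fa, meta = tmp_path / "h.fasta", tmp_path / "h.tsv"
    write_catalogue([], fa, meta)
    assert fa.read_text() == ""
    assert meta.read_text().startswith("id\t")
    assert read_catalogue(fa, meta) == []
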