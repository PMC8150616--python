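"""Shared fixtures: tiny hand-built cohorts and simulator configs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from lcshap.genomic import CohortData, GenomicInterval, GenotypeMatrix, VariantSite
from lcshap.simulate import SimulationConfig, SiteSpec, simulate_cohort


def make_cohort(
    region: tuple[int, int],
    site_defs: list[tuple[int, str, tuple[str, ...]]],
    genotype_rows: list[list[tuple[int, int]]],
    reference: str | None = None,
    contig: str = "chr1",
    sample_names: list[str] | None = None,
) -> CohortData:
    """Hand-build a cohort; the reference defaults to all-A with REF bases
    patched in at each site's footprint."""
    iv = GenomicInterval(contig, *region)
    if reference is None:
        ref = ["A"] * iv.length
        for pos, r, _ in site_defs:
            for k, base in enumerate(r):
                ref[pos - iv.start + k] = base
        reference = "".join(ref)
    sites = [VariantSite(contig, pos, "", r, alts) for pos, r, alts in site_defs]
    samples = sample_names or [f"S{i + 1:02d}" for i in range(len(genotype_rows))]
    gm = GenotypeMatrix.from_pairs(genotype_rows)
    return CohortData(iv, reference, sites, samples, gm)


def random_small_config(seed: int) -> SimulationConfig:
    """A randomized small cohort: ~15 sites incl. indels, 10 samples,
    occasional missing calls — exercises every extraction code path."""
    rng = np.random.default_rng(seed)
    region = GenomicInterval("chr1", 1, 240)
    gene = GenomicInterval("chr1", 90, 150)
    positions = sorted(rng.choice(np.arange(6, 230, 7), size=15, replace=False))
    sites = []
    for pos in positions:
        kind = rng.choice(["snv", "snv", "snv", "ins", "del"])
        sites.append(
            SiteSpec(int(pos), freq=float(rng.uniform(0.05, 0.5)), kind=str(kind), size=2)
        )
    return SimulationConfig(
        region=region,
        gene=gene,
        sites=sites,
        n_samples=10,
        missing_rate=0.02 if seed % 3 == 0 else 0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def regression_sim():
    from lcshap.simulate import regression_fixture

    return regression_fixture()


@pytest.fixture()
def toy_extension_cohort():
    """Region 1-100, gene 40-60, het SNVs at 20 and 85, hom elsewhere:
    the expected span is [21, 84]."""
    return make_cohort(
        (1, 100),
        [(20, "A", ("C",)), (50, "A", ("G",)), (85, "A", ("T",))],
        [[(0, 1), (0, 0), (1, 0)]],
    )
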