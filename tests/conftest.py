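import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poolsweep.simulate import SimConfig, default_sweeps, simulate_dataset
from poolsweep.variant_io import PooledSiteCounts, SiteTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

POOLS = ("M", "FTPD", "LTPD", "CMD")


def make_site(counts, chrom="chr1", pos=100, ref="A", alt="C", **kw) -> PooledSiteCounts:
    """Site from a {pool: (ref, alt)} mapping, defaulting other fields."""
    return PooledSiteCounts(chrom=chrom, pos=pos, ref=ref, alt=alt, counts=dict(counts), **kw)


def random_table(rng: np.random.Generator, n: int, pools=POOLS) -> SiteTable:
    """Random site table with a mix of SNPs, indels and multi-allelic flags."""
    k = len(pools)
    depth = rng.integers(0, 80, size=(n, k))
    # sprinkle some extreme depths to exercise the depth rule
    extreme = rng.random((n, k)) < 0.02
    depth = np.where(extreme, rng.integers(400, 700, size=(n, k)), depth)
    alt = rng.binomial(depth, rng.random(n)[:, None])
    ref = depth - alt
    is_indel = rng.random(n) < 0.15
    indel_len = np.where(is_indel, rng.integers(1, 9, size=n), 0)
    return SiteTable(
        pools=tuple(pools),
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64) * 10,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["AC" if i else "C" for i in is_indel], dtype=object),
        ref_reads=ref.astype(np.int64),
        alt_reads=alt.astype(np.int64),
        is_indel=is_indel,
        indel_len=indel_len.astype(np.int64),
        is_biallelic=rng.random(n) > 0.1,
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_chroms=1, chrom_len=200_000,
        sweeps=default_sweeps(n_chroms=1, chrom_len=200_000, n_per_chrom=2),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config, with_genome=True)
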