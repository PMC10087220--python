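import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from neozscan import GenomeSpec, PlantedSegment, default_spec, simulate_genome
from neozscan.pipeline import RunConfig, run_all, scan_direct

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_sim():
    """The default toy ZW genome (seed 1): fully degenerate chrZ, two
    moderately degenerate translocated segments, one autosome."""
    return simulate_genome(default_spec(seed=1))


@pytest.fixture(scope="session")
def toy_stats(toy_sim):
    """Direct (chromosome-space) window scan of the toy genome at 100 kb."""
    return scan_direct(toy_sim)


@pytest.fixture(scope="session")
def small_sim():
    """A <=1 Mb simulation with one moderately degenerate segment, small
    enough for exhaustive per-site oracles."""
    spec = GenomeSpec(
        chromosomes=[("c1", 500_000), ("c2", 400_000)],
        segments=[PlantedSegment("c1", 100_000, 400_000, "SEXLINKED",
                                 w_retention=0.5, zw_divergence=2e-3)],
        seed=11, zw_insertion_rate=1e-4,
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full two-pass pipeline run on the toy genome (seed 1)."""
    outdir = tmp_path_factory.mktemp("toyrun")
    return run_all(RunConfig(outdir=outdir, seed=1, write_vcf=False))


def segment_windows(stats: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    return stats[(stats["seq"] == chrom) & (stats["start"] >= start) & (stats["end"] <= end)]


def mean_and_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    return float(values.mean()), float(values.std(ddof=0) / np.sqrt(len(values)))
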