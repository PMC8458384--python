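import numpy as np
import pytest

from secall.cli import run_callse
from secall.genome_io import GenomeDefinition, GenomicInterval
from secall.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def small_genome():
    return GenomeDefinition({"chr1": 10_000, "chr2": 6_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_928)


def random_intervals(rng, genome, n, max_len=500):
    """n random intervals over the genome, length in [1, max_len]."""
    out = []
    chroms = list(genome)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome[chrom] - length))
        strand = "+" if rng.integers(2) == 0 else "-"
        out.append(GenomicInterval(chrom, start, start + length, strand))
    return out


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle plus its full pipeline run, shared."""
    out = tmp_path_factory.mktemp("bundle")
    truth = simulate(SimulationConfig(seed=7), out)
    scored, curve, active, stitched = run_callse(
        out / "chip_reads.bed", out / "input_reads.bed", [out / "peaks.bed"],
        out / "genes.tsv", out / "blacklist.bed", out / "pipeline",
        out / "genome.tsv", write_tracks=False,
    )
    return {
        "dir": out, "truth": truth, "scored": scored, "curve": curve,
        "active": active, "stitched": stitched,
    }
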