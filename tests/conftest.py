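import numpy as np
import pandas as pd
import pytest

from methdyn.genome_io import Genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length: int, p_n: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, length)]
    if p_n > 0:
        seq[rng.random(length) < p_n] = "N"
    return "".join(seq)


@pytest.fixture
def small_genome(rng):
    return Genome(
        {
            "chr1": random_dna(rng, 5000),
            "chrC": random_dna(rng, 1000),
        },
        chloroplast={"chrC"},
    )


def make_counts(sites: pd.DataFrame, meth, unmeth) -> pd.DataFrame:
    """Counts table from a sites frame plus meth/unmeth vectors."""
    out = sites[["chrom", "pos", "strand", "context", "tri"]].copy()
    out["meth"] = meth
    out["unmeth"] = unmeth
    return out


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A miniature simulated study shared by integration-flavoured tests."""
    from methdyn.synthetic import PlantedDmrSpec, SimulationConfig, simulate_study

    outdir = tmp_path_factory.mktemp("study")
    cfg = SimulationConfig(
        seed=7,
        chrom_lengths={"chr1": 50_000, "chr2": 50_000},
        chloroplast_length=6_000,
        n_genes=30,
        n_mirna=6,
        n_mirna_dmfs=2,
        dmr_spec=PlantedDmrSpec(n_tissue=5, n_cultivar=5, n_drought=5),
    )
    manifest = simulate_study(cfg, outdir)
    return cfg, outdir, manifest
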