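import numpy as np
import pytest

import gametemeth as gm
from gametemeth import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """Single 150-kb autosome plus chrM/chrY/lambda; a fast shared fixture."""
    spec = gm.SyntheticGenomeSpec(n_autosomes=1, chrom_length=150_000,
                                  n_genes=8, n_cgis=15, seed=3)
    return gm.generate_genome(spec)


@pytest.fixture(scope="session")
def default_genome():
    """The default study-condition genome (~1.9 Mb over 3 autosomes)."""
    return gm.generate_genome(gm.SyntheticGenomeSpec(seed=11))


@pytest.fixture(scope="session")
def oocyte_methylome(default_genome):
    return gm.generate_true_methylome(default_genome, "oocyte",
                                      gm.MethylomeParams(seed=1))


@pytest.fixture(scope="session")
def sperm_methylome(default_genome):
    return gm.generate_true_methylome(default_genome, "sperm",
                                      gm.MethylomeParams(seed=2))


@pytest.fixture(scope="session")
def oocyte_calls(default_genome, oocyte_methylome):
    return sim.sample_calls_from_methylome(default_genome, oocyte_methylome,
                                           depth=15, failure_rate=0.01,
                                           seed=4)


@pytest.fixture(scope="session")
def sperm_calls(default_genome, sperm_methylome):
    return sim.sample_calls_from_methylome(default_genome, sperm_methylome,
                                           depth=15, failure_rate=0.01,
                                           seed=5)


def toy_genome_from_seq(seq: str, name: str = "chr1", **annotations):
    """Wrap a literal sequence into a Genome with empty annotations."""
    import pandas as pd

    genes = annotations.get("genes", pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "strand",
                 "exon_starts", "exon_ends", "expression_oocyte",
                 "expression_sperm"]))
    cgis = annotations.get("cgis", pd.DataFrame(
        columns=["cgi_id", "chrom", "start", "end", "placement",
                 "meth_class", "fate", "esc_fate"]))
    repeats = annotations.get("repeats", pd.DataFrame(
        columns=["chrom", "start", "end", "family"]))
    icrs = annotations.get("icrs", pd.DataFrame(
        columns=["icr_id", "chrom", "start", "end", "parent", "cgi_id"]))
    seqs = {name: seq} if isinstance(seq, str) else dict(seq)
    return gm.Genome(seqs, genes, cgis, repeats, icrs, lambda_name=None)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2])
    enc = np.searchsorted(cum, rng.random(n), side="right")
    return "".join("ACGT"[i] for i in enc)
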