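import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from smallrna_atlas import simdata


@pytest.fixture(scope="session")
def small_genome():
    """A small toy genome: enough features of every class to exercise the
    pipeline, small enough to simulate in seconds."""
    spec = simdata.GenomeSpec(
        n_chromosomes=2, chrom_length=400_000, n_mirna_loci=30,
        n_pirna_clusters=12, n_trna_genes=25, n_repeat_elements=8,
        n_exons=15, n_unannotated=8, seed=7)
    return simdata.make_genome(spec)


@pytest.fixture(scope="session")
def small_experiment(small_genome):
    """4 normal vs 4 tumor samples at depth 20k."""
    genome, tracks = small_genome
    design = simdata.default_design(n_normal=4, n_tumor=4)
    base = simdata.normal_params(depth=20_000.0)
    params = simdata.default_params_by_group(design["group"].unique(), base)
    reads, truth = simdata.simulate_experiment(genome, tracks, design,
                                               params, seed=11)
    return {"genome": genome, "tracks": tracks, "design": design,
            "reads": reads, "truth": truth, "params": params}


@pytest.fixture
def toy_reads():
    """Hand-written alignments on two strands of one chromosome."""
    rows = [
        ("chr1", 100, 130, "r1", 0, "+", "A" * 30),
        ("chr1", 200, 230, "r2", 0, "+", "C" * 30),
        ("chr1", 120, 150, "r3", 0, "+", "G" * 30),
        ("chr1", 100, 130, "r4", 0, "-", "T" * 30),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand", "seq"])
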