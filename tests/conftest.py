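import numpy as np
import pandas as pd
import pytest

from retrometh.annotate import Annotator
from retrometh.diffmeth import call_dmcs, dmc_test_all
from retrometh.methcall import CONTROL, EXPOSED, GroupDesign, unite_sites
from retrometh.synthetic import SynthConfig, generate_genome, simulate_counts


@pytest.fixture(scope="session")
def design_5v5() -> GroupDesign:
    groups = {f"control_{i}": CONTROL for i in range(1, 6)}
    groups.update({f"exposed_{i}": EXPOSED for i in range(1, 6)})
    return GroupDesign(groups)


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def genome(synth_config):
    return generate_genome(synth_config)


@pytest.fixture(scope="session")
def simulated(genome, synth_config):
    samples, truth = simulate_counts(genome, synth_config)
    return samples, truth


@pytest.fixture(scope="session")
def matrix(simulated, synth_config):
    samples, _ = simulated
    return unite_sites(samples, synth_config.design(),
                       synth_config.min_coverage)


@pytest.fixture(scope="session")
def dmc_table(matrix) -> pd.DataFrame:
    return call_dmcs(dmc_test_all(matrix))


@pytest.fixture(scope="session")
def annotated_sites(dmc_table, genome) -> pd.DataFrame:
    annotator = Annotator(genome.genes, genome.repeats)
    return annotator.annotate_sites(dmc_table)


def make_counts_matrix(design, chrom_pos, n_meth, n_total, min_coverage=10):
    """Build a MethylMatrix directly from arrays (test helper)."""
    from retrometh.methcall import MethylMatrix

    sites = pd.DataFrame(
        {"chrom": [c for c, _ in chrom_pos],
         "pos": [p for _, p in chrom_pos],
         "strand": "+"}
    )
    return MethylMatrix(sites, np.asarray(n_meth), np.asarray(n_total),
                        design, min_coverage)
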