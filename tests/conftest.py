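import numpy as np
import pandas as pd
import pytest

from scribpipe import synthio
from scribpipe.ipstats import SpectralCountTable

# the published pull-down spectral counts: bait row plus four prey proteins,
# WT and the two S1448 point mutants
TABLE2_COUNTS = {
    "SCRIB": (588, 920, 855),
    "VIM": (151, 277, 264),
    "NUMA1": (34, 8, 54),
    "GIT1": (20, 72, 66),
    "ARHGEF7": (11, 49, 60),
}
TABLE2_CHI2 = {"VIM": 0.043, "NUMA1": 34.78, "GIT1": 0.0, "ARHGEF7": 1.68}


@pytest.fixture(scope="session")
def table2() -> SpectralCountTable:
    counts = pd.DataFrame.from_dict(
        TABLE2_COUNTS, orient="index", columns=["WT", "S1448A", "S1448D"]
    )
    counts.index.name = "protein"
    return SpectralCountTable(counts=counts, bait="SCRIB")


@pytest.fixture(scope="session")
def consistent_profiles() -> list[np.ndarray]:
    """Two self-consistent usage profiles (exactly realizable from RPKM)."""
    return [
        synthio.usage_profile([3.0, 3.0, 1.0, 1.0, 1.0]),
        synthio.usage_profile([1.0, 1.0, 1.0, 3.0, 3.0]),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """120 patients, two well-separated clusters, deterministic."""
    spec = synthio.CohortSpec(
        n_patients=120,
        n_exons=37,
        cluster_sizes=(60, 60),
        cluster_profiles=synthio.default_cluster_profiles(37)[:2],
        hazards=(5e-4, 1e-4),
        usage_noise_sd=0.5,
        seed=11,
    )
    return synthio.gen_exon_cohort(spec)
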