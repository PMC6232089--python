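import numpy as np
import pandas as pd
import pytest

from radgen.genome import GenomeTemplate
from radgen.synthetic import CnaImplant, SyntheticCohortSpec, generate_probe_tracks


@pytest.fixture(scope="session")
def mini_template() -> GenomeTemplate:
    """Three short chromosomes at high probe density: fast CBS tests with
    enough probes per implant."""
    return GenomeTemplate(
        chromosomes=(("chr1", 80_000_000), ("chr2", 60_000_000),
                     ("chr3", 50_000_000)),
        probe_density=5.0,
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_template):
    """Two patients, 4 tumor + 2 reference cores each, fixed implants,
    noise-free — exact ground truth for every downstream stage."""
    implants = {
        "P01_T01": [CnaImplant("chr1", 5_000_000, 35_000_000, -0.5),
                    CnaImplant("chr2", 10_000_000, 30_000_000, 0.4)],
        "P01_T02": [CnaImplant("chr1", 5_000_000, 35_000_000, -0.5)],
        "P01_T03": [],
        "P01_T04": [CnaImplant("chr3", 2_000_000, 14_000_000, 0.3)],
        "P02_T01": [CnaImplant("chr2", 20_000_000, 55_000_000, -0.35)],
        "P02_T02": [],
        "P02_T03": [CnaImplant("chr1", 40_000_000, 75_000_000, -0.3),
                    CnaImplant("chr3", 5_000_000, 45_000_000, 0.45)],
        "P02_T04": [],
    }
    spec = SyntheticCohortSpec(n_patients=2, cores_per_patient=(4, 4),
                               n_reference_cores=2, noise_sd=0.0, seed=11)
    return generate_probe_tracks(spec, mini_template, implants), implants


def make_track(values, spacing_bp=1_000_000, chrom="chr1", core_id="core"):
    """Helper: a single-chromosome ProbeTrack from raw log2 ratios."""
    from radgen.cna import ProbeTrack

    values = np.asarray(values, dtype=float)
    return ProbeTrack(core_id, pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(len(values)) * spacing_bp,
        "log2_ratio": values,
    }))
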