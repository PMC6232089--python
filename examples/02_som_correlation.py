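"""400-metagene SOM compression and pairwise sample correlation.

Trains a 20x20 self-organizing map on the per-probe log2-ratio matrix of a
synthetic cohort and prints the mean within- vs between-patient sample
correlation — patient-shared trunk CNAs make cores from the same prostate
correlate, which is the patient-wise clustering seen in such cohorts.
"""

import numpy as np
import pandas as pd

from radgen import (SomConfig, SyntheticCohortSpec, compute_log_ratio,
                    generate_probe_tracks, som_sample_correlation)

cohort = generate_probe_tracks(
    SyntheticCohortSpec(n_patients=3, cores_per_patient=(5, 6), seed=7))

columns = {}
for pid in cohort.patients:
    refs = [cohort.intensities[r] for r in cohort.reference_cores(pid)]
    for cid in cohort.tumor_cores(pid):
        track = compute_log_ratio(cohort.intensities[cid], refs, core_id=cid)
        columns[cid] = track.table["log2_ratio"].to_numpy()

corr = som_sample_correlation(pd.DataFrame(columns), SomConfig(seed=7))
ids = list(columns)
within, between = [], []
for i, a in enumerate(ids):
    for b in ids[i + 1:]:
        (within if a.split("_")[0] == b.split("_")[0] else between).append(
            corr.loc[a, b])
print(f"samples: {len(ids)}  metagenes: 400")
print(f"mean within-patient correlation : {np.mean(within):+.3f}")
print(f"mean between-patient correlation: {np.mean(between):+.3f}")
# within >> between: cores of one prostate share trunk CNAs, so their
# metagene profiles correlate while different patients' cores do not.
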