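"""Radiomic extraction and patient-corrected clustering on texture phantoms.

Generates seven co-registered parameter maps with aggressive/indolent VOI
textures and per-patient batch offsets, extracts the 2,352-feature radiomic
profile per VOI, removes indeterminate/zero-variance columns, standardizes,
subtracts patient-specific intercepts and clusters with Ward's D linkage on
correlation distance.
"""

from sklearn.metrics import adjusted_rand_score

from radgen import (ImagePhantomSpec, extract_feature_matrix, filter_features,
                    generate_texture_phantoms, patient_center,
                    ward_correlation_cluster)

labels, patients = {}, {}
for p in range(3):
    for i in range(6):
        vid = f"P{p}_v{i}"
        labels[vid] = "aggressive" if i < 3 else "indolent"
        patients[vid] = f"P{p}"

maps, masks, _ = generate_texture_phantoms(
    ImagePhantomSpec(seed=5), labels,
    patient_of_voi=patients, patient_offset_sd=0.8)

features = extract_feature_matrix([(maps, m) for m in masks])
print(f"feature matrix: {features.shape[0]} VOIs x {features.shape[1]} features")

filtered, report = filter_features(features)
print(f"filter: removed {report.n_removed}, retained {report.n_retained}")

centered = patient_center(filtered, [patients[v] for v in filtered.index])
result = ward_correlation_cluster(centered, k=2)
truth = [1 if labels[v] == "aggressive" else 0 for v in centered.index]
ari = adjusted_rand_score(truth, result.labels.to_numpy())
print(f"adjusted Rand index vs planted classes: {ari:.2f}")
for v in centered.index:
    print(f"  {v}: cluster {result.labels[v]} ({labels[v]})")
# ARI 1.0 means the two clusters reproduce the planted aggressive/indolent
# split exactly, despite the per-patient intercepts that were removed.
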