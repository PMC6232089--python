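"""Patient-corrected clustering of radiomic features and ADC group summaries.

The analysis chain: drop indeterminate and zero-variance feature columns,
z-standardize, remove a patient-specific intercept per feature (patients
treated as batches), then cluster VOIs by Ward's D linkage on correlation
distance (1 - Pearson r between feature rows) and read cluster composition
against the genomic aggressiveness annotations (hsMut / hiLes / MolTu).
A separate helper summarizes mean VOI ADC by aggressiveness grouping with
a rank test, mirroring the ADC-vs-aggressiveness comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FilterReport:
    n_input_features: int
    n_removed: int
    n_retained: int
    removal_reason: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_input_features == self.n_removed + self.n_retained


def filter_features(matrix: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop columns with any indeterminate (NaN) value or zero variance.

    Removal reasons are mutually exclusive: a column with a NaN is
    'indeterminate' regardless of its variance; an all-finite column with
    exactly zero variance across rows is 'zero_variance'.
    """
    if len(matrix) < 2:
        raise ValueError("filter_features requires >= 2 rows")
    reasons: dict[str, str] = {}
    keep: list[str] = []
    for col in matrix.columns:
        vals = matrix[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            reasons[col] = "indeterminate"
        elif np.ptp(vals) == 0.0:
            reasons[col] = "zero_variance"
        else:
            keep.append(col)
    if not keep:
        raise ValueError("all feature columns were removed")
    report = FilterReport(
        n_input_features=matrix.shape[1],
        n_removed=len(reasons),
        n_retained=len(keep),
        removal_reason=reasons)
    return matrix[keep].copy(), report


def patient_center(matrix: pd.DataFrame, patient_ids: pd.Series | list[str],
                   standardize: bool = True) -> pd.DataFrame:
    """Remove a patient-specific intercept per feature.

    Columns are first z-scored across all VOIs (configurable), then each
    patient's mean is subtracted from that patient's rows. Patients
    contributing a single VOI are centered to exactly zero (flagged).
    """
    pid = pd.Series(list(patient_ids), index=matrix.index, name="patient")
    if pid.isna().any():
        raise ValueError("every row needs a patient id")
    x = matrix.astype(float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd = sd.replace(0.0, 1.0)
        x = (x - x.mean(axis=0)) / sd
    singles = pid.value_counts()
    lonely = singles[singles == 1].index.tolist()
    if lonely:
        warnings.warn(f"patients with a single VOI are centered to zero: "
                      f"{lonely}", stacklevel=2)
    return x - x.groupby(pid).transform("mean")


# ---------------------------------------------------------------------------
# Ward.D on correlation distance
# ---------------------------------------------------------------------------

def correlation_distance(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """d(i, j) = 1 - Pearson r between feature rows i and j."""
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) \
        else np.asarray(matrix, dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        rows = np.nonzero(sd == 0)[0].tolist()
        ids = ([matrix.index[i] for i in rows]
               if isinstance(matrix, pd.DataFrame) else rows)
        raise ValueError(f"zero-variance rows have undefined correlation: {ids}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ClusterResult:
    """Agglomerative tree + flat labels at the requested cut."""

    merges: list[tuple[int, int]]   # cluster indices merged at each step
    heights: list[float]
    labels: pd.Series               # row id -> cluster label 1..k
    k: int
    linkage_matrix: np.ndarray      # scipy-style (n-1, 4)


def ward_correlation_cluster(matrix: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Ward's D hierarchical clustering on correlation distance.

    The Ward-coefficient Lance-Williams recurrence
    ``d(m, i∪j) = [(n_i+n_m) d(m,i) + (n_j+n_m) d(m,j) - n_m d(i,j)] / N``
    (N = n_i+n_j+n_m) is applied directly to the supplied 1 - r distances
    — the hclust "ward.D" convention, no pre-squaring. Ties break on the
    lowest (i, j) cluster-index pair. The k-cluster cut undoes the last
    k - 1 merges (cutree semantics, robust to height inversions).
    """
    n = len(matrix)
    if n < k:
        raise ValueError(f"cannot cut {n} rows into {k} clusters")
    d = correlation_distance(matrix)

    size = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]

    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), h = best
        merges.append((i, j))
        heights.append(h)
        ni, nj = size[i], size[j]
        new = next_id
        next_id += 1
        members[new] = members.pop(i) + members.pop(j)
        for m in active:
            if m in (i, j):
                continue
            nm = size[m]
            dmi = dist.pop((min(i, m), max(i, m)))
            dmj = dist.pop((min(j, m), max(j, m)))
            val = ((ni + nm) * dmi + (nj + nm) * dmj - nm * h) / (ni + nj + nm)
            dist[(min(m, new), max(m, new))] = val
        dist.pop((i, j))
        active = [m for m in active if m not in (i, j)] + [new]
        size[new] = ni + nj
        linkage[step] = [i, j, h, ni + nj]

    # cutree: labels from the partition after undoing the last k-1 merges
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    cid = n
    for (i, j) in merges[: n - k]:
        clusters[cid] = clusters.pop(i) + clusters.pop(j)
        cid += 1
    labels = np.zeros(n, dtype=int)
    # label clusters 1..k in order of their smallest row index
    groups = sorted(clusters.values(), key=min)
    for lab, rows in enumerate(groups, start=1):
        for r in rows:
            labels[r] = lab
    return ClusterResult(
        merges=merges, heights=heights,
        labels=pd.Series(labels, index=matrix.index, name="cluster"),
        k=k, linkage_matrix=linkage)


def cluster_composition(result: ClusterResult,
                        annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster composition of the aggressiveness annotations.

    ``annotations`` is indexed like the clustered matrix with columns
    hsMut (int), hiLes (bool), MolTu (bool) and optionally patient_id.
    """
    ann = annotations.loc[result.labels.index].copy()
    ann["cluster"] = result.labels
    rows = []
    for lab, grp in ann.groupby("cluster"):
        row = {
            "cluster": lab,
            "n_vois": len(grp),
            "hiLes_count": int(grp["hiLes"].sum()),
            "MolTu_count": int(grp["MolTu"].sum()),
            "MolTu_fraction": float(grp["MolTu"].mean()),
            "hsMut_mean": float(grp["hsMut"].mean()),
            "hsMut_max": int(grp["hsMut"].max()),
        }
        if "patient_id" in grp:
            row["n_patients"] = grp["patient_id"].nunique()
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# ADC group summaries
# ---------------------------------------------------------------------------

def adc_group_summary(adc_means: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Mean-VOI-ADC summaries per group with a two-sided rank test.

    Two groups: Mann-Whitney U; more: Kruskal-Wallis. The p-value is
    attached to every row (column ``p_value``). Groupings in use: MolTu
    (tumor signature yes/no), Gleason class, and hsMut > 4 (strictly).
    """
    df = pd.DataFrame({"adc": adc_means.astype(float), "group": groups})
    df = df.dropna()
    parts = [g["adc"].to_numpy() for _, g in df.groupby("group")]
    if len(parts) < 2 or any(len(p) == 0 for p in parts):
        raise ValueError("need >= 2 non-empty groups")
    if len(parts) == 2:
        stat = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided")
        p = float(stat.pvalue)
    else:
        p = float(stats.kruskal(*parts).pvalue)
    out = df.groupby("group")["adc"].agg(n="size", mean="mean", median="median")
    out["p_value"] = p
    return out


def hsmut_over4(hs_mut: pd.Series) -> pd.Series:
    """The 'more than 4 highly significant mutations' grouping (strict >)."""
    return (hs_mut > 4).map({True: "hsMut>4", False: "hsMut<=4"})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def plot_cluster_heatmap(matrix: pd.DataFrame, result: ClusterResult,
                         annotations: pd.DataFrame, path: str) -> None:
    """Feature heatmap with annotation side bars (patNo, hsMut, hiLes, MolTu),
    rows ordered by cluster then patient."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ann = annotations.loc[matrix.index].copy()
    ann["cluster"] = result.labels
    order = ann.sort_values(["cluster", "patient_id"]).index
    x = matrix.loc[order]
    ann = ann.loc[order]

    fig, axes = plt.subplots(
        1, 2, figsize=(10, 6), gridspec_kw={"width_ratios": [20, 2]})
    vmax = np.nanpercentile(np.abs(x.to_numpy()), 98) or 1.0
    axes[0].imshow(x.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, interpolation="nearest")
    axes[0].set_xlabel("radiomic features")
    axes[0].set_yticks(range(len(order)))
    axes[0].set_yticklabels(order, fontsize=5)

    pats = ann["patient_id"].astype("category").cat.codes.to_numpy()
    side = np.stack([
        pats / max(pats.max(), 1),
        ann["hsMut"].to_numpy() / max(ann["hsMut"].max(), 1),
        ann["hiLes"].astype(float).to_numpy(),
        ann["MolTu"].astype(float).to_numpy(),
    ], axis=1)
    axes[1].imshow(side, aspect="auto", cmap="viridis", interpolation="nearest")
    axes[1].set_xticks(range(4))
    axes[1].set_xticklabels(["patNo", "hsMut", "hiLes", "MolTu"],
                            rotation=90, fontsize=7)
    axes[1].set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
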