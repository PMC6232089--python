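"""3D radiomic feature extraction over VOI masks.

Per parameter map, a VOI yields 21 first-order features plus 315 texture
features — 15 neighbourhood gray-level difference (NGLDM), 90 run-length
(RLM), 168 gray-level co-occurrence (GLCM) and 42 size-zone (SZM) — i.e.
336 per map and 2,352 across the seven maps (T2w, ADC1500, B1500, Ktrans,
Kep, ve, vp). The per-family decomposition is frozen in the feature
manifest:

* GLCM: 12 base features x (13 unique 3D directions at distance 1 + their
  directional mean).
* RLM: 15 base features x 6 aggregations (per-direction mean/std/min/max/
  range over the 13 directions + the merged all-direction matrix).
* SZM: 14 base features x 3 gray-level re-binnings (8, 16, 32 levels,
  26-connected zones).
* NGLDM: 5 coarseness-family features x 3 Chebyshev neighbourhood radii.

Indeterminate values (divisions by zero, e.g. GLCM correlation on a single
gray level) propagate as NaN — never as 0 — so the downstream feature
filter can count and remove them. Texture offsets are in voxel units;
anisotropic spacing is ignored for offsets (first-order total energy does
use the physical voxel volume).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .maps import MapVolume, VoiMask

MAP_ORDER = ("T2w", "ADC1500", "B1500", "Ktrans", "Kep", "ve", "vp")

# 13 unique direction offsets in 3D (first non-zero component positive)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)
assert len(DIRECTIONS) == 13

FIRSTORDER_NAMES = (
    "mean", "median", "variance", "stddev", "minimum", "maximum", "range",
    "p10", "p90", "iqr", "skewness", "kurtosis", "energy", "total_energy",
    "rms", "mad", "rmad", "cov", "uniformity", "entropy", "mode",
)
GLCM_BASE = (
    "contrast", "correlation", "energy", "entropy", "homogeneity",
    "dissimilarity", "cluster_shade", "cluster_prominence",
    "max_probability", "sum_average", "sum_entropy", "difference_entropy",
)
RLM_BASE = (
    "sre", "lre", "gln", "glnn", "rln", "rlnn", "rp", "glv", "rv",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)
RLM_AGGS = ("mean", "std", "min", "max", "range", "merged")
SZM_BASE = (
    "sze", "lze", "gln", "glnn", "szn", "sznn", "zp", "glv", "zv",
    "lglze", "hglze", "szlgle", "szhgle", "lzlgle",
)
SZM_REBINS = (8, 16, 32)
NGLDM_BASE = ("coarseness", "contrast", "busyness", "complexity", "strength")
NGLDM_RADII = (1, 2, 3)

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class QuantizedVoi:
    """Gray-level codes 1..ng on the VOI (0 outside the mask)."""

    codes: np.ndarray
    mask: np.ndarray
    ng: int
    mode: str = "fixed_bin_count"

    @property
    def in_mask_codes(self) -> np.ndarray:
        return self.codes[self.mask]


def quantize(values: np.ndarray, mask: np.ndarray, ng: int = 32,
             mode: str = "fixed_bin_count") -> QuantizedVoi:
    """Equal-width fixed-bin-count discretization over the in-mask range.

    A constant VOI maps every voxel to code 1.
    """
    if mode != "fixed_bin_count":
        raise ValueError(f"unknown quantization mode {mode!r}")
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < 2:
        raise ValueError("quantize requires >= 2 in-mask voxels")
    vals = np.asarray(values, dtype=float)
    inm = vals[mask]
    lo, hi = float(inm.min()), float(inm.max())
    codes = np.zeros(vals.shape, dtype=np.int32)
    if hi == lo:
        codes[mask] = 1
    else:
        c = np.floor((vals[mask] - lo) / (hi - lo) * ng).astype(np.int32) + 1
        codes[mask] = np.clip(c, 1, ng)
    return QuantizedVoi(codes=codes, mask=mask, ng=ng, mode=mode)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def firstorder_features(values: np.ndarray, voxel_volume: float = 1.0,
                        ng: int = 32) -> dict[str, float]:
    """21 first-order statistics of the in-mask voxel intensities.

    Moments use population (ddof=0) conventions; kurtosis is the Pearson
    (non-excess) form. Uniformity, entropy (bits) and mode come from an
    ``ng``-bin equal-width histogram over the value range. Undefined
    moments on a zero-variance VOI are NaN.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("firstorder_features requires >= 2 voxels")
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, p90 = (float(v) for v in np.percentile(x, [10, 90]))
    q1, q3 = (float(v) for v in np.percentile(x, [25, 75]))
    if var > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    else:
        skew = kurt = float("nan")
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if len(robust) else float("nan")
    energy = float(np.sum(x ** 2))
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        counts, edges = np.histogram(x, bins=ng, range=(lo, hi))
        p = counts / counts.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
        mode = float(centers[int(np.argmax(counts))])
    else:
        p = np.array([1.0])
        mode = lo
    pz = p[p > 0]
    return {
        "mean": mean, "median": float(np.median(x)), "variance": var,
        "stddev": sd, "minimum": lo, "maximum": hi, "range": hi - lo,
        "p10": p10, "p90": p90, "iqr": q3 - q1,
        "skewness": skew, "kurtosis": kurt,
        "energy": energy, "total_energy": energy * voxel_volume,
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "mad": float(np.abs(x - mean).mean()), "rmad": rmad,
        "cov": sd / mean if mean != 0 else float("nan"),
        "uniformity": float(np.sum(p ** 2)),
        "entropy": float(-np.sum(pz * np.log2(pz))),
        "mode": mode,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedVoi, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one voxel offset."""
    codes, mask, ng = q.codes, q.mask, q.ng
    src, dst = [], []
    for o, size in zip(offset, codes.shape):
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    a = codes[tuple(src)]
    b = codes[tuple(dst)]
    both = mask[tuple(src)] & mask[tuple(dst)]
    mat = np.zeros((ng, ng), dtype=float)
    if np.any(both):
        np.add.at(mat, (a[both] - 1, b[both] - 1), 1.0)
    return mat + mat.T


def _glcm_feature_values(mat: np.ndarray) -> dict[str, float]:
    total = mat.sum()
    if total == 0:
        return {k: float("nan") for k in GLCM_BASE}
    p = mat / total
    ng = p.shape[0]
    levels = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    px = p.sum(axis=1)
    mu = float((levels * px).sum())
    var = float(((levels - mu) ** 2 * px).sum())
    pz = p[p > 0]
    out = {
        "contrast": float((p * (ii - jj) ** 2).sum()),
        "dissimilarity": float((p * np.abs(ii - jj)).sum()),
        "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "energy": float((p ** 2).sum()),
        "entropy": float(-(pz * np.log2(pz)).sum()),
        "max_probability": float(p.max()),
        "cluster_shade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "cluster_prominence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
    }
    if var > 0:
        out["correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / var)
    else:
        out["correlation"] = float("nan")
    # sum / difference distributions
    psum = np.zeros(2 * ng + 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    k = np.arange(2 * ng + 1, dtype=float)
    out["sum_average"] = float((k * psum).sum())
    ps = psum[psum > 0]
    out["sum_entropy"] = float(-(ps * np.log2(ps)).sum())
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    pd_ = pdiff[pdiff > 0]
    out["difference_entropy"] = float(-(pd_ * np.log2(pd_)).sum())
    return out


def glcm_features(q: QuantizedVoi) -> dict[str, float]:
    """168 GLCM values: 12 base features per direction (13) + their mean."""
    per_dir: list[dict[str, float]] = [
        _glcm_feature_values(glcm_matrix(q, off)) for off in DIRECTIONS]
    out: dict[str, float] = {}
    for d, feats in enumerate(per_dir, start=1):
        for name in GLCM_BASE:
            out[f"{name}_d{d:02d}"] = feats[name]
    for name in GLCM_BASE:
        out[f"{name}_mean"] = float(np.mean([f[name] for f in per_dir]))
    return out


# ---------------------------------------------------------------------------
# run length
# ---------------------------------------------------------------------------

def rlm_matrix(q: QuantizedVoi, offset: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts R[gray, length] along one direction.

    A run is a maximal sequence of consecutive in-mask voxels with equal
    gray code; out-of-mask voxels terminate runs.
    """
    codes, mask, ng = q.codes, q.mask, q.ng
    shape = codes.shape
    max_len = int(np.ceil(np.sqrt(sum(s ** 2 for s in shape)))) + 1
    mat = np.zeros((ng, max_len + 1), dtype=float)
    off = np.array(offset)

    # line starts: voxels whose predecessor along -offset is out of bounds
    idx = np.indices(shape).reshape(3, -1).T
    prev = idx - off
    oob = ((prev < 0) | (prev >= np.array(shape))).any(axis=1)
    for start in idx[oob]:
        p = start.copy()
        run_code, run_len = 0, 0
        while np.all((p >= 0) & (p < shape)):
            t = tuple(p)
            c = codes[t] if mask[t] else 0
            if c == run_code and c != 0:
                run_len += 1
            else:
                if run_code != 0:
                    mat[run_code - 1, run_len] += 1
                run_code, run_len = c, (1 if c != 0 else 0)
            p += off
        if run_code != 0:
            mat[run_code - 1, run_len] += 1
    return mat


def _rlm_feature_values(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = mat.sum()
    if nr == 0:
        return {k: float("nan") for k in RLM_BASE}
    ng, nl = mat.shape
    g = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(nl, dtype=float)[None, :]
    l[l == 0] = 1.0  # length-0 column is always empty; avoid 0-division
    p = mat / nr
    rg = mat.sum(axis=1)
    rl = mat.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_l = float((p * l).sum())
    return {
        "sre": float((mat / l ** 2).sum() / nr),
        "lre": float((mat * l ** 2).sum() / nr),
        "gln": float((rg ** 2).sum() / nr),
        "glnn": float((rg ** 2).sum() / nr ** 2),
        "rln": float((rl ** 2).sum() / nr),
        "rlnn": float((rl ** 2).sum() / nr ** 2),
        "rp": float(nr / n_voxels),
        "glv": float((p * (g - mu_g) ** 2).sum()),
        "rv": float((p * (l - mu_l) ** 2).sum()),
        "lglre": float((mat / g ** 2).sum() / nr),
        "hglre": float((mat * g ** 2).sum() / nr),
        "srlgle": float((mat / (g ** 2 * l ** 2)).sum() / nr),
        "srhgle": float((mat * g ** 2 / l ** 2).sum() / nr),
        "lrlgle": float((mat * l ** 2 / g ** 2).sum() / nr),
        "lrhgle": float((mat * g ** 2 * l ** 2).sum() / nr),
    }


def rlm_features(q: QuantizedVoi) -> dict[str, float]:
    """90 run-length values: 15 base features x 6 aggregations."""
    n_vox = int(q.mask.sum())
    mats = [rlm_matrix(q, off) for off in DIRECTIONS]
    per_dir = [_rlm_feature_values(m, n_vox) for m in mats]
    merged = _rlm_feature_values(sum(mats), n_vox)
    out: dict[str, float] = {}
    for name in RLM_BASE:
        vals = np.array([f[name] for f in per_dir])
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_std"] = float(vals.std())
        out[f"{name}_min"] = float(vals.min())
        out[f"{name}_max"] = float(vals.max())
        out[f"{name}_range"] = float(vals.max() - vals.min())
        out[f"{name}_merged"] = merged[name]
    return out


# ---------------------------------------------------------------------------
# size zone
# ---------------------------------------------------------------------------

def szm_matrix(codes: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Zone counts Z[gray, size] with 26-connected zones."""
    sizes: dict[tuple[int, int], int] = {}
    max_size = int(mask.sum())
    mat = np.zeros((ng, max_size + 1), dtype=float)
    for g in range(1, ng + 1):
        level = (codes == g) & mask
        if not level.any():
            continue
        labels, nlab = ndimage.label(level, structure=_STRUCT26)
        if nlab:
            counts = np.bincount(labels.ravel())[1:]
            for s in counts:
                mat[g - 1, int(s)] += 1
    return mat


def _szm_feature_values(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = mat.sum()
    if nz == 0:
        return {k: float("nan") for k in SZM_BASE}
    ng, ns = mat.shape
    g = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(ns, dtype=float)[None, :]
    s[s == 0] = 1.0  # size-0 column always empty
    p = mat / nz
    zg = mat.sum(axis=1)
    zs = mat.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_s = float((p * s).sum())
    return {
        "sze": float((mat / s ** 2).sum() / nz),
        "lze": float((mat * s ** 2).sum() / nz),
        "gln": float((zg ** 2).sum() / nz),
        "glnn": float((zg ** 2).sum() / nz ** 2),
        "szn": float((zs ** 2).sum() / nz),
        "sznn": float((zs ** 2).sum() / nz ** 2),
        "zp": float(nz / n_voxels),
        "glv": float((p * (g - mu_g) ** 2).sum()),
        "zv": float((p * (s - mu_s) ** 2).sum()),
        "lglze": float((mat / g ** 2).sum() / nz),
        "hglze": float((mat * g ** 2).sum() / nz),
        "szlgle": float((mat / (g ** 2 * s ** 2)).sum() / nz),
        "szhgle": float((mat * g ** 2 / s ** 2).sum() / nz),
        "lzlgle": float((mat * s ** 2 / g ** 2).sum() / nz),
    }


def _rebin_codes(codes: np.ndarray, mask: np.ndarray, ng: int, target: int) -> np.ndarray:
    """Coarsen gray codes 1..ng to 1..target (ceil mapping)."""
    if target >= ng:
        return codes
    out = np.zeros_like(codes)
    out[mask] = np.ceil(codes[mask] * target / ng).astype(codes.dtype)
    return out


def szm_features(q: QuantizedVoi) -> dict[str, float]:
    """42 size-zone values: 14 base features x 3 gray-level re-binnings."""
    n_vox = int(q.mask.sum())
    out: dict[str, float] = {}
    for target in SZM_REBINS:
        ng = min(target, q.ng)
        codes = _rebin_codes(q.codes, q.mask, q.ng, ng)
        feats = _szm_feature_values(szm_matrix(codes, q.mask, ng), n_vox)
        for name in SZM_BASE:
            out[f"{name}_ng{target}"] = feats[name]
    return out


# ---------------------------------------------------------------------------
# NGLDM (neighbourhood gray-level difference)
# ---------------------------------------------------------------------------

def _ngldm_feature_values(q: QuantizedVoi, radius: int) -> dict[str, float]:
    codes, mask, ng = q.codes, q.mask, q.ng
    # mean neighbour code within the Chebyshev-radius box, mask-aware
    size = 2 * radius + 1
    kernel = np.ones((size, size, size))
    kernel[radius, radius, radius] = 0.0
    vals = np.where(mask, codes, 0).astype(float)
    nb_sum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0.5)
    n = int(valid.sum())
    if n == 0:
        return {k: float("nan") for k in NGLDM_BASE}
    a_bar = nb_sum[valid] / nb_cnt[valid]
    code_v = codes[valid].astype(float)
    s = np.zeros(ng)
    cnt = np.zeros(ng)
    np.add.at(s, codes[valid] - 1, np.abs(code_v - a_bar))
    np.add.at(cnt, codes[valid] - 1, 1.0)
    p = cnt / n
    present = p > 0
    levels = np.arange(1, ng + 1, dtype=float)
    ngp = int(present.sum())

    ps = float((p * s).sum())
    out: dict[str, float] = {}
    out["coarseness"] = 1.0 / ps if ps > 0 else float("nan")
    if ngp > 1:
        pi = p[present]
        li = levels[present]
        si = s[present]
        dif2 = (li[:, None] - li[None, :]) ** 2
        out["contrast"] = float(
            (pi[:, None] * pi[None, :] * dif2).sum()
            / (ngp * (ngp - 1)) * s.sum() / n)
        denom = float(np.abs(li[:, None] * pi[:, None]
                             - li[None, :] * pi[None, :]).sum())
        out["busyness"] = ps / denom if denom > 0 else float("nan")
        out["complexity"] = float(
            (np.abs(li[:, None] - li[None, :])
             * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
             / (pi[:, None] + pi[None, :])).sum() / n)
        ssum = float(s.sum())
        out["strength"] = (float(((pi[:, None] + pi[None, :]) * dif2).sum())
                           / ssum if ssum > 0 else float("nan"))
    else:
        out["contrast"] = 0.0
        out["busyness"] = float("nan")
        out["complexity"] = 0.0
        out["strength"] = float("nan")
    return out


def ngldm_features(q: QuantizedVoi) -> dict[str, float]:
    """15 NGLDM values: 5 coarseness-family features x 3 neighbourhood radii."""
    out: dict[str, float] = {}
    for r in NGLDM_RADII:
        feats = _ngldm_feature_values(q, r)
        for name in NGLDM_BASE:
            out[f"{name}_d{r}"] = feats[name]
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def per_map_feature_names() -> list[tuple[str, str]]:
    """The 336 (family, name) descriptors computed per map, in fixed order."""
    names: list[tuple[str, str]] = [("firstorder", n) for n in FIRSTORDER_NAMES]
    for d in range(1, 14):
        for n in GLCM_BASE:
            names.append(("glcm", f"{n}_d{d:02d}"))
    for n in GLCM_BASE:
        names.append(("glcm", f"{n}_mean"))
    for n in RLM_BASE:
        for agg in RLM_AGGS:
            names.append(("rlm", f"{n}_{agg}"))
    for target in SZM_REBINS:
        for n in SZM_BASE:
            names.append(("szm", f"{n}_ng{target}"))
    for r in NGLDM_RADII:
        for n in NGLDM_BASE:
            names.append(("ngldm", f"{n}_d{r}"))
    return names


def feature_manifest() -> pd.DataFrame:
    """All 2,352 feature descriptors (map, family, name, column)."""
    rows = []
    for kind in MAP_ORDER:
        for family, name in per_map_feature_names():
            rows.append((kind, family, name, f"{kind}|{family}|{name}"))
    return pd.DataFrame(rows, columns=["map", "family", "name", "column"])


def extract_map_features(volume: MapVolume, mask: VoiMask,
                         ng: int = 32) -> dict[str, float]:
    """336 features of one VOI on one map, keyed ``family|name``."""
    if volume.data.shape != mask.mask.shape:
        raise ValueError("map and mask shapes differ")
    # crop to the mask bounding box: texture statistics only involve
    # in-mask voxels, so this is exact, not an approximation
    idx = np.nonzero(mask.mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    vals = volume.data[box]
    m = mask.mask[box]

    q = quantize(vals, m, ng=ng)
    out: dict[str, float] = {}
    fo = firstorder_features(vals[m], voxel_volume=volume.voxel_volume, ng=ng)
    for name in FIRSTORDER_NAMES:
        out[f"firstorder|{name}"] = fo[name]
    for key, val in glcm_features(q).items():
        out[f"glcm|{key}"] = val
    for key, val in rlm_features(q).items():
        out[f"rlm|{key}"] = val
    for key, val in szm_features(q).items():
        out[f"szm|{key}"] = val
    for key, val in ngldm_features(q).items():
        out[f"ngldm|{key}"] = val
    return out


def extract_all(maps: dict[str, MapVolume | None], mask: VoiMask,
                ng: int = 32) -> pd.Series:
    """One FeatureMatrix row: 2,352 features over the seven maps.

    A missing map (absent key or None) leaves its whole 336-feature block
    NaN (missing modality), keeping the column set fixed.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty VOI mask")
    values: dict[str, float] = {}
    for kind in MAP_ORDER:
        vol = maps.get(kind)
        if vol is None:
            for family, name in per_map_feature_names():
                values[f"{kind}|{family}|{name}"] = float("nan")
        else:
            feats = extract_map_features(vol, mask, ng=ng)
            for key, val in feats.items():
                values[f"{kind}|{key}"] = val
    return pd.Series(values, name=mask.voi_id)


def extract_feature_matrix(vois: list[tuple[dict[str, MapVolume | None], VoiMask]],
                           ng: int = 32) -> pd.DataFrame:
    """Stack ``extract_all`` rows into a VOI x feature matrix."""
    rows = [extract_all(maps, mask, ng=ng) for maps, mask in vois]
    return pd.DataFrame(rows)
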