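"""Copy-number alteration calling from tumor/reference probe intensities.

Pipeline: per-probe log2 tumor/reference ratios -> circular binary
segmentation (CBS) with a permutation test per candidate split -> the
significance filter (|segment mean| strictly above 0.2 and span >= 10 Mbp)
-> per-core aggressiveness annotations and per-patient genomic index
lesions (the core or cores with the maximum count of highly significant
CNAs; ties produce multiple index lesions).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._cbs_core import max_arc_tstat


@dataclass(frozen=True)
class CbsConfig:
    """Segmentation and filtering parameters.

    alpha / n_permutations drive the per-split permutation test; threshold
    (dimensionless log2 ratio) and min_length_bp define a highly significant
    CNA. Winsorization clips per-probe log2 ratios at +/- the given value
    before segmentation so single array spikes cannot fragment segments
    (set to None to disable). merge_threshold, when set, post-merges
    adjacent segments whose means differ by less than it (off by default).
    """

    alpha: float = 0.01
    n_permutations: int = 1000
    seed: int = 0
    min_probes_per_segment: int = 3
    threshold: float = 0.2
    min_length_bp: int = 10_000_000
    winsorize: float | None = 2.0
    merge_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class ProbeTrack:
    """Ordered per-probe log2 tumor/reference ratios for one core."""

    core_id: str
    table: pd.DataFrame  # columns chrom, pos, log2_ratio
    n_dropped: int = 0

    def __post_init__(self) -> None:
        t = self.table
        if not np.all(np.isfinite(t["log2_ratio"])):
            raise ValueError(f"{self.core_id}: non-finite log2 ratios")
        for chrom, grp in t.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError(
                    f"{self.core_id}: probe positions not strictly "
                    f"increasing on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


@dataclass(frozen=True)
class Segment:
    """One CBS segment: [start, end) spans first to last probe, inclusive."""

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log2r: float

    @property
    def length_bp(self) -> int:
        """Last-probe minus first-probe position (the span convention)."""
        return self.end - self.start - 1


@dataclass(frozen=True)
class CnaCall:
    segment: Segment
    direction: str  # "gain" | "loss"

    @property
    def length_bp(self) -> int:
        return self.segment.length_bp


@dataclass
class CoreProfile:
    """Per-core aggressiveness annotations.

    hs_mut: count of highly significant CNAs; mol_tu (molecular tumor
    signature): hs_mut >= 1; hi_les: genomic index lesion membership.
    """

    core_id: str
    patient_id: str
    cna_calls: list[CnaCall] = field(default_factory=list)
    hi_les: bool = False

    @property
    def hs_mut(self) -> int:
        return len(self.cna_calls)

    @property
    def mol_tu(self) -> bool:
        return self.hs_mut >= 1


# ---------------------------------------------------------------------------
# log2 ratio
# ---------------------------------------------------------------------------

def compute_log_ratio(tumor: pd.DataFrame,
                      references: list[pd.DataFrame] | pd.DataFrame,
                      core_id: str = "tumor") -> ProbeTrack:
    """Per-probe log2(tumor / median across reference cores).

    Input tables need columns probe_id, chrom, pos, intensity. Probes absent
    from any input are dropped (counted in ``n_dropped``), as are probes
    with non-positive intensity in any core.
    """
    if isinstance(references, pd.DataFrame):
        references = [references]
    if not references:
        raise ValueError("at least one reference core is required")

    t = tumor.set_index("probe_id")
    ref_cols = []
    common = t.index
    for i, ref in enumerate(references):
        r = ref.set_index("probe_id")["intensity"].rename(f"ref{i}")
        ref_cols.append(r)
        common = common.intersection(r.index)
    if len(common) == 0:
        raise ValueError("tumor and reference cores share no probes")
    n_total = len(t)
    t = t.loc[common]
    refs = pd.concat([c.loc[common] for c in ref_cols], axis=1)

    ref_med = refs.median(axis=1)
    ok = (t["intensity"] > 0) & (ref_med > 0)
    n_dropped = n_total - int(ok.sum())
    if int((~ok).sum()):
        warnings.warn(f"{core_id}: dropped {int((~ok).sum())} probes with "
                      "non-positive intensity", stacklevel=2)
    tab = pd.DataFrame({
        "chrom": t.loc[ok, "chrom"],
        "pos": t.loc[ok, "pos"],
        "log2_ratio": np.log2(t.loc[ok, "intensity"] / ref_med[ok]),
    }).reset_index(drop=True)
    tab = tab.sort_values(["chrom", "pos"],
                          key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
                          kind="stable").reset_index(drop=True)
    return ProbeTrack(core_id, tab, n_dropped=n_dropped)


def _chrom_sort_key(name: str):
    s = str(name).removeprefix("chr")
    if s.isdigit():
        return int(s)
    # stable ordering for non-numeric names (X, Y, MT, ...)
    return 1000 + sum(ord(c) for c in s)


# ---------------------------------------------------------------------------
# CBS
# ---------------------------------------------------------------------------

def _permutation_pvalue(x: np.ndarray, observed: float, min_seg: int,
                        cfg: CbsConfig, rng: np.random.Generator) -> float:
    """Permutation p-value for the observed max arc statistic.

    Early exit once the exceedance count guarantees p >= alpha (cannot
    change the accept/reject decision, only saves work).
    """
    n_perm = cfg.n_permutations
    stop_count = math.ceil(cfg.alpha * (n_perm + 1))
    count = 0
    for b in range(n_perm):
        xp = rng.permutation(x)
        stat, _, _ = max_arc_tstat(xp, min_seg)
        if stat >= observed:
            count += 1
            if count >= stop_count:
                return (1 + count) / (1 + b + 1)
    return (1 + count) / (1 + n_perm)


def _segment_values(x: np.ndarray, cfg: CbsConfig,
                    rng_key: tuple) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's values; returns probe-index spans."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        leaf = (lo, hi)
        if n < 2 * cfg.min_probes_per_segment or np.ptp(x[lo:hi]) == 0.0:
            out.append(leaf)
            continue
        stat, i, j = max_arc_tstat(x[lo:hi], cfg.min_probes_per_segment)
        if stat <= 0.0:
            out.append(leaf)
            continue
        rng = np.random.default_rng(
            [abs(cfg.seed)] + [abs(int(k)) for k in rng_key] + [lo, hi])
        p = _permutation_pvalue(x[lo:hi], stat, cfg.min_probes_per_segment,
                                cfg, rng)
        if p < cfg.alpha:
            cuts = sorted({lo, lo + i, lo + j, hi})
            for a, b in zip(cuts, cuts[1:]):
                stack.append((a, b))
        else:
            out.append(leaf)
    return sorted(out)


def cbs_segment(track: ProbeTrack, cfg: CbsConfig | None = None) -> list[Segment]:
    """Circular binary segmentation of one core's log2-ratio track.

    Each chromosome is segmented independently by recursive binary
    splitting: the arc/complement split maximizing the two-sample t
    statistic is accepted when its permutation p-value (label shuffles
    within the interval, seeded deterministically) falls below alpha.
    The output tiles every chromosome's probe range exactly.
    """
    cfg = cfg or CbsConfig()
    segments: list[Segment] = []
    for ci, chrom in enumerate(track.chromosomes):
        grp = track.table[track.table["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        vals = grp["log2_ratio"].to_numpy(dtype=float)
        if cfg.winsorize is not None:
            vals = np.clip(vals, -cfg.winsorize, cfg.winsorize)
        spans = (_segment_values(vals, cfg, (ci,))
                 if len(vals) >= 2 * cfg.min_probes_per_segment
                 else [(0, len(vals))])
        if cfg.merge_threshold is not None:
            spans = _merge_adjacent(vals, spans, cfg.merge_threshold)
        for a, b in spans:
            segments.append(Segment(
                chrom=chrom, start=int(pos[a]), end=int(pos[b - 1]) + 1,
                n_probes=b - a, mean_log2r=float(vals[a:b].mean())))
    return segments


def _merge_adjacent(vals: np.ndarray, spans: list[tuple[int, int]],
                    tol: float) -> list[tuple[int, int]]:
    merged = [spans[0]]
    for a, b in spans[1:]:
        pa, pb = merged[-1]
        if abs(vals[pa:pb].mean() - vals[a:b].mean()) < tol:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# significance filter, profiles, index lesions
# ---------------------------------------------------------------------------

def filter_significant(segments: list[Segment],
                       cfg: CbsConfig | None = None) -> list[CnaCall]:
    """Highly significant CNAs: |mean log2R| strictly above the threshold
    (a mean of exactly +/-0.2 is excluded) and span >= min_length_bp
    (a span of exactly 10 Mbp is included)."""
    cfg = cfg or CbsConfig()
    calls = []
    for seg in segments:
        if abs(seg.mean_log2r) <= cfg.threshold:
            continue
        if seg.length_bp < cfg.min_length_bp:
            continue
        calls.append(CnaCall(seg, "gain" if seg.mean_log2r > 0 else "loss"))
    return calls


def build_core_profiles(calls_by_core: dict[str, list[CnaCall]],
                        manifest: pd.DataFrame,
                        assign_index_lesions: bool = True) -> list[CoreProfile]:
    """Per-core profiles from calls + manifest (tumor cores only)."""
    tumor = manifest[manifest["role"] == "tumor"]
    profiles = [CoreProfile(core_id=row.core_id, patient_id=row.patient_id,
                            cna_calls=list(calls_by_core.get(row.core_id, [])))
                for row in tumor.itertuples()]
    if assign_index_lesions:
        identify_index_lesions(profiles)
    return profiles


def identify_index_lesions(profiles: list[CoreProfile]) -> dict[str, set[str]]:
    """Flag, per patient, every core achieving the maximum hs_mut count.

    All tied cores become index lesions. A patient whose cores all have
    hs_mut = 0 gets no index lesion (warning emitted). Mutates ``hi_les``
    in place and returns patient -> set of index core_ids.
    """
    by_patient: dict[str, list[CoreProfile]] = {}
    for p in profiles:
        by_patient.setdefault(p.patient_id, []).append(p)
    result: dict[str, set[str]] = {}
    for pid, plist in by_patient.items():
        mx = max(p.hs_mut for p in plist)
        if mx == 0:
            warnings.warn(f"patient {pid}: no core carries a highly "
                          "significant CNA; no index lesion", stacklevel=2)
            result[pid] = set()
            for p in plist:
                p.hi_les = False
            continue
        winners = {p.core_id for p in plist if p.hs_mut == mx}
        for p in plist:
            p.hi_les = p.core_id in winners
        result[pid] = winners
    return result


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_seg(segments_by_core: dict[str, list[Segment]], path: str | Path) -> None:
    """SEG format (1-based inclusive coordinates on write)."""
    rows = []
    for core_id, segs in segments_by_core.items():
        for s in segs:
            rows.append((core_id, s.chrom, s.start + 1, s.end, s.n_probes,
                         round(s.mean_log2r, 6)))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                "n_probes", "seg.mean"]).to_csv(
        path, sep="\t", index=False)


def write_cna_bed(calls_by_core: dict[str, list[CnaCall]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for core_id, calls in calls_by_core.items():
            for c in calls:
                s = c.segment
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t"
                         f"{core_id}:{c.direction}\t"
                         f"{s.mean_log2r:.4f}\n")


def profiles_to_frame(profiles: list[CoreProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "core_id": p.core_id, "patient_id": p.patient_id,
        "hsMut": p.hs_mut, "MolTu": p.mol_tu, "hiLes": p.hi_les,
    } for p in profiles])


def write_index_lesion_report(profiles: list[CoreProfile], path: str | Path) -> None:
    lesions: dict[str, list] = {}
    for p in profiles:
        lesions.setdefault(p.patient_id, [])
        if p.hi_les:
            lesions[p.patient_id].append(
                {"core_id": p.core_id, "hsMut": p.hs_mut})
    Path(path).write_text(json.dumps(lesions, indent=1))
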