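"""Synthetic cohort, image-phantom and forward-model generators.

The study design being emulated: a handful of high-risk prostate cancer
patients, each contributing 6-13 biopsy cores from suspicious and
unsuspicious areas plus non-cancerous reference cores; per-core
methylation-array probe intensities carry chromosomal copy-number
alterations (CNAs); per-core volumes of interest on seven co-registered
parameter maps carry class-dependent texture. Every generator is
deterministic under a fixed seed and records its ground truth, so each
downstream stage can be tested against a known answer.

Intensities are log-normal around a per-probe baseline and CNAs act
multiplicatively (intensity x 2^log2_shift), which makes the implanted
log2 ratio the exact noise-free ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeTemplate, default_template
from .maps import (ArterialInputFunction, MapVolume, ToftsParams, VoiMask,
                   tofts_forward)


@dataclass(frozen=True)
class CnaImplant:
    """A ground-truth copy-number alteration on one core.

    Coordinates are 0-based half-open bp; log2_shift is the exact log2
    tumor/reference ratio inside the region (positive = gain).
    """

    chrom: str
    start: int
    end: int
    log2_shift: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("implant end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate the study design: 5 patients, 6-13 tumor cores each,
    2 non-cancerous reference cores per patient, per-probe log2 noise of
    0.12 (CBS operates near but not at its detection limit), and a trunk
    clonality of 0.6 (each patient has a shared trunk implant set present
    in that fraction of tumor cores, plus private implants).
    """

    n_patients: int = 5
    cores_per_patient: tuple[int, int] = (6, 13)
    n_reference_cores: int = 2
    shared_cna_fraction: float = 0.6
    noise_sd: float = 0.12
    seed: int = 0
    trunk_implants: tuple[int, int] = (2, 4)
    private_implants: tuple[int, int] = (0, 2)
    implant_length: tuple[int, int] = (15_000_000, 60_000_000)
    implant_shift: tuple[float, float] = (0.25, 0.6)
    fraction_negative_cores: float = 0.45

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_cna_fraction <= 1.0):
            raise ValueError("shared_cna_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """Per-core intensity tables plus the ground-truth ledger."""

    manifest: pd.DataFrame           # patient_id, core_id, role, voi_id
    intensities: dict[str, pd.DataFrame]   # core_id -> probe table
    ledger: dict[str, list[CnaImplant]]    # core_id -> implants
    template: GenomeTemplate

    def tumor_cores(self, patient_id: str) -> list[str]:
        m = self.manifest
        sel = (m.patient_id == patient_id) & (m.role == "tumor")
        return list(m.loc[sel, "core_id"])

    def reference_cores(self, patient_id: str) -> list[str]:
        m = self.manifest
        sel = (m.patient_id == patient_id) & (m.role == "reference")
        return list(m.loc[sel, "core_id"])

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.manifest.patient_id))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        for core_id, tab in self.intensities.items():
            tab.to_csv(outdir / f"{core_id}.intensity.tsv", sep="\t", index=False)
        ledger = {cid: [asdict(im) for im in ims] for cid, ims in self.ledger.items()}
        (outdir / "ground_truth.json").write_text(json.dumps(ledger, indent=1))


def _check_implants(implants: list[CnaImplant], template: GenomeTemplate,
                    core_id: str) -> None:
    lengths = template.chrom_lengths
    by_chrom: dict[str, list[CnaImplant]] = {}
    for im in implants:
        if im.chrom not in lengths:
            raise ValueError(f"{core_id}: implant on unknown chromosome {im.chrom}")
        if im.start < 0 or im.end > lengths[im.chrom]:
            raise ValueError(f"{core_id}: implant outside {im.chrom} bounds")
        by_chrom.setdefault(im.chrom, []).append(im)
    for chrom, ims in by_chrom.items():
        ims = sorted(ims, key=lambda x: x.start)
        for a, b in zip(ims, ims[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{core_id}: overlapping implants on {chrom} "
                    f"([{a.start},{a.end}) vs [{b.start},{b.end}))")


def generate_probe_tracks(
    spec: SyntheticCohortSpec,
    template: GenomeTemplate | None = None,
    implants: dict[str, list[CnaImplant]] | None = None,
) -> SyntheticCohort:
    """Simulate per-core probe-intensity tables with implanted CNAs.

    When ``implants`` (core_id -> implant list) is omitted, each patient is
    given a trunk implant set shared by ``shared_cna_fraction`` of its tumor
    cores plus per-core private implants; a ``fraction_negative_cores``
    share of tumor cores carries nothing, emulating biopsies from
    unsuspicious areas. Reference cores never carry implants.
    """
    template = template or default_template()
    rng = np.random.default_rng(spec.seed)

    probes = template.probe_table()
    # per-probe baseline intensity, shared cohort-wide
    baseline = np.exp(rng.normal(np.log(1000.0), 0.3, size=len(probes)))

    manifest_rows = []
    core_ids: dict[str, list[tuple[str, str]]] = {}
    for p in range(1, spec.n_patients + 1):
        pid = f"P{p:02d}"
        lo, hi = spec.cores_per_patient
        n_tumor = int(rng.integers(lo, hi + 1))
        cores = []
        for c in range(1, n_tumor + 1):
            cid = f"{pid}_T{c:02d}"
            cores.append((cid, "tumor"))
            manifest_rows.append((pid, cid, "tumor", f"voi_{cid}"))
        for c in range(1, spec.n_reference_cores + 1):
            cid = f"{pid}_R{c:02d}"
            cores.append((cid, "reference"))
            manifest_rows.append((pid, cid, "reference", ""))
        core_ids[pid] = cores
    manifest = pd.DataFrame(manifest_rows,
                            columns=["patient_id", "core_id", "role", "voi_id"])

    if implants is None:
        implants = _draw_cohort_implants(spec, template, core_ids, rng)
    for pid, cores in core_ids.items():
        for cid, role in cores:
            ims = implants.get(cid, [])
            if role == "reference" and ims:
                raise ValueError(f"reference core {cid} must carry no implants")
            _check_implants(ims, template, cid)

    chrom_arr = probes["chrom"].to_numpy()
    pos_arr = probes["pos"].to_numpy()
    intensities: dict[str, pd.DataFrame] = {}
    ledger: dict[str, list[CnaImplant]] = {}
    for pid, cores in core_ids.items():
        for cid, role in cores:
            shift = np.zeros(len(probes))
            for im in implants.get(cid, []):
                sel = (chrom_arr == im.chrom) & (pos_arr >= im.start) & (pos_arr < im.end)
                shift[sel] = im.log2_shift
            noise = rng.normal(0.0, spec.noise_sd, size=len(probes)) if spec.noise_sd > 0 \
                else np.zeros(len(probes))
            intensity = baseline * np.exp2(shift + noise)
            tab = probes.copy()
            tab["intensity"] = intensity
            intensities[cid] = tab
            ledger[cid] = list(implants.get(cid, []))
    return SyntheticCohort(manifest, intensities, ledger, template)


def _draw_cohort_implants(spec, template, core_ids, rng) -> dict[str, list[CnaImplant]]:
    lengths = template.chrom_lengths
    chroms = list(lengths)
    out: dict[str, list[CnaImplant]] = {}

    def draw_set(n: int, taken: dict[str, list[tuple[int, int]]]) -> list[CnaImplant]:
        ims = []
        attempts = 0
        while len(ims) < n and attempts < 200:
            attempts += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(*spec.implant_length))
            if length >= lengths[chrom]:
                continue
            start = int(rng.integers(0, lengths[chrom] - length))
            span = (start, start + length)
            if any(s < span[1] and span[0] < e for s, e in taken.get(chrom, [])):
                continue
            mag = float(rng.uniform(*spec.implant_shift))
            sign = -1.0 if rng.random() < 0.7 else 1.0  # losses dominate in PCa
            ims.append(CnaImplant(chrom, span[0], span[1], sign * mag))
            taken.setdefault(chrom, []).append(span)
        return ims

    for pid, cores in core_ids.items():
        tumor = [cid for cid, role in cores if role == "tumor"]
        taken: dict[str, list[tuple[int, int]]] = {}
        trunk = draw_set(int(rng.integers(spec.trunk_implants[0],
                                          spec.trunk_implants[1] + 1)), taken)
        n_neg = int(round(spec.fraction_negative_cores * len(tumor)))
        pos_cores = tumor[:len(tumor) - n_neg] if n_neg else tumor
        for cid in tumor:
            out[cid] = []
        for cid in pos_cores:
            ims = []
            if rng.random() < spec.shared_cna_fraction or cid == pos_cores[0]:
                ims.extend(trunk)
            n_priv = int(rng.integers(spec.private_implants[0],
                                      spec.private_implants[1] + 1))
            priv_taken = {c: list(v) for c, v in taken.items()}
            ims.extend(draw_set(n_priv, priv_taken))
            out[cid] = ims
    return out


def expected_significant_implants(
    implants: list[CnaImplant], template: GenomeTemplate,
    threshold: float = 0.2, min_length_bp: int = 10_000_000,
) -> list[CnaImplant]:
    """Apply the significance filter analytically to ground-truth implants.

    Mirrors the call filter: |log2 shift| strictly above ``threshold`` and
    probe span (last minus first covered probe) at least ``min_length_bp``.
    This is the ledger-side oracle for the segmentation + filter stage.
    """
    keep = []
    for im in implants:
        if abs(im.log2_shift) <= threshold:
            continue
        pos = template.probe_positions(im.chrom)
        inside = pos[(pos >= im.start) & (pos < im.end)]
        if len(inside) == 0:
            continue
        if int(inside[-1] - inside[0]) >= min_length_bp:
            keep.append(im)
    return keep


# ---------------------------------------------------------------------------
# DCE and diffusion forward generators
# ---------------------------------------------------------------------------

def generate_dce_series(params: ToftsParams, aif: ArterialInputFunction,
                        times: np.ndarray, noise_sd: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Noisy tissue concentration curve from the extended Tofts model.

    Additive Gaussian noise; negative concentrations are clipped at zero.
    With noise_sd = 0 the output equals ``tofts_forward`` exactly.
    """
    ct = tofts_forward(params, aif, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + rng.normal(0.0, noise_sd, size=ct.shape)
        n_clip = int(np.sum(ct < 0))
        if n_clip:
            import logging
            logging.getLogger(__name__).debug(
                "generate_dce_series: clipped %d negative samples", n_clip)
        ct = np.clip(ct, 0.0, None)
    return ct


def generate_diffusion_pair(adc_map: np.ndarray, s0_map: np.ndarray,
                            noise_sd: float = 0.0, seed: int = 0,
                            b_value: float = 1500.0,
                            spacing=(1.0, 1.0, 1.0)) -> tuple[MapVolume, MapVolume]:
    """(b=0, b=b_value) volume pair from an ADC map via S_b = S0 exp(-b ADC).

    ``adc_map`` is in mm2/s; additive Gaussian noise on both volumes.
    """
    adc = np.asarray(adc_map, dtype=float)
    s0 = np.asarray(s0_map, dtype=float)
    if adc.shape != s0.shape:
        raise ValueError("adc_map and s0_map shapes differ")
    if np.any(adc < 0):
        raise ValueError("ADC values must be >= 0")
    sb = s0 * np.exp(-b_value * adc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s0 = s0 + rng.normal(0.0, noise_sd, size=s0.shape)
        sb = sb + rng.normal(0.0, noise_sd, size=sb.shape)
    return (MapVolume(s0, spacing, "T2w"), MapVolume(sb, spacing, "B1500"))


# ---------------------------------------------------------------------------
# Texture phantoms
# ---------------------------------------------------------------------------

PHANTOM_MAP_KINDS = ("T2w", "ADC1500", "B1500", "Ktrans", "Kep", "ve", "vp")

# per-map (background mean, class shift for "aggressive", noise scale);
# ADC in 1e-6 mm2/s with aggressive tissue ~150 lower, matching the
# direction of the ADC-vs-aggressiveness association.
_MAP_PARAMS: dict[str, tuple[float, float, float]] = {
    "T2w": (400.0, 60.0, 40.0),
    "ADC1500": (1100.0, -150.0, 60.0),
    "B1500": (120.0, 50.0, 15.0),
    "Ktrans": (0.15, 0.10, 0.03),
    "Kep": (0.50, 0.25, 0.08),
    "ve": (0.30, 0.10, 0.05),
    "vp": (0.03, 0.015, 0.008),
}


@dataclass(frozen=True)
class ImagePhantomSpec:
    """Geometry and class contrast for the seven-map texture phantom.

    Each VOI is an ellipsoid; the two texture classes differ in mean shift,
    voxel-noise dispersion and spatial autocorrelation (aggressive VOIs get
    coarser, higher-variance texture).
    """

    shape: tuple[int, int, int] = (36, 36, 14)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    voi_radius: tuple[float, float, float] = (3.0, 3.0, 1.6)
    min_voi_voxels: int = 8
    aggressive_smooth: float = 1.2
    indolent_smooth: float = 0.0
    aggressive_noise_scale: float = 2.0
    seed: int = 0


def generate_texture_phantoms(
    spec: ImagePhantomSpec,
    voi_labels: dict[str, str],
    patient_of_voi: dict[str, str] | None = None,
    patient_offset_sd: float = 0.0,
) -> tuple[dict[str, MapVolume], list[VoiMask], dict[str, str]]:
    """Seven co-registered parameter maps with one VOI per label entry.

    ``voi_labels`` maps voi_id -> class ("aggressive" | "indolent"). VOIs
    are placed on a regular grid inside the volume; an optional per-patient
    additive offset (``patient_offset_sd`` in units of each map's noise
    scale) implants the batch effect the patient-centering step removes.

    Returns (maps by kind, VOI masks, labels as given).
    """
    from scipy import ndimage

    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    rx, ry, rz = spec.voi_radius
    voi_ids = list(voi_labels)

    # grid placement with a margin of one radius
    step_x = int(np.ceil(2 * rx + 2))
    step_y = int(np.ceil(2 * ry + 2))
    step_z = int(np.ceil(2 * rz + 2))
    centers = []
    for z in range(int(np.ceil(rz)) + 1, nz - int(np.ceil(rz)) - 1, step_z):
        for y in range(int(np.ceil(ry)) + 1, ny - int(np.ceil(ry)) - 1, step_y):
            for x in range(int(np.ceil(rx)) + 1, nx - int(np.ceil(rx)) - 1, step_x):
                centers.append((x, y, z))
    if len(centers) < len(voi_ids):
        raise ValueError(
            f"phantom volume {spec.shape} fits {len(centers)} VOIs, "
            f"{len(voi_ids)} requested — enlarge the volume")

    xx, yy, zz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    masks: list[VoiMask] = []
    for voi_id, (cx, cy, cz) in zip(voi_ids, centers):
        m = (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
             + ((zz - cz) / rz) ** 2) <= 1.0
        if int(m.sum()) < spec.min_voi_voxels:
            raise ValueError(f"VOI {voi_id} smaller than {spec.min_voi_voxels} voxels")
        masks.append(VoiMask(m, voi_id=voi_id, min_voxels=spec.min_voi_voxels))

    pat_offsets: dict[str, float] = {}
    if patient_of_voi and patient_offset_sd > 0:
        for pat in sorted(set(patient_of_voi.values())):
            pat_offsets[pat] = float(rng.normal(0.0, patient_offset_sd))

    maps: dict[str, MapVolume] = {}
    for kind in PHANTOM_MAP_KINDS:
        mean, shift, noise = _MAP_PARAMS[kind]
        vol = mean + rng.normal(0.0, 0.25 * noise, size=spec.shape)
        for mask, voi_id in zip(masks, voi_ids):
            label = voi_labels[voi_id]
            aggressive = label == "aggressive"
            tex = rng.normal(0.0, 1.0, size=spec.shape)
            smooth = spec.aggressive_smooth if aggressive else spec.indolent_smooth
            if smooth > 0:
                tex = ndimage.gaussian_filter(tex, sigma=smooth)
                tex /= max(tex.std(), 1e-12)
            scale = noise * (spec.aggressive_noise_scale if aggressive else 1.0)
            voi_mean = mean + (shift if aggressive else 0.0)
            if patient_of_voi and pat_offsets:
                voi_mean += noise * pat_offsets.get(patient_of_voi.get(voi_id, ""), 0.0)
            vol[mask.mask] = voi_mean + scale * tex[mask.mask]
        if kind in ("Ktrans", "Kep", "ve", "vp", "B1500", "ADC1500"):
            vol = np.clip(vol, 0.0, None)
        maps[kind] = MapVolume(vol, spec.spacing, kind)
    return maps, masks, dict(voi_labels)
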