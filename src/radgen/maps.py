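"""Derived MRI/PET parameter maps.

Implements the three map-level operations the radiomic stage consumes:

* ``compute_adc`` — apparent diffusion coefficient from a b=0 / b=1500 s/mm2
  image pair, ADC = -ln(S_b/S_0)/b, reported in 1e-6 mm2/s.
* ``tofts_forward`` / ``fit_tofts`` — the extended Tofts two-compartment
  model Ct(t) = vp*Cp(t) + Ktrans * int_0^t Cp(u) exp(-Kep (t-u)) du with
  Kep = Ktrans/ve, and its bounded nonlinear least-squares inverse.
* ``isocontour_voi`` — 50%-of-maximum isocontour PET VOI grown from the
  hottest seed voxel (26-connected), with SUVmax/SUVmean.

Volumes move through ``MapVolume`` (array + voxel spacing + kind) and binary
``VoiMask`` objects; both round-trip through NIfTI-1 via nibabel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

MAP_KINDS = ("T2w", "ADC1500", "B1500", "Ktrans", "Kep", "ve", "vp", "PET")


@dataclass
class MapVolume:
    """A 3D parameter map with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "T2w"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("MapVolume requires a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str = "T2w") -> "MapVolume":
        import nibabel as nib

        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.get_fdata(), dtype=float), spacing, kind)


@dataclass
class VoiMask:
    """Binary volume-of-interest mask co-registered to a MapVolume."""

    mask: np.ndarray
    voi_id: str
    core_id: str | None = None
    min_voxels: int = 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VoiMask requires a 3D array")
        if int(self.mask.sum()) < self.min_voxels:
            raise ValueError(
                f"VOI {self.voi_id}: {int(self.mask.sum())} voxels "
                f"< minimum {self.min_voxels}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
        import nibabel as nib

        affine = np.diag([*spacing, 1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# ADC
# ---------------------------------------------------------------------------

def compute_adc(b0: MapVolume, b_high: MapVolume, b_value: float = 1500.0) -> MapVolume:
    """ADC map from a b=0 / b=b_value pair, in units of 1e-6 mm2/s.

    ADC = -ln(S_b / S_0) / b. Voxels with S_b >= S_0 floor at 0; voxels with
    S_0 <= 0 are set to NaN (missing).
    """
    if b0.data.shape != b_high.data.shape:
        raise ValueError("b0 and high-b volumes differ in shape")
    if b0.spacing != b_high.spacing:
        raise ValueError("b0 and high-b volumes differ in spacing")
    s0 = b0.data
    sb = b_high.data
    adc = np.full(s0.shape, np.nan)
    valid = s0 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, sb / np.where(valid, s0, 1.0), np.nan)
        adc[valid] = -np.log(np.clip(ratio[valid], 1e-300, None)) / b_value
    adc[valid & (sb >= s0)] = 0.0
    np.maximum(adc, 0.0, out=adc, where=~np.isnan(adc))
    return MapVolume(adc * 1e6, b0.spacing, "ADC1500")


# ---------------------------------------------------------------------------
# Extended Tofts model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToftsParams:
    """Extended-Tofts parameters.

    Ktrans : volume transfer coefficient (1/min)
    ve     : extravascular extracellular volume fraction, in (0, 1]
    vp     : plasma volume fraction, in [0, 1)
    """

    ktrans: float
    ve: float
    vp: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("Ktrans must be >= 0")
        if self.ktrans > 0 and self.ve <= 0:
            raise ValueError("ve = 0 with Ktrans > 0 leaves Kep undefined")
        if not (0 <= self.vp < 1):
            raise ValueError("vp must be in [0, 1)")

    @property
    def kep(self) -> float:
        """Flux rate constant Kep = Ktrans / ve (1/min); 0 when Ktrans = 0."""
        return self.ktrans / self.ve if self.ktrans > 0 else 0.0


@dataclass(frozen=True)
class ArterialInputFunction:
    """Tabulated plasma concentration Cp(t); times in min, Cp in mM."""

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("AIF times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("AIF concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cp", c)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.cp,
                         left=0.0, right=float(self.cp[-1]))


def parker_aif(times: np.ndarray) -> ArterialInputFunction:
    """Parker population-average AIF (two Gaussians + sigmoid washout).

    Times in minutes. Standard population parameters; used as the default
    plasma input when no measured AIF is supplied.
    """
    t = np.asarray(times, dtype=float)
    A = (0.809, 0.330)          # mM min
    T = (0.17046, 0.365)        # min
    sigma = (0.0563, 0.132)     # min
    alpha, beta = 1.050, 0.1685  # mM, 1/min
    s, tau = 38.078, 0.483      # 1/min, min
    cp = np.zeros_like(t)
    for a, mu, sd in zip(A, T, sigma):
        cp += a / (sd * np.sqrt(2 * np.pi)) * np.exp(-((t - mu) ** 2) / (2 * sd ** 2))
    cp += alpha * np.exp(-beta * t) / (1 + np.exp(-s * (t - tau)))
    cp = np.clip(cp, 0.0, None)
    return ArterialInputFunction(t, cp)


def tofts_forward(params: ToftsParams, aif: ArterialInputFunction,
                  times: np.ndarray) -> np.ndarray:
    """Tissue concentration under the extended Tofts model.

    Ct(t) = vp * Cp(t) + Ktrans * int_0^t Cp(u) exp(-Kep (t-u)) du,
    with the convolution evaluated by trapezoidal quadrature on `times`.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    cp = aif(t)
    ct = params.vp * cp
    if params.ktrans > 0:
        kep = params.kep
        n = len(t)
        conv = np.zeros(n)
        # integrand_i(u) = Cp(u) * exp(-kep (t_i - u)); exploit
        # exp(-kep(t_i - u)) = exp(-kep t_i) exp(kep u) with rescaling to
        # avoid overflow: accumulate trapezoids incrementally.
        for i in range(1, n):
            dt = t[i] - t[i - 1]
            decay = np.exp(-kep * dt)
            conv[i] = conv[i - 1] * decay + 0.5 * dt * (cp[i] + cp[i - 1] * decay)
        ct = ct + params.ktrans * conv
    return ct


@dataclass(frozen=True)
class ToftsFitConfig:
    """Bounds and multi-start settings for the Tofts inverse problem.

    Defaults reflect physiologic prostate ranges; three deterministic
    starting points keep per-voxel fits reproducible.
    """

    ktrans_bounds: tuple[float, float] = (0.0, 5.0)
    ve_bounds: tuple[float, float] = (1e-3, 1.0)
    vp_bounds: tuple[float, float] = (0.0, 0.3)
    n_starts: int = 3
    seed: int = 12345
    max_nfev: int = 200


@dataclass
class ToftsFit:
    params: ToftsParams
    residual_rms: float
    converged: bool
    degenerate: bool = False


def fit_tofts(curve: np.ndarray, aif: ArterialInputFunction, times: np.ndarray,
              config: ToftsFitConfig | None = None) -> ToftsFit:
    """Bounded least-squares fit of (Ktrans, ve, vp) to a concentration curve.

    Multi-start: a fixed midpoint start plus pseudo-random starts from the
    config seed; the best (lowest SSE) solution wins. An all-zero curve is
    reported as the degenerate fit Ktrans=0, vp=0.
    """
    cfg = config or ToftsFitConfig()
    t = np.asarray(times, dtype=float)
    y = np.asarray(curve, dtype=float)
    if len(t) < 10:
        raise ValueError("fit_tofts requires >= 10 time points")
    if np.allclose(y, 0.0):
        return ToftsFit(ToftsParams(0.0, cfg.ve_bounds[0], 0.0), 0.0,
                        converged=True, degenerate=True)

    lo = np.array([cfg.ktrans_bounds[0], cfg.ve_bounds[0], cfg.vp_bounds[0]])
    hi = np.array([cfg.ktrans_bounds[1], cfg.ve_bounds[1], cfg.vp_bounds[1]])

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = ToftsParams(max(theta[0], 0.0), theta[1], min(max(theta[2], 0.0), 0.999))
        return tofts_forward(p, aif, t) - y

    rng = np.random.default_rng(cfg.seed)
    starts = [np.array([0.2, 0.3, 0.02])]
    for _ in range(max(cfg.n_starts - 1, 0)):
        starts.append(lo + rng.random(3) * (hi - lo))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                max_nfev=cfg.max_nfev, method="trf")
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        return ToftsFit(ToftsParams(0.0, cfg.ve_bounds[0], 0.0), float("nan"),
                        converged=False)
    sse, sol = best
    k, ve, vp = sol.x
    params = ToftsParams(float(k), float(ve), float(min(vp, 0.999)))
    return ToftsFit(params, float(np.sqrt(sse / len(t))), converged=bool(sol.success))


def fit_tofts_volume(dce: np.ndarray, aif: ArterialInputFunction,
                     times: np.ndarray, mask: np.ndarray | None = None,
                     config: ToftsFitConfig | None = None,
                     spacing=(1.0, 1.0, 1.0)) -> dict[str, MapVolume]:
    """Per-voxel Tofts fit over a 4D (x, y, z, t) series.

    Non-convergent voxels are NaN (missing), never silently zeroed.
    Returns the four parameter maps keyed Ktrans/Kep/ve/vp.
    """
    shape = dce.shape[:3]
    out = {k: np.full(shape, np.nan) for k in ("Ktrans", "Kep", "ve", "vp")}
    sel = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    for idx in zip(*np.nonzero(sel)):
        fit = fit_tofts(dce[idx], aif, times, config)
        if fit.converged:
            out["Ktrans"][idx] = fit.params.ktrans
            out["Kep"][idx] = fit.params.kep
            out["ve"][idx] = fit.params.ve
            out["vp"][idx] = fit.params.vp
    return {k: MapVolume(v, spacing, k) for k, v in out.items()}


# ---------------------------------------------------------------------------
# PET isocontour VOI
# ---------------------------------------------------------------------------

@dataclass
class SuvStats:
    suv_max: float
    suv_mean: float
    n_voxels: int


def isocontour_voi(pet: MapVolume, seed_center: tuple[int, int],
                   seed_slice: int, seed_radius: float,
                   fraction: float = 0.5,
                   voi_id: str = "pet_voi") -> tuple[VoiMask, SuvStats]:
    """Grow a 3D VOI at a fractional isocontour of the hottest seed voxel.

    A circular 2D seed region (``seed_center``/``seed_radius`` on transaxial
    slice ``seed_slice``, axes (x, y)) locates the local maximum; the VOI is
    the 26-connected component, containing that voxel, of all voxels >=
    ``fraction`` * max. Returns the mask plus SUVmax/SUVmean.
    """
    vol = pet.data
    nx, ny, _ = vol.shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    disk = (xx - seed_center[0]) ** 2 + (yy - seed_center[1]) ** 2 <= seed_radius ** 2
    seed_vals = np.where(disk, vol[:, :, seed_slice], -np.inf)
    if not np.any(np.isfinite(seed_vals) & (seed_vals > 0)):
        raise ValueError("seed region contains no uptake above background")
    px, py = np.unravel_index(np.argmax(seed_vals), seed_vals.shape)
    peak = (int(px), int(py), int(seed_slice))
    suv_max = float(vol[peak])

    above = vol >= fraction * suv_max
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    voi = labels == labels[peak]
    stats = SuvStats(suv_max=suv_max,
                     suv_mean=float(vol[voi].mean()),
                     n_voxels=int(voi.sum()))
    mask = VoiMask(voi, voi_id=voi_id, min_voxels=1)
    return mask, stats
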