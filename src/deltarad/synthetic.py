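"""Synthetic three-timepoint PET/CT phantom cohorts.

Every patient gets three co-registered sessions (pre / mid / post
treatment) on a shared frame of reference: a CT-resolution grid and a
coarser PET-resolution grid with the scanner spacings of a typical
whole-body protocol (CT 1.37 x 1.37 x 3.27 mm, PET 5.47 x 5.47 x 3.27 mm).
Tumors are lobulated ellipsoids — an ellipsoid whose radius is modulated by
a smooth band-limited angular perturbation — so their roundness can be
steered continuously: the perturbation amplitude is solved by bisection so
that the *measured* roundness of the voxelized mask follows a per-class
drift between baseline and post-treatment.

The injected effect mirrors the serial-imaging observation the cohort is
meant to emulate: recurrent tumors become rounder after chemoradiation
(mean roundness drift +0.08) while non-recurrent tumors become less round
(mean drift -0.06), the latter through anisotropic single-axis regression.
Both classes shrink in volume.  All randomness derives from the spec seed;
the injected targets and achieved values are recorded per patient in the
``truth`` output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CohortTable, RoiMask, ScanSession, VolumeGrid, resample_mask
from .shape import roundness

CT_SPACING = (1.37, 1.37, 3.27)
PET_SPACING = (5.47, 5.47, 3.27)

_MAX_AMPLITUDE = 0.5


class PhantomError(ValueError):
    """Invalid phantom specification or infeasible target."""


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the serial anal-cancer imaging cohort the pipeline is
    designed for: 17 patients of whom 4 recur, class-mean baseline
    roundness 0.71 (recurrent) / 0.76 (non-recurrent) and class-mean
    roundness drifts +0.08 / -0.06 between baseline and post-treatment,
    with per-class drift scatter matching the observed per-patient spread.
    """

    n_patients: int = 17
    recurrence_fraction: float = 4 / 17
    base_semi_axes: tuple[float, float, float] = (16.0, 14.0, 12.0)  # mm
    lobulation_amplitude: float = 0.25  # starting fraction of radius
    roundness_drift_recurrent: float = 0.08    # pre -> post, sign +
    roundness_drift_nonrecurrent: float = -0.06  # pre -> post, sign -
    roundness_mid_drift_recurrent: float = -0.01   # pre -> mid
    roundness_mid_drift_nonrecurrent: float = -0.06
    roundness_pre_recurrent: float = 0.71
    roundness_pre_nonrecurrent: float = 0.76
    roundness_pre_sd: float = 0.04
    drift_noise_sd_recurrent: float = 0.02
    drift_noise_sd_nonrecurrent: float = 0.045
    shrink_fraction: float = 0.35  # volume lost pre -> post
    ct_mean: float = 45.0   # HU, soft tissue
    ct_sd: float = 12.0     # HU
    suv_peak: float = 8.0
    texture_correlation_length: float = 4.0  # mm
    seed: int = 0
    ct_shape: tuple[int, int, int] = (64, 64, 40)
    pet_shape: tuple[int, int, int] = (18, 18, 40)
    drop_mid_for: tuple[int, ...] = ()  # patient indices without a mid scan
    fill_intensity_volumes: bool = True

    def validate(self) -> None:
        if self.n_patients < 2:
            raise PhantomError("need at least 2 patients")
        if not (0 < self.recurrence_fraction < 1):
            raise PhantomError("recurrence_fraction must lie in (0, 1)")
        if any(a <= 0 for a in self.base_semi_axes):
            raise PhantomError("semi-axes must be positive")
        for d in (self.roundness_drift_recurrent, self.roundness_drift_nonrecurrent):
            if not np.isfinite(d):
                raise PhantomError("roundness drifts must be finite")
        if not (0 <= self.shrink_fraction < 1):
            raise PhantomError("shrink_fraction must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    sessions: list[ScanSession]
    cohort: CohortTable
    truth: dict[str, dict]
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]

    def by_patient(self) -> dict[str, dict[str, ScanSession]]:
        out: dict[str, dict[str, ScanSession]] = {}
        for s in self.sessions:
            out.setdefault(s.patient_id, {})[s.timepoint] = s
        return out


# ---------------------------------------------------------------------------
# Mask generation


def _ct_grid(spec: PhantomSpec) -> VolumeGrid:
    return VolumeGrid(np.zeros(spec.ct_shape, dtype=np.float32), CT_SPACING,
                      (0.0, 0.0, 0.0), "CT")


def _pet_grid(spec: PhantomSpec) -> VolumeGrid:
    # center the PET grid on the CT grid's physical center
    ct_center = (np.array(spec.ct_shape) - 1) * np.array(CT_SPACING) / 2
    origin = ct_center - (np.array(spec.pet_shape) - 1) * np.array(PET_SPACING) / 2
    return VolumeGrid(np.zeros(spec.pet_shape, dtype=np.float32), PET_SPACING,
                      tuple(origin), "SUV")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _sample_perturbation(rng: np.random.Generator, n_waves: int = 8):
    """Band-limited zero-mean angular perturbation P(u), RMS ~ 1.

    P is a sum of plane waves of moderate angular frequency evaluated on
    the unit sphere of directions, clipped to [-1.2, 1.2]; with amplitudes
    below 0.5 the perturbed radius stays positive, so the shape remains
    star-shaped (hence connected) while its roundness can be driven from
    ~0.99 down to ~0.55.
    """
    freqs = rng.normal(size=(n_waves, 3))
    freqs *= (rng.uniform(5.0, 9.0, size=n_waves) /
              np.linalg.norm(freqs, axis=1))[:, None]
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    weights = rng.normal(size=n_waves)
    weights /= np.sqrt((weights**2).sum() / 2.0)  # unit RMS over the sphere

    def perturb(u: np.ndarray) -> np.ndarray:
        acc = np.zeros(u.shape[:-1])
        for w, f, ph in zip(weights, freqs, phases):
            acc += w * np.cos(u @ f + ph)
        return np.clip(acc, -1.2, 1.2)

    return perturb


def _fibonacci_sphere(n: int = 512) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


_FIB_DIRS = _fibonacci_sphere()


def _volume_correction(perturb, amplitude: float) -> float:
    """Radius rescale so the perturbed shape keeps the ellipsoid's volume.

    The enclosed volume of radius field 1 + a*P scales like the spherical
    mean of (1 + a*P)^3 (~1 + 3 a^2 for unit-RMS P), so without correction
    lobulated shapes would be systematically larger than their base
    ellipsoid and the volume time course would leak into the shape drift.
    """
    if amplitude == 0:
        return 1.0
    return float(np.mean((1.0 + amplitude * perturb(_FIB_DIRS)) ** 3) ** (1 / 3))


def _mask_from_params(center: np.ndarray, semi_axes: np.ndarray,
                      rotation: np.ndarray, amplitude: float,
                      perturb, grid: VolumeGrid) -> RoiMask:
    sp = np.asarray(grid.spacing)
    # evaluate only inside the tumor's bounding box (speed)
    reach = semi_axes.max() * (1 + _MAX_AMPLITUDE) + 2 * sp.max()
    lo = np.maximum(((center - reach) / sp).astype(int), 0)
    hi = np.minimum(((center + reach) / sp).astype(int) + 2,
                    np.array(grid.shape))
    if np.any(hi <= lo):
        raise PhantomError("tumor lies outside the grid extent")
    idx = np.indices(hi - lo).astype(float)
    x = (idx + lo.reshape(3, 1, 1, 1)) * sp.reshape(3, 1, 1, 1) \
        - center.reshape(3, 1, 1, 1)
    pts = np.moveaxis(x, 0, -1) @ rotation  # to tumor frame
    s = pts / semi_axes
    rho = np.linalg.norm(s, axis=-1)
    with np.errstate(invalid="ignore"):
        u = np.where(rho[..., None] > 0, s / np.maximum(rho[..., None], 1e-12), 0.0)
    radius = (1.0 + amplitude * perturb(u)) / _volume_correction(perturb,
                                                                 amplitude)
    inside = rho <= radius
    full = np.zeros(grid.shape, dtype=bool)
    full[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    if not full.any():
        raise PhantomError("generated tumor mask is empty")
    return RoiMask(full, grid.spacing, grid.origin)


def generate_tumor_mask(semi_axes: Sequence[float], lobulation_amplitude: float,
                        orientation: np.ndarray | None, grid: VolumeGrid,
                        rng: np.random.Generator,
                        center: Sequence[float] | None = None) -> RoiMask:
    """Voxelized, connected, possibly lobulated ellipsoid on ``grid``."""
    semi_axes = np.asarray(semi_axes, dtype=float)
    sp = np.asarray(grid.spacing)
    if np.any(semi_axes / sp < 2):
        raise PhantomError(
            f"semi-axes {tuple(semi_axes)} smaller than 2 voxels on spacing "
            f"{tuple(sp)}")
    extent = (np.array(grid.shape) - 1) * sp
    if np.any(2 * semi_axes * (1 + max(lobulation_amplitude, 0)) > extent):
        raise PhantomError("tumor larger than the grid")
    if orientation is None:
        orientation = _random_rotation(rng)
    if center is None:
        center = extent / 2
    perturb = _sample_perturbation(rng)
    return _mask_from_params(np.asarray(center, float), semi_axes, orientation,
                             lobulation_amplitude, perturb, grid)


def _solve_amplitude(target_r: float, center, semi_axes, rotation, perturb,
                     grid: VolumeGrid, tol: float = 0.004,
                     max_iter: int = 9) -> tuple[float, RoiMask, float]:
    """Bisect the lobulation amplitude so measured roundness hits target_r.

    Roundness decreases monotonically with amplitude; targets above the
    amplitude-0 roundness clamp to 0, targets below the max-amplitude
    roundness clamp to the maximum.
    """
    lo_amp, hi_amp = 0.0, _MAX_AMPLITUDE
    m_lo = _mask_from_params(center, semi_axes, rotation, lo_amp, perturb, grid)
    r_lo = roundness(m_lo)
    if target_r >= r_lo:
        return lo_amp, m_lo, r_lo
    m_hi = _mask_from_params(center, semi_axes, rotation, hi_amp, perturb, grid)
    r_hi = roundness(m_hi)
    if target_r <= r_hi:
        return hi_amp, m_hi, r_hi
    best = (lo_amp, m_lo, r_lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo_amp + hi_amp)
        m = _mask_from_params(center, semi_axes, rotation, mid, perturb, grid)
        r = roundness(m)
        if abs(r - target_r) < abs(best[2] - target_r):
            best = (mid, m, r)
        if abs(r - target_r) <= tol:
            return mid, m, r
        if r > target_r:
            lo_amp = mid
        else:
            hi_amp = mid
    return best


def simulate_timecourse(label: int, spec: PhantomSpec,
                        rng: np.random.Generator,
                        grid: VolumeGrid | None = None):
    """Pre/mid/post masks with a class-dependent roundness drift.

    Returns ``(masks, info)`` where ``masks`` is a dict of
    :class:`RoiMask` per timepoint and ``info`` records targets, achieved
    roundness and shape parameters.
    """
    spec.validate()
    if grid is None:
        grid = _ct_grid(spec)
    sp = np.asarray(grid.spacing)
    extent = (np.array(grid.shape) - 1) * sp

    axes_pre = np.asarray(spec.base_semi_axes) * rng.uniform(0.9, 1.1, size=3)
    rotation = _random_rotation(rng)
    center = extent / 2 + rng.uniform(-3, 3, size=3)
    perturb = _sample_perturbation(rng)

    if label == 1:
        r_pre = rng.normal(spec.roundness_pre_recurrent, spec.roundness_pre_sd)
        drift = spec.roundness_drift_recurrent + rng.normal(
            0, spec.drift_noise_sd_recurrent)
        mid_drift = spec.roundness_mid_drift_recurrent + rng.normal(0, 0.02)
    else:
        r_pre = rng.normal(spec.roundness_pre_nonrecurrent, spec.roundness_pre_sd)
        drift = spec.roundness_drift_nonrecurrent + rng.normal(
            0, spec.drift_noise_sd_nonrecurrent)
        mid_drift = spec.roundness_mid_drift_nonrecurrent + rng.normal(0, 0.02)
    targets = {"pre": r_pre, "mid": r_pre + mid_drift, "post": r_pre + drift}
    for tp, t in targets.items():
        if not (0.05 < t <= 1.0):
            raise PhantomError(f"infeasible roundness target {t:.3f} at {tp}")

    f_post = 1.0 - spec.shrink_fraction  # volume factor pre -> post
    f_mid = np.sqrt(f_post)

    def axes_at(tp: str) -> np.ndarray:
        f = {"pre": 1.0, "mid": f_mid, "post": f_post}[tp]
        w = {"pre": 0.0, "mid": 0.5, "post": 1.0}[tp]
        if label == 1:
            # relax toward equal axes (rounder), isotropic shrink
            ax = axes_pre + w * 0.5 * (axes_pre.mean() - axes_pre)
            ax *= (f * np.prod(axes_pre) / np.prod(ax)) ** (1 / 3)
        else:
            # anisotropic single-axis regression: z shrinks hardest
            sz = f ** 0.7
            sxy = np.sqrt(f / sz)
            ax = axes_pre * np.array([sxy, sxy, sz])
        return ax

    masks: dict[str, RoiMask] = {}
    info: dict[str, dict] = {"label": label, "targets": targets,
                             "achieved": {}, "amplitude": {}, "axes": {}}
    for tp in ("pre", "mid", "post"):
        amp, mask, r = _solve_amplitude(targets[tp], center, axes_at(tp),
                                        rotation, perturb, grid)
        masks[tp] = mask
        info["achieved"][tp] = r
        info["amplitude"][tp] = amp
        info["axes"][tp] = axes_at(tp).tolist()
    return masks, info


# ---------------------------------------------------------------------------
# Intensity phantoms


def fill_intensities(mask: RoiMask, modality: str, spec: PhantomSpec,
                     rng: np.random.Generator) -> VolumeGrid:
    """Fill a grid with phantom CT or SUV values around the tumor mask.

    CT: a spatially correlated Gaussian field (mean ``ct_mean``, SD
    ``ct_sd``, correlation length ``texture_correlation_length``) inside a
    body ellipse, air (-1000 HU) outside; the tumor region is offset
    slightly denser.  SUV: near-zero background plus tumor uptake that
    peaks at ``suv_peak`` in the core and decays toward the boundary, with
    multiplicative noise clipped at the peak (detector saturation).
    """
    if mask.n_foreground == 0:
        raise ValueError("fill_intensities requires a non-empty mask")
    sp = np.asarray(mask.spacing)
    shape = np.array(mask.shape)
    extent = (shape - 1) * sp
    idx = np.indices(mask.shape).astype(float)
    x = idx * sp.reshape(3, 1, 1, 1)
    center = extent / 2

    if modality == "CT":
        body = (((x[0] - center[0]) / (0.48 * extent[0])) ** 2
                + ((x[1] - center[1]) / (0.48 * extent[1])) ** 2) <= 1.0
        noise = rng.normal(size=mask.shape)
        sigma_vox = np.maximum(spec.texture_correlation_length / sp, 1e-6)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        sd = smooth.std()
        field = spec.ct_mean + (spec.ct_sd / sd if sd > 0 else 0.0) * smooth
        field = np.where(body, field, -1000.0)
        field[mask.mask] += 15.0  # tumor slightly denser than soft tissue
        return VolumeGrid(field.astype(np.float32), mask.spacing, mask.origin, "CT")
    if modality == "SUV":
        dt = ndimage.distance_transform_edt(mask.mask, sampling=sp)
        profile = np.sqrt(dt / dt.max()) if dt.max() > 0 else mask.mask.astype(float)
        uptake = spec.suv_peak * profile * (1.0 + 0.08 * rng.normal(size=mask.shape))
        uptake = np.clip(uptake, 0.0, spec.suv_peak)
        background = np.abs(rng.normal(0.0, 0.05, size=mask.shape))
        field = np.where(mask.mask, np.maximum(uptake, 0.0), background)
        return VolumeGrid(field.astype(np.float32), mask.spacing, mask.origin, "SUV")
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# Cohort assembly


def generate_cohort(spec: PhantomSpec) -> SyntheticCohort:
    """A full synthetic cohort: n_patients x 3 sessions on a shared frame.

    Class counts match ``recurrence_fraction`` exactly (first
    ``ceil(n * fraction)`` patients recurrent, order shuffled by seed); all
    randomness is a pure function of ``spec.seed``.
    """
    spec.validate()
    n = spec.n_patients
    n_rec = int(np.ceil(n * spec.recurrence_fraction))
    if n_rec < 1 or n_rec >= n:
        raise PhantomError(
            f"cannot place both classes with n={n}, fraction={spec.recurrence_fraction}")
    labels = np.array([1] * n_rec + [0] * (n - n_rec))
    root = np.random.default_rng(spec.seed)
    root.shuffle(labels)
    children = np.random.SeedSequence(spec.seed).spawn(n)

    ct_grid = _ct_grid(spec)
    pet_grid = _pet_grid(spec)
    sessions: list[ScanSession] = []
    truth: dict[str, dict] = {}
    rows = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        label = int(labels[i])
        rng = np.random.default_rng(children[i])
        masks, info = simulate_timecourse(label, spec, rng, ct_grid)
        truth[pid] = info
        rows.append({"patient_id": pid, "recurrence": label})
        timepoints = ("pre", "mid", "post") if i not in spec.drop_mid_for \
            else ("pre", "post")
        for tp in timepoints:
            gtv_ct = masks[tp]
            gtv_suv = resample_mask(gtv_ct, pet_grid)
            if spec.fill_intensity_volumes:
                ct = fill_intensities(gtv_ct, "CT", spec, rng)
                suv = fill_intensities(gtv_suv, "SUV", spec, rng)
            else:
                ct = VolumeGrid(np.zeros(ct_grid.shape, np.float32),
                                ct_grid.spacing, ct_grid.origin, "CT")
                suv = VolumeGrid(np.zeros(pet_grid.shape, np.float32),
                                 pet_grid.spacing, pet_grid.origin, "SUV")
            sessions.append(ScanSession(pid, tp, ct, suv, gtv_ct, gtv_suv))
    cohort = CohortTable(pd.DataFrame(rows))
    return SyntheticCohort(sessions, cohort, truth, spec)
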