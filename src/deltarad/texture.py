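"""3D texture features: gray-level co-occurrence and run-length matrices.

The ROI is quantized to 64 gray levels between its own minimum and maximum.
Co-occurrence (GLCM, 8 features) and run-length (GLRM, 10 features)
statistics are computed separately along each of the 13 unique 3D lattice
directions at distance one voxel, then summarized as the mean and the
population standard deviation over directions.

Conventions, recorded in the output metadata: GLCMs are symmetrized and
normalized to unit mass over voxel pairs fully inside the mask; entropy is
log base 2; runs are confined to the mask (a run ends where the mask does);
run lengths are capped at the shortest side of the mask's tight bounding
box, measured in voxels; GLRM features use the 1/N_r normalization with
N_r the total number of runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import RoiMask, VolumeGrid

N_GRAY_LEVELS = 64

GLCM_FEATURE_NAMES = (
    "Energy", "Entropy", "Correlation", "InverseDifferenceMoment",
    "Inertia", "ClusterShade", "ClusterProminence", "HaralickCorrelation",
)
GLRM_FEATURE_NAMES = (
    "SRE", "LRE", "GLN", "RLN", "LGLRE",
    "HGLRE", "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
)
TEXTURE_FEATURE_NAMES = GLCM_FEATURE_NAMES + GLRM_FEATURE_NAMES


@dataclass
class QuantizedRoi:
    """Mask voxels quantized to levels 1..n_levels; 0 marks out-of-mask."""

    levels: np.ndarray  # int array, full volume shape; 0 outside the mask
    n_levels: int
    lo: float
    hi: float

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def quantize_roi(vol: VolumeGrid, mask: RoiMask,
                 n_levels: int = N_GRAY_LEVELS) -> QuantizedRoi:
    """Equal-width binning of masked intensities into ``n_levels`` gray levels.

    Level of value x: ``min(n_levels, 1 + floor(n_levels*(x-lo)/(hi-lo)))``
    with lo/hi the ROI minimum/maximum.  A constant ROI maps to level 1.
    """
    if not mask.same_grid(vol):
        raise ValueError("mask is not aligned to the volume grid")
    if mask.n_foreground == 0:
        raise ValueError("texture quantization requires a non-empty mask")
    x = np.asarray(vol.voxels, dtype=float)
    lo = float(x[mask.mask].min())
    hi = float(x[mask.mask].max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if hi > lo:
        lv = 1 + np.floor(n_levels * (x[mask.mask] - lo) / (hi - lo))
        levels[mask.mask] = np.minimum(n_levels, lv).astype(np.int32)
    else:
        levels[mask.mask] = 1
    return QuantizedRoi(levels, n_levels, lo, hi)


def directions_13() -> list[tuple[int, int, int]]:
    """The 13 unique-up-to-sign nonzero offsets in {-1,0,1}^3."""
    return [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ]


def _offset_slices(shape: tuple[int, ...], offset: tuple[int, int, int]):
    """Slices (a, b) so that a[i] and b[i] are voxel pairs p, p+offset."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        if d > 0:
            sa.append(slice(0, n - d)); sb.append(slice(d, n))
        elif d < 0:
            sa.append(slice(-d, n)); sb.append(slice(0, n + d))
        else:
            sa.append(slice(0, n)); sb.append(slice(0, n))
    return tuple(sa), tuple(sb)


def glcm_build(q: QuantizedRoi, offset: tuple[int, int, int]) -> np.ndarray | None:
    """Symmetric, unit-mass co-occurrence matrix for one direction.

    Counts all voxel pairs (p, p+offset) with both endpoints in the mask,
    adds the transpose and normalizes.  Returns None when the direction has
    no valid pair (flagged empty, excluded from aggregation).
    """
    sa, sb = _offset_slices(q.levels.shape, offset)
    a = q.levels[sa].ravel()
    b = q.levels[sb].ravel()
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    n = q.n_levels
    counts = np.bincount((a[valid] - 1) * n + (b[valid] - 1),
                         minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(m: np.ndarray) -> dict[str, float]:
    """The 8 co-occurrence features of a normalized symmetric GLCM."""
    n = m.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p = m
    px = p.sum(axis=1)  # marginal (symmetric: row = column marginal)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    inertia = float((((ii - jj) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    shade = float(((ii - mu + jj - mu) ** 3 * p).sum())
    prominence = float(((ii - mu + jj - mu) ** 4 * p).sum())
    if var > 0:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / var)
        haralick = float(((ii * jj * p).sum() - mu**2) / var)
    else:
        correlation = haralick = 0.0
    return {
        "Energy": energy, "Entropy": entropy, "Correlation": correlation,
        "InverseDifferenceMoment": idm, "Inertia": inertia,
        "ClusterShade": shade, "ClusterProminence": prominence,
        "HaralickCorrelation": haralick,
    }


def run_cap(mask: RoiMask | np.ndarray) -> int:
    """Shortest side, in voxels, of the mask's tight bounding box."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("run cap of an empty mask is undefined")
    idx = np.nonzero(m)
    return int(min(i.max() - i.min() + 1 for i in idx))


def glrm_build(q: QuantizedRoi, offset: tuple[int, int, int],
               max_run: int) -> np.ndarray | None:
    """Run-length count matrix (levels x max_run) for one direction.

    Maximal same-level runs along each lattice line in the offset
    direction, broken wherever the mask is; runs longer than ``max_run``
    are recorded at length ``max_run``.  Returns None when the mask is
    empty (no runs).
    """
    pts = np.column_stack(np.nonzero(q.levels))
    if len(pts) == 0:
        return None
    lv = q.levels[q.levels > 0]
    d = np.asarray(offset)
    axis0 = int(np.nonzero(d)[0][0])
    t = pts[:, axis0] * d[axis0]  # step index along the line (d[axis0] = +-1)
    line_id = pts - t[:, None] * d[None, :]  # invariant along the line
    order = np.lexsort((t, line_id[:, 2], line_id[:, 1], line_id[:, 0]))
    t_s = t[order]
    lid_s = line_id[order]
    lv_s = lv[order]
    same_line = np.all(lid_s[1:] == lid_s[:-1], axis=1) & (t_s[1:] == t_s[:-1] + 1)
    run_continues = same_line & (lv_s[1:] == lv_s[:-1])
    # positions where a new run starts
    starts = np.flatnonzero(np.concatenate(([True], ~run_continues)))
    lengths = np.diff(np.concatenate((starts, [len(lv_s)])))
    levels = lv_s[starts]
    lengths = np.minimum(lengths, max_run)
    counts = np.zeros((q.n_levels, max_run), dtype=float)
    np.add.at(counts, (levels - 1, lengths - 1), 1.0)
    return counts


def glrm_features(m: np.ndarray) -> dict[str, float]:
    """The 10 run-length features, each normalized by total runs N_r."""
    n_runs = m.sum()
    if n_runs <= 0:
        raise ValueError("run-length features require at least one run")
    n_levels, max_run = m.shape
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]
    l = np.arange(1, max_run + 1, dtype=float)[None, :]
    s = lambda w: float((m * w).sum() / n_runs)
    return {
        "SRE": s(1.0 / l**2),
        "LRE": s(l**2),
        "GLN": float((m.sum(axis=1) ** 2).sum() / n_runs),
        "RLN": float((m.sum(axis=0) ** 2).sum() / n_runs),
        "LGLRE": s(1.0 / i**2),
        "HGLRE": s(i**2),
        "SRLGLE": s(1.0 / (i**2 * l**2)),
        "SRHGLE": s(i**2 / l**2),
        "LRLGLE": s(l**2 / i**2),
        "LRHGLE": s(i**2 * l**2),
    }


def aggregate_directions(values: list[float | None]) -> tuple[float, float] | None:
    """Mean and population SD over the non-flagged directions.

    ``None`` entries mark directions with no valid pairs/runs; if all
    directions are flagged the feature is missing (returns None).
    """
    ok = [v for v in values if v is not None]
    if not ok:
        return None
    arr = np.asarray(ok, dtype=float)
    return float(arr.mean()), float(arr.std())


def compute_texture_features(vol: VolumeGrid, mask: RoiMask,
                             n_levels: int = N_GRAY_LEVELS) -> dict[str, float]:
    """Mean/SD over 13 directions of the 8 GLCM + 10 GLRM features.

    Returns 36 named values (``MeanOfEnergy``, ``SdOfEnergy``, ...,
    ``MeanOfLRHGLE``, ``SdOfLRHGLE``); a feature with every direction
    flagged is NaN.
    """
    q = quantize_roi(vol, mask, n_levels)
    cap = run_cap(mask)
    per_dir: dict[str, list[float | None]] = {k: [] for k in TEXTURE_FEATURE_NAMES}
    for offset in directions_13():
        g = glcm_build(q, offset)
        gf = glcm_features(g) if g is not None else None
        for k in GLCM_FEATURE_NAMES:
            per_dir[k].append(gf[k] if gf is not None else None)
        r = glrm_build(q, offset, cap)
        rf = glrm_features(r) if r is not None and r.sum() > 0 else None
        for k in GLRM_FEATURE_NAMES:
            per_dir[k].append(rf[k] if rf is not None else None)
    out: dict[str, float] = {}
    for k in TEXTURE_FEATURE_NAMES:
        agg = aggregate_directions(per_dir[k])
        mean, sd = agg if agg is not None else (np.nan, np.nan)
        out[f"MeanOf{k}"] = mean
        out[f"SdOf{k}"] = sd
    return out
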