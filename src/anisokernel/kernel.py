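"""Correlation-deformed distances and Gaussian effect-size recreation.

The voxel space is virtually deformed so that highly correlated
neighboring voxels are brought closer while uncorrelated voxels move
apart. The deformed distance between two adjacent voxels is

    D = sqrt((1 - alpha) * D_real**2 + alpha * 2 * sigma**2 * ln(1/rho))

with ``alpha`` the degree of anisotropy (0 = plain Euclidean,
1 = fully correlation-driven). Distances to non-adjacent voxels are
summed along the shortest path (Dijkstra), the search stopping once
the total distance exceeds the FWHM — where the Gaussian kernel value
has already dropped to 1/16 of the peak. The recreated effect size is

    d_voxel = exp(-D**2 / (2 * sigma**2)) * d_peak
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sparse_dijkstra

from .grid import VolumeGrid
from .template import CorrelationTemplate, _shift_slices

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548
_RHO_ONE_TOL = 1e-12


def sigma_from_fwhm(fwhm_mm: float) -> float:
    """Gaussian sigma for a given full-width at half-maximum.

    sigma = FWHM / (2*sqrt(2 ln 2)) ~= 0.425 * FWHM.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_mm}")
    return fwhm_mm / _FWHM_PER_SIGMA


def fwhm_from_sigma(sigma_mm: float) -> float:
    """Inverse of :func:`sigma_from_fwhm`."""
    if sigma_mm <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_mm}")
    return sigma_mm * _FWHM_PER_SIGMA


def gaussian_value(d_mm, sigma_mm: float, d_peak: float):
    """Un-normalized Gaussian kernel: exp(-D^2 / (2 sigma^2)) * d_peak.

    Accepts scalar or array distances; +inf distances map to 0.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    d_mm = np.asarray(d_mm, dtype=float)
    if np.any(d_mm < 0):
        raise ValueError("distances must be non-negative")
    with np.errstate(over="ignore"):
        out = np.exp(-(d_mm**2) / (2.0 * sigma_mm**2)) * d_peak
    out = np.where(np.isinf(d_mm), 0.0, out)
    return float(out) if out.ndim == 0 else out


def deformed_step(rho, sigma_mm: float, alpha: float, d_real_mm):
    """Deformed distance between two contiguous voxels.

    ``rho`` in (0, 1] gives a finite distance; ``rho <= 0`` or missing
    (NaN) gives +inf. ``rho`` within 1e-12 of 1 is treated as exactly 1
    (a zero-weight step). Scalar or array ``rho``/``d_real_mm``.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    rho = np.asarray(rho, dtype=float)
    d_real = np.asarray(d_real_mm, dtype=float)
    if np.any(d_real <= 0):
        raise ValueError("real distances must be positive")
    if np.any(rho > 1.0 + 1e-9):
        raise ValueError("correlations above 1 are not allowed")
    rho = np.where(rho >= 1.0 - _RHO_ONE_TOL, 1.0, rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(rho > 0, -np.log(rho), np.inf)
        log_term = np.where(np.isnan(rho), np.inf, log_term)
        d2 = (1.0 - alpha) * d_real**2 + alpha * 2.0 * sigma_mm**2 * log_term
    # alpha == 0 must stay Euclidean even where the rho term is inf
    if alpha == 0.0:
        d2 = np.broadcast_to(d_real**2, d2.shape)
    out = np.sqrt(d2)
    return float(out) if out.ndim == 0 else out


@dataclass
class KernelConfig:
    """Kernel parameters: FWHM, degree of anisotropy, cutoff rule."""

    fwhm_mm: float = 20.0
    alpha: float = 1.0
    tissue_threshold: float = 0.1
    cutoff_mm: float | None = None  # default: the FWHM

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("FWHM must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tissue_threshold < 0:
            raise ValueError("tissue threshold must be non-negative")

    @property
    def sigma_mm(self) -> float:
        return sigma_from_fwhm(self.fwhm_mm)

    @property
    def cutoff(self) -> float:
        return self.fwhm_mm if self.cutoff_mm is None else self.cutoff_mm


@dataclass
class DeformedDistanceField:
    """Per-voxel shortest deformed distance (mm) from a seed voxel."""

    seed_voxel: tuple[int, int, int]
    distance: np.ndarray
    cutoff_mm: float = math.inf

    def __post_init__(self) -> None:
        if self.distance[self.seed_voxel] != 0.0:
            raise ValueError("distance at the seed must be 0")


def _offset_real_distances(template: CorrelationTemplate) -> np.ndarray:
    """Euclidean mm distance between voxel centers for each half offset."""
    lin = template.affine[:3, :3]
    return np.array(
        [np.linalg.norm(lin @ np.asarray(o, dtype=float))
         for o in template.offsets.unique_half]
    )


def _edge_graph(template: CorrelationTemplate, config: KernelConfig) -> csr_matrix:
    """Symmetric sparse graph of deformed step distances.

    Correlations are attenuated at query time: each edge's rho is
    multiplied by the smaller of its two endpoints' tissue attenuation
    factors (min(p / threshold, 1)). Edges with rho <= 0 or missing are
    omitted (infinite distance). Zero-length edges (rho == 1 at
    alpha == 1) get a tiny positive weight so the sparse representation
    keeps them.
    """
    shape = template.shape
    nvox = int(np.prod(shape))
    sigma = config.sigma_mm
    d_reals = _offset_real_distances(template)

    if config.tissue_threshold > 0:
        factor = np.minimum(
            template.tissue_prob.data / config.tissue_threshold, 1.0
        )
    else:
        factor = np.ones(shape)

    flat = np.arange(nvox).reshape(shape)
    rows, cols, weights = [], [], []
    for k, off in enumerate(template.offsets.unique_half):
        src, dst = _shift_slices(shape, off)
        rho = template.rho[(k,) + src] * np.minimum(factor[src], factor[dst])
        w = deformed_step(rho, sigma, config.alpha, d_reals[k])
        valid = np.isfinite(w)
        if not np.any(valid):
            continue
        u = flat[src][valid]
        v = flat[dst][valid]
        wv = np.maximum(w[valid], 1e-300)  # keep zero-weight edges stored
        rows.append(u)
        cols.append(v)
        weights.append(wv)
    if not rows:
        return csr_matrix((nvox, nvox))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    graph = csr_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(nvox, nvox),
    )
    return graph


def propagate_multi(
    template: CorrelationTemplate,
    seeds: list[tuple[int, int, int]],
    config: KernelConfig,
) -> np.ndarray:
    """Shortest deformed distances from several seeds at once.

    Returns an array of shape ``(len(seeds),) + grid shape`` with +inf
    beyond the cutoff. Propagation is unrestricted by any tissue mask;
    low-tissue voxels only attenuate the correlations.
    """
    shape = template.shape
    for s in seeds:
        idx = np.asarray(s, dtype=int)
        if np.any(idx < 0) or np.any(idx >= np.array(shape)):
            raise ValueError(f"seed {tuple(s)} outside grid of shape {shape}")
    if not seeds:
        return np.empty((0,) + shape)
    graph = _edge_graph(template, config)
    flat_seeds = [int(np.ravel_multi_index(tuple(s), shape)) for s in seeds]
    dist = _sparse_dijkstra(
        graph, directed=False, indices=flat_seeds, limit=config.cutoff
    )
    return dist.reshape((len(seeds),) + shape)


def propagate(
    template: CorrelationTemplate,
    seed: tuple[int, int, int],
    config: KernelConfig,
) -> DeformedDistanceField:
    """Dijkstra propagation of deformed distances from one seed voxel.

    Expansion stops when the total distance exceeds the cutoff
    (default: the FWHM, where the kernel value is d_peak/16).
    """
    dist = propagate_multi(template, [tuple(seed)], config)[0]
    return DeformedDistanceField(
        seed_voxel=tuple(int(i) for i in seed),
        distance=dist,
        cutoff_mm=config.cutoff,
    )


def recreate_from_peak(
    template: CorrelationTemplate,
    peak,
    config: KernelConfig,
) -> VolumeGrid:
    """Recreate the effect-size map of a single reported peak.

    ``peak`` needs ``coord_mm`` and ``value`` attributes (see
    :class:`~anisokernel.meta.Peak`); the coordinate is snapped to the
    nearest voxel. Voxels beyond the cutoff get 0; the peak voxel gets
    the full peak value.
    """
    ref = VolumeGrid(np.zeros(template.shape), template.affine)
    voxel = ref.nearest_voxel(peak.coord_mm)
    field = propagate(template, voxel, config)
    data = gaussian_value(field.distance, config.sigma_mm, peak.value)
    return VolumeGrid(data, template.affine.copy())


def combine_peak_maps(
    per_peak_maps: list[VolumeGrid],
    per_peak_weights: list[VolumeGrid],
) -> VolumeGrid:
    """Weighted-average combination of per-peak effect-size maps.

    A voxel close to two peaks receives an effect size that depends on
    both: voxelwise sum(w_i * v_i) / sum(w_i), with w_i the
    un-normalized Gaussian factor of peak i at that voxel. Voxels
    reached by no peak (all weights 0) stay 0.
    """
    if not per_peak_maps:
        raise ValueError("need at least one peak map")
    if len(per_peak_maps) != len(per_peak_weights):
        raise ValueError("maps and weights must pair up")
    first = per_peak_maps[0]
    for g in list(per_peak_maps[1:]) + list(per_peak_weights):
        if not first.same_geometry(g):
            raise ValueError("peak maps must share shape and affine")
    values = np.stack([m.data for m in per_peak_maps])
    weights = np.stack([w.data for w in per_peak_weights])
    wsum = weights.sum(axis=0)
    num = (weights * values).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), 0.0)
    return first.copy_with(out)
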