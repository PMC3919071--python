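"""Per-study effect-size map recreation and random-effects combination.

Each study contributes a table of reported peaks (MNI mm coordinate +
t or d value + group sizes). The pipeline converts t-values to Cohen's
d, recreates a whole-volume effect-size map with the (an)isotropic
kernel, attaches a variance map, and pools studies voxelwise with a
DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid, check_same_geometry
from .kernel import (
    KernelConfig,
    combine_peak_maps,
    gaussian_value,
    propagate_multi,
)
from .template import CorrelationTemplate

log = logging.getLogger(__name__)


@dataclass
class Peak:
    """A reported peak: world coordinate + statistic value."""

    coord_mm: tuple[float, float, float]
    value: float
    stat: str = "d"  # "t" or "d"

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord_mm, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"invalid peak coordinate {self.coord_mm}")
        if not np.isfinite(self.value):
            raise ValueError(f"invalid peak value {self.value}")
        if self.stat not in ("t", "d"):
            raise ValueError(f"stat must be 't' or 'd', got {self.stat!r}")
        self.coord_mm = tuple(float(c) for c in coord)


@dataclass
class Study:
    """A study: peak set + group sizes (n2 = 0 for one-sample designs)."""

    study_id: str
    peaks: list[Peak]
    n1: int
    n2: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2:
            raise ValueError(f"study {self.study_id}: n1 must be >= 2")
        if self.n2 < 0:
            raise ValueError(f"study {self.study_id}: n2 must be >= 0")


@dataclass
class StudyMaps:
    effect: VolumeGrid
    variance: VolumeGrid


@dataclass
class MetaResult:
    pooled_effect: VolumeGrid
    tau2: VolumeGrid
    se: VolumeGrid
    z: VolumeGrid


def t_to_d(t, n1: int, n2: int = 0):
    """Convert a t-statistic to Cohen's d given the group sizes.

    Two-sample: d = t * sqrt(1/n1 + 1/n2); one-sample (n2 == 0):
    d = t / sqrt(n1).
    """
    if n1 < 2:
        raise ValueError("n1 must be >= 2")
    if n2 < 0 or n2 == 1:
        raise ValueError("n2 must be 0 (one-sample) or >= 2")
    t = np.asarray(t, dtype=float)
    if n2 == 0:
        out = t / np.sqrt(n1)
    else:
        out = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    return float(out) if out.ndim == 0 else out


def d_variance(d, n1: int, n2: int = 0):
    """Large-sample variance of Cohen's d.

    Two-sample: 1/n1 + 1/n2 + d^2 / (2 (n1 + n2)); one-sample:
    1/n1 + d^2 / (2 n1).
    """
    if n1 < 2:
        raise ValueError("n1 must be >= 2")
    if n2 < 0 or n2 == 1:
        raise ValueError("n2 must be 0 (one-sample) or >= 2")
    d = np.asarray(d, dtype=float)
    if n2 == 0:
        out = 1.0 / n1 + d**2 / (2.0 * n1)
    else:
        out = 1.0 / n1 + 1.0 / n2 + d**2 / (2.0 * (n1 + n2))
    return float(out) if out.ndim == 0 else out


def recreate_study_effect(
    study: Study,
    template: CorrelationTemplate,
    config: KernelConfig,
) -> VolumeGrid:
    """Whole-volume effect-size map recreated from a study's peaks.

    Peaks with t statistics are converted to d first. Per-peak kernel
    maps are combined with the weighted average; peaks whose coordinate
    falls outside the volume are skipped with a warning (peaks outside
    the tissue mask but inside the volume are retained). No tissue
    masking is applied here.
    """
    ref = VolumeGrid(np.zeros(template.shape), template.affine)
    voxels, d_values = [], []
    for peak in study.peaks:
        d = peak.value if peak.stat == "d" else t_to_d(
            peak.value, study.n1, study.n2
        )
        try:
            voxels.append(ref.nearest_voxel(peak.coord_mm))
        except ValueError as exc:
            warnings.warn(
                f"study {study.study_id}: skipping peak outside volume: {exc}",
                stacklevel=2,
            )
            log.warning("study %s: skipped peak %s", study.study_id,
                        peak.coord_mm)
            continue
        d_values.append(d)

    if not voxels:
        return ref
    dist = propagate_multi(template, voxels, config)
    sigma = config.sigma_mm
    maps, weights = [], []
    for i, d in enumerate(d_values):
        w = gaussian_value(dist[i], sigma, 1.0)
        maps.append(ref.copy_with(w * d))
        weights.append(ref.copy_with(w))
    return combine_peak_maps(maps, weights)


def preprocess_study(
    study: Study,
    template: CorrelationTemplate,
    config: KernelConfig,
) -> StudyMaps:
    """Recreate a study's effect-size and variance maps.

    Recreation runs over the whole volume for diagnostic purposes;
    voxels outside the tissue mask (tissue probability below the
    attenuation threshold) are then discarded (set to NaN). The
    variance map follows :func:`d_variance` voxelwise.
    """
    effect = recreate_study_effect(study, template, config)
    mask = template.tissue_prob.data >= config.tissue_threshold
    eff = np.where(mask, effect.data, np.nan)
    var = np.where(mask, d_variance(effect.data, study.n1, study.n2), np.nan)
    return StudyMaps(
        effect=effect.copy_with(eff),
        variance=effect.copy_with(var),
    )


def random_effects_combine(studies: list[StudyMaps]) -> MetaResult:
    """Voxelwise DerSimonian-Laird random-effects pooling.

    Per voxel: method-of-moments tau^2; weights 1/(var_i + tau^2);
    pooled effect = weighted mean; se = 1/sqrt(sum of weights);
    z = pooled/se. Voxels masked out (NaN) in any study are NaN in the
    result.
    """
    if not studies:
        raise ValueError("need at least one study")
    check_same_geometry([s.effect for s in studies] +
                        [s.variance for s in studies], "study maps")
    d = np.stack([s.effect.data for s in studies])
    var = np.stack([s.variance.data for s in studies])
    k = d.shape[0]
    ref = studies[0].effect

    with np.errstate(invalid="ignore", divide="ignore"):
        w = 1.0 / var
        wsum = w.sum(axis=0)
        mu_fixed = (w * d).sum(axis=0) / wsum
        q = (w * (d - mu_fixed) ** 2).sum(axis=0)
        if k == 1:
            tau2 = np.zeros_like(q)
        else:
            c = wsum - (w**2).sum(axis=0) / wsum
            tau2 = np.maximum(0.0, (q - (k - 1)) / c)
        wstar = 1.0 / (var + tau2)
        wstar_sum = wstar.sum(axis=0)
        pooled = (wstar * d).sum(axis=0) / wstar_sum
        se = 1.0 / np.sqrt(wstar_sum)
        z = pooled / se

    return MetaResult(
        pooled_effect=ref.copy_with(pooled),
        tau2=ref.copy_with(tau2),
        se=ref.copy_with(se),
        z=ref.copy_with(z),
    )
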