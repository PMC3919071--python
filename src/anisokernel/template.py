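"""Correlation templates: neighbor-pair correlations + tissue probability.

A template stores, for every voxel, the across-subject Pearson
correlation with each of its 26 adjacent voxels. By symmetry only the
13 offsets that are lexicographically positive are stored; the value
for an offset ``-o`` at voxel ``v`` is the value stored for ``o`` at
voxel ``v + (-o)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import VolumeGrid, check_same_geometry

Offset = tuple[int, int, int]


@dataclass(frozen=True)
class NeighborOffsets:
    """The 26-neighborhood offsets and their canonical 13-offset half."""

    offsets: tuple[Offset, ...]
    unique_half: tuple[Offset, ...]

    def half_index(self, offset: Offset) -> tuple[int, bool]:
        """Index into ``unique_half`` for an offset.

        Returns ``(index, flipped)`` where ``flipped`` is True when the
        stored representative is ``-offset``.
        """
        o = tuple(int(c) for c in offset)
        if o in self._half_lookup:
            return self._half_lookup[o], False
        neg = tuple(-c for c in o)
        if neg in self._half_lookup:
            return self._half_lookup[neg], True
        raise KeyError(f"{offset} is not a 26-neighborhood offset")

    @property
    def _half_lookup(self) -> dict[Offset, int]:
        return {o: i for i, o in enumerate(self.unique_half)}


def neighbor_offsets() -> NeighborOffsets:
    """Enumerate the 26-neighborhood in fixed lexicographic order.

    The canonical half consists of the 13 offsets whose first nonzero
    component is positive, so that for every offset exactly one of
    ``{o, -o}`` is a representative.
    """
    offs = tuple(
        o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
    )
    half = tuple(o for o in offs if o > (0, 0, 0))
    return NeighborOffsets(offsets=offs, unique_half=half)


@dataclass
class CorrelationTemplate:
    """13 neighbor-correlation maps + a tissue-probability map.

    ``rho`` has shape ``(13,) + grid shape``; slot ``k`` holds the
    correlation of each voxel with its neighbor at
    ``offsets.unique_half[k]``. Missing correlations (zero variance,
    out-of-bounds neighbor) are NaN.
    """

    rho: np.ndarray
    tissue_prob: VolumeGrid
    offsets: NeighborOffsets = field(default_factory=neighbor_offsets)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 4 or self.rho.shape[0] != len(self.offsets.unique_half):
            raise ValueError(
                f"rho must have shape (13, nx, ny, nz), got {self.rho.shape}"
            )
        if self.rho.shape[1:] != self.tissue_prob.shape:
            raise ValueError(
                f"rho grid {self.rho.shape[1:]} does not match tissue map "
                f"{self.tissue_prob.shape}"
            )
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tissue_prob.shape

    @property
    def affine(self) -> np.ndarray:
        return self.tissue_prob.affine

    def correlation(self, voxel, offset) -> float:
        """Correlation between ``voxel`` and its neighbor at ``offset``.

        Works for all 26 offsets: querying ``-o`` returns the value
        stored for ``o`` at the displaced voxel. NaN outside the grid.
        """
        k, flipped = self.offsets.half_index(offset)
        v = np.asarray(voxel, dtype=int)
        base = v + np.asarray(offset, dtype=int) if flipped else v
        if np.any(base < 0) or np.any(base >= np.array(self.shape)):
            return float("nan")
        return float(self.rho[(k, *base)])


def neighbor_correlations(subject_volumes: list[VolumeGrid]) -> CorrelationTemplate:
    """Across-subject Pearson correlation of each voxel with its neighbors.

    For each voxel and each of the 13 canonical offsets the per-subject
    values at the voxel are correlated with the per-subject values at
    the neighbor. Voxels where either series has zero variance, and
    neighbors outside the grid, are NaN.

    The returned template carries a uniform tissue probability of 1;
    replace it via :func:`tissue_probability` when attenuation is
    wanted.
    """
    if len(subject_volumes) < 3:
        raise ValueError(
            f"need at least 3 subject volumes, got {len(subject_volumes)}"
        )
    check_same_geometry(subject_volumes, "subject volumes")
    offsets = neighbor_offsets()
    stack = np.stack([v.data for v in subject_volumes])  # (n, x, y, z)
    n = stack.shape[0]
    centered = stack - stack.mean(axis=0)
    ss = (centered**2).sum(axis=0)

    shape = stack.shape[1:]
    rho = np.full((len(offsets.unique_half),) + shape, np.nan)
    for k, off in enumerate(offsets.unique_half):
        src, dst = _shift_slices(shape, off)
        a = centered[(slice(None),) + src]
        b = centered[(slice(None),) + dst]
        cov = (a * b).sum(axis=0)
        denom = np.sqrt(ss[src] * ss[dst])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
        rho[(k,) + src] = np.clip(r, -1.0, 1.0)

    tissue = VolumeGrid(np.ones(shape), subject_volumes[0].affine.copy())
    meta = {"n_subjects": n, "tissue": None, "smoothing_sigma_mm": None}
    return CorrelationTemplate(rho=rho, tissue_prob=tissue, offsets=offsets,
                               metadata=meta)


def _shift_slices(shape, offset):
    """Slices (src, dst) so arr[dst] is arr shifted by ``offset`` at src."""
    src, dst = [], []
    for size, o in zip(shape, offset):
        if o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif o > 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    return tuple(src), tuple(dst)


def tissue_probability(
    subject_segmentations: list[VolumeGrid],
    smoothing_sigma_mm: float = 4.0,
) -> VolumeGrid:
    """Smoothed average tissue-probability map.

    Voxelwise mean of the per-subject maps, Gaussian-smoothed with the
    stated sigma (in mm) and clipped to [0, 1]. ``sigma=0`` is the
    plain mean.
    """
    check_same_geometry(subject_segmentations, "segmentations")
    stack = np.stack([v.data for v in subject_segmentations])
    if stack.min() < -1e-9 or stack.max() > 1 + 1e-9:
        raise ValueError(
            f"tissue maps must lie in [0, 1]; observed range "
            f"[{stack.min():.4g}, {stack.max():.4g}]"
        )
    mean = stack.mean(axis=0)
    if smoothing_sigma_mm < 0:
        raise ValueError("smoothing sigma must be non-negative")
    if smoothing_sigma_mm > 0:
        sigma_vox = smoothing_sigma_mm / subject_segmentations[0].voxel_size
        mean = gaussian_filter(mean, sigma=sigma_vox)
    return VolumeGrid(np.clip(mean, 0.0, 1.0),
                      subject_segmentations[0].affine.copy())


def attenuate(rho, tissue_p, threshold: float = 0.1):
    """Proportionally down-weight correlations in low-tissue voxels.

    Where the smoothed tissue probability falls below ``threshold`` the
    correlation is multiplied by ``tissue_p / threshold`` — e.g. with
    the default threshold 0.1, divided by 2 at probability 0.05 and by
    10 at 0.01. At or above the threshold correlations are unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    rho = np.asarray(rho, dtype=float)
    tissue_p = np.asarray(tissue_p, dtype=float)
    if threshold == 0:
        return rho.copy() if rho.shape else float(rho)
    factor = np.minimum(tissue_p / threshold, 1.0)
    out = rho * factor
    return float(out) if out.ndim == 0 else out


def save_template(template: CorrelationTemplate, prefix) -> None:
    """Write a template as NIfTI volumes + JSON sidecar.

    Produces ``<prefix>_rho.nii.gz`` (4D, 13 volumes in canonical
    offset order), ``<prefix>_tissue.nii.gz`` and ``<prefix>.json``.
    """
    import nibabel as nib

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = template.affine
    rho4d = np.moveaxis(template.rho, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(rho4d, affine), str(prefix) + "_rho.nii.gz")
    nib.save(
        nib.Nifti1Image(template.tissue_prob.data.astype(np.float32), affine),
        str(prefix) + "_tissue.nii.gz",
    )
    sidecar = {
        "offsets": [list(o) for o in template.offsets.unique_half],
        "tissue": template.metadata.get("tissue"),
        "n_subjects": template.metadata.get("n_subjects"),
        "smoothing_sigma_mm": template.metadata.get("smoothing_sigma_mm"),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_template(prefix) -> CorrelationTemplate:
    """Load a template written by :func:`save_template`."""
    import nibabel as nib

    sidecar_path = Path(str(prefix) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing template sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())

    img = nib.load(str(prefix) + "_rho.nii.gz")
    rho4d = np.asarray(img.dataobj, dtype=float)
    if rho4d.ndim != 4 or rho4d.shape[-1] != 13:
        raise ValueError(
            f"expected 13 correlation volumes, file has shape {rho4d.shape}"
        )
    offsets = neighbor_offsets()
    stored = [tuple(o) for o in sidecar["offsets"]]
    if stored != list(offsets.unique_half):
        raise ValueError(
            "offset order in sidecar does not match the canonical order"
        )
    timg = nib.load(str(prefix) + "_tissue.nii.gz")
    tissue = VolumeGrid(np.asarray(timg.dataobj, dtype=float), timg.affine)
    meta = {
        "tissue": sidecar.get("tissue"),
        "n_subjects": sidecar.get("n_subjects"),
        "smoothing_sigma_mm": sidecar.get("smoothing_sigma_mm"),
    }
    return CorrelationTemplate(
        rho=np.moveaxis(rho4d, -1, 0),
        tissue_prob=tissue,
        offsets=offsets,
        metadata=meta,
    )
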