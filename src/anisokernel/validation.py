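"""Empirical validation of the kernel recreation accuracy.

Subjects are split into balanced, pairwise-orthogonal halves; each
split yields a two-sample t-map whose suprathreshold cluster peaks are
fed back into the kernel pipeline. Recreated maps are scored against
the "true" effect-size map (the unthresholded t-map converted to d)
with the relative mean square error: the MSE of the current
(anisotropy, FWHM) combination divided by the MSE of the reference
isotropic FWHM = 20 mm setting, in percent. Cells are compared to the
reference with a paired Wilcoxon signed-rank test across splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.linalg import hadamard

from .grid import VolumeGrid, check_same_geometry
from .kernel import KernelConfig
from .meta import Peak, Study, recreate_study_effect, t_to_d
from .template import CorrelationTemplate

REFERENCE_ALPHA = 0.0
REFERENCE_FWHM_MM = 20.0


@dataclass
class SplitPlan:
    """k balanced, pairwise-orthogonal binary splits of n subjects."""

    assignments: np.ndarray  # bool, shape (k, n)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=bool)
        if self.assignments.ndim != 2:
            raise ValueError("assignments must be a (k, n) array")
        k, n = self.assignments.shape
        if np.any(self.assignments.sum(axis=1) != n // 2) or n % 2:
            raise ValueError("each split must be balanced")
        signs = np.where(self.assignments, 1, -1)
        gram = signs @ signs.T
        if k > 1 and np.any(gram[~np.eye(k, dtype=bool)] != 0):
            raise ValueError("splits are not pairwise orthogonal")

    @property
    def n_splits(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.assignments.shape[1]


def orthogonal_splits(n: int, k: int, seed: int = 0) -> SplitPlan:
    """Construct k balanced pairwise-orthogonal splits of n subjects.

    Two splits are orthogonal when they agree on exactly n/2 subjects.
    Uses tiled Sylvester-Hadamard sign columns when n is divisible by a
    suitable power of two; falls back to a seeded randomized search
    otherwise. Deterministic given the seed.
    """
    if n < 2 or n % 2:
        raise ValueError(f"n must be even and >= 2, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)

    m = 2
    while m <= n:
        if m > k and n % m == 0:
            h = hadamard(m)
            cols = h[:, 1 : k + 1].T  # balanced, mutually orthogonal
            signs = np.tile(cols, (1, n // m))
            perm = rng.permutation(n)
            return SplitPlan(assignments=(signs[:, perm] > 0))
        m *= 2

    # randomized search: grow a set of mutually orthogonal sign vectors
    base = np.array([1] * (n // 2) + [-1] * (n // 2))
    for _ in range(100):
        chosen: list[np.ndarray] = []
        for _ in range(k):
            ok = False
            for _ in range(500):
                cand = rng.permutation(base)
                if all(int(cand @ c) == 0 for c in chosen):
                    chosen.append(cand)
                    ok = True
                    break
            if not ok:
                break
        if len(chosen) == k:
            return SplitPlan(assignments=(np.stack(chosen) > 0))
    raise ValueError(
        f"could not construct {k} orthogonal balanced splits of {n} "
        f"subjects; try fewer splits or n divisible by a power of two > k"
    )


def two_sample_t_map(
    group_a: list[VolumeGrid], group_b: list[VolumeGrid]
) -> tuple[VolumeGrid, int]:
    """Voxelwise pooled-variance two-sample t-map and its df.

    Voxels with zero pooled variance are NaN.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    check_same_geometry(list(group_a) + list(group_b), "group volumes")
    a = np.stack([v.data for v in group_a])
    b = np.stack([v.data for v in group_b])
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) /
                     np.where(se > 0, se, 1.0), np.nan)
    return group_a[0].copy_with(t), df


def extract_peaks(
    t_map: VolumeGrid,
    df: int,
    p_threshold: float = 0.001,
    min_extent: int = 10,
) -> list[Peak]:
    """Cluster peaks of a thresholded t-map.

    Voxels with two-tailed p < ``p_threshold`` form clusters under
    26-connectivity; clusters smaller than ``min_extent`` voxels are
    discarded. One peak per cluster at the maximum |t| voxel, sign
    preserved, coordinate reported in world mm.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t_crit = stats.t.isf(p_threshold / 2.0, df)
    t = t_map.data
    supra = np.abs(t) > t_crit
    supra &= np.isfinite(t)
    labels, n_clusters = ndimage.label(supra, structure=np.ones((3, 3, 3)))
    peaks: list[Peak] = []
    for lab in range(1, n_clusters + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) < min_extent:
            continue
        vals = t[tuple(voxels.T)]
        best = voxels[np.argmax(np.abs(vals))]
        peaks.append(
            Peak(
                coord_mm=tuple(t_map.voxel_to_world(best)),
                value=float(t[tuple(best)]),
                stat="t",
            )
        )
    return peaks


def relative_mse(
    recreated: VolumeGrid,
    truth: VolumeGrid,
    mask: np.ndarray,
    reference_mse: float,
) -> float:
    """MSE of the recreation over ``mask``, as percent of a reference MSE."""
    if reference_mse <= 0:
        raise ValueError("reference MSE must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if not recreated.same_geometry(truth):
        raise ValueError("recreated and truth volumes must share geometry")
    mse = float(np.mean((recreated.data[mask] - truth.data[mask]) ** 2))
    return 100.0 * mse / reference_mse


def wilcoxon_signed_rank(values, reference_values) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact distribution (enumeration over sign patterns via convolution)
    for n <= 25 pairs after dropping zero differences; normal
    approximation with tie correction beyond that. All-zero differences
    give p = 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    reference_values = np.asarray(reference_values, dtype=float)
    if values.shape != reference_values.shape or values.ndim != 1:
        raise ValueError("paired 1D vectors required")
    if values.size < 1:
        raise ValueError("need at least one pair")
    diffs = values - reference_values
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= 25:
        return _exact_signed_rank_p(ranks, w_plus)
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var == 0:
        return 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p via the distribution of W+ over all 2^n signs.

    Midranks are doubled so all rank sums are integers; the count of
    sign patterns attaining each W+ is built by convolution.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_patterns = counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


@dataclass
class ValidationGrid:
    """Relative-MSE surface over (alpha, FWHM) with per-split values."""

    alphas: np.ndarray
    fwhms: np.ndarray
    rel_mse: np.ndarray  # (n_alpha, n_fwhm, n_splits), percent
    p_values: np.ndarray  # (n_alpha, n_fwhm) vs the reference cell
    reference: tuple[float, float] = (REFERENCE_ALPHA, REFERENCE_FWHM_MM)
    split_mse: np.ndarray | None = None  # raw per-cell MSEs
    reference_mse: np.ndarray | None = None  # per-split reference MSE

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (alpha, fwhm, split)."""
        rows = []
        for i, a in enumerate(self.alphas):
            for j, f in enumerate(self.fwhms):
                for s in range(self.rel_mse.shape[2]):
                    rows.append(
                        {"alpha": a, "fwhm_mm": f, "split": s,
                         "rel_mse_pct": self.rel_mse[i, j, s]}
                    )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        """One row per cell: mean relative MSE and Wilcoxon p."""
        rows = []
        for i, a in enumerate(self.alphas):
            for j, f in enumerate(self.fwhms):
                rows.append(
                    {"alpha": a, "fwhm_mm": f,
                     "mean_rel_mse_pct": self.rel_mse[i, j].mean(),
                     "wilcoxon_p": self.p_values[i, j]}
                )
        return pd.DataFrame(rows)


def evaluate_grid(
    subject_volumes: list[VolumeGrid],
    template: CorrelationTemplate,
    alphas,
    fwhms,
    split_plan: SplitPlan,
    p_threshold: float = 0.001,
    min_extent: int = 10,
    tissue_threshold: float = 0.1,
    reference: tuple[float, float] = (REFERENCE_ALPHA, REFERENCE_FWHM_MM),
) -> ValidationGrid:
    """Score kernel recreation over an (anisotropy, FWHM) grid.

    For each split: t-map -> thresholded cluster peaks -> per-cell
    recreation -> MSE against the true effect-size map (the
    unthresholded t-map converted to d), over the tissue mask. Relative
    MSE divides by the MSE at the reference cell (isotropic, 20 mm) of
    the same split; a paired Wilcoxon signed-rank p per cell compares
    its MSEs with the reference MSEs across splits.
    """
    alphas = np.asarray(alphas, dtype=float)
    fwhms = np.asarray(fwhms, dtype=float)
    check_same_geometry(subject_volumes, "subject volumes")
    if subject_volumes[0].shape != template.shape:
        raise ValueError("template geometry does not match subject volumes")
    if split_plan.n_subjects != len(subject_volumes):
        raise ValueError("split plan does not match number of subjects")

    mask = template.tissue_prob.data >= tissue_threshold
    if not mask.any():
        raise ValueError("tissue mask is empty")
    n_splits = split_plan.n_splits
    mse = np.full((len(alphas), len(fwhms), n_splits), np.nan)
    ref_mse = np.full(n_splits, np.nan)

    for s in range(n_splits):
        sel = split_plan.assignments[s]
        group_a = [v for v, in_a in zip(subject_volumes, sel) if in_a]
        group_b = [v for v, in_a in zip(subject_volumes, sel) if not in_a]
        try:
            t_map, df = two_sample_t_map(group_a, group_b)
            na, nb = len(group_a), len(group_b)
            truth_data = t_to_d(np.nan_to_num(t_map.data), na, nb)
            truth = t_map.copy_with(truth_data)
            peaks = extract_peaks(t_map, df, p_threshold, min_extent)
            study = Study(f"split{s}", peaks, n1=na, n2=nb)

            def cell_mse(alpha: float, fwhm: float) -> float:
                cfg = KernelConfig(fwhm_mm=fwhm, alpha=alpha,
                                   tissue_threshold=tissue_threshold)
                rec = recreate_study_effect(study, template, cfg)
                return float(np.mean((rec.data[mask] - truth.data[mask]) ** 2))

            ref_mse[s] = cell_mse(*reference)
            if ref_mse[s] <= 0:
                raise ValueError("reference MSE is zero")
            for i, a in enumerate(alphas):
                for j, f in enumerate(fwhms):
                    if (a, f) == tuple(reference):
                        mse[i, j, s] = ref_mse[s]
                    else:
                        mse[i, j, s] = cell_mse(a, f)
        except Exception as exc:
            raise RuntimeError(f"validation failed at split {s}: {exc}") from exc

    rel = 100.0 * mse / ref_mse[None, None, :]
    p_values = np.full((len(alphas), len(fwhms)), np.nan)
    for i in range(len(alphas)):
        for j in range(len(fwhms)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_values[i, j] = wilcoxon_signed_rank(mse[i, j], ref_mse)
    return ValidationGrid(
        alphas=alphas,
        fwhms=fwhms,
        rel_mse=rel,
        p_values=p_values,
        reference=tuple(reference),
        split_mse=mse,
        reference_mse=ref_mse,
    )
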