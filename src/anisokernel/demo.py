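"""Packaged synthetic validation dataset.

Builds, from a single seed, everything the validation harness needs: a
phantom whose tissue is a lattice of small spherical regions separated
by zero-tissue gaps, multi-subject volumes with strong within-region
correlations, one injected group effect per planned split, and the
correlation template computed from the same subjects.

The geometry deliberately places regions within kernel range of each
other: an isotropic kernel bleeds across the gaps into neighboring
regions ("bridges"), while the correlation-deformed kernel is blocked
there by the tissue attenuation — the failure mode the anisotropic
method is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid
from .synthetic import (
    Phantom,
    PhantomSpec,
    Region,
    SimulationParams,
    inject_group_effect,
    make_phantom,
    simulate_subjects,
)
from .template import CorrelationTemplate, neighbor_correlations
from .validation import SplitPlan, orthogonal_splits


@dataclass
class DemoDataset:
    phantom: Phantom
    subject_volumes: list[VolumeGrid]
    template: CorrelationTemplate
    split_plan: SplitPlan
    effect_regions: list[int]


def demo_phantom_spec(
    shape=(28, 28, 28),
    voxel_size_mm: float = 2.0,
    radius_vox: float = 2.5,
    pitch_vox: int = 7,
) -> PhantomSpec:
    """A lattice of small spherical regions separated by tissue gaps."""
    coords = range(pitch_vox // 2 + 1, shape[0], pitch_vox)
    centers = [
        (float(x), float(y), float(z))
        for x in coords
        for y in coords
        for z in coords
    ]
    regions = [
        Region(label=i + 1, kind="sphere", center=cc, size=radius_vox,
               tissue_level=1.0)
        for i, cc in enumerate(centers)
    ]
    return PhantomSpec(
        grid_shape=tuple(shape),
        voxel_size_mm=voxel_size_mm,
        regions=regions,
        background_tissue=0.0,
        boundary_softness_mm=0.25 * voxel_size_mm,
    )


def demo_dataset(
    seed: int = 0,
    n_subjects: int = 24,
    n_splits: int = 4,
    shape=(28, 28, 28),
    effect_d: float = 2.5,
    latent_weight: float = 0.9,
    noise_sigma: float = 0.25,
) -> DemoDataset:
    """Simulate subjects, inject per-split region effects, build template.

    Split ``j`` gets an effect of size ``effect_d`` injected into one
    region for its group-1 subjects, so every split's t-map carries a
    real localized difference (the splits are orthogonal, so each
    effect cancels exactly in every other split's group means). The
    correlation template is computed from the same (post-injection)
    subjects, mirroring a design where template and validation share
    one sample.
    """
    spec = demo_phantom_spec(shape=shape)
    phantom = make_phantom(spec)
    n_regions = len(spec.regions)
    if n_splits > n_regions:
        raise ValueError("more splits than regions to carry effects")
    # spread the effect regions across the lattice
    effect_regions = [
        1 + round(j * (n_regions - 1) / max(n_splits - 1, 1))
        for j in range(n_splits)
    ]
    params = SimulationParams(
        n_subjects=n_subjects,
        latent_weight=latent_weight,
        noise_sigma=noise_sigma,
        smoothing_sigma_mm=spec.voxel_size_mm,
        seed=seed,
    )
    volumes = simulate_subjects(phantom, params)
    plan = orthogonal_splits(n_subjects, n_splits, seed=seed)
    for j in range(n_splits):
        volumes = inject_group_effect(
            volumes, phantom.labels, region=effect_regions[j], d=effect_d,
            group_assignment=plan.assignments[j],
        )
    template = neighbor_correlations(volumes)
    template.tissue_prob = phantom.tissue_prob
    template.metadata.update({"tissue": "demo", "smoothing_sigma_mm": None})
    return DemoDataset(
        phantom=phantom,
        subject_volumes=volumes,
        template=template,
        split_plan=plan,
        effect_regions=effect_regions,
    )
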