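"""Synthetic multi-subject resting-state datasets with known ground truth.

The generator emulates the statistical structure the decoding approach
relies on: a convex "brain" (a flattened ellipsoid), K latent network time
series, and for each network a spatial map that intersects *both* a deep
interior ROI (deeper than any tested surface-mask thickness) and a patch on
the superior surface shell. Surface voxels therefore carry information
linearly related to the interior target signals, which is exactly the
premise the surface decoder tests. On top of the signal the generator adds
polynomial drift, WM/CSF-like and motion-like nuisance time series, and
white voxel noise — each matched to a term the preprocessing removes, so
with all amplitudes at zero the pipeline is exactly invertible.

All subjects share the spatial layout (as if normalized to a common space);
latent draws are independent across subjects and runs, mirroring the
split-half design in which a subject's two runs alternate as training and
testing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    BoldRun,
    ConfigurationError,
    VolumeGrid,
    write_bold,
    write_motion,
    write_volume,
)
from .preprocess import orthogonal_polynomial_basis
from .surface import depth_from_background_mm

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticDataset", "make_brain_mask", "simulate_dataset", "write_dataset"]


@dataclass
class SyntheticSpec:
    """Generator parameters (defaults are the desk-scale study conditions).

    shape / voxel_size_mm : 24^3 grid of 4 mm isotropic voxels (a ~96 mm
        field of view).
    t_len / tr_s : 180 time points per run at TR = 2 s (a 6 min run).
    n_runs / n_subjects : two runs per subject (split-half design).
    n_networks : number of latent networks, each with an interior ROI and a
        superior-surface patch.
    n_null_networks : trailing networks whose surface amplitude is zero
        (their interior signal is invisible from the surface; decoding
        accuracy for them should be centered on zero).
    effect_amplitude : scale of the network signal at each member voxel.
    noise_sd : white voxel noise standard deviation.
    drift_order / drift_amplitude : random polynomial drift per voxel, same
        family the preprocessing removes.
    nuisance_amplitude : scale of WM/CSF/motion-like contamination of brain
        voxels.
    ar_coef : AR(1) coefficient of the latent series (0.5 gives a smooth,
        BOLD-like non-flat spectrum for the wavestrap to preserve).
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    t_len: int = 180
    tr_s: float = 2.0
    n_runs: int = 2
    n_subjects: int = 3
    n_networks: int = 4
    n_null_networks: int = 0
    effect_amplitude: float = 1.0
    noise_sd: float = 1.0
    drift_order: int = 4
    drift_amplitude: float = 1.0
    nuisance_amplitude: float = 0.5
    roi_voxels: int = 25
    interior_min_depth_mm: float = 21.0
    ar_coef: float = 0.5
    seed: int = 0
    semi_axes_vox: tuple[float, float, float] | None = None
    flatten_fraction: float | None = 0.75

    def __post_init__(self) -> None:
        if any(s < 12 for s in self.shape):
            raise ConfigurationError("grid shape must be >= 12 on every axis")
        if self.t_len < 32:
            raise ConfigurationError("t_len must be >= 32 (wavestrap needs room)")
        for name in ("effect_amplitude", "noise_sd", "drift_amplitude", "nuisance_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0 <= self.n_null_networks <= self.n_networks):
            raise ConfigurationError("n_null_networks must be within [0, n_networks]")
        if self.n_networks < 1 or self.n_subjects < 1 or self.n_runs < 1:
            raise ConfigurationError("need >= 1 network, subject and run")


@dataclass
class GroundTruth:
    """Everything downstream stages can be checked against."""

    brain_mask: VolumeGrid
    network_names: list[str]
    roi_masks: list[VolumeGrid]          # interior target ROIs, disjoint
    surface_masks: list[VolumeGrid]      # superior-shell patches (empty for null networks)
    mixing_maps: list[VolumeGrid]        # per-network voxel mixing weights
    wm_mask: VolumeGrid
    csf_mask: VolumeGrid
    latents: dict                        # (subject, run) -> (K, T) array, zero mean unit var
    nuisance_series: dict                # (subject, run) -> dict(wm=, csf=, motion=(T,6))
    spec: SyntheticSpec = None


@dataclass
class SyntheticDataset:
    runs: list                # runs[subject][run] -> BoldRun
    motion: list              # motion[subject][run] -> (T, 6) array
    truth: GroundTruth


def make_brain_mask(spec: SyntheticSpec) -> VolumeGrid:
    """A filled ellipsoid, strictly inside the volume, flattened inferiorly.

    Semi-axes default to 0.8 of the half-extent per axis (so the brain spans
    ~80% of the field of view with at least one empty voxel on every face).
    ``flatten_fraction`` f cuts away everything below z_center - f * r_z;
    ``None`` disables the cut (a pure ellipsoid, for geometric checks).
    """
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0
    if spec.semi_axes_vox is not None:
        radii = np.asarray(spec.semi_axes_vox, dtype=float)
    else:
        radii = 0.8 * (shape / 2.0)
    if np.any(radii >= shape / 2.0 - 0.5):
        radii = np.minimum(radii, shape / 2.0 - 1.0)
    idx = np.indices(spec.shape).astype(float)
    u = (idx - center[:, None, None, None]) / radii[:, None, None, None]
    mask = (u**2).sum(axis=0) <= 1.0
    if spec.flatten_fraction is not None:
        z_cut = center[2] - spec.flatten_fraction * radii[2]
        mask &= idx[2] >= z_cut
    # guarantee the one-voxel margin on every face
    mask[0, :, :] = mask[-1, :, :] = False
    mask[:, 0, :] = mask[:, -1, :] = False
    mask[:, :, 0] = mask[:, :, -1] = False
    if not mask.any():
        raise ConfigurationError("degenerate geometry: empty brain mask")
    return VolumeGrid(mask, spec.voxel_size_mm)


def _farthest_point_seeds(candidates: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point sampling over candidate coordinates."""
    # start from the lexicographically smallest candidate (stable)
    order = np.lexsort(candidates.T[::-1])
    pts = candidates[order].astype(float)
    chosen = [0]
    d = np.sum((pts - pts[0]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.sum((pts - pts[nxt]) ** 2, axis=1))
    return pts[chosen].astype(int)


def _blob(candidates: np.ndarray, seed_pt: np.ndarray, n: int) -> np.ndarray:
    """The n candidates nearest to seed_pt (ties by lexicographic order)."""
    d = np.sum((candidates - seed_pt) ** 2, axis=1)
    order = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0], d))
    return candidates[order[:n]]


def _layout(spec: SyntheticSpec, brain: VolumeGrid):
    """Place interior ROIs, WM/CSF blobs and superior-surface patches."""
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0
    depth = depth_from_background_mm(brain)
    K = spec.n_networks

    interior = np.argwhere(brain.data & (depth > spec.interior_min_depth_mm))
    need = K * spec.roi_voxels + 2 * 15
    if interior.shape[0] < need:
        raise ConfigurationError(
            f"interior too small for layout: {interior.shape[0]} voxels deeper than "
            f"{spec.interior_min_depth_mm} mm, need {need}"
        )
    seeds = _farthest_point_seeds(interior, K + 2)
    used = np.zeros(interior.shape[0], dtype=bool)

    def take(seed_pt, n):
        nonlocal used
        avail = interior[~used]
        blob = _blob(avail, seed_pt, n)
        blob_set = {tuple(v) for v in blob}
        used |= np.array([tuple(v) in blob_set for v in interior])
        return blob

    roi_masks = []
    for k in range(K):
        vox = take(seeds[k], spec.roi_voxels)
        m = np.zeros(spec.shape, dtype=bool)
        m[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        roi_masks.append(VolumeGrid(m, spec.voxel_size_mm))
    wm_vox = take(seeds[K], 15)
    csf_vox = take(seeds[K + 1], 15)
    wm = np.zeros(spec.shape, dtype=bool)
    wm[wm_vox[:, 0], wm_vox[:, 1], wm_vox[:, 2]] = True
    csf = np.zeros(spec.shape, dtype=bool)
    csf[csf_vox[:, 0], csf_vox[:, 1], csf_vox[:, 2]] = True

    # superior surface: topmost in-brain voxel of each (x, y) column whose top
    # lies above the volume center; these voxels stay in the final surface
    # mask at every tested thickness (nothing above them to shadow them)
    top = np.full(spec.shape[:2], -1)
    bd = np.asarray(brain.data)
    for x, y in np.argwhere(bd.any(axis=2)):
        top[x, y] = int(np.max(np.nonzero(bd[x, y])[0]))
    cols = np.argwhere(top > center[2])
    n_active = K - spec.n_null_networks
    patch_masks = []
    if n_active > 0:
        ang = np.arctan2(cols[:, 1] - center[1], cols[:, 0] - center[0])
        sector = np.floor((ang + np.pi) / (2 * np.pi) * n_active).astype(int)
        sector = np.clip(sector, 0, n_active - 1)
    for k in range(K):
        m = np.zeros(spec.shape, dtype=bool)
        if k < n_active:
            sel = cols[sector == k]
            m[sel[:, 0], sel[:, 1], top[sel[:, 0], sel[:, 1]]] = True
        patch_masks.append(VolumeGrid(m, spec.voxel_size_mm))
    return roi_masks, patch_masks, VolumeGrid(wm, spec.voxel_size_mm), VolumeGrid(csf, spec.voxel_size_mm)


def _ar1(rng: np.random.Generator, t_len: int, coef: float) -> np.ndarray:
    """Standardized AR(1) series (exact zero mean, unit variance)."""
    innov = rng.standard_normal(t_len)
    x = np.empty(t_len)
    x[0] = innov[0]
    for t in range(1, t_len):
        x[t] = coef * x[t - 1] + innov[t]
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate all runs plus the ground truth for oracle checks.

    Each brain voxel's series is
    ``sum_k w_k(v) latent_k(t) + drift_v(t) + nuisance mixture + noise``;
    WM/CSF blob voxels carry their own nuisance series instead of network
    signal, so the nuisance-design columns built from those masks recover the
    injected series. Identical seeds give bit-identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    brain = make_brain_mask(spec)
    roi_masks, patch_masks, wm_mask, csf_mask = _layout(spec, brain)
    K, T = spec.n_networks, spec.t_len

    bd = np.asarray(brain.data)
    signal_mask = bd & ~wm_mask.data & ~csf_mask.data
    mixing_maps = []
    for k in range(K):
        w = np.zeros(spec.shape)
        for m in (roi_masks[k].data, patch_masks[k].data):
            sel = m & signal_mask
            w[sel] = spec.effect_amplitude * rng.uniform(0.5, 1.5, int(sel.sum()))
        mixing_maps.append(VolumeGrid(w, spec.voxel_size_mm))

    poly = orthogonal_polynomial_basis(T, spec.drift_order)  # T x (order+1)
    n_brain = int(bd.sum())
    brain_idx = np.argwhere(bd)

    runs: list[list[BoldRun]] = []
    motions: list[list[np.ndarray]] = []
    latents: dict = {}
    nuisance: dict = {}
    names = [f"net{k + 1}" for k in range(K)]

    for s in range(spec.n_subjects):
        # nuisance spatial weights are a stable property of the subject
        nw = spec.nuisance_amplitude * rng.standard_normal((n_brain, 8))
        subj_runs: list[BoldRun] = []
        subj_motion: list[np.ndarray] = []
        for r in range(spec.n_runs):
            lat = np.stack([_ar1(rng, T, spec.ar_coef) for _ in range(K)])
            wm_series = _ar1(rng, T, spec.ar_coef)
            csf_series = _ar1(rng, T, spec.ar_coef)
            motion = np.cumsum(0.1 * rng.standard_normal((T, 6)), axis=0)
            drift_coef = spec.drift_amplitude * rng.standard_normal((n_brain, spec.drift_order + 1))

            data = np.zeros(spec.shape + (T,))
            vol = np.zeros((n_brain, T))
            # network signal
            for k in range(K):
                w = np.asarray(mixing_maps[k].data)[bd]
                vol += np.outer(w, lat[k])
            # WM/CSF blobs carry their own series (replacing network signal there)
            wm_sel = np.asarray(wm_mask.data)[bd]
            csf_sel = np.asarray(csf_mask.data)[bd]
            vol[wm_sel] = wm_series
            vol[csf_sel] = csf_series
            # drift, nuisance contamination, noise
            vol += drift_coef @ poly.T
            nuis = np.column_stack([wm_series, csf_series, motion])  # T x 8
            contaminate = ~(wm_sel | csf_sel)
            vol[contaminate] += nw[contaminate] @ nuis.T
            if spec.noise_sd > 0:
                vol += spec.noise_sd * rng.standard_normal((n_brain, T))
            data[brain_idx[:, 0], brain_idx[:, 1], brain_idx[:, 2]] = vol

            subj_runs.append(BoldRun(data, spec.voxel_size_mm, spec.tr_s))
            subj_motion.append(motion)
            latents[(s, r)] = lat
            nuisance[(s, r)] = {"wm": wm_series, "csf": csf_series, "motion": motion}
        runs.append(subj_runs)
        motions.append(subj_motion)

    truth = GroundTruth(
        brain_mask=brain,
        network_names=names,
        roi_masks=roi_masks,
        surface_masks=patch_masks,
        mixing_maps=mixing_maps,
        wm_mask=wm_mask,
        csf_mask=csf_mask,
        latents=latents,
        nuisance_series=nuisance,
        spec=spec,
    )
    return SyntheticDataset(runs=runs, motion=motions, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset as NIfTI volumes plus plain-text motion tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t = ds.truth
    write_volume(t.brain_mask, out / "brain_mask.nii.gz")
    write_volume(t.wm_mask, out / "wm_mask.nii.gz")
    write_volume(t.csf_mask, out / "csf_mask.nii.gz")
    for name, roi, patch, mix in zip(t.network_names, t.roi_masks, t.surface_masks, t.mixing_maps):
        write_volume(roi, out / f"roi_{name}.nii.gz")
        write_volume(mix, out / f"template_{name}.nii.gz")
        if np.asarray(patch.data).any():
            write_volume(patch, out / f"surface_patch_{name}.nii.gz")
    for s, (subj_runs, subj_motion) in enumerate(zip(ds.runs, ds.motion), start=1):
        for r, (run, motion) in enumerate(zip(subj_runs, subj_motion), start=1):
            write_bold(run, out / f"sub-{s:02d}_run-{r}_bold.nii.gz")
            write_motion(motion, out / f"sub-{s:02d}_run-{r}_motion.par")
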