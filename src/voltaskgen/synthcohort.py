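"""Synthetic cohorts with known rest-to-task structure.

The generator emulates the statistical premise of the whole pipeline — that
resting-state and task-evoked activity share an intrinsic network
architecture — in a fully controlled form:

* An ellipsoidal "brain" mask carries K compact pseudo-ICA components
  (nearest-seed parcels from farthest-point seed sampling).
* Each subject has a latent fingerprint ``f_s``.  Resting series mix K
  latent ROI signals: a voxel of ROI k reads the ROI's own signal plus a
  subject-specific cross-ROI coupling ``C_s = coupling_scale * H f_s``
  scaled by a smooth fixed spatial profile, plus i.i.d. noise.  The
  fingerprint is therefore encoded in the voxel-to-ROI connectome.
* Contrast maps are per-ROI affine functions of the subject's *empirical*
  connectome: ``map = template_amplitude * (b0 + b . conn_ref)
  + subject_amplitude * g(b . (conn_s - conn_ref)) + noise`` where
  ``conn_ref`` is the cohort-mean connectome, so the template is the same
  function of the group connectome.  With ``g`` the identity (linear mode)
  and unit amplitudes the per-ROI linear baseline is exactly
  well-specified; nonlinear mode applies a tanh squashing to the
  standardized subject-deviation readout.
* Phenotypes couple linearly to the fingerprint at a stated effect size.

A transfer cohort reuses the *same* contrast-generating heads (b0, b,
conn_ref, readout scales) while shifting the low-level rest statistics
(dataset-level coupling offset, inflated rest noise) by a stated
magnitude; with magnitude 0 and the same spec it reproduces the base
cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .connectome import BoldTimeSeries, IcaAtlas, voxel_to_roi_connectome
from .volio import MaskedGrid, scatter_mask

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_atlas",
    "generate_cohort",
    "generate_transfer_cohort",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for a generated cohort (desk-scale defaults)."""

    n_subjects: int = 32
    shape: tuple[int, int, int] = (12, 12, 12)
    n_components: int = 6
    n_contrasts: int = 3
    n_timepoints: int = 120
    fingerprint_dim: int = 4
    template_amplitude: float = 1.0
    subject_amplitude: float = 1.0
    coupling_scale: float = 0.8
    rest_noise_sd: float = 0.5
    task_noise_sd: float = 0.3
    nonlinear: bool = False
    nonlinear_gain: float = 2.5
    phenotype_effect: float = 0.5
    transfer_shift: float = 0.5
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_subjects, self.n_components, self.n_contrasts,
                  self.n_timepoints, self.fingerprint_dim, *self.shape)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        amps = (self.template_amplitude, self.subject_amplitude,
                self.coupling_scale, self.rest_noise_sd, self.task_noise_sd)
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes and noise SDs must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort with its complete ground truth."""

    spec: SyntheticCohortSpec
    atlas: IcaAtlas
    rest: list[BoldTimeSeries]
    connectomes: np.ndarray       # (S, K, nx, ny, nz)
    maps: np.ndarray              # (S, C, nx, ny, nz)
    noiseless_maps: np.ndarray    # (S, C, nx, ny, nz)
    templates: np.ndarray         # (C, nx, ny, nz)
    phenotypes: pd.DataFrame
    fingerprints: np.ndarray      # (S, fingerprint_dim)
    ground_truth: dict = field(default_factory=dict)

    @property
    def grid(self) -> MaskedGrid:
        return self.atlas.grid

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.phenotypes["subject_id"])


def _ellipsoid_grid(shape: tuple[int, int, int]) -> MaskedGrid:
    """2 mm grid with an ellipsoidal in-brain mask (radii 0.45 * dims)."""
    coords = np.indices(shape, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.maximum(np.asarray(shape) * 0.45, 0.75)
    dist2 = sum(((coords[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -center * 2.0
    return MaskedGrid(dims=shape, affine=affine, mask=mask)


def generate_atlas(spec: SyntheticCohortSpec) -> IcaAtlas:
    """K compact parcels over an ellipsoidal mask (hard labels, 1..K).

    Seeds are chosen by farthest-point sampling (deterministic given the
    spec seed); every in-mask voxel is assigned to its nearest seed, so
    component supports partition the mask and are all non-empty.
    """
    grid = _ellipsoid_grid(spec.shape)
    if spec.n_components > grid.n_mask:
        raise ValueError("grid too small for the requested component count")
    rng = np.random.default_rng([spec.seed, 0])
    pts = np.argwhere(grid.mask).astype(float)
    seeds = [int(rng.integers(len(pts)))]
    d_min = np.linalg.norm(pts - pts[seeds[0]], axis=1)
    for _ in range(1, spec.n_components):
        nxt = int(np.argmax(d_min))
        seeds.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(pts - pts[nxt], axis=1))
    seed_pts = pts[seeds]
    dists = np.linalg.norm(pts[:, None, :] - seed_pts[None, :, :], axis=2)
    masked_labels = dists.argmin(axis=1) + 1
    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[grid.mask] = masked_labels
    return IcaAtlas(grid=grid, mode="hard-labels", labels=labels)


def _smooth_profile(grid: MaskedGrid, rng) -> np.ndarray:
    """Smooth per-voxel coupling profile in [-0.5, 2.5], fixed per head.

    The wide range (including sign flips, as for anticorrelated networks)
    gives the voxel-to-ROI connectome substantial within-parcel contrast,
    which keeps the per-ROI linear readout well-conditioned.
    """
    noise = rng.normal(size=grid.dims)
    smooth = gaussian_filter(noise, sigma=1.5)
    vals = smooth[grid.mask]
    vals = (vals - vals.mean()) / (vals.std() + 1e-12)
    return 1.0 + 1.5 * np.clip(vals, -1.0, 1.0)


def _coupling_profiles(grid: MaskedGrid, n_components: int, rng) -> np.ndarray:
    """One smooth spatial profile per source ROI, shape (n_mask, K).

    Coupling topography varies by connection, not only by voxel; this also
    makes the voxel-to-ROI connectome vary over K directions within each
    parcel, so the per-ROI linear readout is identifiable.
    """
    return np.stack([_smooth_profile(grid, rng) for _ in range(n_components)],
                    axis=1)


def _make_head(spec: SyntheticCohortSpec, atlas: IcaAtlas) -> dict:
    """Cohort-level generative parameters shared with transfer cohorts."""
    rng = np.random.default_rng([spec.seed, 1])
    K, C, F = spec.n_components, spec.n_contrasts, spec.fingerprint_dim
    R = K  # one parcel per component
    H = rng.normal(size=(K, K, F))
    for k in range(K):
        H[k, k, :] = 0.0
    # contrast heads share half their variance: task contrasts ride on a
    # common functional architecture, which is what makes backbone
    # adaptation learned on one contrast transfer to another
    share = np.sqrt(0.5)
    beta0 = (share * rng.normal(size=(1, R))
             + np.sqrt(1 - share**2) * rng.normal(size=(C, R)))
    beta = (share * rng.normal(size=(1, R, K))
            + np.sqrt(1 - share**2) * rng.normal(size=(C, R, K))) / np.sqrt(K)
    w_pheno = rng.normal(size=F)
    rho = _coupling_profiles(atlas.grid, K, rng)
    return {"H": H, "beta0": beta0, "beta": beta, "w_pheno": w_pheno,
            "rho": rho, "conn_ref": None, "z_scale": None}


def _draw_subjects(spec: SyntheticCohortSpec, atlas: IcaAtlas, head: dict,
                   coupling_offset: np.ndarray | float = 0.0,
                   noise_scale: float = 1.0):
    """Rest series, empirical connectomes, fingerprints, latent signals."""
    rng = np.random.default_rng([spec.seed, 2])
    grid = atlas.grid
    labels = atlas.masked_labels()
    K, T, F = spec.n_components, spec.n_timepoints, spec.fingerprint_dim
    rho = head["rho"]

    rest, conns, fingerprints, latents, couplings = [], [], [], [], []
    for s in range(spec.n_subjects):
        f = rng.normal(size=F)
        C_s = spec.coupling_scale * (head["H"] @ f) / np.sqrt(F)
        C_s = C_s + coupling_offset
        np.fill_diagonal(C_s, 0.0)
        latent = rng.normal(size=(K, T))
        base = latent[labels - 1]                       # (n_mask, T)
        mix = (rho * C_s[labels - 1]) @ latent          # (n_mask, T)
        noise = spec.rest_noise_sd * noise_scale * rng.normal(
            size=(grid.n_mask, T))
        ts = BoldTimeSeries(subject_id=f"sub-{s:03d}",
                            values=base + mix + noise, grid=grid)
        rest.append(ts)
        conns.append(voxel_to_roi_connectome(ts, atlas))
        fingerprints.append(f)
        latents.append(latent)
        couplings.append(C_s)
    return (rest, np.stack(conns), np.stack(fingerprints), latents,
            np.stack(couplings))


def _subject_maps(spec: SyntheticCohortSpec, atlas: IcaAtlas, head: dict,
                  connectomes: np.ndarray,
                  center_ref: np.ndarray | None = None):
    """Noiseless maps and templates from the contrast-generating heads.

    The template is the head applied to the reference (base-cohort mean)
    connectome; the subject effect reads out deviations from *center_ref*,
    the generating cohort's own mean connectome (scanner-level mean shifts
    do not propagate into individual activation patterns).
    """
    grid = atlas.grid
    labels = atlas.masked_labels()
    K, C = spec.n_components, spec.n_contrasts
    conn_m = connectomes[:, :, grid.mask]              # (S, K, n_mask)
    conn_ref = head["conn_ref"]                        # (K, n_mask)
    if center_ref is None:
        center_ref = conn_ref
    beta0, beta = head["beta0"], head["beta"]

    # per-voxel ROI-wise coefficients
    b0_vox = beta0[:, labels - 1]                      # (C, n_mask)
    b_vox = beta[:, labels - 1, :]                     # (C, n_mask, K)

    template_m = spec.template_amplitude * (
        b0_vox + np.einsum("cvk,kv->cv", b_vox, conn_ref))

    dev = conn_m - center_ref[None]                    # (S, K, n_mask)
    z = np.einsum("cvk,skv->scv", b_vox, dev)          # (S, C, n_mask)
    if head["z_scale"] is None:
        head["z_scale"] = np.maximum(z.std(axis=(0, 2)), 1e-12)  # (C,)
    z_scale = head["z_scale"]
    if spec.nonlinear:
        g = z_scale[None, :, None] * np.tanh(
            spec.nonlinear_gain * z / z_scale[None, :, None])
    else:
        g = z
    noiseless_m = template_m[None] + spec.subject_amplitude * g

    templates = np.stack([scatter_mask(t, grid) for t in template_m])
    noiseless = np.stack([
        np.stack([scatter_mask(m, grid) for m in subj]) for subj in noiseless_m])
    return noiseless, templates


def _phenotypes(spec: SyntheticCohortSpec, fingerprints: np.ndarray,
                w: np.ndarray) -> pd.DataFrame:
    rng = np.random.default_rng([spec.seed, 4])
    latent = fingerprints @ w
    sd = latent.std()
    z = (latent - latent.mean()) / (sd if sd > 0 else 1.0)
    eff = spec.phenotype_effect
    resid = np.sqrt(max(1.0 - eff**2, 0.0))
    y_cont = eff * z + resid * rng.normal(size=len(z))
    y_bin_latent = eff * z + resid * rng.normal(size=len(z))
    y_bin = (y_bin_latent > np.median(y_bin_latent)).astype(int)
    return pd.DataFrame({
        "subject_id": [f"sub-{s:03d}" for s in range(len(z))],
        "pheno_continuous": y_cont,
        "pheno_binary": y_bin,
    })


def generate_cohort(spec: SyntheticCohortSpec,
                    atlas: IcaAtlas | None = None) -> SyntheticCohort:
    """Generate rest series, contrast maps, phenotypes, and ground truth."""
    if atlas is None:
        atlas = generate_atlas(spec)
    head = _make_head(spec, atlas)
    rest, conns, fingerprints, latents, couplings = _draw_subjects(
        spec, atlas, head)
    head["conn_ref"] = conns[:, :, atlas.grid.mask].mean(axis=0)
    noiseless, templates = _subject_maps(spec, atlas, head, conns)
    rng_task = np.random.default_rng([spec.seed, 3])
    maps = noiseless + spec.task_noise_sd * rng_task.normal(
        size=noiseless.shape) * atlas.grid.mask[None, None]
    phenos = _phenotypes(spec, fingerprints, head["w_pheno"])
    return SyntheticCohort(
        spec=spec, atlas=atlas, rest=rest, connectomes=conns,
        maps=maps.astype(np.float64), noiseless_maps=noiseless,
        templates=templates, phenotypes=phenos, fingerprints=fingerprints,
        ground_truth={"head": head, "latent_signals": latents,
                      "couplings": couplings})


def generate_transfer_cohort(spec: SyntheticCohortSpec,
                             base: SyntheticCohort) -> SyntheticCohort:
    """A second cohort with shifted low-level statistics but the same heads.

    The contrast-generating parameters (b0, b, reference connectome,
    readout scales, spatial profile) come from *base*; the rest data get a
    dataset-level cross-ROI coupling offset of magnitude ``transfer_shift``
    and rest noise inflated by ``1 + transfer_shift``.  With
    ``transfer_shift = 0`` and a spec equal to the base spec this
    reproduces the base cohort exactly.
    """
    atlas = base.atlas
    head = dict(base.ground_truth["head"])  # shared heads, incl. conn_ref
    if head["conn_ref"] is None or head["z_scale"] is None:
        raise ValueError("base cohort ground truth is incomplete")
    shift = spec.transfer_shift
    rng_shift = np.random.default_rng([spec.seed, 5])
    K = spec.n_components
    # dataset-level cross-ROI coupling bias; entries ~ N(0, shift^2), i.e.
    # comparable to the full subject-level coupling variation at shift ~ 0.5
    offset = shift * rng_shift.normal(size=(K, K))
    if shift == 0:
        offset = 0.0
    rest, conns, fingerprints, latents, couplings = _draw_subjects(
        spec, atlas, head, coupling_offset=offset,
        noise_scale=1.0 + shift)
    center = conns[:, :, atlas.grid.mask].mean(axis=0)
    noiseless, templates = _subject_maps(spec, atlas, head, conns,
                                         center_ref=center)
    rng_task = np.random.default_rng([spec.seed, 3])
    maps = noiseless + spec.task_noise_sd * rng_task.normal(
        size=noiseless.shape) * atlas.grid.mask[None, None]
    phenos = _phenotypes(spec, fingerprints, head["w_pheno"])
    return SyntheticCohort(
        spec=spec, atlas=atlas, rest=rest, connectomes=conns,
        maps=maps.astype(np.float64), noiseless_maps=noiseless,
        templates=templates, phenotypes=phenos, fingerprints=fingerprints,
        ground_truth={"head": head, "latent_signals": latents,
                      "couplings": couplings, "coupling_offset": offset})
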