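"""Regional and voxelwise PET statistics: SUVR, rOGI, mixed models, FDR.

Images live in :class:`VoxelImage` (a value grid plus NIfTI affine and an
optional brain mask); regional summaries travel as tidy pandas frames with
columns ``subject, condition, region, value`` (plus ``modality``), the two
clamp conditions coded ``"eu"`` and ``"hyper"``.

The condition contrast at each voxel is a linear mixed model -- a fixed
effect for clamp condition with a random intercept per subject, estimated
by REML (statsmodels MixedLM) with Wald p-values -- followed by
Benjamini-Hochberg control of the false discovery rate across voxels.
Unpaired subjects (only one condition available) are retained, as in the
study's unbalanced design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "VoxelImage",
    "ReferenceRegion",
    "VoxelStatResult",
    "CONDITIONS",
    "regional_delta",
    "select_reference_region",
    "reference_mask",
    "compute_suvr",
    "compute_rogi",
    "smooth_image",
    "random_intercept_lmm",
    "voxelwise_condition_model",
    "fdr_threshold",
    "baseline_change_correlation",
]

CONDITIONS = ("eu", "hyper")


@dataclass(frozen=True)
class VoxelImage:
    """A 3-D value grid with a world affine and optional brain mask."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None
    modality: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, float)
        affine = np.asarray(self.affine, float)
        if data.ndim != 3:
            raise ValueError("data must be a 3-D array")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        if self.mask is not None:
            mask = np.asarray(self.mask, bool)
            if mask.shape != data.shape:
                raise ValueError("mask shape must match data shape")
            object.__setattr__(self, "mask", mask)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def in_mask(self) -> np.ndarray:
        return np.ones(self.data.shape, bool) if self.mask is None else self.mask

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "VoxelImage":
        return VoxelImage(data, self.affine, self.mask,
                          self.modality if modality is None else modality)

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None,
                   modality: str = "") -> "VoxelImage":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), float), img.affine, mask, modality)


@dataclass(frozen=True)
class ReferenceRegion:
    """Named parcellation regions pooled into one reference mask."""

    labels: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("a reference region needs at least one member")


def _check_table(table: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")


def regional_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region mean change (hyper - eu) from a tidy regional table.

    Subject-level values are first averaged within (region, condition)
    using all available subjects per condition, so unpaired subjects
    contribute where they have data.  Returns columns ``region, delta``.
    """
    _check_table(table, ("subject", "condition", "region", "value"))
    bad = set(table["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    means = (table.groupby(["region", "condition"])["value"].mean().unstack())
    for cond in CONDITIONS:
        if cond not in means.columns:
            raise ValueError(f"condition {cond!r} has no data")
    out = (means["hyper"] - means["eu"]).rename("delta").reset_index()
    return out


def select_reference_region(delta_table: pd.DataFrame, n_regions: int = 3
                            ) -> ReferenceRegion:
    """Pick the regions with the smallest absolute metabolic change.

    ``delta_table`` has columns ``region, delta`` (e.g. from
    :func:`regional_delta`).  Ties break deterministically by label order.
    """
    _check_table(delta_table, ("region", "delta"))
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if len(delta_table) < n_regions:
        raise ValueError(
            f"asked for {n_regions} regions but only {len(delta_table)} available")
    ranked = delta_table.assign(absdelta=delta_table["delta"].abs()) \
        .sort_values(["absdelta", "region"], kind="mergesort")
    labels = tuple(ranked["region"].head(n_regions))
    return ReferenceRegion(labels, provenance=f"smallest |delta| of {len(delta_table)} regions")


def reference_mask(ref: ReferenceRegion, parcellation: VoxelImage,
                   lookup: Mapping[str, int] | pd.DataFrame) -> np.ndarray:
    """Voxel mask of the reference region within a label image.

    ``lookup`` maps region name -> integer label, either as a mapping or a
    frame with columns ``label_id, name``.
    """
    if isinstance(lookup, pd.DataFrame):
        _check_table(lookup, ("label_id", "name"))
        lookup = dict(zip(lookup["name"], lookup["label_id"]))
    missing = [lab for lab in ref.labels if lab not in lookup]
    if missing:
        raise ValueError(f"labels {missing} not in the parcellation lookup")
    ids = [int(lookup[lab]) for lab in ref.labels]
    mask = np.isin(parcellation.data.astype(int), ids)
    if not mask.any():
        raise ValueError("reference mask is empty in this parcellation")
    return mask


def compute_suvr(image: VoxelImage, ref: ReferenceRegion,
                 parcellation: VoxelImage,
                 lookup: Mapping[str, int] | pd.DataFrame) -> VoxelImage:
    """Normalise an uptake image by its reference-region mean.

    The reference mean is taken within the brain mask; by construction the
    output's reference-region mean equals 1.
    """
    if image.data.shape != parcellation.data.shape:
        raise ValueError("image and parcellation grids differ")
    mask = reference_mask(ref, parcellation, lookup) & image.in_mask()
    if not mask.any():
        raise ValueError("reference region lies outside the brain mask")
    ref_mean = float(image.data[mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean {ref_mean:.4g}")
    return image.with_data(image.data / ref_mean, modality=f"{image.modality}_suvr".lstrip("_"))


def compute_rogi(o2_suvr: VoxelImage, fdg_suvr: VoxelImage,
                 ref: ReferenceRegion, parcellation: VoxelImage,
                 lookup: Mapping[str, int] | pd.DataFrame,
                 eps: float = 1e-12) -> VoxelImage:
    """Relative oxygen-to-glucose index: O2 SUVR / FDG SUVR, re-anchored.

    Voxels with a (near-)zero FDG denominator are masked out and counted;
    the surviving map is renormalised so its reference-region mean is 1.
    A falling rOGI marks rising non-oxidative glucose use.
    """
    if o2_suvr.data.shape != fdg_suvr.data.shape:
        raise ValueError("O2 and FDG maps must share a grid")
    denom_ok = np.abs(fdg_suvr.data) > eps
    n_masked = int(np.size(denom_ok) - np.count_nonzero(denom_ok))
    if n_masked:
        warnings.warn(f"rOGI: {n_masked} voxels masked for zero FDG denominator",
                      stacklevel=2)
    ratio = np.where(denom_ok, o2_suvr.data / np.where(denom_ok, fdg_suvr.data, 1.0),
                     np.nan)
    base_mask = o2_suvr.in_mask() & fdg_suvr.in_mask() & denom_ok
    ref_vox = reference_mask(ref, parcellation, lookup) & base_mask
    if not ref_vox.any():
        raise ValueError("reference region fully masked in the rOGI map")
    ratio = ratio / float(np.nanmean(ratio[ref_vox]))
    return VoxelImage(np.where(base_mask, ratio, np.nan), o2_suvr.affine,
                      base_mask, modality="rogi")


def smooth_image(image: VoxelImage, fwhm_mm: float = 5.0) -> VoxelImage:
    """Gaussian-smooth an image with an isotropic FWHM in millimetres."""
    if fwhm_mm <= 0:
        return image
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / image.voxel_sizes
    return image.with_data(ndimage.gaussian_filter(image.data, sigma=sigma_vox))


@dataclass(frozen=True)
class VoxelStatResult:
    """Voxelwise condition contrast with FDR-thresholded significance."""

    effect: np.ndarray  # hyper - eu fixed effect per voxel
    p_values: np.ndarray
    q: float
    significant: np.ndarray  # boolean mask, FDR-corrected
    n_obs: int
    mask: np.ndarray
    n_failed: int = 0


def random_intercept_lmm(y: np.ndarray, exog: np.ndarray, groups: np.ndarray,
                         inference: str = "t-containment",
                         n_lambda: int = 601) -> pd.DataFrame:
    """Vectorised REML for ``y ~ X + (1 | group)`` over many responses.

    Fits the same random-intercept design to every column of ``y``
    (``n_obs x n_responses``) at once by profiling the variance ratio
    ``lambda = sigma_b^2 / sigma_e^2`` on a dense log grid: for the
    random-intercept structure ``V = I + lambda*Z Z'`` the GLS solve,
    ``log|V|`` and the REML criterion are all closed-form per lambda, so
    no per-response iterative optimiser is needed.  Estimates agree with
    statsmodels MixedLM to within the grid resolution (the REML surface
    is flat near its optimum).

    Inference on each coefficient uses the Wald statistic referred to a t
    distribution with containment degrees of freedom
    ``n_obs - n_groups - (p - 1)`` -- the exact paired-t df in the
    balanced two-condition case, which keeps small-sample type-I rates
    near nominal where the large-sample normal reference
    (``inference="normal"``) is anticonservative.

    Returns a frame with one row per response: columns ``beta_<j>``,
    ``se_<j>``, ``p_<j>`` per coefficient plus ``sigma2_resid``,
    ``sigma2_group`` and ``lam``.
    """
    Y = np.atleast_2d(np.asarray(y, float))
    if Y.shape[0] == 1:
        Y = Y.T
    X = np.asarray(exog, float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("y and exog disagree on the number of observations")
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = uniques.size
    group_sizes = np.bincount(codes).astype(float)

    lam_grid = np.concatenate([[0.0], np.geomspace(1e-6, 1e6, n_lambda - 1)])
    n_resp = Y.shape[1]
    best = np.full(n_resp, np.inf)
    best_lam = np.zeros(n_resp)
    best_beta = np.zeros((p, n_resp))
    best_xvxi = np.empty((n_resp, p, p))
    best_quad = np.empty(n_resp)

    group_sum = np.zeros((n_groups, n_resp))
    np.add.at(group_sum, codes, Y)
    Xg = np.zeros((n_groups, p))
    np.add.at(Xg, codes, X)

    for lam in lam_grid:
        shrink = lam / (1.0 + lam * group_sizes)  # per group
        # V^{-1} A = A - shrink_g * (group sums broadcast back)
        ViY = Y - (shrink[:, None] * group_sum)[codes]
        ViX = X - (shrink[:, None] * Xg)[codes]
        XtViX = X.T @ ViX
        XtViY = X.T @ ViY
        xvxi = np.linalg.inv(XtViX)
        beta = xvxi @ XtViY
        resid = Y - X @ beta
        rsum = np.zeros((n_groups, n_resp))
        np.add.at(rsum, codes, resid)
        quad = np.einsum("ij,ij->j", resid, resid) \
            - np.einsum("gj,g,gj->j", rsum, shrink, rsum)
        logdet_v = float(np.sum(np.log1p(lam * group_sizes)))
        sign, logdet_x = np.linalg.slogdet(XtViX)
        crit = (n - p) * np.log(np.maximum(quad, 1e-300)) + logdet_v + logdet_x
        better = crit < best
        best[better] = crit[better]
        best_lam[better] = lam
        best_beta[:, better] = beta[:, better]
        best_xvxi[better] = xvxi
        best_quad[better] = quad[better]

    sigma2 = best_quad / max(n - p, 1)
    se = np.sqrt(np.maximum(np.einsum("jkk->jk", best_xvxi * sigma2[:, None, None]), 0.0)
                 ).T  # (p, n_resp)
    stat = np.divide(best_beta, se, out=np.zeros_like(best_beta), where=se > 0)
    if inference == "normal":
        pvals = 2.0 * stats.norm.sf(np.abs(stat))
    elif inference == "t-containment":
        df = max(n - n_groups - (p - 1), 1)
        pvals = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        raise ValueError("inference must be 't-containment' or 'normal'")
    # degenerate zero-residual responses: no evidence against a zero effect
    scale = np.maximum(np.var(Y, axis=0), 1e-300)
    degenerate = sigma2 < 1e-12 * scale
    for j in range(p):
        zero_eff = np.abs(best_beta[j]) <= 1e-8 * np.sqrt(scale)
        pvals[j, degenerate & zero_eff] = 1.0

    out = {}
    for j in range(p):
        out[f"beta_{j}"] = best_beta[j]
        out[f"se_{j}"] = se[j]
        out[f"p_{j}"] = pvals[j]
    out["sigma2_resid"] = sigma2
    out["sigma2_group"] = best_lam * sigma2
    out["lam"] = best_lam
    return pd.DataFrame(out)


def voxelwise_condition_model(images: Sequence[tuple[str, str, VoxelImage]],
                              q: float = 0.05,
                              smooth_fwhm_mm: float = 5.0,
                              mask: np.ndarray | None = None,
                              inference: str = "t-containment"
                              ) -> VoxelStatResult:
    """Fit ``value ~ condition + (1 | subject)`` at every voxel.

    ``images`` is a sequence of ``(subject, condition, image)`` with
    condition in ``{"eu", "hyper"}``; subjects present in only one
    condition are kept.  Images are Gaussian-smoothed first (5 mm FWHM by
    default, the pipeline's pre-statistics smoothing; pass 0 to disable),
    then each in-mask voxel gets a REML mixed model (vectorised via
    :func:`random_intercept_lmm`) and a Wald-t p-value for the condition
    effect; the map is thresholded by Benjamini-Hochberg at level ``q``.
    Voxels where the fit degenerates are masked out and counted.
    """
    if len(images) < 4:
        raise ValueError("need at least 2 subjects x 2 conditions of data")
    conds = [c for _, c, _ in images]
    bad = set(conds) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    for cond in CONDITIONS:
        if sum(c == cond for c in conds) < 2:
            raise ValueError(f"need >= 2 images in condition {cond!r}")

    shape = images[0][2].data.shape
    vox_mask = images[0][2].in_mask().copy() if mask is None else np.asarray(mask, bool)
    smoothed = []
    for subj, cond, img in images:
        if img.data.shape != shape:
            raise ValueError("all images must share a grid")
        smoothed.append((subj, cond, smooth_image(img, smooth_fwhm_mm)))
        vox_mask &= img.in_mask()

    idx = np.flatnonzero(vox_mask.ravel())
    y_mat = np.stack([img.data.ravel()[idx] for _, _, img in smoothed])
    subjects = pd.factorize(np.asarray([s for s, _, _ in smoothed]))[0]
    condition = np.array([1.0 if c == "hyper" else 0.0 for _, c, _ in smoothed])

    n_vox = idx.size
    exog = np.column_stack([np.ones_like(condition), condition])
    fit = random_intercept_lmm(y_mat, exog, subjects, inference=inference)
    effect = fit["beta_1"].to_numpy()
    pvals = fit["p_1"].to_numpy()
    ok = np.isfinite(effect) & np.isfinite(pvals)
    failed = ~ok

    sig_flat = np.zeros(n_vox, bool)
    if ok.any():
        sig_flat[ok] = fdr_threshold(pvals[ok], q)

    def unflatten(values, fill=np.nan):
        out = np.full(np.prod(shape), fill, dtype=values.dtype if values.dtype != bool else bool)
        out[idx] = values
        return out.reshape(shape)

    final_mask = vox_mask.copy()
    final_mask.ravel()[idx[failed]] = False
    return VoxelStatResult(
        effect=unflatten(np.where(ok, effect, np.nan)),
        p_values=unflatten(np.where(ok, pvals, np.nan)),
        q=q,
        significant=unflatten(sig_flat & ok, fill=False),
        n_obs=len(images),
        mask=final_mask,
        n_failed=int(failed.sum()),
    )


def fdr_threshold(p_values: Sequence[float], q: float = 0.05,
                  method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``.

    ``method="by"`` applies the Benjamini-Yekutieli correction for
    arbitrary dependence instead.  Returns a boolean array aligned with
    the input; the rejected set grows monotonically with ``q``.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    m = p.size
    scale = np.sum(1.0 / np.arange(1, m + 1)) if method == "by" else 1.0
    if method not in ("bh", "by"):
        raise ValueError("method must be 'bh' or 'by'")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    crit = q * np.arange(1, m + 1) / (m * scale)
    below = np.flatnonzero(ranked <= crit)
    mask = np.zeros(m, bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


def baseline_change_correlation(baseline: VoxelImage, delta: VoxelImage,
                                mask: np.ndarray | None = None) -> float:
    """Pearson correlation of baseline values against their change.

    Quantifies the spatial coupling between resting metabolism and the
    hyperglycemia-induced change; a strongly negative r means increases
    concentrate where baseline values are low.
    """
    if baseline.data.shape != delta.data.shape:
        raise ValueError("baseline and delta grids differ")
    m = baseline.in_mask() & delta.in_mask()
    if mask is not None:
        m &= np.asarray(mask, bool)
    x = baseline.data[m]
    y = delta.data[m]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 in-mask voxels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
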