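"""Voxel-wise trait-association mapping.

A per-voxel general linear model (intercept + one trait covariate) over
subjects' BPnd images yields a t map (Z-converted through the t null
distribution). Two inference modes mirror the study's two analyses:

* small-volume family-wise-error control on a VOI by max-statistic
  permutation of the covariate (exact under exchangeability, in place of
  random-field theory);
* whole-brain uncorrected height thresholding with a cluster-extent filter
  (connected components, default 6-connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import ConfigurationError, ContractError

#: 6-connectivity (faces only) structuring element for 3-D cluster labelling.
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class AssociationMap:
    """Voxel-wise statistic image for one trait covariate."""

    t_voxels: np.ndarray
    z_voxels: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    trait: str
    n: int
    df: int


@dataclass
class ClusterRecord:
    """One suprathreshold cluster: peak location, height and extent."""

    peak_xyz_mm: tuple
    peak_z: float
    peak_t: float
    size_mm3: float
    n_voxels: int
    direction: str                 # "positive" | "negative"
    p: float | None = None         # corrected or uncorrected, per caller
    trait: str = ""


def _stack(images) -> np.ndarray:
    arrs = [np.asarray(getattr(im, "bpnd_voxels", im), dtype=float)
            for im in images]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ContractError("all subject images must share one grid")
    return np.stack(arrs, axis=0)          # (n, x, y, z)


def _t_from_r(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -0.999999, 0.999999)
    return r * np.sqrt(df / (1.0 - r * r))


def _z_from_t(t: np.ndarray, df: int) -> np.ndarray:
    # SPM-style conversion through the probability integral transform
    p = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0))
    return np.sign(t) * z


def voxelwise_glm(images, covariate, mask, affine=None, trait: str = ""
                  ) -> AssociationMap:
    """Per-voxel OLS of BPnd on [1, trait]; t and Z maps for the slope."""
    data = _stack(images)
    c = np.asarray(covariate, dtype=float)
    n = data.shape[0]
    if len(c) != n:
        raise ContractError("covariate length must match number of images")
    if n < 4:
        raise ContractError("need at least 4 subjects")
    if np.ptp(c) == 0:
        raise ConfigurationError("zero-variance covariate")
    mask = np.asarray(mask, dtype=bool)
    df = n - 2
    X = data[:, mask]                       # (n, V)
    cc = (c - c.mean()) / (c.std() * np.sqrt(n))
    Xc = X - X.mean(axis=0, keepdims=True)
    sd = Xc.std(axis=0) * np.sqrt(n)
    sd = np.where(sd > 0, sd, np.inf)
    r = (cc @ Xc) / sd
    t = _t_from_r(r, df)
    t_img = np.zeros(mask.shape)
    z_img = np.zeros(mask.shape)
    t_img[mask] = t
    z_img[mask] = _z_from_t(t, df)
    if affine is None:
        affine = getattr(images[0], "affine", np.eye(4))
    return AssociationMap(t_img, z_img, mask, np.asarray(affine), trait, n, df)


# ---------------------------------------------------------------------------
# Permutation small-volume FWE
# ---------------------------------------------------------------------------


def _perm_t_matrix(X: np.ndarray, c: np.ndarray, perms: np.ndarray, df: int
                   ) -> np.ndarray:
    """t statistics for many covariate orderings at once: (P, V)."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    sd = Xc.std(axis=0) * np.sqrt(n)
    sd = np.where(sd > 0, sd, np.inf)
    C = c[perms]                                  # (P, n)
    Cc = (C - C.mean(axis=1, keepdims=True))
    Cn = Cc / (C.std(axis=1, keepdims=True) * np.sqrt(n))
    r = (Cn @ Xc) / sd[None, :]
    return _t_from_r(r, df)


def fwe_smallvolume(images, covariate, voi_mask, n_perm: int = 1000,
                    alpha: float = 0.05, seed: int = 0, affine=None,
                    trait: str = "", tail: str = "two",
                    map_builder=voxelwise_glm):
    """Max-statistic permutation FWE correction over a VOI.

    The covariate is permuted across subjects ``n_perm`` times (seeded); each
    voxel's corrected p is the fraction of permutation maxima of |t| (or
    signed t for one-tailed use) at least as large as its observed statistic,
    with the identity permutation included. Returns a dict with the observed
    map, the alpha-level critical value, per-voxel corrected p values, the
    significant-voxel mask, and cluster records of the significant voxels.
    """
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if not voi_mask.any():
        raise ConfigurationError("empty VOI mask")
    if n_perm < 1000:
        raise ConfigurationError("n_perm must be >= 1000")
    if 1.0 / n_perm > alpha:
        raise ConfigurationError("n_perm too small to resolve alpha")
    amap = map_builder(images, covariate, voi_mask, affine=affine, trait=trait)
    data = _stack(images)
    c = np.asarray(covariate, dtype=float)
    n = len(c)
    rng = np.random.default_rng(seed)
    perms = np.stack([np.arange(n)] +
                     [rng.permutation(n) for _ in range(n_perm - 1)], axis=0)
    T = _perm_t_matrix(data[:, voi_mask], c, perms, amap.df)
    stat = np.abs(T) if tail == "two" else (T if tail == "pos" else -T)
    maxima = stat.max(axis=1)                     # (P,)
    obs = stat[0]
    corrected_p = (maxima[None, :] >= obs[:, None]).mean(axis=1)
    crit = float(np.quantile(maxima, 1.0 - alpha))
    sig = corrected_p <= alpha

    sig_mask = np.zeros(voi_mask.shape, dtype=bool)
    sig_mask[voi_mask] = sig
    p_img = np.ones(voi_mask.shape)
    p_img[voi_mask] = corrected_p
    clusters = _clusters_from_mask(amap, sig_mask, p_img=p_img)
    return {"map": amap, "critical_value": crit, "corrected_p": p_img,
            "significant_mask": sig_mask, "clusters": clusters,
            "n_significant": int(sig.sum())}


# ---------------------------------------------------------------------------
# Cluster-extent thresholding
# ---------------------------------------------------------------------------


def _world_coords(affine: np.ndarray, ijk) -> tuple:
    v = affine @ np.array([ijk[0], ijk[1], ijk[2], 1.0])
    return tuple(float(x) for x in v[:3])


def _clusters_from_mask(amap: AssociationMap, supra: np.ndarray,
                        connectivity: int = 6, min_extent_mm3: float = 0.0,
                        p_img: np.ndarray | None = None) -> list[ClusterRecord]:
    vol = float(abs(np.linalg.det(amap.affine[:3, :3])))
    struct = _STRUCT_6 if connectivity == 6 else _STRUCT_18
    records = []
    for sign, direction in ((1.0, "positive"), (-1.0, "negative")):
        m = supra & (np.sign(amap.t_voxels) == sign)
        if not m.any():
            continue
        lab, n_lab = ndimage.label(m, structure=struct)
        for i in range(1, n_lab + 1):
            idx = np.argwhere(lab == i)
            tvals = amap.t_voxels[tuple(idx.T)]
            k = int(np.argmax(np.abs(tvals)))
            peak_ijk = idx[k]
            size = len(idx) * vol
            # tolerance: det() of the affine is only float-exact to ~1e-13
            if size < min_extent_mm3 * (1.0 - 1e-9):
                continue
            records.append(ClusterRecord(
                peak_xyz_mm=_world_coords(amap.affine, peak_ijk),
                peak_z=float(amap.z_voxels[tuple(peak_ijk)]),
                peak_t=float(amap.t_voxels[tuple(peak_ijk)]),
                size_mm3=float(size), n_voxels=len(idx), direction=direction,
                p=None if p_img is None else float(p_img[tuple(peak_ijk)]),
                trait=amap.trait))
    records.sort(key=lambda r: -abs(r.peak_t))
    return records


def cluster_threshold(amap: AssociationMap, p_uncorrected: float = 0.001,
                      min_extent_mm3: float = 80.0, connectivity: int = 6
                      ) -> list[ClusterRecord]:
    """Uncorrected height threshold + cluster-extent filter, per direction.

    The height threshold is the one-sided critical t at ``p_uncorrected``,
    applied separately to positive and negative effects (the convention of
    the mapping software this replaces); clusters smaller than
    ``min_extent_mm3`` are dropped.
    """
    t_crit = stats.t.isf(p_uncorrected, amap.df)
    supra = (np.abs(amap.t_voxels) > t_crit) & amap.mask
    return _clusters_from_mask(amap, supra, connectivity=connectivity,
                               min_extent_mm3=min_extent_mm3)


def subthreshold_coincidence(cluster_sets: dict[str, list[ClusterRecord]],
                             tolerance_mm: float = 0.0) -> list[dict]:
    """Group clusters across traits whose peak coordinates agree.

    ``cluster_sets`` maps trait name to its cluster records (including
    sub-extent clusters). Peaks agreeing within ``tolerance_mm`` (default:
    exact coordinate match) across two or more traits are reported with each
    trait's direction and peak Z.
    """
    if len(cluster_sets) < 2:
        raise ContractError("need cluster records from at least 2 traits")
    entries = [(trait, rec) for trait, recs in cluster_sets.items()
               for rec in recs]
    used = [False] * len(entries)
    groups = []
    for i, (trait_i, rec_i) in enumerate(entries):
        if used[i]:
            continue
        members = [(trait_i, rec_i)]
        used[i] = True
        for j in range(i + 1, len(entries)):
            if used[j]:
                continue
            trait_j, rec_j = entries[j]
            d = np.linalg.norm(np.subtract(rec_i.peak_xyz_mm, rec_j.peak_xyz_mm))
            if d <= tolerance_mm + 1e-9:
                members.append((trait_j, rec_j))
                used[j] = True
        if len({t for t, _ in members}) >= 2:
            groups.append({
                "peak_xyz_mm": rec_i.peak_xyz_mm,
                "n_traits": len({t for t, _ in members}),
                "traits": [{"trait": t, "direction": r.direction,
                            "peak_z": r.peak_z} for t, r in members]})
    groups.sort(key=lambda g: -g["n_traits"])
    return groups
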