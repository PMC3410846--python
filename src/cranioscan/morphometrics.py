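"""Landmark-based geometric morphometrics of the canine skull.

Turns raw dual-view 3-D landmark tables into allometry-corrected shape
principal-component scores and breed-sex phenotype averages suitable for
genetic mapping.  The workflow mirrors standard geometric-morphometrics
practice:

1. merge dorsal and ventral digitizations of each skull into one
   configuration via a rigid fit on shared landmarks,
2. generalized Procrustes analysis (GPA): center, scale to unit centroid
   size, and rotate all configurations to a consensus,
3. optional object-symmetry averaging (left/right reflection),
4. pooled within-group regression of shape on log centroid size to remove
   allometry, with a permutation test,
5. PCA of the allometric residuals,
6. breed-sex averaging of PC scores for use as mapping phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


class MorphometricsError(ValueError):
    """Raised for invalid landmark configurations or degenerate fits."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LandmarkConfig:
    """One specimen's ordered, named 3-D landmarks with metadata.

    ``landmarks`` maps landmark id (1-based integer) to a length-3
    coordinate array in millimetres.  Missing landmarks are simply absent
    from the mapping.
    """

    specimen_id: str
    breed: str
    sex: str
    view: str  # dorsal | ventral | merged
    landmarks: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for lid, xyz in self.landmarks.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,):
                raise MorphometricsError(
                    f"landmark {lid} of {self.specimen_id}: expected 3 coordinates"
                )
            if not np.all(np.isfinite(arr)):
                raise MorphometricsError(
                    f"landmark {lid} of {self.specimen_id}: non-finite coordinates"
                )
            clean[int(lid)] = arr
        self.landmarks = clean

    @property
    def ids(self) -> list[int]:
        return sorted(self.landmarks)

    def coords(self, ids: list[int] | None = None) -> np.ndarray:
        """Coordinate matrix (k, 3) over ``ids`` (default: all, sorted)."""
        ids = self.ids if ids is None else list(ids)
        missing = [i for i in ids if i not in self.landmarks]
        if missing:
            raise MorphometricsError(
                f"specimen {self.specimen_id} is missing landmarks {missing}"
            )
        return np.array([self.landmarks[i] for i in ids])

    def replace_coords(self, ids: list[int], coords: np.ndarray, view: str | None = None
                       ) -> "LandmarkConfig":
        return LandmarkConfig(
            specimen_id=self.specimen_id,
            breed=self.breed,
            sex=self.sex,
            view=self.view if view is None else view,
            landmarks={i: c for i, c in zip(ids, np.asarray(coords, float))},
        )


@dataclass
class ShapeSample:
    specimen_id: str
    aligned_coords: np.ndarray  # flattened (3k,)
    centroid_size: float
    neurocranium_centroid_size: float


@dataclass
class ShapeSpace:
    """PCA decomposition of a set of (residual) shapes."""

    mean_shape: np.ndarray        # flattened (3k,)
    loadings: np.ndarray          # (n_pc, 3k), rows orthonormal
    eigenvalues: np.ndarray       # (n_pc,)
    variance_fractions: np.ndarray
    scores: np.ndarray            # (n_specimens, n_pc)
    specimen_ids: list[str] = field(default_factory=list)


@dataclass
class AllometryFit:
    """Pooled within-group allometry fit.

    ``residuals`` are the shapes with the common allometric component
    removed but between-group differences retained (the input to the
    shape PCA); ``fitted`` is the within-group allometric component,
    orthogonal to the within-group remainder.
    """

    slope: np.ndarray             # per shape coordinate
    percent_variance: float       # % of within-group shape variance on size
    permutation_p: float
    residuals: np.ndarray         # (n_specimens, 3k), group structure retained
    fitted: np.ndarray            # within-group fitted component


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

DEFAULT_SHARED_IDS = frozenset({1, 2, 28, 29})


def _rigid_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with source @ R + t ≈ target.

    Kabsch algorithm; proper rotation only (no scaling, no reflection).
    """
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (source - mu_s).T @ (target - mu_t)
    U, _, Vt = linalg.svd(H)
    d = np.sign(linalg.det(U @ Vt))
    D = np.diag([1.0] * (len(U) - 1) + [d])
    R = U @ D @ Vt
    t = mu_t - mu_s @ R
    return R, t


def merge_views(dorsal: LandmarkConfig, ventral: LandmarkConfig,
                shared_ids: set[int] | frozenset[int] = DEFAULT_SHARED_IDS,
                ) -> tuple[LandmarkConfig, float]:
    """Map the ventral view into the dorsal frame and merge landmark sets.

    The rigid (rotation + translation, no scaling) transform is fitted by
    least squares on the shared landmarks; shared landmarks take the
    average of the two views' positions after transformation.  Returns the
    merged configuration and the RMS discrepancy over shared landmarks.
    """
    shared = sorted(shared_ids)
    for cfg, name in ((dorsal, "dorsal"), (ventral, "ventral")):
        absent = [i for i in shared if i not in cfg.landmarks]
        if absent:
            raise MorphometricsError(
                f"{name} view of {cfg.specimen_id} lacks shared landmarks {absent}"
            )
    if len(shared) < 3:
        raise MorphometricsError(
            f"need >=3 shared landmarks, got {shared}"
        )
    src = ventral.coords(shared)
    tgt = dorsal.coords(shared)
    # collinearity check: rank of centered target must be >=2
    if np.linalg.matrix_rank(tgt - tgt.mean(0), tol=1e-9) < 2 or \
       np.linalg.matrix_rank(src - src.mean(0), tol=1e-9) < 2:
        raise MorphometricsError(
            f"shared landmarks {shared} are collinear; rigid fit is degenerate"
        )
    R, t = _rigid_fit(src, tgt)

    merged: dict[int, np.ndarray] = {}
    for lid, xyz in dorsal.landmarks.items():
        merged[lid] = xyz.copy()
    for lid, xyz in ventral.landmarks.items():
        mapped = xyz @ R + t
        if lid in merged:
            if lid in shared_ids:
                merged[lid] = 0.5 * (merged[lid] + mapped)
            # non-shared duplicate ids keep the dorsal position
        else:
            merged[lid] = mapped
    rms = float(np.sqrt(np.mean(np.sum((src @ R + t - tgt) ** 2, axis=1))))
    out = LandmarkConfig(dorsal.specimen_id, dorsal.breed, dorsal.sex,
                         "merged", merged)
    return out, rms


def centroid_size(config: LandmarkConfig, subset: set[int] | None = None) -> float:
    """Square root of summed squared landmark deviations from their centroid."""
    ids = config.ids if subset is None else sorted(subset)
    if len(ids) < 2:
        raise MorphometricsError("centroid size needs at least 2 landmarks")
    X = config.coords(ids)
    return float(np.sqrt(np.sum((X - X.mean(axis=0)) ** 2)))


def symmetric_component(config: LandmarkConfig,
                        pairing: dict[int, int],
                        reflect_axis: int = 0,
                        align: bool = True) -> LandmarkConfig:
    """Object-symmetry averaging of a bilaterally symmetric configuration.

    ``pairing`` maps every landmark id to its mirror partner; midline ids
    map to themselves.  The configuration is averaged with its relabeled
    reflection (coordinates negated along ``reflect_axis``, left/right
    labels swapped).  With ``align=True`` the reflected copy is first
    superimposed on the original by a least-squares rigid fit, making the
    result invariant to the configuration's orientation in space; with
    ``align=False`` the reflection plane is taken to be the coordinate
    plane itself.
    """
    ids = config.ids
    unpaired = [i for i in ids if i not in pairing or pairing[i] not in config.landmarks]
    if unpaired:
        raise MorphometricsError(f"unpaired landmark ids: {unpaired}")
    X = config.coords(ids)
    # reflect, then relabel: position of landmark i in the reflected copy is
    # the reflected position of its partner.
    refl = X.copy()
    refl[:, reflect_axis] *= -1.0
    idx = {lid: k for k, lid in enumerate(ids)}
    relabeled = np.array([refl[idx[pairing[i]]] for i in ids])
    if align:
        R, t = _rigid_fit(relabeled, X)
        relabeled = relabeled @ R + t
    sym = 0.5 * (X + relabeled)
    return config.replace_coords(ids, sym)


def gpa(configs: list[LandmarkConfig],
        neurocranium_subset: set[int] | None = None,
        tol: float = 1e-10, max_iter: int = 100,
        ) -> tuple[list[ShapeSample], np.ndarray]:
    """Generalized Procrustes superimposition.

    All configurations must carry the identical landmark id set.  Each is
    centered and scaled to unit centroid size (full Procrustes), then
    iteratively rotated to the evolving mean shape until the mean changes
    by less than ``tol`` (Frobenius norm) or ``max_iter`` iterations.

    Returns per-specimen :class:`ShapeSample` (with centroid sizes recorded
    before scaling) and the flattened mean shape.
    """
    if len(configs) < 2:
        raise MorphometricsError("GPA needs at least 2 configurations")
    ids = configs[0].ids
    bad = [c.specimen_id for c in configs if c.ids != ids]
    if bad:
        raise MorphometricsError(f"inconsistent landmark id sets for specimens: {bad}")

    sizes = np.array([centroid_size(c) for c in configs])
    neuro = np.array([
        centroid_size(c, neurocranium_subset) if neurocranium_subset else centroid_size(c)
        for c in configs
    ])
    X = np.stack([c.coords(ids) for c in configs])          # (n, k, 3)
    X = X - X.mean(axis=1, keepdims=True)
    X = X / sizes[:, None, None]

    mean = X[0].copy()
    mean /= np.sqrt(np.sum(mean ** 2))
    for _ in range(max_iter):
        for i in range(len(X)):
            R, _ = _rigid_fit(X[i], mean)
            X[i] = X[i] @ R
        new_mean = X.mean(axis=0)
        new_mean /= np.sqrt(np.sum(new_mean ** 2))
        if np.sqrt(np.sum((new_mean - mean) ** 2)) < tol:
            mean = new_mean
            break
        mean = new_mean
    # final rotation pass onto the converged mean
    for i in range(len(X)):
        R, _ = _rigid_fit(X[i], mean)
        X[i] = X[i] @ R
    # canonical orientation: principal axes of the mean shape, signed so the
    # largest-|loading| landmark on each axis is positive — makes the output
    # independent of the input configurations' original frames
    _, _, Vt = linalg.svd(mean, full_matrices=False)
    R_can = Vt.T
    for j in range(3):
        k = np.argmax(np.abs(mean @ R_can[:, j]))
        if (mean @ R_can[:, j])[k] < 0:
            R_can[:, j] *= -1
    if linalg.det(R_can) < 0:
        R_can[:, 2] *= -1
    mean = mean @ R_can
    X = X @ R_can

    samples = [
        ShapeSample(
            specimen_id=c.specimen_id,
            aligned_coords=X[i].ravel(),
            centroid_size=float(sizes[i]),
            neurocranium_centroid_size=float(neuro[i]),
        )
        for i, c in enumerate(configs)
    ]
    return samples, mean.ravel()


def filter_complete(configs: list[LandmarkConfig], required_ids: list[int],
                    ) -> tuple[list[LandmarkConfig], list[str]]:
    """Drop specimens missing any required landmark (no imputation).

    Returns (kept configs, excluded specimen ids).
    """
    kept, dropped = [], []
    req = set(required_ids)
    for c in configs:
        (kept if req.issubset(c.landmarks) else dropped).append(c)
    return kept, [c.specimen_id for c in dropped]


def allometric_regression(shapes: list[ShapeSample],
                          groups: list[tuple[str, str]],
                          n_perm: int = 10_000,
                          rng: np.random.Generator | None = None,
                          ) -> AllometryFit:
    """Pooled within-group regression of shape on log neurocranium size.

    Group means (breed, sex) are removed from both the shape coordinates
    and log centroid size before fitting a single common slope, the
    standard pooled-allometry correction.  Significance of the variance
    explained is assessed by permuting size values within groups; the
    p-value uses the (b + 1) / (n_perm + 1) estimator.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    Y = np.stack([s.aligned_coords for s in shapes])
    x = np.log(np.array([s.neurocranium_centroid_size for s in shapes]))

    labels = pd.Series([f"{b}|{s}" for b, s in groups])
    Yc = Y.copy()
    xc = x.copy()
    for _, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx)
        Yc[idx] -= Yc[idx].mean(axis=0)
        xc[idx] -= xc[idx].mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise MorphometricsError("zero within-group variance in log centroid size")

    slope = (xc @ Yc) / sxx
    fitted = np.outer(xc, slope)
    ss_tot = float(np.sum(Yc ** 2))
    ss_fit = float(np.sum(fitted ** 2))
    pct = 100.0 * ss_fit / ss_tot if ss_tot > 0 else 0.0
    # residuals for PCA: remove the common allometric component from the
    # overall-centered shapes, keeping between-group (breed) differences
    resid = (Y - Y.mean(axis=0)) - np.outer(x - x.mean(), slope)

    group_indices = [np.asarray(idx) for _, idx in labels.groupby(labels).groups.items()]
    b = 0
    for _ in range(n_perm):
        xp = xc.copy()
        for idx in group_indices:
            xp[idx] = rng.permutation(xp[idx])
        sxx_p = float(xp @ xp)
        if sxx_p <= 0:
            continue
        ss_fit_p = float(np.sum((xp @ Yc) ** 2)) / sxx_p
        if ss_fit_p >= ss_fit - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return AllometryFit(slope=slope, percent_variance=pct,
                        permutation_p=p, residuals=resid, fitted=fitted)


def shape_pca(residuals: np.ndarray, specimen_ids: list[str] | None = None,
              ) -> ShapeSpace:
    """PCA of the specimen-level covariance matrix of shape residuals.

    PCs are ordered by decreasing eigenvalue; each loading vector is
    signed so that its largest-magnitude entry is positive.
    """
    Y = np.asarray(residuals, float)
    if Y.shape[0] < 2:
        raise MorphometricsError("PCA needs at least 2 specimens")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    # SVD of the data matrix == eigendecomposition of the covariance
    U, s, Vt = linalg.svd(Yc, full_matrices=False)
    eig = s ** 2 / (Y.shape[0] - 1)
    n_pc = min(Y.shape[0] - 1, Y.shape[1])
    eig = eig[:n_pc]
    Vt = Vt[:n_pc]
    scores = U[:, :n_pc] * s[:n_pc]
    for j in range(n_pc):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1.0
            scores[:, j] *= -1.0
    total = eig.sum()
    frac = eig / total if total > 0 else np.zeros_like(eig)
    return ShapeSpace(
        mean_shape=mean, loadings=Vt, eigenvalues=eig,
        variance_fractions=frac, scores=scores,
        specimen_ids=list(specimen_ids) if specimen_ids is not None else [],
    )


def breed_sex_average(scores: np.ndarray,
                      metadata: pd.DataFrame,
                      log_neuro_size: np.ndarray | None = None,
                      ) -> pd.DataFrame:
    """Arithmetic breed-sex means of PC scores (single specimens pass through).

    ``metadata`` needs columns ``breed`` and ``sex`` aligned with the score
    rows.  Returns a table keyed by (breed, sex) with columns ``pc1..pcK``,
    ``log_neurocranium_centroid`` (if sizes given) and ``n_specimens``.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] == len(metadata) or scores.shape[1] == len(metadata):
        if scores.shape[0] != len(metadata):
            scores = scores.T
    df = pd.DataFrame(scores, columns=[f"pc{j + 1}" for j in range(scores.shape[1])])
    df["breed"] = metadata["breed"].to_numpy()
    df["sex"] = metadata["sex"].to_numpy()
    if log_neuro_size is not None:
        df["log_neurocranium_centroid"] = np.asarray(log_neuro_size, float)
    grouped = df.groupby(["breed", "sex"], sort=True)
    out = grouped.mean(numeric_only=True)
    out["n_specimens"] = grouped.size()
    return out.reset_index()


def morph_along_pc(space: ShapeSpace, pc: int, c: float) -> np.ndarray:
    """Landmark coordinates at ``mean + c * loading[pc]``, shape (k, 3)."""
    if not 0 <= pc < space.loadings.shape[0]:
        raise MorphometricsError(f"PC index {pc} out of range")
    flat = space.mean_shape + c * space.loadings[pc]
    return flat.reshape(-1, 3)
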