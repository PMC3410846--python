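"""Breed-average GWAS of the skull-shape trait.

Single-marker association of breed-sex-average phenotypes carried by
individual dogs, by ordinary least squares and by a single-random-effect
linear mixed model

    y = W a + x b + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with a marker-derived kinship matrix K.  The mixed model eigendecomposes
K once and profiles the restricted likelihood over the variance ratio
(EMMA-style), re-estimating the ratio for every marker; fixed effects are
tested by Wald t-tests with n - p residual degrees of freedom, so with
K = I the mixed model collapses exactly to ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel


class AssociationError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x markers minor-allele dosage matrix with maps.

    ``calls`` is an int8 array with entries in {0, 1, 2, -1} (-1 missing).
    ``individuals`` has columns ``iid``, ``breed``, ``sex``; ``markers``
    has ``chrom``, ``pos`` (1-based), ``a1``, ``a2``.
    """

    calls: np.ndarray
    individuals: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise AssociationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise AssociationError("dosages must be 0/1/2 or -1 (missing)")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise AssociationError(
                    f"marker positions not strictly increasing on {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.calls[mask],
            self.individuals.loc[mask].reset_index(drop=True),
            self.markers,
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.calls[:, mask],
            self.individuals,
            self.markers.loc[mask].reset_index(drop=True),
        )

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker over non-missing calls."""
        calls = self.calls.astype(float)
        obs = calls != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs, calls, 0.0).sum(0) / (2.0 * obs.sum(0))
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)


@dataclass
class AssocResult:
    markers: pd.DataFrame       # chrom, pos + beta, se, p_value, neg_log10_p
    model: str                  # "linear" | "mixed"
    covariates: list[str] = field(default_factory=list)

    @property
    def p_values(self) -> np.ndarray:
        return self.markers["p_value"].to_numpy()

    def genomic_inflation(self) -> float:
        """Lambda_GC: median chi2(1) of p-values over its expectation."""
        p = self.p_values
        p = p[np.isfinite(p)]
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# QC and design assembly
# ---------------------------------------------------------------------------


def snp_qc(G: GenotypeMatrix, max_missing: float = 0.10,
           min_maf: float = 0.01) -> GenotypeMatrix:
    """Retain markers with missingness strictly below ``max_missing`` and
    MAF strictly above ``min_maf``."""
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise AssociationError("thresholds must lie in [0, 1]")
    miss = G.missing_fraction()
    maf = np.nan_to_num(G.maf(), nan=0.0)
    keep = (miss < max_missing) & (maf > min_maf)
    n_miss = int((~(miss < max_missing)).sum())
    n_maf = int((~(maf > min_maf)).sum())
    log.info("snp_qc: removed %d for missingness, %d for MAF; kept %d/%d",
             n_miss, n_maf, int(keep.sum()), G.n_markers)
    if not keep.any():
        log.warning("snp_qc removed every marker")
    return G.subset_markers(keep)


def assign_phenotypes(G: GenotypeMatrix, pheno: pd.DataFrame,
                      pc: str = "pc1",
                      sex_fallback: bool = False,
                      ) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Attach each dog's breed-sex average phenotype and size covariate.

    ``pheno`` is a breed-sex table with columns ``breed``, ``sex``, the PC
    column and optionally ``log_neurocranium_centroid``.  Dogs whose
    (breed, sex) cell is absent are dropped (or, with ``sex_fallback``,
    given the opposite sex's average when only that is available).

    Returns the genotype subset plus aligned phenotype and size arrays.
    """
    table = pheno.set_index(["breed", "sex"])
    y, size, keep = [], [], []
    n_dropped = 0
    has_size = "log_neurocranium_centroid" in pheno.columns
    for i, row in G.individuals.iterrows():
        key = (row["breed"], row["sex"])
        if key in table.index:
            rec = table.loc[key]
        elif sex_fallback:
            other = (row["breed"], "F" if row["sex"] == "M" else "M")
            if other in table.index:
                rec = table.loc[other]
            else:
                n_dropped += 1
                continue
        else:
            n_dropped += 1
            continue
        y.append(float(rec[pc]))
        size.append(float(rec["log_neurocranium_centroid"]) if has_size else np.nan)
        keep.append(i)
    if n_dropped:
        log.info("assign_phenotypes: dropped %d dogs without a phenotype row",
                 n_dropped)
    mask = np.zeros(G.n_individuals, bool)
    mask[keep] = True
    return G.subset_individuals(mask), np.array(y), np.array(size)


def stratify(pheno: pd.DataFrame, mode: str,
             drop_breeds: list[str] | None = None,
             pc: str = "pc1", pc_threshold: float = 0.15) -> list[str]:
    """Select the breed subset for a stratified scan.

    ``size_below_median``: breeds whose breed-sex rows all fall strictly
    below the 50th percentile of log neurocranium size.
    ``drop_listed_breeds``: remove a named breed list.
    ``pc_cutoff``: drop "extreme brachycephalic" breeds, defined as both
    sexes' PC1 averages exceeding ``pc_threshold`` (default 0.15).
    """
    breeds = pheno["breed"].unique().tolist()
    if mode == "size_below_median":
        med = float(np.median(pheno["log_neurocranium_centroid"]))
        keep = [
            b for b in breeds
            if (pheno.loc[pheno["breed"] == b, "log_neurocranium_centroid"] < med).all()
        ]
        return keep
    if mode == "drop_listed_breeds":
        drop = set(drop_breeds or [])
        unknown = drop - set(breeds)
        if unknown:
            log.warning("stratify: unknown breed names %s", sorted(unknown))
        return [b for b in breeds if b not in drop]
    if mode == "pc_cutoff":
        keep = []
        for b in breeds:
            sub = pheno[pheno["breed"] == b]
            extreme = len(sub) > 0 and (sub[pc] > pc_threshold).all()
            if not extreme:
                keep.append(b)
        return keep
    raise AssociationError(f"unknown stratification mode {mode!r}")


# ---------------------------------------------------------------------------
# Single-marker tests
# ---------------------------------------------------------------------------


def _marker_design(W: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.column_stack([W, x])


def _ols_marker(y: np.ndarray, W: np.ndarray, x: np.ndarray,
                ) -> tuple[float, float, float]:
    """OLS of y on [W, x]; Wald t-test on the marker coefficient."""
    X = _marker_design(W, x)
    n, p = X.shape
    if n < p + 1:
        return np.nan, np.nan, np.nan
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    rss = float(resid @ resid)
    # degenerate fit (e.g. constant phenotype): no evidence either way
    if rss <= n * (100 * np.finfo(float).eps * max(1.0, float(np.abs(y).max()))) ** 2:
        return float(beta[-1]), 0.0, 1.0
    s2 = rss / df
    se = float(np.sqrt(max(s2 * XtX_inv[-1, -1], 0.0)))
    b = float(beta[-1])
    if se == 0.0:
        return b, se, 1.0
    t = b / se
    pval = float(2.0 * stats.t.sf(abs(t), df))
    return b, se, max(pval, np.finfo(float).tiny)


def _check_collinear(W: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise AssociationError(f"collinear covariate columns: {names}")


def linear_assoc(G: GenotypeMatrix, y: np.ndarray,
                 covariates: np.ndarray | None = None,
                 covariate_names: list[str] | None = None) -> AssocResult:
    """Per-marker additive OLS of phenotype on dosage (+ covariates).

    Individuals missing a marker's call are dropped marker-wise.
    """
    y = np.asarray(y, float)
    n = G.n_individuals
    W = np.ones((n, 1))
    names = ["intercept"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        W = np.column_stack([W, C])
        names += covariate_names or [f"cov{j}" for j in range(C.shape[1])]
    _check_collinear(W, names)

    out = np.full((G.n_markers, 3), np.nan)
    for j in range(G.n_markers):
        x = G.calls[:, j].astype(float)
        obs = x != MISSING
        if obs.sum() < W.shape[1] + 2:
            continue
        out[j] = _ols_marker(y[obs], W[obs], x[obs])
    res = G.markers[["chrom", "pos"]].copy()
    res["beta"], res["se"], res["p_value"] = out.T
    with np.errstate(divide="ignore"):
        res["neg_log10_p"] = -np.log10(res["p_value"])
    return AssocResult(res, model="linear", covariates=names[1:])


def kinship(G: GenotypeMatrix) -> np.ndarray:
    """Centered relationship matrix K = Z Z^T / m.

    Z is the column-centered dosage matrix; missing dosages are replaced
    by the marker mean (for K only).
    """
    calls = G.calls.astype(float)
    obs = calls != MISSING
    with np.errstate(invalid="ignore"):
        mean = np.where(obs, calls, 0.0).sum(0) / np.maximum(obs.sum(0), 1)
    Z = np.where(obs, calls, mean[None, :]) - mean[None, :]
    return Z @ Z.T / G.n_markers


def _reml_neg_loglik(log_ratio: float, eigvals: np.ndarray,
                     Uy: np.ndarray, UX: np.ndarray) -> float:
    """Negative restricted log-likelihood at variance ratio sg2/se2 = exp(log_ratio)."""
    lam = np.exp(log_ratio)
    d = lam * eigvals + 1.0
    n, p = UX.shape
    Xt_dinv = UX.T / d
    XtHiX = Xt_dinv @ UX
    XtHiy = Xt_dinv @ Uy
    try:
        beta = np.linalg.solve(XtHiX, XtHiy)
    except np.linalg.LinAlgError:
        return np.inf
    r = Uy - UX @ beta
    rss = float(r @ (r / d))
    if rss <= 0:
        return np.inf
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return np.inf
    _, logdet_XtX = np.linalg.slogdet(UX.T @ UX)
    df = n - p
    ll = -0.5 * (
        df * np.log(2 * np.pi * rss / df) + df
        + np.sum(np.log(d)) + logdet_XtHiX - logdet_XtX
    )
    return -ll


def lmm_assoc(G: GenotypeMatrix, y: np.ndarray, K: np.ndarray,
              covariates: np.ndarray | None = None,
              covariate_names: list[str] | None = None,
              log_ratio_bounds: tuple[float, float] = (-5.0, 5.0),
              tol: float = 1e-6) -> AssocResult:
    """Mixed-model association with per-marker REML variance-ratio profiling.

    K is eigendecomposed once; for each marker the restricted likelihood is
    maximized over log(sg^2/se^2) within ``log_ratio_bounds`` by bounded
    scalar search, then the marker effect is Wald-tested (t, n - p dof)
    under the fitted covariance.
    """
    y = np.asarray(y, float)
    n = G.n_individuals
    K = np.asarray(K, float)
    if K.shape != (n, n):
        raise AssociationError(f"K shape {K.shape} does not match n={n}")
    eigvals, U = np.linalg.eigh((K + K.T) / 2.0)
    if eigvals.min() < -1e-6 * max(1.0, abs(eigvals.max())):
        raise AssociationError(f"K is not PSD (min eigenvalue {eigvals.min():.3g})")
    eigvals = np.clip(eigvals, 0.0, None)

    W = np.ones((n, 1))
    names = ["intercept"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        W = np.column_stack([W, C])
        names += covariate_names or [f"cov{j}" for j in range(C.shape[1])]
    _check_collinear(W, names)

    Uy_full = U.T @ y
    UW_full = U.T @ W

    out = np.full((G.n_markers, 3), np.nan)
    for j in range(G.n_markers):
        x = G.calls[:, j].astype(float)
        obs = x != MISSING
        p_fixed = W.shape[1] + 1
        if obs.sum() < p_fixed + 1:
            continue
        if obs.all():
            Uy, UX = Uy_full, np.column_stack([UW_full, U.T @ x])
            ev = eigvals
        else:
            # marker-wise missing: re-decompose the sub-kinship
            Ks = K[np.ix_(obs, obs)]
            ev, Us = np.linalg.eigh((Ks + Ks.T) / 2.0)
            ev = np.clip(ev, 0.0, None)
            Uy = Us.T @ y[obs]
            UX = np.column_stack([Us.T @ W[obs], Us.T @ x[obs]])
        if np.ptp(x[obs]) == 0:
            out[j] = (0.0, np.nan, 1.0)
            continue
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=log_ratio_bounds, args=(ev, Uy, UX),
            method="bounded", options={"xatol": tol},
        )
        lam = np.exp(res.x)
        d = lam * ev + 1.0
        nn, pp = UX.shape
        Xt_dinv = UX.T / d
        XtHiX = Xt_dinv @ UX
        beta = np.linalg.solve(XtHiX, Xt_dinv @ Uy)
        r = Uy - UX @ beta
        df = nn - pp
        s2 = float(r @ (r / d)) / df
        var_beta = s2 * np.linalg.inv(XtHiX)
        se = float(np.sqrt(max(var_beta[-1, -1], 0.0)))
        b = float(beta[-1])
        if se == 0.0:
            out[j] = (b, se, 1.0)
            continue
        t = b / se
        pval = float(2.0 * stats.t.sf(abs(t), df))
        out[j] = (b, se, max(pval, np.finfo(float).tiny))

    res_df = G.markers[["chrom", "pos"]].copy()
    res_df["beta"], res_df["se"], res_df["p_value"] = out.T
    with np.errstate(divide="ignore"):
        res_df["neg_log10_p"] = -np.log10(res_df["p_value"])
    return AssocResult(res_df, model="mixed", covariates=names[1:])


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Genome-wide significance on the -log10 scale: -log10(alpha / m)."""
    if m < 1:
        raise AssociationError("marker count must be >= 1")
    if not 0 < alpha < 1:
        raise AssociationError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / m))
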