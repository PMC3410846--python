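"""Selective-sweep scans: observed heterozygosity, log H_O ratios and F_ST.

Breeds at the polar extremes of the skull-shape axis (brachycephalic vs
dolichocephalic) are contrasted per SNP; statistics are averaged over
ten-SNP sliding windows within chromosomes and flagged by empirical
genome-wide percentile (high F_ST, low heterozygosity in the selected
class are the sweep signatures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class PopulationSpec:
    name: str
    breeds: list[str]
    role: str = "subpopulation"  # brachy | dolicho | subpopulation | rest

    def mask(self, G: GenotypeMatrix) -> np.ndarray:
        return G.individuals["breed"].isin(self.breeds).to_numpy()


def _require_disjoint(a: PopulationSpec, b: PopulationSpec) -> None:
    overlap = set(a.breeds) & set(b.breeds)
    if overlap:
        raise SelectionError(f"populations {a.name}/{b.name} share breeds {sorted(overlap)}")


def obs_het(G: GenotypeMatrix, population: PopulationSpec) -> np.ndarray:
    """Per-SNP observed heterozygosity: het calls / non-missing calls.

    Markers with no non-missing call in the population are NaN.
    """
    mask = population.mask(G)
    if not mask.any():
        raise SelectionError(f"population {population.name} matches no individuals")
    calls = G.calls[mask]
    obs = calls != MISSING
    het = calls == 1
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_obs > 0, het.sum(axis=0) / n_obs, np.nan)
    return ho


def log_h_ratio(ho_dolicho: np.ndarray, ho_brachy: np.ndarray,
                pseudocount: float = 0.0, base: float = 10.0) -> np.ndarray:
    """log of the dolicho/brachy heterozygosity ratio (base 10 by default).

    Markers undefined in either population, or with a zero term when the
    pseudocount is zero, come back NaN.
    """
    a = np.asarray(ho_dolicho, float) + pseudocount
    b = np.asarray(ho_brachy, float) + pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((a > 0) & (b > 0), np.log(a / b) / np.log(base), np.nan)
    return out


def _allele_stats(G: GenotypeMatrix, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt-allele frequency, allele sample count) per marker in a group."""
    calls = G.calls[mask].astype(float)
    obs = calls != MISSING
    n_allele = 2.0 * obs.sum(axis=0)
    count = np.where(obs, calls, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_allele > 0, count / n_allele, np.nan)
    return p, n_allele


def fst(G: GenotypeMatrix, subpop: PopulationSpec, rest: PopulationSpec,
        estimator: str = "hudson") -> np.ndarray:
    """Per-SNP two-population F_ST, clipped to [0, 1].

    ``hudson`` (default): the sample-size-robust estimator
        [ (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) ]
        / [ p1(1-p2) + p2(1-p1) ]
    with n the allele counts.  ``nei``: (H_T - H_S) / H_T from mean
    frequencies.  Markers monomorphic in both groups are NaN.
    """
    _require_disjoint(subpop, rest)
    m1, m2 = subpop.mask(G), rest.mask(G)
    if not m1.any() or not m2.any():
        raise SelectionError("both populations must be non-empty")
    p1, n1 = _allele_stats(G, m1)
    p2, n2 = _allele_stats(G, m2)
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "hudson":
            num = (p1 - p2) ** 2 \
                - p1 * (1 - p1) / np.maximum(n1 - 1, 1) \
                - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
        elif estimator == "nei":
            pbar = (p1 + p2) / 2.0
            ht = 2.0 * pbar * (1.0 - pbar)
            hs = p1 * (1 - p1) + p2 * (1 - p2)
            num, den = ht - hs, ht
        else:
            raise SelectionError(f"unknown estimator {estimator!r}")
        out = np.where(den > 0, num / den, np.nan)
    return np.clip(out, 0.0, 1.0)


def sliding_windows(values: np.ndarray, markers: pd.DataFrame,
                    stat: str, k: int = 10, step: int = 1,
                    max_undefined: float = 0.20) -> pd.DataFrame:
    """Mean of per-SNP values over k-marker windows within chromosomes.

    Windows advance by ``step`` markers and never span chromosomes; the
    mean ignores NaN values, and windows with more than ``max_undefined``
    of their markers undefined are flagged.  Chromosomes with fewer than
    ``k`` markers contribute no windows.
    """
    if k < 1:
        raise SelectionError("window size must be >= 1")
    values = np.asarray(values, float)
    rows = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        m = len(idx)
        if m < k:
            log.info("sliding_windows: chromosome %s has %d < %d markers", chrom, m, k)
            continue
        for start in range(0, m - k + 1, step):
            vals = values[idx[start:start + k]]
            n_undef = int(np.isnan(vals).sum())
            mean = float(np.nanmean(vals)) if n_undef < k else np.nan
            rows.append({
                "chrom": chrom,
                "start_index": int(idx[start]),
                "end_index": int(idx[start + k - 1]),
                "start_pos": int(pos[start]),
                "end_pos": int(pos[start + k - 1]),
                "stat": stat,
                "value": mean,
                "flag_undefined": n_undef / k > max_undefined,
            })
    return pd.DataFrame(rows, columns=[
        "chrom", "start_index", "end_index", "start_pos", "end_pos",
        "stat", "value", "flag_undefined",
    ])


def percentile_flags(windows: pd.DataFrame, tail: str,
                     fraction: float) -> pd.DataFrame:
    """Empirical percentile ranks and tail flags over the genome-wide
    window distribution.

    Ties share a mid-rank percentile.  ``tail='high'`` flags windows with
    percentile > 100*(1 - fraction); ``tail='low'`` flags percentile <
    100*fraction (open tails: equal-valued degenerate distributions flag
    nothing).
    """
    if tail not in {"low", "high"}:
        raise SelectionError("tail must be 'low' or 'high'")
    out = windows.copy()
    vals = out["value"].to_numpy()
    finite = np.isfinite(vals)
    pct = np.full(len(vals), np.nan)
    if finite.sum() > 0:
        ranks = stats.rankdata(vals[finite], method="average")
        pct[finite] = 100.0 * ranks / finite.sum()
    out["percentile"] = pct
    if tail == "high":
        out["flagged"] = pct > 100.0 * (1.0 - fraction)
    else:
        out["flagged"] = pct < 100.0 * fraction
    out.loc[~finite, "flagged"] = False
    return out
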