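"""Haplotype-sharing critical intervals and breakpoint refinement.

A critical interval is the run of consecutive markers over which all
high-frequency haplotypes of the phenotype-sharing (brachycephalic)
breeds carry identical alleles; it bounds the causal variant.  The
interval is subsequently narrowed by the allelic agreement of two
sequenced genomes (a recombination breakpoint shows up as the first
downstream disagreement), and the breakpoint is confirmed by tabulating
a genotyping panel at diagnostic markers.

Phasing of small marker windows is done by an explicit EM over the 2^m
haplotype space; pre-phased input is accepted wherever haplotypes are
consumed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


class HaplotypeError(ValueError):
    pass


@dataclass
class Interval:
    """1-based inclusive chromosome segment anchored at marker positions."""

    chrom: str
    start: int
    end: int
    n_markers: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise HaplotypeError(f"interval start {self.start} > end {self.end}")

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        """Span in kb, rounded to 1 decimal (printed as e.g. 190.1 or 85.7)."""
        return round(self.span_bp / 1000.0, 1)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open BED coordinates (start-1, end)."""
        return self.chrom, self.start - 1, self.end

    def __str__(self) -> str:
        return (f"{self.chrom}:{self.start:,}-{self.end:,} "
                f"({self.length_kb} kb, {self.n_markers} markers, {self.provenance})")


@dataclass
class PhasedHaplotypes:
    """Haplotype alleles and per-breed frequencies over an ordered marker map."""

    markers: pd.DataFrame                 # chrom, pos
    haplotypes: np.ndarray                # (n_hap, n_markers) 0/1 alleles
    frequencies: dict[str, np.ndarray]    # breed -> (n_hap,) freq, sums to 1

    def __post_init__(self) -> None:
        self.haplotypes = np.atleast_2d(np.asarray(self.haplotypes, dtype=np.int8))
        if self.haplotypes.shape[1] != len(self.markers):
            raise HaplotypeError("haplotype length does not match marker map")
        for breed, f in self.frequencies.items():
            f = np.asarray(f, float)
            if abs(f.sum() - 1.0) > 1e-6:
                raise HaplotypeError(f"frequencies for {breed} sum to {f.sum():.8f}")
            self.frequencies[breed] = f


# ---------------------------------------------------------------------------
# EM phasing of small windows
# ---------------------------------------------------------------------------


def _compatible_pairs(genotype: np.ndarray) -> list[tuple[int, int]]:
    """All (hapA, hapB) bit-index pairs consistent with a 0/1/2/missing
    genotype vector (unordered pairs listed once, A <= B)."""
    m = len(genotype)
    choices: list[list[tuple[int, int]]] = []
    for g in genotype:
        if g == 0:
            choices.append([(0, 0)])
        elif g == 2:
            choices.append([(1, 1)])
        elif g == 1:
            choices.append([(0, 1), (1, 0)])
        else:  # missing
            choices.append([(0, 0), (0, 1), (1, 0), (1, 1)])
    pairs = set()
    for combo in itertools.product(*choices):
        a = sum(bit_a << (m - 1 - i) for i, (bit_a, _) in enumerate(combo))
        b = sum(bit_b << (m - 1 - i) for i, (_, bit_b) in enumerate(combo))
        pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def em_phase(G: GenotypeMatrix, max_markers: int = 12,
             tol: float = 1e-8, max_iter: int = 500,
             prune_below: float = 1e-6,
             by_breed: bool = True) -> PhasedHaplotypes:
    """Haplotype frequencies over a small marker window by EM.

    E-step distributes each genotype over its compatible haplotype pairs
    under current frequencies; M-step re-estimates frequencies from the
    expected haplotype counts.  Converges when the maximum frequency
    change drops below ``tol``.  Frequencies are estimated pooled and,
    with ``by_breed``, within each breed as well.
    """
    m = G.n_markers
    if m > max_markers:
        raise HaplotypeError(
            f"window has {m} markers > max {max_markers}; split the window"
        )
    n_hap = 2 ** m
    pair_lists = [_compatible_pairs(G.calls[i]) for i in range(G.n_individuals)]

    def run_em(rows: list[int]) -> np.ndarray:
        freq = np.full(n_hap, 1.0 / n_hap)
        for _ in range(max_iter):
            counts = np.zeros(n_hap)
            for i in rows:
                pairs = pair_lists[i]
                w = np.array([
                    (2.0 if a != b else 1.0) * freq[a] * freq[b] for a, b in pairs
                ])
                tot = w.sum()
                if tot <= 0:
                    w = np.ones(len(pairs))
                    tot = w.sum()
                w /= tot
                for (a, b), wt in zip(pairs, w):
                    counts[a] += wt
                    counts[b] += wt
            new = counts / (2.0 * len(rows))
            delta = np.max(np.abs(new - freq))
            freq = new
            if delta < tol:
                break
        return freq

    all_rows = list(range(G.n_individuals))
    pooled = run_em(all_rows)
    freqs = {"__pooled__": pooled}
    if by_breed:
        for breed, sub in G.individuals.groupby("breed", sort=True):
            freqs[str(breed)] = run_em(list(sub.index))

    keep = pooled >= prune_below
    for breed in list(freqs):
        keep |= freqs[breed] >= prune_below
    hap_idx = np.nonzero(keep)[0]
    haps = np.array([
        [(h >> (m - 1 - j)) & 1 for j in range(m)] for h in hap_idx
    ], dtype=np.int8)
    out_freqs = {}
    for breed, f in freqs.items():
        f = f[keep]
        s = f.sum()
        out_freqs[breed] = f / s if s > 0 else f
    return PhasedHaplotypes(markers=G.markers[["chrom", "pos"]].copy(),
                            haplotypes=haps, frequencies=out_freqs)


# ---------------------------------------------------------------------------
# Interval logic
# ---------------------------------------------------------------------------


def shared_interval(haps: PhasedHaplotypes, target_breeds: list[str],
                    min_freq: float = 0.05) -> Interval | None:
    """Maximal run of consecutive markers with identical alleles across all
    contributing haplotypes of the target breeds.

    Each target breed contributes every haplotype at frequency >=
    ``min_freq``.  Ties are broken by the leftmost maximal run.  Returns
    ``None`` (logged) when no marker is shared.
    """
    contrib = []
    for breed in target_breeds:
        if breed not in haps.frequencies:
            raise HaplotypeError(f"no haplotype frequencies for breed {breed!r}")
        sel = np.nonzero(haps.frequencies[breed] >= min_freq)[0]
        if len(sel) == 0:
            raise HaplotypeError(
                f"breed {breed!r} has no haplotype at frequency >= {min_freq}"
            )
        contrib.extend(sel.tolist())
    H = haps.haplotypes[sorted(set(contrib))]
    same = np.all(H == H[0], axis=0)

    best_start = best_len = -1
    run_start = None
    for j, ok in enumerate(list(same) + [False]):
        if ok and run_start is None:
            run_start = j
        elif not ok and run_start is not None:
            if j - run_start > best_len:
                best_len, best_start = j - run_start, run_start
            run_start = None
    if best_len <= 0:
        log.warning("shared_interval: no shared marker run among %s", target_breeds)
        return None
    pos = haps.markers["pos"].to_numpy()
    chrom = str(haps.markers["chrom"].iloc[0])
    return Interval(chrom=chrom,
                    start=int(pos[best_start]),
                    end=int(pos[best_start + best_len - 1]),
                    n_markers=best_len,
                    provenance="haplotype-sharing")


def refine_breakpoint(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                      interval: Interval) -> Interval | None:
    """Narrow an interval to the run of two-genome allelic agreement.

    ``calls_a``/``calls_b`` carry columns ``pos`` and ``gt`` (0/1/2 dosage,
    -1 missing) covering the interval.  Positions are scanned in ascending
    order from the interval start; the refined interval ends at the last
    position where both genomes agree before their first disagreement
    (het vs hom counts as disagreement; missing in either genome is
    skipped).  Returns ``None`` (logged) if the genomes disagree before
    ever agreeing.
    """
    a = calls_a.set_index("pos")["gt"]
    b = calls_b.set_index("pos")["gt"]
    common = sorted(set(a.index) & set(b.index))
    common = [p for p in common if interval.contains(int(p))]
    if not common:
        raise HaplotypeError("call sets share no positions inside the interval")
    last_agree = None
    n = 0
    for pos in common:
        ga, gb = int(a.loc[pos]), int(b.loc[pos])
        if ga == MISSING or gb == MISSING:
            continue
        if ga == gb:
            last_agree = int(pos)
            n += 1
        else:
            break
    if last_agree is None:
        log.warning("refine_breakpoint: disagreement at the first informative "
                    "position; empty interval")
        return None
    return Interval(chrom=interval.chrom, start=interval.start, end=last_agree,
                    n_markers=n, provenance="breakpoint-refined")


@dataclass
class BreakpointReport:
    markers: pd.DataFrame      # pos, plus per-allele counts
    consistency: float         # fraction of panel chromosomes matching


def confirm_breakpoint(panel: pd.DataFrame, markers: list[int],
                       shared_alleles: dict[int, int]) -> BreakpointReport:
    """Tabulate a genotyping panel at diagnostic markers.

    ``panel`` has one row per individual with a column per marker position
    holding 0/1/2 dosage of the shared allele (-1 missing).  Reports
    per-marker allele counts and the fraction of panel chromosomes
    carrying the shared-haplotype allele across the markers.
    """
    rows = []
    consistent = 0
    total = 0
    for pos in markers:
        if pos not in panel.columns:
            raise HaplotypeError(f"panel not genotyped at marker {pos}")
        g = panel[pos].to_numpy()
        obs = g != MISSING
        n_shared = int(g[obs].sum())
        n_chrom = int(2 * obs.sum())
        rows.append({
            "pos": pos,
            "n_individuals": int(obs.sum()),
            "shared_allele": shared_alleles.get(pos),
            "shared_allele_chromosomes": n_shared,
            "total_chromosomes": n_chrom,
        })
        consistent += n_shared
        total += n_chrom
    frac = consistent / total if total else float("nan")
    return BreakpointReport(markers=pd.DataFrame(rows), consistency=frac)
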