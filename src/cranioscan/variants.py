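"""Candidate-variant prioritization within a critical interval.

Variants from a small resequencing panel are filtered by four criteria —
genotype-quality masking, association-percentile, cross-species
conservation, and gene context (exonic or near a splice junction) — and
the survivors inside the active interval are flagged "of interest".
Coding consequences (e.g. the F452L missense notation) are annotated
from a gene model and CDS sequence via the standard genetic code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import Interval

log = logging.getLogger(__name__)

MISSING = -1


class VariantError(ValueError):
    pass


@dataclass
class VariantRecord:
    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray         # per-sample 0/1/2 dosage, -1 missing
    qualities: np.ndarray         # per-sample GQ
    conservation: float | None = None
    assoc_p: float | None = None
    in_exon: bool = False
    near_splice: bool = False
    conserved: bool = False
    associated: bool = False
    of_interest: bool = False
    unevaluable: bool = False

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.qualities = np.asarray(self.qualities, dtype=float)
        if self.genotypes.shape != self.qualities.shape:
            raise VariantError(f"{self.chrom}:{self.pos}: genotype/GQ length mismatch")


@dataclass
class GeneModel:
    """A gene's exon structure with optional CDS bounds (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str                    # '+' | '-'
    exons: list[tuple[int, int]]   # sorted, non-overlapping
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise VariantError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if a > b:
                raise VariantError(f"gene {self.gene_id}: exon {a}-{b} reversed")
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 <= b1:
                raise VariantError(f"gene {self.gene_id}: overlapping exons")
        self.exons = exons

    def cds_exons(self) -> list[tuple[int, int]]:
        """Exon pieces clipped to [cds_start, cds_end]."""
        if self.cds_start is None or self.cds_end is None:
            return []
        out = []
        for a, b in self.exons:
            lo, hi = max(a, self.cds_start), min(b, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def mask_gq(records: list[VariantRecord], threshold: float = 8.0,
            ) -> tuple[list[VariantRecord], int]:
    """Reset per-sample genotypes with GQ strictly below ``threshold`` to
    missing.  Returns (records, number of calls masked)."""
    if threshold < 0:
        raise VariantError("GQ threshold must be >= 0")
    n_masked = 0
    for rec in records:
        low = (rec.qualities < threshold) & (rec.genotypes != MISSING)
        n_masked += int(low.sum())
        rec.genotypes = np.where(low, MISSING, rec.genotypes).astype(np.int8)
    log.info("mask_gq: masked %d calls below GQ %g", n_masked, threshold)
    return records, n_masked


def variant_assoc(records: list[VariantRecord], phenotype: np.ndarray,
                  sample_names: list[str],
                  exclude: list[str] | None = None,
                  tail: float = 0.05) -> list[VariantRecord]:
    """Additive per-variant regression over the resequencing panel.

    Phenotype is regressed on dosage per variant (samples in ``exclude``
    omitted, e.g. an outlier breed); the ``associated`` flag marks variants
    whose p-value percentile (mid-rank ties) over evaluable variants falls
    within the smallest ``tail`` fraction.
    """
    exclude = exclude or []
    keep = np.array([s not in exclude for s in sample_names])
    y_all = np.asarray(phenotype, float)[keep]
    if keep.sum() < 4:
        raise VariantError("need >= 4 non-excluded genomes with phenotype")
    for rec in records:
        g = rec.genotypes[keep].astype(float)
        obs = g != MISSING
        rec.assoc_p = None
        rec.unevaluable = False
        if obs.sum() < 3 or np.ptp(g[obs]) == 0:
            rec.unevaluable = True
            continue
        res = stats.linregress(g[obs], y_all[obs])
        rec.assoc_p = float(res.pvalue)
    pvals = np.array([r.assoc_p for r in records if r.assoc_p is not None])
    if len(pvals):
        ranks = stats.rankdata(pvals, method="average")
        cutoff_rank = tail * len(pvals)
        it = iter(ranks)
        for rec in records:
            if rec.assoc_p is None:
                rec.associated = False
            else:
                rec.associated = bool(next(it) <= cutoff_rank)
    return records


def conservation_filter(records: list[VariantRecord], min_score: float = 0.7,
                        ) -> list[VariantRecord]:
    """Flag ``conserved`` when the conservation score is >= ``min_score``
    (absent scores are never flagged)."""
    for rec in records:
        rec.conserved = rec.conservation is not None and rec.conservation >= min_score
    return records


def gene_context_filter(records: list[VariantRecord], models: list[GeneModel],
                        splice_window: int = 20) -> list[VariantRecord]:
    """Flag exonic positions and intronic positions within ``splice_window``
    bases of an exon boundary.

    Exon endpoints are inclusive and UTRs count as exonic; the splice
    distance is measured on the intronic side only (a position inside an
    exon is ``in_exon``, never ``near_splice``).
    """
    if splice_window < 0:
        raise VariantError("splice window must be >= 0")
    for rec in records:
        rec.in_exon = False
        rec.near_splice = False
        for gm in models:
            if gm.chrom != rec.chrom:
                continue
            for a, b in gm.exons:
                if a <= rec.pos <= b:
                    rec.in_exon = True
                    break
            if rec.in_exon:
                break
        if rec.in_exon:
            continue
        for gm in models:
            if gm.chrom != rec.chrom:
                continue
            for k, (a, b) in enumerate(gm.exons):
                # intronic side: upstream of exon start (only if a previous
                # exon exists => internal junction) or downstream of exon end
                if 1 <= a - rec.pos <= splice_window and k > 0:
                    rec.near_splice = True
                if 1 <= rec.pos - b <= splice_window and k < len(gm.exons) - 1:
                    rec.near_splice = True
    return records


def combine_filters(records: list[VariantRecord], interval: Interval,
                    ) -> tuple[list[VariantRecord], dict[str, int]]:
    """Set ``of_interest`` = inside interval AND any criterion flag.

    Returns the records and a summary count per criterion (counts taken
    inside the interval) plus the overall of-interest total.
    """
    counts = {"in_interval": 0, "conserved": 0, "associated": 0,
              "in_exon": 0, "near_splice": 0, "of_interest": 0}
    for rec in records:
        inside = rec.chrom == interval.chrom and interval.contains(rec.pos)
        rec.of_interest = inside and (rec.conserved or rec.associated
                                      or rec.in_exon or rec.near_splice)
        if inside:
            counts["in_interval"] += 1
            for flag in ("conserved", "associated", "in_exon", "near_splice"):
                counts[flag] += int(getattr(rec, flag))
        counts["of_interest"] += int(rec.of_interest)
    return records, counts


# ---------------------------------------------------------------------------
# Coding consequence
# ---------------------------------------------------------------------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Consequence:
    kind: str                   # missense | synonymous | stop_gain | stop_loss | non_coding
    notation: str               # e.g. "F452L", "G12=", "Y88*"
    codon_ref: str = ""
    codon_alt: str = ""
    aa_pos: int = 0


def annotate_codon_change(model: GeneModel, cds_sequence: str,
                          pos: int, alt: str) -> Consequence:
    """Amino-acid consequence of a SNV at genomic ``pos`` with alternate
    base ``alt`` (given on the forward genomic strand).

    ``cds_sequence`` is the coding sequence in transcript (5'->3')
    orientation; its length must be divisible by 3.  Positions outside
    the CDS come back as ``non_coding``.
    """
    cds_sequence = cds_sequence.upper()
    if len(cds_sequence) % 3 != 0:
        raise VariantError(
            f"gene {model.gene_id}: CDS length {len(cds_sequence)} not divisible by 3"
        )
    pieces = model.cds_exons()
    if not pieces:
        raise VariantError(f"gene {model.gene_id}: no CDS coordinates")
    # genomic CDS positions 5'->3'
    genomic: list[int] = []
    for a, b in pieces:
        genomic.extend(range(a, b + 1))
    if model.strand == "-":
        genomic = genomic[::-1]
    if len(genomic) != len(cds_sequence):
        raise VariantError(
            f"gene {model.gene_id}: CDS coordinates cover {len(genomic)} bases "
            f"but sequence has {len(cds_sequence)}"
        )
    if pos not in set(genomic):
        return Consequence(kind="non_coding", notation="")
    idx = genomic.index(pos)
    alt_base = alt.upper() if model.strand == "+" else alt.upper().translate(_COMPLEMENT)
    codon_i, offset = divmod(idx, 3)
    codon_ref = cds_sequence[3 * codon_i: 3 * codon_i + 3]
    codon_alt = codon_ref[:offset] + alt_base + codon_ref[offset + 1:]
    aa_ref = CODON_TABLE[codon_ref]
    aa_alt = CODON_TABLE[codon_alt]
    aa_pos = codon_i + 1
    if aa_ref == aa_alt:
        kind, notation = "synonymous", f"{aa_ref}{aa_pos}="
    elif aa_alt == "*":
        kind, notation = "stop_gain", f"{aa_ref}{aa_pos}*"
    elif aa_ref == "*":
        kind, notation = "stop_loss", f"*{aa_pos}{aa_alt}"
    else:
        kind, notation = "missense", f"{aa_ref}{aa_pos}{aa_alt}"
    return Consequence(kind=kind, notation=notation, codon_ref=codon_ref,
                       codon_alt=codon_alt, aa_pos=aa_pos)


def records_to_frame(records: list[VariantRecord]) -> pd.DataFrame:
    """Flatten records (flags and scores, not genotypes) to a DataFrame."""
    return pd.DataFrame([
        {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "conservation": r.conservation, "assoc_p": r.assoc_p,
            "in_exon": r.in_exon, "near_splice": r.near_splice,
            "conserved": r.conserved, "associated": r.associated,
            "of_interest": r.of_interest, "unevaluable": r.unevaluable,
        }
        for r in records
    ])
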