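"""Seeded synthetic datasets with the statistical structure of a
breed-average skull-shape mapping study.

The generator emulates, at desk scale, the data a mapping study of this
design consumes:

* ~60 breeds with hierarchical relatedness (Balding–Nichols drift from a
  shared ancestral population, optionally through breed clades), several
  dogs per breed genotyped at SNPs laid out on chromosomes;
* a quantitative shape trait controlled by a handful of QTLs acting at
  the breed level plus a breed effect and noise;
* per-specimen 3-D skull landmark configurations (51 landmarks, dorsal +
  ventral views sharing four landmarks) deformed along a symmetric axis
  in proportion to the trait, with allometric size coupling;
* selective sweeps at a QTL in the "selected" (brachycephalic) breeds;
* a small resequencing panel (11 genomes) over a critical interval with
  per-sample genotype qualities, a two-gene model, a conservation track
  and one planted causal missense variant.

All randomness flows from ``SimConfig.seed`` through independent
per-stage substreams, so identical configs give bit-identical outputs
regardless of which stages are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import GenotypeMatrix
from .haplotypes import Interval
from .morphometrics import LandmarkConfig
from .variants import CODON_TABLE, GeneModel, VariantRecord

# fixed substream offsets (keep stage draws independent of call order)
_STREAM_FREQ = 1
_STREAM_GENO = 2
_STREAM_LANDMARK = 3
_STREAM_SWEEP = 4
_STREAM_PANEL = 5


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator parameters.  Defaults define the study conditions."""

    seed: int = 0
    # population structure
    n_breeds: int = 60
    dogs_per_breed: int = 8
    n_clades: int = 6
    f_clade: float = 0.08          # drift ancestral -> clade
    f_breed: float = 0.15          # drift clade -> breed
    hierarchical: bool = True
    ancestral_beta: tuple[float, float] = (1.2, 1.2)
    maf_floor: float = 0.05        # ancestral frequencies clipped away from 0/1
    # marker map
    n_chromosomes: int = 10
    markers_per_chromosome: int = 100
    marker_spacing_bp: int = 50_000
    # trait architecture
    n_qtls: int = 5
    qtl_effects: tuple[float, ...] = (1.0, 0.95, 0.9, 0.85, 0.8)
    qtl_freq_beta: float = 0.2     # U-shaped per-breed QTL allele frequencies
    breed_effect_sd: float = 0.25
    trait_noise_sd: float = 0.05
    sex_offset_sd: float = 0.02
    # landmarks
    n_landmark_pairs: int = 23     # 2*23 paired + 5 midline = 51
    n_midline: int = 5
    specimens_per_breed_sex: int = 2
    landmark_noise_sd: float = 0.006  # per coordinate, unit-shape scale
    deformation_scale: float = 0.06
    allometry_coeff: float = 0.04
    size_log_sd: float = 0.12
    size_trait_coupling: float = -0.15  # brachy breeds run smaller
    base_skull_mm: float = 120.0
    # sweep
    sweep_target_freq: float = 0.95
    sweep_halfwidth: int = 5       # markers either side of the swept QTL
    n_selected_breeds: int = 7
    # resequencing panel
    panel_size: int = 11
    n_panel_variants: int = 452            # within the refined interval
    n_downstream_variants: int = 250       # between breakpoint and interval end
    panel_interval: tuple[str, int, int] = ("chr32", 8_152_258, 8_342_370)
    breakpoint_pos: int = 8_237_937        # last position of two-genome agreement
    causal_pos: int = 8_196_098
    frac_low_gq: float = 0.08
    gq_threshold: float = 8.0
    frac_conserved: float = 0.10
    n_panel_brachy: int = 4

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), stream])

    @property
    def n_landmarks(self) -> int:
        return 2 * self.n_landmark_pairs + self.n_midline

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


# ---------------------------------------------------------------------------
# Landmark template geometry
# ---------------------------------------------------------------------------


def landmark_template(config: SimConfig) -> tuple[np.ndarray, dict[int, int],
                                                  list[int], list[int], set[int]]:
    """Deterministic bilaterally symmetric 51-landmark template.

    Returns (coords (k,3) in unit-shape scale, left/right pairing map,
    dorsal-view ids, ventral-view ids, neurocranium subset).  Midline
    landmarks get ids 1..n_midline and lie on the x=0 plane; pairs get
    consecutive ids (left, right) mirrored in x.  The template geometry is
    a fixed function of the landmark counts, not of the seed.
    """
    rng = np.random.default_rng([777, config.n_landmark_pairs, config.n_midline])
    k = config.n_landmarks
    coords = np.zeros((k, 3))
    pairing: dict[int, int] = {}
    # midline: along the rostro-caudal (y) axis
    for i in range(config.n_midline):
        lid = i + 1
        coords[i] = [0.0, -0.5 + i / max(config.n_midline - 1, 1),
                     0.1 * rng.normal()]
        pairing[lid] = lid
    for j in range(config.n_landmark_pairs):
        left_id = config.n_midline + 2 * j + 1
        right_id = left_id + 1
        base = np.array([
            0.15 + 0.35 * rng.random(),           # lateral offset
            rng.uniform(-0.55, 0.55),             # rostro-caudal
            rng.uniform(-0.25, 0.25),             # dorso-ventral
        ])
        coords[left_id - 1] = base * np.array([-1.0, 1.0, 1.0])
        coords[right_id - 1] = base
        pairing[left_id] = right_id
        pairing[right_id] = left_id
    coords -= coords.mean(axis=0)
    coords /= np.sqrt(np.sum(coords ** 2))

    ids = list(range(1, k + 1))
    # the shared landmarks of the two digitizing views
    shared = [1, 2, 28, 29]
    half = [i for i in ids if i not in shared]
    dorsal = sorted(shared + half[: len(half) // 2])
    ventral = sorted(shared + half[len(half) // 2:])
    neuro = set(ids[: config.n_midline + 8])   # midline + first 4 pairs
    return coords, pairing, dorsal, ventral, neuro


def _symmetric_axis(config: SimConfig, coords: np.ndarray,
                    pairing: dict[int, int], stream_salt: int) -> np.ndarray:
    """Random unit deformation axis respecting bilateral symmetry."""
    rng = np.random.default_rng([888, int(config.seed) % (2 ** 31), stream_salt])
    k = config.n_landmarks
    v = rng.normal(size=(k, 3))
    sym = np.zeros_like(v)
    for lid in range(1, k + 1):
        partner = pairing[lid]
        mirror = v[partner - 1] * np.array([-1.0, 1.0, 1.0])
        sym[lid - 1] = 0.5 * (v[lid - 1] + mirror)
    sym -= sym.mean(axis=0)
    sym /= np.sqrt(np.sum(sym ** 2))
    return sym


# ---------------------------------------------------------------------------
# Stage 1: breed allele frequencies
# ---------------------------------------------------------------------------


def simulate_breed_frequencies(config: SimConfig) -> tuple[np.ndarray, np.ndarray,
                                                           np.ndarray]:
    """Balding–Nichols drift of ancestral frequencies into breeds.

    Ancestral frequencies p are Beta(*ancestral_beta*), clipped to
    [maf_floor, 1 - maf_floor].  A branch with drift F draws the derived
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F).  With ``hierarchical``
    the drift happens in two levels (ancestral -> clade -> breed), giving
    breed clades ("small breeds related to small breeds").

    Returns (ancestral p (m,), breed frequencies (n_breeds, m),
    clade index per breed (n_breeds,)).
    """
    for f in (config.f_clade, config.f_breed):
        if not 0.0 < f < 1.0:
            raise SimulationError(f"drift F={f} outside (0, 1)")
    rng = config.rng(_STREAM_FREQ)
    m = config.n_markers
    a, b = config.ancestral_beta
    p = rng.beta(a, b, size=m)
    p = np.clip(p, config.maf_floor, 1.0 - config.maf_floor)

    def drift(freq: np.ndarray, F: float, size: int) -> np.ndarray:
        alpha = freq * (1.0 - F) / F
        beta = (1.0 - freq) * (1.0 - F) / F
        out = rng.beta(alpha[None, :].repeat(size, 0),
                       beta[None, :].repeat(size, 0))
        return np.clip(out, 1e-6, 1.0 - 1e-6)

    clade_of = np.arange(config.n_breeds) % config.n_clades
    if config.hierarchical:
        clade_freq = drift(p, config.f_clade, config.n_clades)
        breed_freq = np.empty((config.n_breeds, m))
        for i in range(config.n_breeds):
            alpha = clade_freq[clade_of[i]] * (1.0 - config.f_breed) / config.f_breed
            beta = (1.0 - clade_freq[clade_of[i]]) * (1.0 - config.f_breed) / config.f_breed
            breed_freq[i] = np.clip(rng.beta(alpha, beta), 1e-6, 1.0 - 1e-6)
    else:
        breed_freq = drift(p, config.f_breed, config.n_breeds)
    return p, breed_freq, clade_of


def expected_breed_heterozygosity(p: np.ndarray, F: float) -> np.ndarray:
    """Analytic within-breed expected heterozygosity 2 p (1-p) (1-F)."""
    return 2.0 * p * (1.0 - p) * (1.0 - F)


# ---------------------------------------------------------------------------
# Stage 2: genotypes, trait, landmarks
# ---------------------------------------------------------------------------


def marker_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    for c in range(config.n_chromosomes):
        for j in range(config.markers_per_chromosome):
            rows.append({
                "chrom": f"chr{c + 1}",
                "pos": (j + 1) * config.marker_spacing_bp,
                "a1": "A", "a2": "G",
            })
    return pd.DataFrame(rows)


def qtl_marker_indices(config: SimConfig) -> np.ndarray:
    """QTL marker indices: mid-chromosome markers of the first n_qtls
    chromosomes (deterministic placement)."""
    if config.n_qtls > config.n_chromosomes:
        raise SimulationError("need at least one chromosome per QTL")
    half = config.markers_per_chromosome // 2
    return np.array([
        q * config.markers_per_chromosome + half for q in range(config.n_qtls)
    ])


@dataclass
class SimulatedStudy:
    """Everything stage 2 produces, plus ground truth for test harnesses."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame            # breed-sex table (pc1 = planted trait)
    landmarks: list[LandmarkConfig]     # merged per-specimen configs
    landmark_views: list[LandmarkConfig]  # dorsal+ventral views per specimen
    specimen_traits: pd.DataFrame       # specimen_id, breed, sex, trait, size
    pairing: dict[int, int]
    neurocranium_subset: set[int]
    dorsal_ids: list[int]
    ventral_ids: list[int]
    breed_traits: np.ndarray
    breed_frequencies: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    clade_of: np.ndarray
    selected_breeds: list[str]          # top-trait ("brachycephalic") breeds


def simulate_genotypes_and_trait(config: SimConfig,
                                 breed_freq: np.ndarray | None = None,
                                 ) -> SimulatedStudy:
    """Draw dog genotypes and build the breed-level trait and specimen
    landmark configurations.

    Dogs are binomial draws from their breed's allele frequencies.  The
    trait is assembled at breed level: sum of QTL effects times the breed
    mean dosage at each QTL marker, plus a breed effect and noise.  Each
    breed-sex cell receives ``specimens_per_breed_sex`` museum "specimens"
    whose landmark coordinates are the symmetric template deformed along a
    fixed axis in proportion to the trait, an allometric term in log
    relative size, and isotropic noise, then scaled to the specimen's
    centroid size and placed at a random orientation in digitizer space.
    """
    if breed_freq is None:
        _, breed_freq, clade_of = simulate_breed_frequencies(config)
    else:
        clade_of = np.arange(config.n_breeds) % config.n_clades
    rng = config.rng(_STREAM_GENO)
    markers = marker_map(config)
    m = config.n_markers
    n = config.n_breeds * config.dogs_per_breed

    qtls = qtl_marker_indices(config)
    # QTL alleles were targets of breed-formation selection: their per-breed
    # frequencies are strongly differentiated (U-shaped), unlike the neutral
    # Balding-Nichols background
    breed_freq = breed_freq.copy()
    breed_freq[:, qtls] = np.clip(
        rng.beta(config.qtl_freq_beta, config.qtl_freq_beta,
                 size=(config.n_breeds, len(qtls))), 1e-6, 1.0 - 1e-6)

    breeds = [f"Breed{i + 1:03d}" for i in range(config.n_breeds)]
    calls = np.empty((n, m), dtype=np.int8)
    iid, breed_col, sex_col = [], [], []
    for i, breed in enumerate(breeds):
        for d in range(config.dogs_per_breed):
            row = i * config.dogs_per_breed + d
            calls[row] = rng.binomial(2, breed_freq[i])
            iid.append(f"{breed}_dog{d + 1}")
            breed_col.append(breed)
            sex_col.append("M" if d % 2 == 0 else "F")
    individuals = pd.DataFrame({"iid": iid, "breed": breed_col, "sex": sex_col})
    G = GenotypeMatrix(calls, individuals, markers)

    effects = np.asarray(config.qtl_effects[: config.n_qtls], float)
    if len(effects) != config.n_qtls:
        raise SimulationError("qtl_effects shorter than n_qtls")
    # breed mean dosage at the QTLs (genetic value acts at breed level)
    mean_dosage = np.vstack([
        calls[i * config.dogs_per_breed:(i + 1) * config.dogs_per_breed, qtls]
        .mean(axis=0)
        for i in range(config.n_breeds)
    ])
    genetic = (mean_dosage - 1.0) @ effects
    breed_effect = rng.normal(0.0, config.breed_effect_sd, config.n_breeds)
    noise = rng.normal(0.0, config.trait_noise_sd, config.n_breeds)
    trait = genetic + breed_effect + noise
    # center and put on a PC1-like scale
    trait = (trait - trait.mean()) / max(trait.std(), 1e-12) * 0.12

    order = np.argsort(trait)[::-1]
    selected = [breeds[i] for i in order[: config.n_selected_breeds]]

    # --- landmarks -------------------------------------------------------
    template, pairing, dorsal_ids, ventral_ids, neuro = landmark_template(config)
    axis = _symmetric_axis(config, template, pairing, stream_salt=1)
    allo_axis = _symmetric_axis(config, template, pairing, stream_salt=2)
    lrng = config.rng(_STREAM_LANDMARK)

    log_size_breed = (config.size_trait_coupling * (trait / 0.12)
                      + lrng.normal(0.0, config.size_log_sd, config.n_breeds))

    specimens: list[LandmarkConfig] = []
    views: list[LandmarkConfig] = []
    srows = []
    all_ids = list(range(1, config.n_landmarks + 1))
    for i, breed in enumerate(breeds):
        for sex in ("M", "F"):
            cell_offset = lrng.normal(0.0, config.sex_offset_sd)
            for s in range(config.specimens_per_breed_sex):
                sid = f"{breed}_{sex}{s + 1}"
                t = trait[i] + cell_offset
                log_rel = log_size_breed[i] + lrng.normal(0.0, 0.03)
                shape = (template
                         + (t / 0.12) * config.deformation_scale * axis
                         + config.allometry_coeff * log_rel * allo_axis
                         + lrng.normal(0.0, config.landmark_noise_sd,
                                       template.shape))
                size_mm = config.base_skull_mm * np.exp(log_rel)
                coords = shape * size_mm
                # random placement in digitizer space
                Q, _ = np.linalg.qr(lrng.normal(size=(3, 3)))
                if np.linalg.det(Q) < 0:
                    Q[:, 0] *= -1
                coords = coords @ Q + lrng.normal(0.0, 50.0, 3)
                full = LandmarkConfig(sid, breed, sex, "merged",
                                      {lid: coords[lid - 1] for lid in all_ids})
                specimens.append(full)
                # split into the two digitizing views, each in its own frame
                dors = {lid: coords[lid - 1] for lid in dorsal_ids}
                Q2, _ = np.linalg.qr(lrng.normal(size=(3, 3)))
                if np.linalg.det(Q2) < 0:
                    Q2[:, 0] *= -1
                t2 = lrng.normal(0.0, 30.0, 3)
                vent = {lid: coords[lid - 1] @ Q2 + t2 for lid in ventral_ids}
                views.append(LandmarkConfig(sid, breed, sex, "dorsal", dors))
                views.append(LandmarkConfig(sid, breed, sex, "ventral", vent))
                srows.append({"specimen_id": sid, "breed": breed, "sex": sex,
                              "trait": t, "log_rel_size": log_rel,
                              "size_mm": size_mm})

    specimen_traits = pd.DataFrame(srows)
    pheno_rows = []
    for i, breed in enumerate(breeds):
        for sex in ("M", "F"):
            cell = specimen_traits[(specimen_traits["breed"] == breed)
                                   & (specimen_traits["sex"] == sex)]
            pheno_rows.append({
                "breed": breed, "sex": sex,
                "pc1": float(cell["trait"].mean()),
                "log_neurocranium_centroid": float(
                    np.log(cell["size_mm"]).mean()),
                "n_specimens": len(cell),
            })
    phenotypes = pd.DataFrame(pheno_rows)

    return SimulatedStudy(
        genotypes=G, phenotypes=phenotypes, landmarks=specimens,
        landmark_views=views, specimen_traits=specimen_traits,
        pairing=pairing, neurocranium_subset=neuro,
        dorsal_ids=dorsal_ids, ventral_ids=ventral_ids,
        breed_traits=trait, breed_frequencies=breed_freq,
        qtl_indices=qtls, qtl_effects=effects, clade_of=clade_of,
        selected_breeds=selected,
    )


# ---------------------------------------------------------------------------
# Stage 3: selective sweep
# ---------------------------------------------------------------------------


def simulate_sweep(config: SimConfig, G: GenotypeMatrix,
                   breed_freq: np.ndarray,
                   locus: int | None = None,
                   selected_breeds: list[str] | None = None,
                   ) -> tuple[GenotypeMatrix, dict]:
    """Drive one haplotype toward fixation around a locus in selected breeds.

    Within ``sweep_halfwidth`` markers either side of the locus, each
    chromosome copy of each dog in a selected breed is replaced by the
    sweep haplotype with probability ``sweep_target_freq`` (otherwise
    redrawn from the breed's frequencies).  Other breeds' genotypes are
    untouched.  Returns a new matrix and a truth dict.
    """
    rng = config.rng(_STREAM_SWEEP)
    if locus is None:
        locus = int(qtl_marker_indices(config)[0])
    lo = max(0, locus - config.sweep_halfwidth)
    chrom = G.markers["chrom"].iloc[locus]
    hi = min(G.n_markers - 1, locus + config.sweep_halfwidth)
    # clip the window to the locus's chromosome
    while G.markers["chrom"].iloc[lo] != chrom:
        lo += 1
    while G.markers["chrom"].iloc[hi] != chrom:
        hi -= 1
    window = np.arange(lo, hi + 1)
    sweep_hap = rng.binomial(1, 0.5, size=len(window)).astype(np.int8)

    if selected_breeds is None:
        raise SimulationError("selected_breeds must be provided")
    breeds = [f"Breed{i + 1:03d}" for i in range(config.n_breeds)]
    breed_index = {b: i for i, b in enumerate(breeds)}

    calls = G.calls.copy()
    sel_mask = G.individuals["breed"].isin(selected_breeds).to_numpy()
    for row in np.nonzero(sel_mask)[0]:
        bi = breed_index[G.individuals["breed"].iloc[row]]
        dosage = np.zeros(len(window), dtype=np.int8)
        for _copy in range(2):
            take_sweep = rng.random() < config.sweep_target_freq
            if take_sweep:
                dosage += sweep_hap
            else:
                dosage += rng.binomial(1, breed_freq[bi, window]).astype(np.int8)
        calls[row, window] = dosage
    truth = {"locus": int(locus), "window": (int(lo), int(hi)),
             "haplotype": sweep_hap.tolist(),
             "selected_breeds": list(selected_breeds)}
    return GenotypeMatrix(calls, G.individuals, G.markers), truth


# ---------------------------------------------------------------------------
# Stage 4: resequencing panel over the critical interval
# ---------------------------------------------------------------------------

_PANEL_BREEDS = [
    "Pekingese", "Bulldog", "BostonTerrier", "Pug",          # brachycephalic
    "ScottishTerrier",                                       # outlier
    "Greyhound", "Borzoi", "Collie", "Saluki",
    "GoldenRetriever", "Beagle",
]


def _random_cds(rng: np.random.Generator, n_codons: int,
                fixed: dict[int, str]) -> str:
    """Random stop-free CDS of ``n_codons`` codons with fixed codons
    (1-based codon index -> codon) planted; ends with a stop codon."""
    sense = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
    codons = [sense[rng.integers(len(sense))] for _ in range(n_codons - 1)]
    codons.append("TAA")
    for idx, codon in fixed.items():
        codons[idx - 1] = codon
    return "".join(codons)


@dataclass
class ResequencingPanel:
    records: list[VariantRecord]
    sample_names: list[str]
    phenotypes: np.ndarray              # PC1-like value per genome
    gene_models: list[GeneModel]
    cds_sequences: dict[str, str]
    conservation: pd.DataFrame          # chrom, start, end, score (BedGraph rows)
    interval: Interval
    truth: dict


def simulate_resequencing_panel(config: SimConfig,
                                interval: Interval | None = None,
                                ) -> ResequencingPanel:
    """Emit the critical-interval variant table and its annotation tracks.

    The 11-genome panel covers the full haplotype-sharing interval.  The
    brachycephalic panel members carry one shared haplotype (identical
    genotypes) from the interval start through ``breakpoint_pos``; beyond
    it the lead brachycephalic genome is recombinant, so the two-genome
    agreement scan recovers the breakpoint.  452 SNVs fall inside the
    refined interval plus a downstream block, each with per-sample GQ
    values (a configured fraction below the masking threshold), a
    two-gene model with one gene fully inside the refined interval, a
    conservation track with a configured fraction of scores >= 0.7, and
    one planted causal missense variant (third codon position TTC -> TTA,
    Phe -> Leu) carried homozygous by the brachycephalic members (and by
    the outlier breed, motivating its exclusion from the association
    filter).
    """
    rng = config.rng(_STREAM_PANEL)
    chrom, istart, iend = config.panel_interval
    bp = config.breakpoint_pos
    if interval is None:
        interval = Interval(chrom, istart, iend, provenance="haplotype-sharing")
    n_s = config.panel_size
    names = list(_PANEL_BREEDS[:n_s])
    brachy = set(names[: config.n_panel_brachy])
    outlier = "ScottishTerrier"

    # PC1-like phenotypes: brachy high, rest low
    pheno = np.array([
        rng.uniform(0.18, 0.30) if b in brachy else rng.uniform(-0.20, 0.02)
        for b in names
    ])

    # gene models: gene A fully inside the interval carries the causal codon;
    # gene B straddles the interval start.
    causal = config.causal_pos
    aa_index = 452
    cds_before = 3 * (aa_index - 1) + 2          # CDS bases preceding the causal base
    exon1_cds_len = 300
    exon2_start = causal - (cds_before - exon1_cds_len)
    exon1_end = exon2_start - 3_500
    cds_start = exon1_end - exon1_cds_len + 1
    exon1_start = cds_start - 300                # 5' UTR
    total_cds = 3 * (aa_index + 16)              # 16 codons past the causal one
    cds_end = exon2_start + (total_cds - exon1_cds_len) - 1
    exon2_end = cds_end + 250                    # 3' UTR
    gene_a = GeneModel("geneA", chrom, "+",
                       [(exon1_start, exon1_end), (exon2_start, exon2_end)],
                       cds_start=cds_start, cds_end=cds_end)
    gene_b = GeneModel("geneB", chrom, "+",
                       [(istart - 30_000, istart - 29_200),
                        (istart - 200, istart + 700),
                        (istart + 9_000, istart + 9_700)],
                       cds_start=istart - 29_900 + 200, cds_end=istart + 9_500)
    cds_a = _random_cds(rng, total_cds // 3, fixed={aa_index: "TTC"})

    # variant positions: 452 inside the refined interval (causal and the
    # breakpoint marker included), plus a downstream block
    inner = np.setdiff1d(np.arange(istart, bp), [causal])
    pos_in = rng.choice(inner, size=config.n_panel_variants - 2, replace=False)
    downstream = np.arange(bp + 1, iend + 1)
    pos_down = rng.choice(downstream, size=config.n_downstream_variants,
                          replace=False)
    first_down = int(pos_down.min())
    positions = np.sort(np.concatenate([pos_in, [causal, bp], pos_down]))

    bases = np.array(list("ACGT"))
    records: list[VariantRecord] = []
    brachy_vec = np.array([b in brachy for b in names])
    recombinant = names[0]                 # lead brachy genome (Pekingese)
    i_recomb = names.index(recombinant)
    for p in positions:
        if p == causal:
            ref, alt = "C", "A"
            g = np.where(brachy_vec, 2, 0).astype(np.int8)
            g[names.index(outlier)] = 2   # the outlier carries it too
            gq = rng.integers(30, 100, n_s).astype(float)
            cons = 0.95
        else:
            ref, alt = rng.choice(bases, size=2, replace=False)
            freq = rng.uniform(0.05, 0.95)
            # a minority of variants track the phenotype split
            if rng.random() < 0.15:
                g = np.where(brachy_vec, 2, rng.binomial(2, 0.1, n_s)
                             ).astype(np.int8)
            else:
                g = rng.binomial(2, freq, n_s).astype(np.int8)
                # brachy genomes share one haplotype up to the breakpoint
                if p <= bp:
                    g[brachy_vec] = 0
            if p > bp:
                # recombinant genome is drawn independently downstream
                g[i_recomb] = rng.binomial(2, freq)
                if p == first_down:
                    # sharp breakpoint: guaranteed disagreement right after
                    others = np.nonzero(brachy_vec)[0]
                    others = others[others != i_recomb]
                    g[others] = 0
                    g[i_recomb] = 2
            gq = rng.integers(8, 100, n_s).astype(float)
            low = rng.random(n_s) < config.frac_low_gq
            gq[low] = rng.integers(0, 8, int(low.sum()))
            if p in (bp, first_down):
                gq = rng.integers(60, 100, n_s).astype(float)
            if rng.random() < config.frac_conserved:
                cons = float(rng.uniform(0.7, 1.0))
            else:
                cons = float(rng.uniform(0.0, 0.7))
        records.append(VariantRecord(chrom=chrom, pos=int(p), ref=str(ref),
                                     alt=str(alt), genotypes=g, qualities=gq,
                                     conservation=cons))

    cons_rows = [{"chrom": r.chrom, "start": r.pos - 1, "end": r.pos,
                  "score": r.conservation} for r in records]
    truth = {"causal_pos": int(causal), "causal_gene": "geneA",
             "causal_codon": aa_index, "outlier": outlier,
             "brachy_samples": sorted(brachy), "breakpoint_pos": int(bp),
             "recombinant": recombinant,
             "agreement_pair": [names[1], recombinant]}
    return ResequencingPanel(
        records=records, sample_names=names, phenotypes=pheno,
        gene_models=[gene_a, gene_b], cds_sequences={"geneA": cds_a},
        conservation=pd.DataFrame(cons_rows), interval=interval, truth=truth,
    )
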