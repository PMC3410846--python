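"""End-to-end orchestration: simulate -> morpho -> gwas -> sweep ->
interval -> filter.

Stages hand data to each other through plain files (CSV/TSV/VCF/GFF3/
BED), so each stage is independently runnable and testable; a JSON run
manifest records the config hash, seed, per-stage inputs/outputs and the
package version.  Re-running with the same config and seed reproduces
identical stage outputs; completed stages are skipped on resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, morphometrics as mm
from .association import (assign_phenotypes, bonferroni_threshold, kinship,
                          linear_assoc, lmm_assoc, snp_qc)
from .haplotypes import Interval, em_phase, refine_breakpoint, shared_interval
from .selection import (PopulationSpec, fst, log_h_ratio, obs_het,
                        percentile_flags, sliding_windows)
from .simulate import (SimConfig, simulate_breed_frequencies,
                       simulate_genotypes_and_trait, simulate_resequencing_panel,
                       simulate_sweep)
from .variants import (annotate_codon_change, combine_filters,
                       conservation_filter, gene_context_filter, mask_gq,
                       records_to_frame, variant_assoc)

log = logging.getLogger(__name__)

STAGES = ["simulate", "morpho", "gwas", "sweep", "interval", "filter"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.update(overrides or {})
    cfg.setdefault("seed", 0)
    cfg.setdefault("sim", {})
    cfg.setdefault("gwas", {"model": "mixed", "covar": ["size"],
                            "alpha": 0.05, "strata": "all"})
    cfg.setdefault("morpho", {"n_perm": 200})
    cfg.setdefault("sweep", {"window": 10, "fst_tail": 0.05, "hr_tail": 0.002})
    cfg.setdefault("filter", {"gq": 8, "cons": 0.7, "assoc_tail": 0.05,
                              "splice": 20})
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    return SimConfig(seed=int(cfg["seed"]), **cfg.get("sim", {}))


def _hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage implementations (each reads its declared inputs from ``out``)
# ---------------------------------------------------------------------------


def stage_simulate(cfg: dict, out: Path) -> list[str]:
    sim = _sim_config(cfg)
    _, freqs, _ = simulate_breed_frequencies(sim)
    study = simulate_genotypes_and_trait(sim, breed_freq=freqs)
    G, sweep_truth = simulate_sweep(sim, study.genotypes,
                                    study.breed_frequencies,
                                    selected_breeds=study.selected_breeds)
    panel = simulate_resequencing_panel(sim)

    io.write_landmarks_csv(study.landmark_views, out / "landmarks.csv")
    io.write_morpho_config(study.pairing, study.neurocranium_subset,
                           {1, 2, 28, 29}, out / "morpho.yaml")
    io.write_plink(G, out / "genotypes")
    io.write_vcf(panel.records, panel.sample_names, out / "panel.vcf")
    io.write_gff3(panel.gene_models, out / "genes.gff3")
    io.write_bedgraph(panel.conservation, out / "conservation.bedgraph")
    pd.DataFrame({"sample": panel.sample_names,
                  "pc1": panel.phenotypes}).to_csv(
        out / "panel_phenotypes.tsv", sep="\t", index=False)
    (out / "cds_geneA.txt").write_text(panel.cds_sequences["geneA"] + "\n")
    truth = {
        "qtl_indices": study.qtl_indices.tolist(),
        "qtl_effects": study.qtl_effects.tolist(),
        "selected_breeds": study.selected_breeds,
        "sweep": sweep_truth,
        "panel": panel.truth,
        "panel_interval": [panel.interval.chrom, panel.interval.start,
                           panel.interval.end],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return ["landmarks.csv", "morpho.yaml", "genotypes.ped", "genotypes.map",
            "panel.vcf", "genes.gff3", "conservation.bedgraph",
            "panel_phenotypes.tsv", "cds_geneA.txt", "truth.json"]


def stage_morpho(cfg: dict, out: Path) -> list[str]:
    views = io.read_landmarks_csv(out / "landmarks.csv")
    mcfg = io.read_morpho_config(out / "morpho.yaml")
    by_spec: dict[str, dict[str, object]] = {}
    for v in views:
        by_spec.setdefault(v.specimen_id, {})[v.view] = v
    merged = []
    for sid, d in by_spec.items():
        if "merged" in d:
            merged.append(d["merged"])
        elif "dorsal" in d and "ventral" in d:
            cfg_m, _ = mm.merge_views(d["dorsal"], d["ventral"], mcfg["shared"])
            merged.append(cfg_m)
        else:
            raise PipelineError(f"specimen {sid}: incomplete views")
    required = sorted(set().union(*[set(c.ids) for c in merged]))
    merged, dropped = mm.filter_complete(merged, required)
    if dropped:
        log.warning("morpho: excluded %d specimens with missing landmarks",
                    len(dropped))
    sym = [mm.symmetric_component(c, mcfg["pairing"]) for c in merged]
    samples, _ = mm.gpa(sym, neurocranium_subset=mcfg["neurocranium"])
    groups = [(c.breed, c.sex) for c in merged]
    n_perm = int(cfg["morpho"].get("n_perm", 200))
    try:
        fit = mm.allometric_regression(samples, groups, n_perm=n_perm,
                                       rng=np.random.default_rng(cfg["seed"]))
    except mm.MorphometricsError:
        # singleton breed-sex cells leave no within-group size variance;
        # fall back to pooling sexes within breed
        log.warning("morpho: breed-sex cells too small for the pooled "
                    "regression; pooling sexes within breed")
        groups_b = [(c.breed, "") for c in merged]
        fit = mm.allometric_regression(samples, groups_b, n_perm=n_perm,
                                       rng=np.random.default_rng(cfg["seed"]))
    space = mm.shape_pca(fit.residuals, [s.specimen_id for s in samples])
    meta = pd.DataFrame({"specimen_id": [s.specimen_id for s in samples],
                         "breed": [c.breed for c in merged],
                         "sex": [c.sex for c in merged]})
    log_neuro = np.log([s.neurocranium_centroid_size for s in samples])
    n_pc = min(4, space.scores.shape[1])
    scores = pd.concat([meta, pd.DataFrame(
        space.scores[:, :n_pc], columns=[f"pc{j + 1}" for j in range(n_pc)])],
        axis=1)
    scores["log_neurocranium_centroid"] = log_neuro
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    pheno = mm.breed_sex_average(space.scores[:, :n_pc], meta, log_neuro)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    summary = {
        "n_specimens": len(samples),
        "allometry_percent_variance": fit.percent_variance,
        "allometry_permutation_p": fit.permutation_p,
        "variance_fractions": space.variance_fractions[:n_pc].tolist(),
    }
    (out / "morpho_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return ["scores.tsv", "phenotypes.tsv", "morpho_summary.json"]


def stage_gwas(cfg: dict, out: Path) -> list[str]:
    G = io.read_plink(out / "genotypes")
    pheno = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    gcfg = cfg["gwas"]
    G = snp_qc(G)
    Gp, y, size = assign_phenotypes(G, pheno)
    covar = size.reshape(-1, 1) if "size" in gcfg.get("covar", []) else None
    names = ["log_neurocranium_centroid"] if covar is not None else None
    if gcfg.get("model", "mixed") == "mixed":
        K = kinship(Gp)
        res = lmm_assoc(Gp, y, K, covariates=covar, covariate_names=names)
    else:
        res = linear_assoc(Gp, y, covariates=covar, covariate_names=names)
    thr = bonferroni_threshold(float(gcfg.get("alpha", 0.05)), Gp.n_markers)
    tab = res.markers.copy()
    tab["significant"] = tab["neg_log10_p"] >= thr
    tab.to_csv(out / "gwas.tsv", sep="\t", index=False)
    summary = {"model": res.model, "n_markers": int(Gp.n_markers),
               "n_dogs": int(Gp.n_individuals),
               "bonferroni_neg_log10": thr,
               "n_significant": int(tab["significant"].sum()),
               "lambda_gc": res.genomic_inflation()}
    (out / "gwas_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return ["gwas.tsv", "gwas_summary.json"]


def _polar_populations(pheno: pd.DataFrame, n_each: int = 10,
                       ) -> tuple[PopulationSpec, PopulationSpec]:
    by_breed = pheno.groupby("breed")["pc1"].mean().sort_values()
    n_each = min(n_each, len(by_breed) // 2)
    dolicho = by_breed.index[:n_each].tolist()
    brachy = by_breed.index[-n_each:].tolist()
    return (PopulationSpec("brachy", brachy, "brachy"),
            PopulationSpec("dolicho", dolicho, "dolicho"))


def stage_sweep(cfg: dict, out: Path) -> list[str]:
    G = io.read_plink(out / "genotypes")
    pheno = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    scfg = cfg["sweep"]
    brachy, dolicho = _polar_populations(pheno)
    ho_b = obs_het(G, brachy)
    ho_d = obs_het(G, dolicho)
    hr = log_h_ratio(ho_d, ho_b)
    f = fst(G, brachy, dolicho)
    per_snp = G.markers[["chrom", "pos"]].copy()
    per_snp["ho_brachy"], per_snp["ho_dolicho"] = ho_b, ho_d
    per_snp["log_hr"], per_snp["fst"] = hr, f
    per_snp.to_csv(out / "sweep_per_snp.tsv", sep="\t", index=False)
    k = int(scfg.get("window", 10))
    wins = []
    for stat, vals, tail, frac in (
        ("FST", f, "high", float(scfg.get("fst_tail", 0.05))),
        ("log_HR", hr, "low", float(scfg.get("hr_tail", 0.002))),
        ("HO_brachy", ho_b, "low", 0.05),
    ):
        w = sliding_windows(vals, G.markers, stat, k=k)
        wins.append(percentile_flags(w, tail, frac))
    windows = pd.concat(wins, ignore_index=True)
    windows.to_csv(out / "sweep_windows.tsv", sep="\t", index=False)
    return ["sweep_per_snp.tsv", "sweep_windows.tsv"]


def stage_interval(cfg: dict, out: Path) -> list[str]:
    G = io.read_plink(out / "genotypes")
    gwas = pd.read_csv(out / "gwas.tsv", sep="\t")
    truth = json.loads((out / "truth.json").read_text())
    # focus on the associated locus with selection evidence: the best GWAS
    # marker inside an F_ST-flagged sweep window (fall back to the global top)
    wins = pd.read_csv(out / "sweep_windows.tsv", sep="\t")
    cand = gwas
    marks = {}
    for stat in ("FST", "HO_brachy"):
        flagged = wins[(wins["stat"] == stat) & wins["flagged"]]
        hit = np.zeros(len(gwas), bool)
        for w in flagged.itertuples():
            hit |= ((gwas["chrom"] == w.chrom)
                    & (gwas["pos"] >= w.start_pos)
                    & (gwas["pos"] <= w.end_pos)).to_numpy()
        marks[stat] = hit
    both = marks["FST"] & marks["HO_brachy"]
    if both.any():
        cand = gwas[both]
    top = cand["neg_log10_p"].idxmax()
    chrom, pos = gwas.loc[top, "chrom"], gwas.loc[top, "pos"]
    on_chrom = np.nonzero((G.markers["chrom"] == chrom).to_numpy())[0]
    center = int(np.argmin(np.abs(G.markers["pos"].to_numpy()[on_chrom] - pos)))
    lo = max(0, center - 4)
    win_idx = on_chrom[lo: lo + 8]
    Gw = G.subset_markers(np.isin(np.arange(G.n_markers), win_idx))
    selected = truth["selected_breeds"]
    keep = Gw.individuals["breed"].isin(selected).to_numpy()
    haps = em_phase(Gw.subset_individuals(keep))
    iv = shared_interval(haps, selected, min_freq=0.10)
    intervals = []
    if iv is not None:
        intervals.append(iv)
    # breakpoint refinement: allelic agreement of the two lead brachycephalic
    # panel genomes over the haplotype-sharing panel interval
    records, samples = io.read_vcf_records(out / "panel.vcf")
    pchrom, pstart, pend = truth["panel_interval"]
    panel_iv = Interval(pchrom, pstart, pend, provenance="haplotype-sharing")
    a, b = truth["panel"]["agreement_pair"]
    ia, ib = samples.index(a), samples.index(b)
    calls_a = pd.DataFrame({"pos": [r.pos for r in records],
                            "gt": [int(r.genotypes[ia]) for r in records]})
    calls_b = pd.DataFrame({"pos": [r.pos for r in records],
                            "gt": [int(r.genotypes[ib]) for r in records]})
    refined = refine_breakpoint(calls_a, calls_b, panel_iv)
    intervals.append(panel_iv)
    if refined is not None:
        intervals.append(refined)
    io.write_bed(intervals, out / "intervals.bed")
    report = "\n".join(str(iv) for iv in intervals) + "\n"
    (out / "interval_report.txt").write_text(report)
    return ["intervals.bed", "interval_report.txt"]


def stage_filter(cfg: dict, out: Path) -> list[str]:
    fcfg = cfg["filter"]
    records, samples = io.read_vcf_records(out / "panel.vcf")
    track = io.read_bedgraph(out / "conservation.bedgraph")
    io.attach_conservation(records, track)
    models = io.read_gff3(out / "genes.gff3")
    pheno = pd.read_csv(out / "panel_phenotypes.tsv", sep="\t")
    truth = json.loads((out / "truth.json").read_text())
    y = pheno.set_index("sample").loc[samples, "pc1"].to_numpy()

    intervals = io.read_bed_intervals(out / "intervals.bed")
    refined = [iv for iv in intervals if iv.provenance == "breakpoint-refined"]
    interval = refined[-1] if refined else intervals[-1]

    mask_gq(records, float(fcfg.get("gq", 8)))
    variant_assoc(records, y, samples,
                  exclude=[truth["panel"]["outlier"]],
                  tail=float(fcfg.get("assoc_tail", 0.05)))
    conservation_filter(records, float(fcfg.get("cons", 0.7)))
    gene_context_filter(records, models, int(fcfg.get("splice", 20)))
    records, counts = combine_filters(records, interval)
    tab = records_to_frame(records)
    tab.to_csv(out / "variants_filtered.tsv", sep="\t", index=False)

    cds = (out / "cds_geneA.txt").read_text().strip()
    gene_a = next(g for g in models if g.gene_id == "geneA")
    causal = next(r for r in records if r.pos == truth["panel"]["causal_pos"])
    cons = annotate_codon_change(gene_a, cds, causal.pos, causal.alt)
    counts["causal_pos"] = causal.pos
    counts["causal_of_interest"] = bool(causal.of_interest)
    counts["causal_consequence"] = cons.notation
    (out / "filter_summary.json").write_text(json.dumps(counts, indent=2) + "\n")
    return ["variants_filtered.tsv", "filter_summary.json"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "morpho": stage_morpho,
    "gwas": stage_gwas,
    "sweep": stage_sweep,
    "interval": stage_interval,
    "filter": stage_filter,
}

_STAGE_INPUTS = {
    "simulate": [],
    "morpho": ["landmarks.csv", "morpho.yaml"],
    "gwas": ["genotypes.ped", "genotypes.map", "phenotypes.tsv"],
    "sweep": ["genotypes.ped", "genotypes.map", "phenotypes.tsv"],
    "interval": ["genotypes.ped", "gwas.tsv", "panel.vcf", "truth.json"],
    "filter": ["panel.vcf", "genes.gff3", "conservation.bedgraph",
               "panel_phenotypes.tsv", "intervals.bed", "truth.json"],
}


def run_pipeline(cfg: dict, outdir: str | Path,
                 stages: list[str] | None = None,
                 resume: bool = False) -> RunManifest:
    """Execute the requested stages in order, writing into ``outdir``.

    Each stage reads the previous stages' declared file outputs.  With
    ``resume`` a stage whose outputs already exist is skipped.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]
    manifest = RunManifest(config_hash=_hash(cfg), seed=int(cfg["seed"]),
                           version=__version__)
    for name in stages:
        missing = [f for f in _STAGE_INPUTS[name] if not (out / f).exists()]
        if missing:
            raise PipelineError(
                f"stage {name!r}: missing upstream outputs {missing}"
            )
        t0 = time.time()
        prior = manifest_outputs(out, name)
        if resume and prior:
            log.info("stage %s: outputs present, skipping", name)
            manifest.stages.append({"stage": name, "skipped": True,
                                    "outputs": prior})
            continue
        outputs = _STAGE_FUNCS[name](cfg, out)
        log.info("stage %s finished in %.1fs", name, time.time() - t0)
        manifest.stages.append({
            "stage": name,
            "inputs": _STAGE_INPUTS[name],
            "outputs": outputs,
            "elapsed_s": round(time.time() - t0, 2),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })
    manifest.save(out / "manifest.json")
    return manifest


def manifest_outputs(out: Path, stage: str) -> list[str] | None:
    """Outputs recorded for ``stage`` in an existing manifest, if complete."""
    mpath = out / "manifest.json"
    if not mpath.exists():
        return None
    data = json.loads(mpath.read_text())
    for entry in data.get("stages", []):
        if entry["stage"] == stage:
            outs = entry.get("outputs", [])
            if outs and all((out / f).exists() for f in outs):
                return outs
    return None
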