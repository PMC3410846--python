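"""File formats: landmark CSV, PLINK PED/MAP, VCF, GFF3, BED, BedGraph, TSV.

Coordinates are 1-based inclusive internally (PLINK/VCF/GFF3 convention);
BED/BedGraph exports convert to 0-based half-open.  VCF is read through
pysam; the writer emits plain uncompressed VCF with a GQ FORMAT field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import MISSING, GenotypeMatrix
from .haplotypes import Interval
from .morphometrics import LandmarkConfig
from .variants import GeneModel, VariantRecord


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ["specimen_id", "breed", "sex", "view", "landmark_id",
                    "x", "y", "z"]


def write_landmarks_csv(configs: list[LandmarkConfig], path: str | Path) -> None:
    rows = []
    for c in configs:
        for lid in c.ids:
            x, y, z = c.landmarks[lid]
            rows.append((c.specimen_id, c.breed, c.sex, c.view, lid, x, y, z))
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> list[LandmarkConfig]:
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV lacks columns {sorted(missing)}")
    configs = []
    for (sid, view), sub in df.groupby(["specimen_id", "view"], sort=False):
        configs.append(LandmarkConfig(
            specimen_id=str(sid),
            breed=str(sub["breed"].iloc[0]),
            sex=str(sub["sex"].iloc[0]),
            view=str(view),
            landmarks={int(r.landmark_id): np.array([r.x, r.y, r.z])
                       for r in sub.itertuples()},
        ))
    return configs


def read_morpho_config(path: str | Path) -> dict:
    """YAML with left/right/midline pairing and the neurocranium subset.

    Expected keys: ``pairs`` (list of [left, right]), ``midline`` (list of
    ids), ``neurocranium`` (list of ids), optional ``shared`` (merge ids).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    pairing: dict[int, int] = {}
    for left, right in raw.get("pairs", []):
        pairing[int(left)] = int(right)
        pairing[int(right)] = int(left)
    for mid in raw.get("midline", []):
        pairing[int(mid)] = int(mid)
    return {
        "pairing": pairing,
        "neurocranium": set(int(i) for i in raw.get("neurocranium", [])),
        "shared": set(int(i) for i in raw.get("shared", [1, 2, 28, 29])),
    }


def write_morpho_config(pairing: dict[int, int], neurocranium: set[int],
                        shared: set[int], path: str | Path) -> None:
    pairs = sorted({tuple(sorted((a, b))) for a, b in pairing.items() if a != b})
    data = {
        "pairs": [[int(a), int(b)] for a, b in pairs],
        "midline": sorted(int(a) for a, b in pairing.items() if a == b),
        "neurocranium": sorted(int(i) for i in neurocranium),
        "shared": sorted(int(i) for i in shared),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """PED/MAP pair.  Allele a1 counts the dosage; missing is '0 0'."""
    prefix = str(prefix)
    mp = G.markers
    with open(prefix + ".map", "w") as fh:
        for r in mp.itertuples():
            name = f"{r.chrom}_{r.pos}"
            fh.write(f"{r.chrom}\t{name}\t0\t{r.pos}\n")
    a1 = mp["a1"].to_numpy()
    a2 = mp["a2"].to_numpy()
    sex_code = {"M": "1", "F": "2"}
    with open(prefix + ".ped", "w") as fh:
        for i, ind in G.individuals.iterrows():
            fields = [str(ind["breed"]), str(ind["iid"]), "0", "0",
                      sex_code.get(ind["sex"], "0"), "-9"]
            row = G.calls[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a2[j], a2[j]]
                elif g == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = str(prefix)
    mp = pd.read_csv(prefix + ".map", sep="\t", header=None,
                     names=["chrom", "name", "cm", "pos"])
    rows, meta = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            fid, iid, _, _, sex, _ = parts[:6]
            alleles = parts[6:]
            meta.append({"iid": iid, "breed": fid,
                         "sex": {"1": "M", "2": "F"}.get(sex, "U")})
            rows.append(alleles)
    m = len(mp)
    calls = np.full((len(rows), m), MISSING, dtype=np.int8)
    # determine a1 per marker as in write_plink: first allele listed in
    # heterozygotes, else alphabetical minor choice from observed alleles
    allele_arr = np.array(rows).reshape(len(rows), m, 2)
    a1_list, a2_list = [], []
    for j in range(m):
        col = allele_arr[:, j, :]
        obs = col[col[:, 0] != "0"]
        uniq = sorted(set(obs.ravel()))
        if not uniq:
            a1_list.append("A"), a2_list.append("G")
            continue
        het = obs[obs[:, 0] != obs[:, 1]]
        if len(het):
            a1, a2 = het[0][0], het[0][1]
        elif len(uniq) == 2:
            a1, a2 = uniq[0], uniq[1]
        else:
            a1, a2 = uniq[0], uniq[0]
        a1_list.append(a1), a2_list.append(a2)
        count = (col == a1).sum(axis=1)
        called = col[:, 0] != "0"
        calls[called, j] = count[called]
    mp = mp[["chrom", "pos"]].copy()
    mp["a1"], mp["a2"] = a1_list, a2_list
    return GenotypeMatrix(calls, pd.DataFrame(meta), mp)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(records: list[VariantRecord], sample_names: list[str],
              path: str | Path) -> None:
    """Plain uncompressed VCF 4.2 with GT:GQ per sample."""
    contigs = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cranioscan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write('##INFO=<ID=CONS,Number=1,Type=Float,'
                 'Description="Conservation score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = f"CONS={r.conservation:.4f}" if r.conservation is not None else "."
            cells = [f"{_GT_STR[int(g)]}:{int(q)}"
                     for g, q in zip(r.genotypes, r.qualities)]
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                     f"{info}\tGT:GQ\t" + "\t".join(cells) + "\n")


def read_vcf_records(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read bi-allelic SNVs with GT and GQ via pysam."""
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            geno = np.full(len(samples), MISSING, dtype=np.int8)
            gq = np.zeros(len(samples))
            for i, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call.get("GT")
                if alleles is not None and None not in alleles:
                    geno[i] = sum(alleles)
                q = call.get("GQ")
                gq[i] = q if q is not None else 99
            cons = rec.info.get("CONS")
            records.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                genotypes=geno, qualities=gq,
                conservation=float(cons) if cons is not None else None,
            ))
    return records, samples


def read_vcf_genotypes(path: str | Path,
                       breed_of: dict[str, str] | None = None,
                       ) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (alt-dosage coding)."""
    records, samples = read_vcf_records(path)
    calls = np.stack([r.genotypes for r in records], axis=1)
    markers = pd.DataFrame({
        "chrom": [r.chrom for r in records],
        "pos": [r.pos for r in records],
        "a1": [r.alt for r in records],
        "a2": [r.ref for r in records],
    })
    breed_of = breed_of or {}
    individuals = pd.DataFrame({
        "iid": samples,
        "breed": [breed_of.get(s, s) for s in samples],
        "sex": ["U"] * len(samples),
    })
    return GenotypeMatrix(calls, individuals, markers)


# ---------------------------------------------------------------------------
# GFF3 / BED / BedGraph
# ---------------------------------------------------------------------------


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            gstart = min(a for a, _ in gm.exons)
            gend = max(b for _, b in gm.exons)
            fh.write(f"{gm.chrom}\tcranioscan\tgene\t{gstart}\t{gend}\t.\t"
                     f"{gm.strand}\t.\tID={gm.gene_id}\n")
            for k, (a, b) in enumerate(gm.exons, 1):
                fh.write(f"{gm.chrom}\tcranioscan\texon\t{a}\t{b}\t.\t"
                         f"{gm.strand}\t.\tID={gm.gene_id}.e{k};"
                         f"Parent={gm.gene_id}\n")
            if gm.cds_start is not None:
                for k, (a, b) in enumerate(gm.cds_exons(), 1):
                    fh.write(f"{gm.chrom}\tcranioscan\tCDS\t{a}\t{b}\t.\t"
                             f"{gm.strand}\t0\tID={gm.gene_id}.c{k};"
                             f"Parent={gm.gene_id}\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = \
                line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[fields["ID"]] = {"chrom": chrom, "strand": strand,
                                       "exons": [], "cds": []}
            elif ftype in ("exon", "CDS"):
                parent = fields.get("Parent", fields.get("ID", "?")).split(".")[0]
                rec = genes.setdefault(parent, {"chrom": chrom, "strand": strand,
                                                "exons": [], "cds": []})
                key = "exons" if ftype == "exon" else "cds"
                rec[key].append((int(start), int(end)))
    out = []
    for gid, rec in genes.items():
        cds = sorted(rec["cds"])
        out.append(GeneModel(
            gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
            exons=sorted(rec["exons"]) or cds,
            cds_start=cds[0][0] if cds else None,
            cds_end=cds[-1][1] if cds else None,
        ))
    return out


def write_bed(intervals: list[Interval], path: str | Path) -> None:
    """Intervals as BED (0-based half-open; converted from 1-based inclusive)."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv.to_bed()
            fh.write(f"{chrom}\t{start}\t{end}\t{iv.provenance}\n")


def read_bed_intervals(path: str | Path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            name = parts[3] if len(parts) > 3 else ""
            out.append(Interval(parts[0], int(parts[1]) + 1, int(parts[2]),
                                provenance=name))
    return out


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    """BedGraph rows (chrom, start, end, score), 0-based half-open."""
    track[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.4f")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "score"],
                       comment="#")


def attach_conservation(records: list[VariantRecord],
                        track: pd.DataFrame) -> list[VariantRecord]:
    """Set per-record conservation from a BedGraph track (0-based half-open)."""
    scores: dict[tuple[str, int], float] = {}
    for row in track.itertuples():
        for pos in range(int(row.start) + 1, int(row.end) + 1):
            scores[(row.chrom, pos)] = float(row.score)
    for rec in records:
        rec.conservation = scores.get((rec.chrom, rec.pos), rec.conservation)
    return records
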