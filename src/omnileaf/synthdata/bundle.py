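"""Write simulated cohorts to standard formats and read them back.

Formats: VCF 4.2 (GT only), GFF3 (gene/mRNA/exon/CDS/UTR features),
phenotype CSV, counts TSV, GMT gene sets, ground-truth JSON. The manifest
lists every written file with a sha256 checksum plus the seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from omnileaf.synthdata.config import SimConfig, GroundTruth
from omnileaf.synthdata.simulate import ExpressionData, GenotypeData

__all__ = ["write_bundle", "read_vcf", "read_gmt", "write_gmt"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(path: Path, geno: GenotypeData) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in geno.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.genotype_ids) + "\n"
        )
        dosages = geno.dosages
        for j, row in enumerate(geno.snps.itertuples(index=False)):
            calls = "\t".join(_GT[int(d)] for d in dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\tsnp{j + 1}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def _write_gff3(path: Path, geno: GenotypeData) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in geno.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in geno.genes:
            gid = g.gene_id
            fh.write(
                f"{g.chrom}\tomnileaf\tgene\t{g.start}\t{g.end}\t.\t{g.strand}"
                f"\t.\tID={gid}\n"
            )
            mrna = f"{gid}.1"
            fh.write(
                f"{g.chrom}\tomnileaf\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}"
                f"\t.\tID={mrna};Parent={gid}\n"
            )
            n = 0
            for ftype in ("five_prime_UTR", "CDS", "three_prime_UTR"):
                for s, e in sorted(g.features.get(ftype, [])):
                    n += 1
                    fh.write(
                        f"{g.chrom}\tomnileaf\t{ftype}\t{s}\t{e}\t.\t{g.strand}"
                        f"\t.\tID={mrna}.{ftype}.{n};Parent={mrna}\n"
                    )
            # exon features mirror the exonic blocks (UTRs + CDS merged per block)
            exonic = sorted(
                g.features.get("five_prime_UTR", [])
                + g.features.get("CDS", [])
                + g.features.get("three_prime_UTR", [])
            )
            merged: list[list[int]] = []
            for s, e in exonic:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for i, (s, e) in enumerate(merged, start=1):
                fh.write(
                    f"{g.chrom}\tomnileaf\texon\t{s}\t{e}\t.\t{g.strand}"
                    f"\t.\tID={mrna}.exon.{i};Parent={mrna}\n"
                )


def write_gmt(path: Path, gene_sets: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_bundle(
    out_dir: str | Path,
    cfg: SimConfig,
    geno: GenotypeData,
    pheno: pd.DataFrame,
    expr: ExpressionData | None = None,
    truth: GroundTruth | None = None,
) -> dict:
    """Write every simulated artefact; returns the manifest dict."""

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise IOError(f"cannot create output directory {out}: {err}") from err

    files = {}
    vcf = out / "genotypes.vcf"
    _write_vcf(vcf, geno)
    files["vcf"] = vcf
    gff = out / "genes.gff3"
    _write_gff3(gff, geno)
    files["gff3"] = gff
    pcsv = out / "phenotypes.csv"
    pheno.to_csv(pcsv, index=False)
    files["phenotypes"] = pcsv
    gmt = out / "gene_sets.gmt"
    write_gmt(gmt, geno.gene_sets)
    files["gene_sets"] = gmt
    if expr is not None:
        ctsv = out / "counts.tsv"
        expr.counts.to_csv(ctsv, sep="\t")
        files["counts"] = ctsv
        scsv = out / "samples.csv"
        expr.sample_map.rename_axis("sample").reset_index().to_csv(
            scsv, index=False
        )
        files["samples"] = scsv
    if truth is not None:
        tjson = out / "ground_truth.json"
        with open(tjson, "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
        files["ground_truth"] = tjson

    manifest = {
        "seed": cfg.seed,
        "files": {
            key: {"path": str(p), "sha256": _sha256(p)} for key, p in files.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_vcf(path: str | Path):
    """Read GT dosages from a VCF; returns (dosages, snp table, sample ids).

    Missing genotypes become -1.
    """

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    for var in vcf:
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else "."))
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(gt == 3, 2, np.where(gt == 2, -1, gt))
        dosage_rows.append(d)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (
        np.vstack(dosage_rows).T if dosage_rows else np.empty((len(samples), 0))
    )
    return dosages.astype(np.int8), snps, samples
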