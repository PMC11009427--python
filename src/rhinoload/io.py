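"""Readers and writers for the on-disk formats.

Disk dialects: VCF positions are 1-based, annotation TSV positions are
1-based (converted to the package's 0-based internal coordinates on read),
ROH BED intervals are 0-based half-open.  The VCF writer emits a minimal
deterministic VCF 4.2 with GT:GQ and the ancestral allele in INFO/AA, so a
synthetic cohort round-trips byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .load import MISSING, GenotypeMatrix
from .roh import ROHSegment

logger = logging.getLogger(__name__)

ANNOT_COLUMNS = ["scaffold", "pos", "ref", "alt", "ancestral", "rs", "impact"]


def write_annotation_tsv(table: pd.DataFrame, path) -> None:
    """Per-site annotation with 1-based positions on disk."""
    out = pd.DataFrame(
        {
            "scaffold": table["scaffold"],
            "pos": table["pos"] + 1,
            "ref": table["ref"],
            "alt": table["alt"],
            "ancestral": table.get("ancestral_state", "ref"),
            "rs": table["rs"].map(lambda x: f"{x:.6g}" if pd.notna(x) else "."),
            "impact": table["impact"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"scaffold": str}, na_values=["."])
    table = pd.DataFrame(
        {
            "scaffold": raw["scaffold"],
            "pos": raw["pos"].astype(np.int64) - 1,
            "ref": raw["ref"],
            "alt": raw["alt"],
            "ancestral_state": raw.get("ancestral", "ref"),
            "rs": pd.to_numeric(raw["rs"], errors="coerce"),
            "impact": raw["impact"].fillna("NONE"),
        }
    )
    return table


def write_scaffolds_tsv(scaffolds: pd.DataFrame, path) -> None:
    scaffolds[["scaffold", "length"]].to_csv(path, sep="\t", index=False)


def read_scaffolds_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"scaffold": str, "length": np.int64})


def write_vcf(gm: GenotypeMatrix, table: pd.DataFrame, scaffolds: pd.DataFrame, path) -> None:
    """Minimal deterministic VCF 4.2 (GT:GQ, INFO/AA) for a cohort."""
    anc_state = table.get("ancestral_state", pd.Series(["ref"] * len(table))).to_numpy()
    ref = table["ref"].to_numpy(dtype=object)
    alt = table["alt"].to_numpy(dtype=object)
    aa = np.where(anc_state == "alt", alt, np.where(anc_state == "ref", ref, "."))
    # dosages count the derived allele; convert to ALT-allele counts for GT
    alt_count = np.where(
        anc_state[None, :] == "alt", 2 - gm.dosages, gm.dosages
    )
    alt_count = np.where(gm.dosages == MISSING, MISSING, alt_count)
    gt_str = np.array(["./.", "0/0", "0/1", "1/1"], dtype=object)[alt_count + 1]

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for _, row in scaffolds.iterrows():
            fh.write(f"##contig=<ID={row['scaffold']},length={row['length']}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        pos = table["pos"].to_numpy() + 1
        scaf = table["scaffold"].to_numpy(dtype=object)
        gq = gm.gq if gm.gq is not None else np.full(gm.dosages.shape, 99, dtype=int)
        for j in range(len(table)):
            cells = [
                f"{gt_str[i, j]}:{int(gq[i, j])}" for i in range(gm.n_individuals)
            ]
            fh.write(
                f"{scaf[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t"
                f"AA={aa[j]}\tGT:GQ\t" + "\t".join(cells) + "\n"
            )


def read_genotypes(
    vcf_path, annot_path, scaffolds_path=None
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame | None]:
    """Load a cohort: VCF genotypes + annotation table (+ scaffold lengths).

    Multi-allelic records are skipped with a logged count.  Sites in the
    VCF must match the annotation row-for-row after the skip; the first ten
    offenders are reported otherwise.  Dosages are oriented to the derived
    allele using the annotation's ancestral column, and population tags are
    taken from the sample-name prefix before the first underscore.
    """
    table = read_annotation_tsv(annot_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    sites, dosage_rows, gq_rows = [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        sites.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        dosage_rows.append(rec.gt_types.copy())
        try:
            gq_rows.append(rec.format("GQ")[:, 0].copy())
        except (KeyError, TypeError):
            gq_rows.append(np.full(len(samples), 99))
    if n_skipped:
        logger.info("skipped %d multi-allelic records", n_skipped)

    got = pd.DataFrame(sites, columns=["scaffold", "pos", "ref", "alt"])
    if len(got) != len(table) or not (
        got[["scaffold", "pos"]].to_numpy() == table[["scaffold", "pos"]].to_numpy()
    ).all():
        merged = got.merge(table, on=["scaffold", "pos"], how="outer", indicator=True)
        offenders = merged[merged["_merge"] != "both"].head(10)
        raise ValueError(
            "VCF and annotation site lists differ; first offenders:\n"
            + offenders.to_string()
        )

    alt_count = np.array(dosage_rows, dtype=np.int8).T  # gts012: 0/1/2, 3=missing
    alt_count = np.where(alt_count == 3, MISSING, alt_count)
    anc = table["ancestral_state"].to_numpy()
    dosages = np.where(
        (anc[None, :] == "alt") & (alt_count != MISSING), 2 - alt_count, alt_count
    ).astype(np.int8)
    gq = np.array(gq_rows).T
    gm = GenotypeMatrix(
        samples=samples,
        populations=[s.split("_")[0] for s in samples],
        dosages=dosages,
        gq=gq,
    )
    scaffolds = read_scaffolds_tsv(scaffolds_path) if scaffolds_path else None
    return gm, table, scaffolds


def write_roh_bed(segments_by_individual: dict[str, list[ROHSegment]], path) -> None:
    """ROH calls as BED with name, quality and marker-count columns."""
    with open(path, "w") as fh:
        for ind in sorted(segments_by_individual):
            for seg in segments_by_individual[ind]:
                fh.write(
                    f"{seg.scaffold}\t{seg.start}\t{seg.end}\t{ind}\t"
                    f"{seg.quality:.1f}\t{seg.n_sites}\n"
                )


def write_config_echo(config: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")


def crossing_report(medians: pd.DataFrame) -> pd.DataFrame:
    """First generation at which median fitness falls strictly below the
    benchmark median, per growth scenario (NaN when it never does)."""
    if "benchmark_median_fitness" not in medians.columns:
        raise ValueError("medians table lacks a benchmark reference column")
    rows = []
    for growth, grp in medians.groupby("growth"):
        grp = grp.sort_values("generation")
        below = grp["median_fitness"] < grp["benchmark_median_fitness"]
        gen = grp.loc[below, "generation"].iloc[0] if below.any() else np.nan
        rows.append({"growth": growth, "crossing_generation": gen})
    return pd.DataFrame(rows)
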