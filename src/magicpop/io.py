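"""Tab-delimited (and optional VCF) readers/writers for the pipeline's tables.

Formats: genotype matrix (lines x markers, calls 0/1/2/NA), genetic map
(marker, chrom, cM), phenotype (line_id, phenotype), pedigree (line_id,
family_id, generation, parent_id) and cross-plan tables (structured columns,
so cross ids never need parsing).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    CrossPlan,
    EightWayCross,
    FourWayCross,
    Pedigree,
    TwoWayCross,
)
from .simulate import MISSING, GeneticMap, GenotypeMatrix

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_map", "read_map",
    "write_phenotype", "read_phenotype",
    "write_pedigree", "read_pedigree",
    "write_plan", "read_plan",
    "write_vcf",
]


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.calls, index=genotypes.lines, columns=genotypes.markers)
    df = df.replace(int(MISSING), pd.NA)
    df.to_csv(path, sep="\t", index_label="line_id", na_rep="NA")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line_id", na_values=["NA"])
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(calls=calls, lines=df.index.tolist(), markers=df.columns.to_numpy())


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_phenotype(phenotype: pd.Series, path) -> None:
    phenotype.rename("phenotype").to_csv(path, sep="\t", index_label="line_id", na_rep="NA")


def read_phenotype(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="line_id", na_values=["NA"])
    return df["phenotype"].astype(float)


def write_pedigree(pedigree: Pedigree, path) -> None:
    df = pedigree.records.copy()
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# ssd_generations={pedigree.ssd_generations}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    with open(path) as fh:
        first = fh.readline()
        ssd = int(first.strip().split("=")[1]) if first.startswith("#") else None
        df = pd.read_csv(fh if first.startswith("#") else path, sep="\t")
    if ssd is None:
        gens = df["generation"].str.lstrip("F").astype(int)
        ssd = int(gens.max()) - 1
    return Pedigree(records=df, ssd_generations=ssd)


def write_plan(plan: CrossPlan, prefix) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        [(tw.id, tw.parents[0], tw.parents[1]) for tw in plan.twoways],
        columns=["id", "parent1", "parent2"],
    ).to_csv(f"{prefix}.twoways.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(fw.id, fw.f1_pair[0].id, fw.f1_pair[1].id) for fw in plan.fourways],
        columns=["id", "twoway1", "twoway2"],
    ).to_csv(f"{prefix}.fourways.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(ew.id, ew.fourway_pair[0].id, ew.fourway_pair[1].id) for ew in plan.eightways],
        columns=["id", "fourway1", "fourway2"],
    ).to_csv(f"{prefix}.eightways.tsv", sep="\t", index=False)


def read_plan(prefix) -> CrossPlan:
    prefix = Path(prefix)
    tw_df = pd.read_csv(f"{prefix}.twoways.tsv", sep="\t")
    fw_df = pd.read_csv(f"{prefix}.fourways.tsv", sep="\t")
    ew_df = pd.read_csv(f"{prefix}.eightways.tsv", sep="\t")
    twoways = {r["id"]: TwoWayCross((r["parent1"], r["parent2"])) for _, r in tw_df.iterrows()}
    fourways = {
        r["id"]: FourWayCross((twoways[r["twoway1"]], twoways[r["twoway2"]]))
        for _, r in fw_df.iterrows()
    }
    eightways = [
        EightWayCross((fourways[r["fourway1"]], fourways[r["fourway2"]]))
        for _, r in ew_df.iterrows()
    ]
    founders = sorted({p for tw in twoways.values() for p in tw.parents})
    return CrossPlan(
        founders=founders,
        twoways=sorted(twoways.values()),
        fourways=sorted(fourways.values()),
        eightways=sorted(eightways),
    )


CM_TO_BP = 10_000  # synthetic coordinate scale: VCF POS = round(cM * 1e4) + 1


def write_vcf(genotypes: GenotypeMatrix, gmap: GeneticMap, path) -> None:
    """Export as VCF v4.2 (uncompressed, GT field; markers as records, lines
    as samples).  cM positions are scaled to integer coordinates since VCF
    requires base-pair POS; alleles are written as placeholder A/T."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, sl in gmap.chrom_slices():
        length = int(round(gmap.pos[sl].max() * CM_TO_BP)) + 2
        header.contigs.add(chrom, length=length)
    for line in genotypes.lines:
        header.add_sample(str(line))
    lookup = {m: i for i, m in enumerate(genotypes.markers)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, sl in gmap.chrom_slices():
            for k in range(sl.start, sl.stop):
                marker = gmap.markers[k]
                if marker not in lookup:
                    continue
                rec = vcf.new_record(
                    contig=chrom,
                    start=int(round(gmap.pos[k] * CM_TO_BP)),
                    alleles=("A", "T"),
                    id=str(marker),
                )
                calls = genotypes.calls[:, lookup[marker]]
                for s, c in zip(rec.samples.values(), calls):
                    if c == MISSING:
                        s["GT"] = (None, None)
                    else:
                        s["GT"] = ((0, 0), (0, 1), (1, 1))[int(c)]
                vcf.write(rec)
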