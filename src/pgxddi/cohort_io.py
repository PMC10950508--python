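"""Cohort genotypes: VCF -> dosage matrix, and allele-frequency tables.

Genotypes are stored as a samples x variants matrix of alternate-allele
dosages {0, 1, 2} with ``MISSING`` (-1) for uncalled genotypes. Only
biallelic SNVs are loaded; multiallelic records, indels and mitochondrial
sites are skipped with logged counts (population genetic reference panels
rarely cover mtDNA consistently). Phase is ignored throughout: every
downstream statistic uses dosage only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import CatalogError, DiplotypeCall

log = logging.getLogger("pgxddi.cohort_io")

MISSING: int = -1
_BASES = {"A", "C", "G", "T"}
_MT_NAMES = {"MT", "M", "chrM", "chrMT"}


@dataclass(frozen=True)
class VariantKey:
    """A biallelic SNV on the reference genome (1-based coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")

    @property
    def allele_id(self) -> str:
        """rsID when available, else chrom:pos:ref:alt."""
        return self.rsid or f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CohortGenotypes:
    """Diploid alt-allele dosages for one labelled population."""

    population: str
    samples: list[str]
    variants: list[VariantKey]
    dosage: np.ndarray  # int8, shape (n_samples, n_variants), MISSING = -1

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict[str, int]:
        """allele_id -> column index (rsid preferred, positional key always present)."""
        idx: dict[str, int] = {}
        for j, v in enumerate(self.variants):
            idx[f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"] = j
            if v.rsid:
                idx[v.rsid] = j
        return idx

    def subset_samples(self, sample_ids: Sequence[str], population: str | None = None
                       ) -> "CohortGenotypes":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in cohort: {missing[:5]}")
        rows = [pos[s] for s in sample_ids]
        return CohortGenotypes(
            population=population or self.population,
            samples=list(sample_ids),
            variants=list(self.variants),
            dosage=self.dosage[rows, :].copy(),
        )


def read_vcf(
    path: str | Path,
    variant_subset: Iterable[str] | None = None,
    population: str = "cohort",
) -> CohortGenotypes:
    """Load biallelic SNVs from a VCF 4.x file into a dosage matrix.

    ``variant_subset`` optionally restricts loading to a set of rsIDs or
    ``chrom:pos:ref:alt`` keys; requested variants that never appear are
    summarised in the log, not raised. Multiallelic records, indels and
    mtDNA sites are skipped (counted in the log). Missing genotypes (./.)
    become the ``MISSING`` sentinel.
    """
    from cyvcf2 import VCF

    wanted = set(variant_subset) if variant_subset is not None else None
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    n_skip_multi = n_skip_indel = n_skip_mt = 0
    found: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skip_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            n_skip_indel += 1
            continue
        if rec.CHROM in _MT_NAMES:
            n_skip_mt += 1
            continue
        rsid = rec.ID if rec.ID not in (None, ".", "") else None
        key = VariantKey(chrom=rec.CHROM, pos=rec.POS, ref=ref, alt=alt, rsid=rsid)
        if wanted is not None:
            ids = {key.allele_id, f"{key.chrom}:{key.pos}:{key.ref}:{key.alt}"}
            if rsid:
                ids.add(rsid)
            hit = ids & wanted
            if not hit:
                continue
            found |= hit
        # with gts012=True: 0/1/2 = alt dosage, 3 = unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        variants.append(key)
        columns.append(g)
    if n_skip_multi:
        log.info("read_vcf: skipped %d multiallelic record(s)", n_skip_multi)
    if n_skip_indel:
        log.info("read_vcf: skipped %d non-SNV record(s)", n_skip_indel)
    if n_skip_mt:
        log.info("read_vcf: excluded %d mitochondrial record(s)", n_skip_mt)
    if wanted is not None and wanted - found:
        log.info("read_vcf: %d requested variant(s) absent from %s",
                 len(wanted - found), path)
    dosage = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return CohortGenotypes(
        population=population, samples=samples, variants=variants, dosage=dosage
    )


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read sample_id -> population TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        raise CatalogError(f"{path}: expected columns sample_id, population")
    return dict(zip(df["sample_id"], df["population"]))


def split_by_population(
    cohort: CohortGenotypes, popmap: Mapping[str, str]
) -> dict[str, CohortGenotypes]:
    """Partition one loaded cohort into per-population cohorts."""
    pops: dict[str, list[str]] = {}
    for s in cohort.samples:
        try:
            pops.setdefault(popmap[s], []).append(s)
        except KeyError:
            raise CatalogError(f"sample {s!r} missing from population map") from None
    return {p: cohort.subset_samples(ids, population=p) for p, ids in sorted(pops.items())}


def allele_frequencies(cohort: CohortGenotypes) -> pd.DataFrame:
    """Per-variant alternate-allele frequencies, excluding missing genotypes.

    Returns a frame with columns allele_id, population, alt_count,
    total_count, af. A variant with every genotype missing gets
    total_count 0 and af NaN (flagged in the log).
    """
    d = cohort.dosage
    observed = d != MISSING
    alt = np.where(observed, d, 0).sum(axis=0)
    total = 2 * observed.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    n_undef = int((total == 0).sum())
    if n_undef:
        log.info("allele_frequencies: %d variant(s) with all genotypes missing", n_undef)
    return pd.DataFrame({
        "allele_id": [v.allele_id for v in cohort.variants],
        "population": cohort.population,
        "alt_count": alt.astype(int),
        "total_count": total.astype(int),
        "af": af,
    })


def diplotype_frequencies(
    calls: Sequence[DiplotypeCall],
    allele_universe: Mapping[str, Iterable[str]] | None = None,
    population: str = "cohort",
) -> pd.DataFrame:
    """Named-allele frequencies from diplotype calls (2 observations/sample/gene).

    ``allele_universe`` optionally maps gene -> alleles that must appear in
    the output even at frequency zero. Raises if any sample carries more
    than one call for a gene.
    """
    per_gene: dict[str, list[DiplotypeCall]] = {}
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.sample_id, c.gene)
        if key in seen:
            raise CatalogError(f"sample {c.sample_id!r} has multiple calls for {c.gene!r}")
        seen.add(key)
        per_gene.setdefault(c.gene, []).append(c)
    rows = []
    genes = set(per_gene)
    if allele_universe:
        genes |= set(allele_universe)
    for gene in sorted(genes):
        gene_calls = per_gene.get(gene, [])
        total = 2 * len(gene_calls)
        counts: dict[str, int] = {}
        for c in gene_calls:
            counts[c.allele1] = counts.get(c.allele1, 0) + 1
            counts[c.allele2] = counts.get(c.allele2, 0) + 1
        alleles = set(counts)
        if allele_universe and gene in allele_universe:
            alleles |= set(allele_universe[gene])
        for allele in sorted(alleles):
            n = counts.get(allele, 0)
            rows.append({
                "allele_id": allele,
                "population": population,
                "alt_count": n,
                "total_count": total,
                "af": n / total if total else float("nan"),
            })
    return pd.DataFrame(rows, columns=["allele_id", "population", "alt_count",
                                       "total_count", "af"])


def write_vcf(
    cohorts: Sequence[CohortGenotypes], path: str | Path
) -> None:
    """Write cohorts sharing one variant list as a single plain-text VCF 4.2.

    Samples are concatenated in cohort order; genotypes are emitted unphased
    (0/0, 0/1, 1/1, ./.). Used to materialise synthetic cohorts in the
    standard interchange format.
    """
    first = cohorts[0]
    for c in cohorts[1:]:
        if c.variants != first.variants:
            raise ValueError("all cohorts must share one variant list")
    samples = [s for c in cohorts for s in c.samples]
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for v in first.variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        stacked = np.concatenate([c.dosage for c in cohorts], axis=0)
        for j, v in enumerate(first.variants):
            gts = "\t".join(gt_text[int(g)] for g in stacked[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def write_population_map(cohorts: Sequence[CohortGenotypes], path: str | Path) -> None:
    rows = [{"sample_id": s, "population": c.population} for c in cohorts for s in c.samples]
    pd.DataFrame(rows, columns=["sample_id", "population"]).to_csv(path, sep="\t", index=False)
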