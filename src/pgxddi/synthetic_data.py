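"""Synthetic input generation with known ground truth.

Real pharmacogenomic studies of this kind consume restricted cohort VCFs and
licensed curated drug databases. This module generates structurally
equivalent inputs whose true parameters are known, so every downstream
statistic can be validated against planted truth:

* multi-population genotypes under the Balding-Nichols model, whose expected
  Weir-Cockerham Fst approximately equals the divergence parameter F;
* drug -> CTET-gene catalogs with planted shared elements, so the set of
  truly interacting drug pairs is known exactly;
* clinical-annotation tables assigning risk alleles to existing cohort
  variants, with per-sample carrier counts recorded directly from the
  genotype matrix;
* deleteriousness-prediction tables and star/HLA diplotype tables with known
  allele frequencies.

All randomness flows from one integer seed through a named numpy generator;
no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import (
    CTET_ROLES,
    EVIDENCE_LEVELS,
    ClinicalAnnotation,
    DeleteriousnessAnnotation,
    DiplotypeCall,
    Drug,
    DrugGeneCatalog,
    write_clinical_annotations,
    write_ctet_catalog,
    write_deleteriousness,
    write_diplotypes,
    write_drug_list,
)
from .cohort_io import MISSING, CohortGenotypes, VariantKey, write_population_map, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth recorded while generating synthetic inputs."""

    seed: int
    divergence_F: float | None = None
    true_afs: pd.DataFrame | None = None  # allele_id, population, true_af
    true_ddi_pairs: set[frozenset[str]] | None = None
    planted_carrier_counts: pd.DataFrame | None = None  # samples x drugs
    diplotype_afs: dict[str, dict[str, float]] | None = None

    def to_json(self, path: str | Path) -> None:
        payload: dict = {"seed": self.seed}
        if self.divergence_F is not None:
            payload["divergence_F"] = self.divergence_F
        if self.true_afs is not None:
            payload["true_afs"] = self.true_afs.to_dict(orient="records")
        if self.true_ddi_pairs is not None:
            payload["true_ddi_pairs"] = sorted(sorted(p) for p in self.true_ddi_pairs)
        if self.planted_carrier_counts is not None:
            payload["planted_carrier_counts"] = {
                "samples": list(self.planted_carrier_counts.index),
                "drugs": list(self.planted_carrier_counts.columns),
                "counts": self.planted_carrier_counts.values.tolist(),
            }
        if self.diplotype_afs is not None:
            payload["diplotype_afs"] = self.diplotype_afs
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def simulate_populations(
    n_variants: int,
    pop_sizes: Mapping[str, int],
    F: float,
    seed: int,
    ancestral_af_law: tuple[float, float] = (0.05, 0.95),
) -> tuple[dict[str, CohortGenotypes], SimulationTruth]:
    """Simulate diploid genotypes for several populations under Balding-Nichols.

    Per variant, an ancestral frequency p is drawn uniformly on
    ``ancestral_af_law``; each population's frequency is drawn from a Beta
    with mean p and variance p(1-p)F (so F=0 collapses to identical
    frequencies); genotypes are Binomial(2, population frequency). Variants
    that come out with all population frequencies at the boundary are
    redrawn (and would otherwise be monomorphic everywhere).

    The expected Weir-Cockerham Fst between any two populations is
    approximately F, which is the recovery target used in validation.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError(f"divergence F must be in [0,1), got {F}")
    for pop, n in pop_sizes.items():
        if n < 2:
            raise ValueError(f"population {pop!r} needs >= 2 individuals")
    lo, hi = ancestral_af_law
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"ancestral AF law bounds must satisfy 0 < lo < hi < 1, got {ancestral_af_law}")
    rng = np.random.default_rng(seed)
    pops = list(pop_sizes)

    p_anc = rng.uniform(lo, hi, size=n_variants)
    if F == 0.0:
        pop_freq = {pop: p_anc.copy() for pop in pops}
    else:
        scale = (1.0 - F) / F
        pop_freq = {}
        for pop in pops:
            q = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
            # Beta draws can underflow to exactly 0/1 for extreme shapes;
            # redraw those to keep frequencies interior.
            for _ in range(100):
                bad = (q <= 0.0) | (q >= 1.0)
                if not bad.any():
                    break
                q[bad] = rng.beta(p_anc[bad] * scale, (1.0 - p_anc[bad]) * scale)
            pop_freq[pop] = q

    refs = rng.integers(0, 4, size=n_variants)
    alts = (refs + rng.integers(1, 4, size=n_variants)) % 4
    variants = [
        VariantKey(chrom="1", pos=1000 + 10 * i, ref=_BASES[refs[i]], alt=_BASES[alts[i]],
                   rsid=f"rs{1000000 + i}")
        for i in range(n_variants)
    ]

    cohorts: dict[str, CohortGenotypes] = {}
    for pop in pops:
        n = pop_sizes[pop]
        dosage = rng.binomial(2, pop_freq[pop], size=(n, n_variants)).astype(np.int8)
        cohorts[pop] = CohortGenotypes(
            population=pop,
            samples=[f"{pop}_{i:05d}" for i in range(n)],
            variants=variants,
            dosage=dosage,
        )

    truth_rows = [
        {"allele_id": variants[i].allele_id, "population": pop, "true_af": float(pop_freq[pop][i])}
        for pop in pops
        for i in range(n_variants)
    ]
    truth = SimulationTruth(
        seed=seed, divergence_F=F, true_afs=pd.DataFrame(truth_rows)
    )
    return cohorts, truth


def simulate_ctet_catalog(
    n_drugs: int,
    n_genes: int,
    role_density: float | Mapping[str, float],
    planted_pairs: Sequence[tuple[str, str]],
    seed: int,
    drug_names: Sequence[str] | None = None,
) -> tuple[DrugGeneCatalog, SimulationTruth]:
    """Random role-typed drug-gene catalog with planted shared elements.

    Background links: each (drug, role, gene) triple is included with the
    role's density. Each planted pair is then forced to share one dedicated
    element (a fresh gene, roles cycled), so the pair is guaranteed to be a
    true interaction. ``true_ddi_pairs`` is recomputed afterwards by
    brute-force (role, gene)-set intersection over the emitted catalog, so
    it also contains pairs that happen to share background elements.
    """
    if drug_names is None:
        drug_names = [f"drug{i + 1:02d}" for i in range(n_drugs)]
    elif len(drug_names) != n_drugs:
        raise ValueError("drug_names length must equal n_drugs")
    known = set(drug_names)
    for a, b in planted_pairs:
        if a not in known or b not in known:
            raise ValueError(f"planted pair ({a!r}, {b!r}) references unknown drug")
    if isinstance(role_density, Mapping):
        density = {r: float(role_density.get(r, 0.0)) for r in CTET_ROLES}
    else:
        density = {r: float(role_density) for r in CTET_ROLES}
    for r, p in density.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"density for role {r!r} must be in [0,1]")

    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    entries: set[tuple[str, str, str]] = set()
    for role in CTET_ROLES:
        mask = rng.random((len(drug_names), n_genes)) < density[role]
        for di, gi in zip(*np.nonzero(mask)):
            entries.add((drug_names[di], role, genes[gi]))
    for k, (a, b) in enumerate(planted_pairs):
        role = CTET_ROLES[k % len(CTET_ROLES)]
        gene = f"PLANT{k + 1:03d}"
        entries.add((a, role, gene))
        entries.add((b, role, gene))

    catalog = DrugGeneCatalog(entries=frozenset(entries))
    truth = SimulationTruth(
        seed=seed, true_ddi_pairs=true_ddi_pairs_from_catalog(catalog, list(drug_names))
    )
    return catalog, truth


def true_ddi_pairs_from_catalog(
    catalog: DrugGeneCatalog, drugs: Sequence[str]
) -> set[frozenset[str]]:
    """Brute-force reference: unordered pairs sharing >= 1 (role, gene) element."""
    elements = {d: catalog.elements_for(d) for d in drugs}
    pairs: set[frozenset[str]] = set()
    names = sorted(drugs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if elements[a] & elements[b]:
                pairs.add(frozenset((a, b)))
    return pairs


def simulate_annotations(
    drugs: Sequence[Drug],
    cohort: CohortGenotypes,
    per_drug_counts: Mapping[str, int],
    level_mix: Mapping[str, float],
    seed: int,
) -> tuple[list[ClinicalAnnotation], SimulationTruth]:
    """Assign SNP risk alleles to existing cohort variants, recording truth.

    Each drug receives ``per_drug_counts[drug]`` annotations drawn without
    replacement from the cohort's variants; the risk allele is the variant's
    alternate base. ``planted_carrier_counts`` is computed directly from the
    genotype matrix: a sample carries an annotation iff its alt dosage at
    that variant is >= 1 (missing genotypes do not count).
    """
    names = [d.name for d in drugs]
    for d, k in per_drug_counts.items():
        if d not in names:
            raise ValueError(f"per_drug_counts references unknown drug {d!r}")
        if k > cohort.n_variants:
            raise ValueError(
                f"drug {d!r} requests {k} annotations but only "
                f"{cohort.n_variants} variants are available"
            )
    levels = list(level_mix)
    probs = np.array([level_mix[l] for l in levels], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("level_mix must be a probability distribution over levels")
    for l in levels:
        if l not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence level {l!r} in level_mix")

    rng = np.random.default_rng(seed)
    annotations: list[ClinicalAnnotation] = []
    carrier = (cohort.dosage >= 1)  # MISSING (-1) is False
    counts = np.zeros((cohort.n_samples, len(names)), dtype=int)
    for di, name in enumerate(names):
        k = per_drug_counts.get(name, 0)
        if k == 0:
            continue
        cols = rng.choice(cohort.n_variants, size=k, replace=False)
        drawn_levels = rng.choice(levels, size=k, p=probs)
        for j, lev in zip(cols, drawn_levels):
            v = cohort.variants[j]
            annotations.append(
                ClinicalAnnotation(
                    allele_id=v.allele_id,
                    allele_type="snp",
                    gene=f"GENE{j % 97:04d}",
                    drug=name,
                    level=str(lev),
                    risk_allele=v.alt,
                )
            )
        counts[:, di] = carrier[:, cols].sum(axis=1)

    truth = SimulationTruth(
        seed=seed,
        planted_carrier_counts=pd.DataFrame(counts, index=list(cohort.samples), columns=names),
    )
    return annotations, truth


def simulate_deleteriousness(
    variant_ids: Sequence[str],
    genes: Sequence[str],
    seed: int,
    p_nonsynonymous: float = 0.5,
    p_damaging: float = 0.4,
    p_missing: float = 0.1,
) -> list[DeleteriousnessAnnotation]:
    """Random categorical predictor calls for a variant list.

    Each of the three predictors independently abstains with ``p_missing``,
    calls damaging with ``p_damaging`` and benign otherwise.
    """
    if len(genes) != len(variant_ids):
        raise ValueError("genes must align with variant_ids")
    rng = np.random.default_rng(seed)
    damaging_token = {
        "sift": "damaging",
        "polyphen": "probably_damaging",
        "mutation_taster": "disease_causing",
    }
    benign_token = {"sift": "tolerated", "polyphen": "benign", "mutation_taster": "polymorphism"}
    out = []
    for vid, gene in zip(variant_ids, genes):
        calls = {}
        for tool in damaging_token:
            u = rng.random()
            if u < p_missing:
                calls[tool] = "missing"
            elif u < p_missing + p_damaging:
                calls[tool] = damaging_token[tool]
            else:
                calls[tool] = benign_token[tool]
        out.append(
            DeleteriousnessAnnotation(
                variant_id=vid,
                gene=gene,
                functional_class=(
                    "nonsynonymous_exonic" if rng.random() < p_nonsynonymous else "other"
                ),
                sift=calls["sift"],
                polyphen=calls["polyphen"],
                mutation_taster=calls["mutation_taster"],
            )
        )
    return out


def simulate_diplotypes(
    sample_ids: Sequence[str],
    allele_freqs: Mapping[str, Mapping[str, float]],
    seed: int,
) -> tuple[list[DiplotypeCall], SimulationTruth]:
    """Draw two alleles per sample per gene from per-gene allele frequencies."""
    rng = np.random.default_rng(seed)
    calls: list[DiplotypeCall] = []
    for gene in sorted(allele_freqs):
        freqs = allele_freqs[gene]
        alleles = sorted(freqs)
        p = np.array([freqs[a] for a in alleles], dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"allele frequencies for {gene!r} must sum to 1")
        draws = rng.choice(alleles, size=(len(sample_ids), 2), p=p)
        for s, (a1, a2) in zip(sample_ids, draws):
            calls.append(DiplotypeCall(sample_id=s, gene=gene, allele1=str(a1), allele2=str(a2)))
    truth = SimulationTruth(
        seed=seed,
        diplotype_afs={g: dict(allele_freqs[g]) for g in allele_freqs},
    )
    return calls, truth


def write_simulated_inputs(
    outdir: str | Path,
    cohorts: Mapping[str, CohortGenotypes],
    drugs: Sequence[Drug],
    catalog: DrugGeneCatalog,
    annotations: Sequence[ClinicalAnnotation],
    deleterious: Sequence[DeleteriousnessAnnotation],
    diplotypes: Sequence[DiplotypeCall],
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Materialise a full simulated input bundle in the standard file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_list = [cohorts[p] for p in sorted(cohorts)]
    paths = {
        "vcf": outdir / "cohort.vcf",
        "popmap": outdir / "populations.tsv",
        "drugs": outdir / "drugs.tsv",
        "ctet": outdir / "ctet_catalog.tsv",
        "annotations": outdir / "clinical_annotations.tsv",
        "deleterious": outdir / "deleterious.tsv",
        "diplotypes": outdir / "diplotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(cohort_list, paths["vcf"])
    write_population_map(cohort_list, paths["popmap"])
    write_drug_list(drugs, paths["drugs"])
    write_ctet_catalog(catalog, paths["ctet"])
    write_clinical_annotations(annotations, paths["annotations"])
    write_deleteriousness(deleterious, paths["deleterious"])
    write_diplotypes(diplotypes, paths["diplotypes"])
    truth.to_json(paths["truth"])
    return paths
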