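"""Per-drug pharmacogenomic risk landscape over a genotyped cohort.

For every drug, counts how many of its clinically annotated risk
variants/alleles each individual carries (carrier-based: a variant counts
once whether one or two risk alleles are present), and summarises the
cohort distribution by median, range, quartiles and carrier fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import ClinicalAnnotation, DiplotypeCall, Drug
from .cohort_io import MISSING, CohortGenotypes

log = logging.getLogger("pgxddi.pgx_landscape")


@dataclass(frozen=True)
class DrugRiskSummary:
    """Cohort distribution of per-individual risk-variant counts for one drug."""

    drug: str
    n_annotations: int
    per_sample_counts: tuple[int, ...]
    median: float
    min: int
    max: int
    q1: float
    q3: float
    carrier_fraction: float


def _diplotype_lookup(diplotypes: Sequence[DiplotypeCall]) -> dict[tuple[str, str], tuple[str, str]]:
    return {(c.sample_id, c.gene): (c.allele1, c.allele2) for c in diplotypes}


def carrier_status(
    sample_id: str,
    annotation: ClinicalAnnotation,
    cohort: CohortGenotypes,
    diplotypes: Sequence[DiplotypeCall] = (),
) -> bool:
    """True iff the individual carries >= 1 copy of the annotation's risk allele.

    SNPs are resolved against the cohort dosage matrix (a missing genotype
    counts as non-carrier and is logged); star/HLA annotations against the
    diplotype calls for the annotation's gene. Raises KeyError when the
    annotation cannot be resolved at all.
    """
    if annotation.allele_type == "snp":
        j = cohort.variant_index().get(annotation.allele_id)
        if j is None:
            raise KeyError(f"variant {annotation.allele_id!r} not in cohort")
        try:
            i = cohort.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in cohort") from None
        return bool(_snp_carrier_column(cohort, j, annotation)[i])
    lookup = _diplotype_lookup(diplotypes)
    pair = lookup.get((sample_id, annotation.gene))
    if pair is None:
        raise KeyError(f"no diplotype call for ({sample_id!r}, {annotation.gene!r})")
    return annotation.risk_allele in pair


def _snp_carrier_column(
    cohort: CohortGenotypes, j: int, annotation: ClinicalAnnotation
) -> np.ndarray:
    """Boolean carrier vector for one SNP annotation (missing -> False)."""
    v = cohort.variants[j]
    d = cohort.dosage[:, j]
    observed = d != MISSING
    n_miss = int((~observed).sum())
    if n_miss:
        log.debug("carrier_status: %d missing genotype(s) at %s counted as non-carrier",
                  n_miss, annotation.allele_id)
    if annotation.risk_allele == v.alt:
        return observed & (d >= 1)
    if annotation.risk_allele == v.ref:
        return observed & (d <= 1)  # >= 1 reference copy
    raise KeyError(
        f"risk allele {annotation.risk_allele!r} matches neither ref nor alt "
        f"of {annotation.allele_id!r}"
    )


def count_risk_variants(
    cohort: CohortGenotypes,
    annotations_for_drug: Sequence[ClinicalAnnotation],
    diplotypes: Sequence[DiplotypeCall] = (),
    weight_by_dosage: bool = False,
) -> tuple[np.ndarray, list[ClinicalAnnotation]]:
    """Per-sample counts of carried annotations for one drug.

    Returns (counts aligned with cohort.samples, unmatched annotations).
    Unresolvable annotations are excluded from counting and reported; with
    ``weight_by_dosage`` a SNP homozygous for the risk allele contributes 2.
    """
    vindex = cohort.variant_index()
    dlookup = _diplotype_lookup(diplotypes)
    counts = np.zeros(cohort.n_samples, dtype=int)
    unmatched: list[ClinicalAnnotation] = []
    for ann in annotations_for_drug:
        if ann.allele_type == "snp":
            j = vindex.get(ann.allele_id)
            if j is None:
                unmatched.append(ann)
                continue
            v = cohort.variants[j]
            if ann.risk_allele not in (v.ref, v.alt):
                unmatched.append(ann)
                continue
            if weight_by_dosage:
                d = cohort.dosage[:, j]
                observed = d != MISSING
                risk_dosage = d if ann.risk_allele == v.alt else 2 - d
                counts += np.where(observed, risk_dosage, 0)
            else:
                counts += _snp_carrier_column(cohort, j, ann)
        else:
            hit = np.zeros(cohort.n_samples, dtype=bool)
            any_call = False
            for i, s in enumerate(cohort.samples):
                pair = dlookup.get((s, ann.gene))
                if pair is not None:
                    any_call = True
                    hit[i] = ann.risk_allele in pair
            if not any_call:
                unmatched.append(ann)
                continue
            counts += hit
    if unmatched:
        log.info("count_risk_variants: %d unmatched annotation(s) excluded", len(unmatched))
    return counts, unmatched


def _exclusive_quartiles(sorted_counts: np.ndarray) -> tuple[float, float]:
    """Quartiles by the midpoint-exclusive (Tukey, median-excluded) method.

    The sorted data are split at the median; with odd n the middle element
    belongs to neither half. Q1/Q3 are the medians of the halves.
    """
    n = len(sorted_counts)
    half = n // 2
    lower = sorted_counts[:half]
    upper = sorted_counts[n - half:]
    if half == 0:  # n == 1
        return float(sorted_counts[0]), float(sorted_counts[0])
    return float(np.median(lower)), float(np.median(upper))


def summarize_drug(
    drug: str, counts: Sequence[int] | np.ndarray, n_annotations: int
) -> DrugRiskSummary:
    """Median (linear midpoint for even n), range, exclusive quartiles, carrier fraction."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError(f"cannot summarise drug {drug!r} over an empty cohort")
    s = np.sort(counts)
    q1, q3 = _exclusive_quartiles(s)
    return DrugRiskSummary(
        drug=drug,
        n_annotations=n_annotations,
        per_sample_counts=tuple(int(c) for c in counts),
        median=float(np.median(s)),
        min=int(s[0]),
        max=int(s[-1]),
        q1=q1,
        q3=q3,
        carrier_fraction=float((counts >= 1).mean()),
    )


def landscape_table(
    cohort: CohortGenotypes,
    annotations: Sequence[ClinicalAnnotation],
    drugs: Sequence[Drug],
    diplotypes: Sequence[DiplotypeCall] = (),
    level_filter: Iterable[str] | None = None,
    weight_by_dosage: bool = False,
) -> tuple[list[DrugRiskSummary], list[str]]:
    """One DrugRiskSummary per drug with >= 1 annotation passing the level filter.

    Returns (summaries, names of drugs with no usable annotation). The level
    filter is explicit by design: whether weak-evidence (3/4) records enter
    the landscape materially changes it, so callers must choose.
    """
    allowed = set(level_filter) if level_filter is not None else None
    by_drug: dict[str, list[ClinicalAnnotation]] = {d.name: [] for d in drugs}
    for ann in annotations:
        if ann.drug in by_drug and (allowed is None or ann.level in allowed):
            by_drug[ann.drug].append(ann)
    summaries: list[DrugRiskSummary] = []
    no_info: list[str] = []
    for d in drugs:
        anns = by_drug[d.name]
        if not anns:
            no_info.append(d.name)
            continue
        counts, unmatched = count_risk_variants(
            cohort, anns, diplotypes, weight_by_dosage=weight_by_dosage
        )
        usable = len(anns) - len(unmatched)
        if usable == 0:
            no_info.append(d.name)
            continue
        summaries.append(summarize_drug(d.name, counts, n_annotations=usable))
    return summaries, no_info


def landscape_to_frame(summaries: Sequence[DrugRiskSummary]) -> pd.DataFrame:
    """Tabular export (one row per drug; per-sample counts omitted)."""
    return pd.DataFrame(
        [
            {
                "drug": s.drug,
                "n_annotations": s.n_annotations,
                "median": s.median,
                "min": s.min,
                "max": s.max,
                "q1": s.q1,
                "q3": s.q3,
                "carrier_fraction": s.carrier_fraction,
            }
            for s in summaries
        ],
        columns=["drug", "n_annotations", "median", "min", "max", "q1", "q3",
                 "carrier_fraction"],
    )
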