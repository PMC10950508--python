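"""Cross-population comparison: Fisher exact AF tests and Weir-Cockerham Fst.

The differentiation statistic is the Weir & Cockerham (1984) fixation index
for two populations, aggregated across sites as a ratio of sums
(sum(a) / sum(a+b+c)), the weighting used by PLINK's ``--fst``. Per-site
variance components are computed from observed (non-missing) sample sizes,
allele frequencies and heterozygote proportions; negative components are
kept as computed, never clamped.

Allele-frequency differences between populations are tested per variant
with a two-sided Fisher exact test on the 2x2 table of (alt, ref) allele
counts, under the minimum-likelihood convention (sum of hypergeometric
point probabilities no larger than the observed table's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MISSING, CohortGenotypes

log = logging.getLogger("pgxddi.popgen_compare")


def fisher_exact_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p for a non-negative integer 2x2 table.

    A table with a zero margin carries no information about association;
    p = 1 by convention (logged).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError(f"expected a non-negative 2x2 table, got {table!r}")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        log.debug("fisher_exact_2x2: zero margin in %s, p = 1 by convention", t.tolist())
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def compare_allele_frequencies(
    af_table_a: pd.DataFrame,
    af_table_b: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-allele 2x2 Fisher tests between two allele-frequency tables.

    Both inputs follow the allele_frequencies() schema (allele_id,
    population, alt_count, total_count, af). Alleles present in only one
    table are reported to the log and skipped. With ``bh_correct`` the
    significance flag uses Benjamini-Hochberg adjusted p-values; raw
    p-values are always reported.
    """
    a = af_table_a.set_index("allele_id")
    b = af_table_b.set_index("allele_id")
    shared = sorted(set(a.index) & set(b.index))
    only = (set(a.index) ^ set(b.index))
    if only:
        log.info("compare_allele_frequencies: %d allele(s) present in only one table skipped",
                 len(only))
    rows = []
    for allele in shared:
        ra, rb = a.loc[allele], b.loc[allele]
        alt_a, tot_a = int(ra["alt_count"]), int(ra["total_count"])
        alt_b, tot_b = int(rb["alt_count"]), int(rb["total_count"])
        table = [[alt_a, tot_a - alt_a], [alt_b, tot_b - alt_b]]
        p = fisher_exact_2x2(table)
        rows.append({
            "allele_id": allele,
            "pop_a": ra["population"],
            "pop_b": rb["population"],
            "alt_a": alt_a, "total_a": tot_a,
            "alt_b": alt_b, "total_b": tot_b,
            "af_a": ra["af"], "af_b": rb["af"],
            "p_value": p,
        })
    out = pd.DataFrame(rows, columns=["allele_id", "pop_a", "pop_b", "alt_a", "total_a",
                                      "alt_b", "total_b", "af_a", "af_b", "p_value"])
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    if bh_correct:
        m = len(out)
        order = np.argsort(out["p_value"].to_numpy(), kind="stable")
        adj = np.empty(m)
        ranked = out["p_value"].to_numpy()[order] * m / np.arange(1, m + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out["p_adjusted"] = np.minimum(adj, 1.0)
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


@dataclass(frozen=True)
class FstResult:
    """Pairwise weighted Weir-Cockerham Fst with per-site variance components."""

    pop_a: str
    pop_b: str
    n_variants_used: int
    a: np.ndarray  # among-population component per site
    b: np.ndarray  # among-individuals-within-population component per site
    c: np.ndarray  # within-individual component per site
    weighted_fst: float  # sum(a) / sum(a+b+c), ratio of sums
    mean_fst: float  # mean of per-site a/(a+b+c)


def wc_fst_components(
    alt_count_a, het_count_a, n_a, alt_count_b, het_count_b, n_b
):
    """Weir & Cockerham (1984) variance components for two populations.

    Inputs are per-site observed quantities (scalars or aligned arrays):
    alternate-allele counts, heterozygote counts, and non-missing diploid
    sample sizes. Returns the (a, b, c) components — among populations,
    among individuals within populations, within individuals. Components
    may be negative; the estimator is unbiased, not bounded.
    """
    alt_a = np.asarray(alt_count_a, dtype=float)
    alt_b = np.asarray(alt_count_b, dtype=float)
    het_a = np.asarray(het_count_a, dtype=float)
    het_b = np.asarray(het_count_b, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)

    r = 2.0
    p_a = alt_a / (2.0 * n_a)
    p_b = alt_b / (2.0 * n_b)
    h_a = het_a / n_a
    h_b = het_b / n_b

    n_bar = (n_a + n_b) / r
    n_c = (r * n_bar - (n_a ** 2 + n_b ** 2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n_a * p_a + n_b * p_b) / (r * n_bar)
    s2 = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n_a * h_a + n_b * h_b) / (r * n_bar)

    inner = p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (inner - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar)
    c = h_bar / 2.0
    return a, b, c


def _site_stats(cohort: CohortGenotypes, cols: np.ndarray):
    """Per-site (alt count, het count, non-missing n) over selected columns."""
    d = cohort.dosage[:, cols]
    observed = d != MISSING
    alt = np.where(observed, d, 0).sum(axis=0)
    het = ((d == 1) & observed).sum(axis=0)
    n = observed.sum(axis=0)
    return alt.astype(float), het.astype(float), n.astype(float)


def weighted_fst(
    cohort_a: CohortGenotypes,
    cohort_b: CohortGenotypes,
    variant_subset: Iterable[str] | None = None,
) -> FstResult:
    """Weighted (ratio-of-sums) WC84 Fst between two cohorts.

    Sites are matched by variant identity across the two cohorts; sites
    monomorphic for the same allele across both populations, and sites with
    fewer than two observed genotypes in either population, are excluded
    from the sums. Raises when no usable site remains.
    """
    ids_a = {v.allele_id: j for j, v in enumerate(cohort_a.variants)}
    ids_b = {v.allele_id: j for j, v in enumerate(cohort_b.variants)}
    shared = [i for i in ids_a if i in ids_b]
    if variant_subset is not None:
        subset = set(variant_subset)
        shared = [i for i in shared if i in subset]
    if not shared:
        raise ValueError(
            f"no shared variant between {cohort_a.population!r} and "
            f"{cohort_b.population!r} (subset applied: {variant_subset is not None})"
        )
    cols_a = np.array([ids_a[i] for i in shared])
    cols_b = np.array([ids_b[i] for i in shared])
    alt_a, het_a, n_a = _site_stats(cohort_a, cols_a)
    alt_b, het_b, n_b = _site_stats(cohort_b, cols_b)

    enough = (n_a >= 2) & (n_b >= 2)
    pooled_alt = alt_a + alt_b
    pooled_total = 2.0 * (n_a + n_b)
    polymorphic = (pooled_alt > 0) & (pooled_alt < pooled_total)
    keep = enough & polymorphic
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("weighted_fst: excluded %d monomorphic/underpopulated site(s)", n_excluded)
    if not keep.any():
        raise ValueError(
            f"no polymorphic site with sufficient data between "
            f"{cohort_a.population!r} and {cohort_b.population!r}"
        )
    a, b, c = wc_fst_components(
        alt_a[keep], het_a[keep], n_a[keep], alt_b[keep], het_b[keep], n_b[keep]
    )
    denom = a + b + c
    total = float(denom.sum())
    if total == 0.0:
        raise ValueError("zero total variance across retained sites")
    per_site = np.divide(a, denom, out=np.full_like(a, np.nan), where=denom != 0)
    return FstResult(
        pop_a=cohort_a.population,
        pop_b=cohort_b.population,
        n_variants_used=int(keep.sum()),
        a=a, b=b, c=c,
        weighted_fst=float(a.sum() / total),
        mean_fst=float(np.nanmean(per_site)),
    )


def fst_matrix(
    cohorts: Sequence[CohortGenotypes],
    variant_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise weighted Fst (zero diagonal)."""
    if len(cohorts) < 2:
        raise ValueError("fst_matrix needs >= 2 cohorts")
    labels = [c.population for c in cohorts]
    if len(set(labels)) != len(labels):
        raise ValueError("cohort population labels must be unique")
    m = pd.DataFrame(0.0, index=labels, columns=labels)
    for i in range(len(cohorts)):
        for j in range(i + 1, len(cohorts)):
            f = weighted_fst(cohorts[i], cohorts[j], variant_subset).weighted_fst
            m.iloc[i, j] = f
            m.iloc[j, i] = f
    return m


def fst_matrix_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (pop_a, pop_b, weighted_fst) over the upper triangle."""
    rows = []
    labels = list(matrix.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            rows.append({"pop_a": a, "pop_b": b, "weighted_fst": matrix.loc[a, b]})
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "weighted_fst"])
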