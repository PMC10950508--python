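"""Candidate deleterious-variant filter.

A variant is retained when all four conditions hold:

1. it is a nonsynonymous exonic variant;
2. its gene encodes a CTET element (carrier/transporter/enzyme/target) of at
   least one drug in the active drug list;
3. at least two of the three predictors call it damaging — SIFT
   "Damaging", PolyPhen-2 "Damaging"/"Probably damaging", MutationTaster
   "Disease causing"; a missing call abstains;
4. its cohort allele frequency is strictly greater than the threshold
   (default 1%).

Every input variant yields a decision row carrying all four sub-flags, so
the conjunction is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .catalog_io import (
    MUTATION_TASTER_CALLS,
    POLYPHEN_CALLS,
    SIFT_CALLS,
    CatalogError,
    DeleteriousnessAnnotation,
    Drug,
    DrugGeneCatalog,
)

log = logging.getLogger("pgxddi.variant_filter")

_DAMAGING = {
    "sift": {"damaging"},
    "polyphen": {"damaging", "probably_damaging"},
    "mutation_taster": {"disease_causing"},
}
_VOCAB = {"sift": SIFT_CALLS, "polyphen": POLYPHEN_CALLS, "mutation_taster": MUTATION_TASTER_CALLS}


@dataclass(frozen=True)
class FilterDecision:
    """Audit record for one variant through the candidate filter."""

    variant_id: str
    gene: str
    damaging_votes: int
    af: float | None
    passed_class: bool
    passed_gene: bool
    passed_votes: bool
    passed_af: bool | None  # None when the variant has no AF record
    retained: bool


def is_deleterious(sift: str, polyphen: str, mutation_taster: str) -> tuple[int, bool]:
    """(damaging votes, votes >= 2). Missing calls abstain."""
    calls = {"sift": sift, "polyphen": polyphen, "mutation_taster": mutation_taster}
    votes = 0
    for tool, call in calls.items():
        if call not in _VOCAB[tool]:
            raise CatalogError(f"unknown {tool} category {call!r}")
        if call in _DAMAGING[tool]:
            votes += 1
    return votes, votes >= 2


def filter_candidates(
    deleterious_table: Sequence[DeleteriousnessAnnotation],
    af_table: pd.DataFrame,
    ctet_catalog: DrugGeneCatalog,
    drugs: Sequence[Drug],
    af_threshold: float = 0.01,
) -> list[FilterDecision]:
    """Apply the four-way candidate filter; one decision row per input variant.

    ``af_table`` follows the allele_frequencies() schema from the study
    cohort. The AF condition is strict (af > threshold). A variant absent
    from the AF table gets passed_af None and retained False (logged).
    """
    if not 0.0 <= af_threshold < 1.0:
        raise ValueError(f"af_threshold must be in [0,1), got {af_threshold}")
    drug_names = {d.name for d in drugs}
    catalog_genes = frozenset(
        g for (drug, _, g) in ctet_catalog.entries if drug in drug_names
    )
    af_lookup: Mapping[str, float] = dict(
        zip(af_table["allele_id"], af_table["af"])
    )
    decisions: list[FilterDecision] = []
    n_no_af = 0
    for rec in deleterious_table:
        votes, enough_votes = is_deleterious(rec.sift, rec.polyphen, rec.mutation_taster)
        passed_class = rec.functional_class == "nonsynonymous_exonic"
        passed_gene = rec.gene in catalog_genes
        af = af_lookup.get(rec.variant_id)
        if af is None or pd.isna(af):
            n_no_af += 1
            passed_af: bool | None = None
            af = None
        else:
            af = float(af)
            passed_af = af > af_threshold
        decisions.append(
            FilterDecision(
                variant_id=rec.variant_id,
                gene=rec.gene,
                damaging_votes=votes,
                af=af,
                passed_class=passed_class,
                passed_gene=passed_gene,
                passed_votes=enough_votes,
                passed_af=passed_af,
                retained=bool(passed_class and passed_gene and enough_votes and passed_af),
            )
        )
    if n_no_af:
        log.info("filter_candidates: %d variant(s) missing from the AF table", n_no_af)
    return decisions


def decisions_to_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    cols = ["variant_id", "gene", "damaging_votes", "af", "passed_class",
            "passed_gene", "passed_votes", "passed_af", "retained"]
    return pd.DataFrame([{c: getattr(d, c) for c in cols} for d in decisions], columns=cols)
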