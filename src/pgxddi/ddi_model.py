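"""Binary-vector drug-drug interaction (DDI) prediction.

Each drug is encoded as five binary vectors over element universes built
from the analysed drug set: one per CTET role (carrier, transporter,
enzyme, target) and a hybrid vector concatenating all four. Pairwise
similarity is Russell-Rao, S = x'y / d — the fraction of the universe
shared by both drugs — and a pair is a potential DDI iff its hybrid
similarity is positive, i.e. iff the two drugs share at least one catalogued
element. Drugs with an all-zero hybrid vector (no catalogued elements) are
eliminated before scoring.

Because d is the size of the universe induced by the analysed drug set,
S values are universe-relative: adding unrelated drugs to the analysis
changes d (and hence every S) but can never flip an S > 0 decision.

The hybrid universe is keyed by (role, gene) by default, so a gene serving
two roles contributes two elements and hybrid positive matches decompose
exactly over roles; ``hybrid_keying="gene"`` collapses roles and treats a
gene shared under different roles as a match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog_io import CTET_ROLES, DrugGeneCatalog, Regimen

log = logging.getLogger("pgxddi.ddi_model")

VECTOR_TYPES = CTET_ROLES + ("hybrid",)


@dataclass(frozen=True)
class ElementUniverse:
    """Ordered element universe for one vector type over a drug set."""

    vector_type: str
    elements: tuple  # gene strings, or (role, gene) tuples for hybrid
    def __post_init__(self) -> None:
        if self.vector_type not in VECTOR_TYPES:
            raise ValueError(f"unknown vector type {self.vector_type!r}")
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("universe elements must be unique")

    @property
    def d(self) -> int:
        return len(self.elements)

    def index(self) -> dict:
        return {e: i for i, e in enumerate(self.elements)}


@dataclass(frozen=True)
class CTETVector:
    """One drug's binary membership vector over an ElementUniverse."""

    drug: str
    vector_type: str
    bits: tuple[int, ...]

    @property
    def popcount(self) -> int:
        return sum(self.bits)


@dataclass(frozen=True)
class DDIResult:
    """Similarity scores and interaction flag for one unordered drug pair."""

    drug_a: str
    drug_b: str
    positive_matches: int  # on the hybrid universe
    similarity: float  # hybrid Russell-Rao S
    per_type_similarity: Mapping[str, float | None]
    is_ddi: bool


@dataclass(frozen=True)
class RegimenDDICount:
    """Counts of potential DDI pairs within and across one or two regimens."""

    regimen_a: str
    regimen_b: str | None
    n_drugs_after_elimination: int
    within_a: int
    within_b: int
    cross: int
    union_count: int
    ddi_pairs: tuple[tuple[str, str], ...]


def build_universe(
    catalog: DrugGeneCatalog,
    drugs: Sequence[str],
    vector_type: str,
    hybrid_keying: str = "role_gene",
) -> ElementUniverse:
    """Union of elements of the given type across the drug set, canonically ordered.

    Role universes are lexicographically sorted genes; the hybrid universe
    is the concatenation of the four role universes (role order fixed:
    carrier, transporter, enzyme, target), keyed (role, gene). With
    ``hybrid_keying="gene"`` the hybrid universe is the sorted union of all
    genes regardless of role.
    """
    if not drugs:
        raise ValueError("drug set must be non-empty")
    dset = set(drugs)
    if vector_type in CTET_ROLES:
        genes = sorted({g for (d, r, g) in catalog.entries if d in dset and r == vector_type})
        return ElementUniverse(vector_type=vector_type, elements=tuple(genes))
    if vector_type != "hybrid":
        raise ValueError(f"unknown vector type {vector_type!r}")
    if hybrid_keying == "role_gene":
        elements: list = []
        for role in CTET_ROLES:
            genes = sorted({g for (d, r, g) in catalog.entries if d in dset and r == role})
            elements.extend((role, g) for g in genes)
        return ElementUniverse(vector_type="hybrid", elements=tuple(elements))
    if hybrid_keying == "gene":
        genes = sorted({g for (d, _, g) in catalog.entries if d in dset})
        return ElementUniverse(vector_type="hybrid", elements=tuple(genes))
    raise ValueError(f"unknown hybrid keying {hybrid_keying!r}")


def _drug_elements(catalog: DrugGeneCatalog, drug: str, universe: ElementUniverse) -> set:
    if universe.vector_type in CTET_ROLES:
        return set(catalog.genes_for(drug, universe.vector_type))
    if universe.elements and not isinstance(universe.elements[0], tuple):
        return set(catalog.genes_for(drug))  # gene-keyed hybrid
    return set(catalog.elements_for(drug))


def build_vector(drug: str, universe: ElementUniverse, catalog: DrugGeneCatalog) -> CTETVector:
    """Binary membership vector of a drug over a universe."""
    members = _drug_elements(catalog, drug, universe)
    bits = tuple(1 if e in members else 0 for e in universe.elements)
    return CTETVector(drug=drug, vector_type=universe.vector_type, bits=bits)


def eliminate_zero_vectors(
    vectors: Sequence[CTETVector],
) -> tuple[list[CTETVector], list[str]]:
    """Split vectors into (kept with popcount >= 1, dropped drug names)."""
    kept = [v for v in vectors if v.popcount >= 1]
    dropped = [v.drug for v in vectors if v.popcount == 0]
    if dropped:
        log.info("eliminate_zero_vectors: %d drug(s) without catalogued elements dropped: %s",
                 len(dropped), ", ".join(dropped))
    return kept, dropped


def russell_rao(x: CTETVector | Sequence[int], y: CTETVector | Sequence[int]) -> float:
    """Russell-Rao similarity S = (positive matches) / d for binary vectors."""
    bx = x.bits if isinstance(x, CTETVector) else tuple(x)
    by = y.bits if isinstance(y, CTETVector) else tuple(y)
    if len(bx) != len(by):
        raise ValueError(f"vector length mismatch: {len(bx)} vs {len(by)}")
    if len(bx) == 0:
        raise ValueError("similarity undefined on an empty universe (d = 0)")
    matches = sum(a & b for a, b in zip(bx, by))
    return matches / len(bx)


def detect_ddis(
    drugs: Sequence[str],
    catalog: DrugGeneCatalog,
    hybrid_keying: str = "role_gene",
) -> tuple[list[DDIResult], list[str]]:
    """Score all unordered pairs on the five vector types; flag DDIs by hybrid S > 0.

    Returns (results over drugs surviving zero-vector elimination, dropped
    drug names). Per-type similarities are None where that role's universe
    is empty for the analysed drug set.
    """
    hybrid_universe = build_universe(catalog, drugs, "hybrid", hybrid_keying)
    hybrid_vectors = [build_vector(d, hybrid_universe, catalog) for d in drugs]
    kept, dropped = eliminate_zero_vectors(hybrid_vectors)
    kept_names = [v.drug for v in kept]
    if len(kept_names) < 2:
        log.info("detect_ddis: fewer than 2 drugs after zero-vector elimination")
        return [], dropped

    role_universes = {r: build_universe(catalog, drugs, r) for r in CTET_ROLES}
    role_vectors = {
        r: {d: build_vector(d, u, catalog) for d in kept_names}
        for r, u in role_universes.items()
    }
    hv = {v.drug: v for v in kept}
    results: list[DDIResult] = []
    for a, b in combinations(kept_names, 2):
        per_type: dict[str, float | None] = {}
        for r in CTET_ROLES:
            u = role_universes[r]
            per_type[r] = russell_rao(role_vectors[r][a], role_vectors[r][b]) if u.d else None
        s = russell_rao(hv[a], hv[b])
        per_type["hybrid"] = s
        matches = sum(x & y for x, y in zip(hv[a].bits, hv[b].bits))
        results.append(
            DDIResult(
                drug_a=a, drug_b=b,
                positive_matches=matches,
                similarity=s,
                per_type_similarity=per_type,
                is_ddi=s > 0.0,
            )
        )
    return results, dropped


def count_regimen_ddis(
    regimen_a: Regimen,
    regimen_b: Regimen | None,
    catalog: DrugGeneCatalog,
    hybrid_keying: str = "role_gene",
) -> RegimenDDICount:
    """Count potential DDI pairs within and across regimens.

    Counting runs over the union of the two drug sets (a drug listed in
    both regimens enters once). Each DDI pair is bucketed exclusively:
    both drugs in regimen A -> within_a; otherwise both in B -> within_b;
    otherwise cross. The union count therefore always decomposes as
    within_a + within_b + cross.
    """
    set_a = set(regimen_a.drugs)
    set_b = set(regimen_b.drugs) if regimen_b else set()
    union_drugs = sorted(set_a | set_b)
    results, dropped = detect_ddis(union_drugs, catalog, hybrid_keying)
    within_a = within_b = cross = 0
    pairs: list[tuple[str, str]] = []
    for r in results:
        if not r.is_ddi:
            continue
        pairs.append((r.drug_a, r.drug_b))
        if r.drug_a in set_a and r.drug_b in set_a:
            within_a += 1
        elif r.drug_a in set_b and r.drug_b in set_b:
            within_b += 1
        else:
            cross += 1
    return RegimenDDICount(
        regimen_a=regimen_a.name,
        regimen_b=regimen_b.name if regimen_b else None,
        n_drugs_after_elimination=len(union_drugs) - len(dropped),
        within_a=within_a,
        within_b=within_b,
        cross=cross,
        union_count=within_a + within_b + cross,
        ddi_pairs=tuple(sorted(pairs)),
    )


def build_drug_gene_network(
    catalog: DrugGeneCatalog, drugs: Sequence[str]
) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite drug-gene graph with role-annotated edges and a degree table.

    A gene node's degree is the number of distinct drugs linked to it (the
    quantity label sizes are scaled by in the usual network rendering); a
    drug node's degree is its number of distinct pathway genes.
    """
    dset = set(drugs)
    g = nx.Graph()
    for d in sorted(dset):
        g.add_node(d, kind="drug")
    edge_roles: dict[tuple[str, str], set[str]] = {}
    for drug, role, gene in sorted(catalog.entries):
        if drug not in dset:
            continue
        edge_roles.setdefault((drug, gene), set()).add(role)
    for (drug, gene), roles in sorted(edge_roles.items()):
        if gene not in g:
            g.add_node(gene, kind="gene")
        g.add_edge(drug, gene, roles=";".join(sorted(roles)))
    rows = [
        {"name": n, "kind": g.nodes[n]["kind"], "degree": g.degree(n)}
        for n in sorted(g.nodes)
    ]
    return g, pd.DataFrame(rows, columns=["name", "kind", "degree"])


def ddi_results_to_frame(results: Sequence[DDIResult]) -> pd.DataFrame:
    cols = (["drug_a", "drug_b", "positive_matches"]
            + [f"s_{t}" for t in VECTOR_TYPES] + ["is_ddi"])
    rows = []
    for r in results:
        row = {"drug_a": r.drug_a, "drug_b": r.drug_b,
               "positive_matches": r.positive_matches, "is_ddi": r.is_ddi}
        for t in VECTOR_TYPES:
            row[f"s_{t}"] = r.per_type_similarity.get(t)
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def network_edges_to_frame(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, data in sorted(g.edges(data=True)):
        drug, gene = (u, v) if g.nodes[u]["kind"] == "drug" else (v, u)
        rows.append({"drug": drug, "gene": gene, "roles": data.get("roles", "")})
    rows.sort(key=lambda r: (r["drug"], r["gene"]))
    return pd.DataFrame(rows, columns=["drug", "gene", "roles"])
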