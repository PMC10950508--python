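"""Domain types and TSV readers/writers for the non-genotype inputs.

All tables are UTF-8, tab-delimited, with a header row. Lists within a cell
(e.g. a drug's therapeutic groups) are semicolon-separated. Readers are
strict: closed vocabularies are enforced with hard errors naming the
offending row, and every dropped or deduplicated record class is counted and
logged, never silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger("pgxddi.catalog_io")

#: Therapeutic group vocabulary: COVID-19 treatment categories, the four
#: post-COVID condition groups, and the three chronic-comorbidity groups.
DRUG_GROUPS = frozenset({
    "cause_treatment", "corticoid", "antithrombotic", "superinfection",
    "post_covid_fatigue", "post_covid_respiratory",
    "post_covid_cardiovascular", "post_covid_mental",
    "comorbidity_t2d", "comorbidity_cvd", "comorbidity_cancer",
})

#: PharmGKB-style clinical-annotation evidence tiers, strongest (1A) to
#: weakest (4). Levels 1-2 are conventionally called "actionable".
EVIDENCE_LEVELS = ("1A", "1B", "2A", "2B", "3", "4")
ACTIONABLE_LEVELS = frozenset({"1A", "1B", "2A", "2B"})

ALLELE_TYPES = ("snp", "star", "hla")
PHENOTYPE_CATEGORIES = frozenset({"efficacy", "toxicity", "dosage", "metabolism", "other"})

#: DrugBank-style protein role categories (CTET).
CTET_ROLES = ("carrier", "transporter", "enzyme", "target")

SIFT_CALLS = frozenset({"damaging", "tolerated", "missing"})
POLYPHEN_CALLS = frozenset({"probably_damaging", "damaging", "benign", "missing"})
MUTATION_TASTER_CALLS = frozenset({"disease_causing", "polymorphism", "missing"})
FUNCTIONAL_CLASSES = frozenset({"nonsynonymous_exonic", "other"})


class CatalogError(ValueError):
    """Raised on malformed or vocabulary-violating catalog input."""


@dataclass(frozen=True)
class Drug:
    """A drug with one or more therapeutic group tags."""

    name: str
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("drug name must be non-empty")
        bad = set(self.groups) - DRUG_GROUPS
        if bad:
            raise CatalogError(f"unknown drug group(s) {sorted(bad)} for drug {self.name!r}")


@dataclass(frozen=True)
class ClinicalAnnotation:
    """One variant/allele -> drug clinical annotation with an evidence level.

    ``allele_id`` is an rsID for SNPs, a star allele (``CYP2C19*2``) for
    pharmacogene haplotypes, or an HLA allele (``HLA-B*15:02``).
    ``risk_allele`` is the alternate base for a SNP and the allele name for
    star/HLA records.
    """

    allele_id: str
    allele_type: str
    gene: str
    drug: str
    level: str
    risk_allele: str
    phenotype_category: str = "other"

    def __post_init__(self) -> None:
        if self.level not in EVIDENCE_LEVELS:
            raise CatalogError(f"unknown evidence level {self.level!r} for {self.allele_id!r}")
        if self.allele_type not in ALLELE_TYPES:
            raise CatalogError(f"unknown allele type {self.allele_type!r}")
        if self.phenotype_category not in PHENOTYPE_CATEGORIES:
            raise CatalogError(f"unknown phenotype category {self.phenotype_category!r}")
        if self.allele_type == "snp" and not set(self.risk_allele) <= set("ACGT"):
            raise CatalogError(
                f"snp annotation {self.allele_id!r} must carry a nucleotide risk allele, "
                f"got {self.risk_allele!r}"
            )


def infer_allele_type(allele_id: str) -> str:
    """Classify an allele identifier by its syntax.

    ``rs...`` -> snp; ``HLA-...`` -> hla; ``GENE*n`` -> star.
    """
    if allele_id.startswith("rs"):
        return "snp"
    if allele_id.startswith("HLA-"):
        return "hla"
    if "*" in allele_id and not allele_id.startswith("*"):
        return "star"
    raise CatalogError(f"cannot infer allele type from identifier {allele_id!r}")


@dataclass(frozen=True)
class DrugGeneCatalog:
    """Mapping drug -> role-typed gene sets (carrier/transporter/enzyme/target)."""

    entries: frozenset[tuple[str, str, str]]  # (drug, role, gene)

    def __post_init__(self) -> None:
        for drug, role, gene in self.entries:
            if role not in CTET_ROLES:
                raise CatalogError(f"unknown CTET role {role!r} for ({drug!r}, {gene!r})")

    def drugs(self) -> list[str]:
        return sorted({d for d, _, _ in self.entries})

    def genes_for(self, drug: str, role: str | None = None) -> frozenset[str]:
        return frozenset(
            g for d, r, g in self.entries if d == drug and (role is None or r == role)
        )

    def elements_for(self, drug: str) -> frozenset[tuple[str, str]]:
        """All (role, gene) elements linked to a drug."""
        return frozenset((r, g) for d, r, g in self.entries if d == drug)

    def all_genes(self) -> frozenset[str]:
        return frozenset(g for _, _, g in self.entries)


@dataclass(frozen=True)
class DeleteriousnessAnnotation:
    """Pre-computed functional-impact calls for one variant.

    The three predictor columns hold categorical calls from SIFT,
    PolyPhen-2 and MutationTaster; ``missing`` means the tool produced no
    call for this variant.
    """

    variant_id: str
    gene: str
    functional_class: str
    sift: str
    polyphen: str
    mutation_taster: str

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise CatalogError(f"unknown functional class {self.functional_class!r}")
        if self.sift not in SIFT_CALLS:
            raise CatalogError(f"unknown SIFT call {self.sift!r}")
        if self.polyphen not in POLYPHEN_CALLS:
            raise CatalogError(f"unknown PolyPhen-2 call {self.polyphen!r}")
        if self.mutation_taster not in MUTATION_TASTER_CALLS:
            raise CatalogError(f"unknown MutationTaster call {self.mutation_taster!r}")


@dataclass(frozen=True)
class DiplotypeCall:
    """Two named alleles for one gene in one individual (star or HLA calls)."""

    sample_id: str
    gene: str
    allele1: str
    allele2: str


@dataclass(frozen=True)
class Regimen:
    """An ordered set of co-administered drugs."""

    name: str
    drugs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.drugs:
            raise CatalogError(f"regimen {self.name!r} has no drugs")
        if len(set(self.drugs)) != len(self.drugs):
            raise CatalogError(f"regimen {self.name!r} lists a drug twice")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing required column(s) {missing}")
    return df


def read_drug_list(path: str | Path) -> list[Drug]:
    """Read drugs.tsv (columns: name, groups semicolon-separated)."""
    df = _read_tsv(path, ["name", "groups"])
    drugs: list[Drug] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        name = row.name.strip()
        if name in seen:
            raise CatalogError(f"{path}: duplicate drug name {name!r} at line {i}")
        groups = tuple(g.strip() for g in row.groups.split(";") if g.strip())
        bad = set(groups) - DRUG_GROUPS
        if bad:
            raise CatalogError(f"{path}: unknown group token(s) {sorted(bad)} at line {i}")
        drugs.append(Drug(name=name, groups=groups))
        seen.add(name)
    return drugs


def read_clinical_annotations(
    path: str | Path, drug_list: Sequence[Drug]
) -> list[ClinicalAnnotation]:
    """Read clinical_annotations.tsv, dropping records for unlisted drugs.

    The allele type is inferred from the identifier syntax; if the file also
    carries an ``allele_type`` column it must agree, otherwise loading fails.
    Records are deduplicated on (allele_id, drug, level).
    """
    df = _read_tsv(path, ["allele_id", "gene", "drug", "level", "risk_allele"])
    known = {d.name for d in drug_list}
    out: list[ClinicalAnnotation] = []
    seen: set[tuple[str, str, str]] = set()
    n_dup = n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        allele_id = row.allele_id.strip()
        inferred = infer_allele_type(allele_id)
        explicit = getattr(row, "allele_type", "").strip()
        if explicit and explicit != inferred:
            raise CatalogError(
                f"{path}: line {i}: allele_type {explicit!r} disagrees with "
                f"identifier syntax ({inferred!r}) for {allele_id!r}"
            )
        if row.drug not in known:
            n_dropped += 1
            continue
        key = (allele_id, row.drug, row.level)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append(
            ClinicalAnnotation(
                allele_id=allele_id,
                allele_type=inferred,
                gene=row.gene.strip().upper() if inferred == "snp" else row.gene.strip(),
                drug=row.drug,
                level=row.level,
                risk_allele=row.risk_allele.strip(),
                phenotype_category=getattr(row, "phenotype_category", "other") or "other",
            )
        )
    if n_dup:
        log.info("read_clinical_annotations: %d duplicate record(s) removed", n_dup)
    if n_dropped:
        log.info(
            "read_clinical_annotations: %d record(s) for drugs absent from the drug list dropped",
            n_dropped,
        )
    return out


def read_ctet_catalog(path: str | Path, drug_list: Sequence[Drug]) -> DrugGeneCatalog:
    """Read ctet_catalog.tsv (columns drug, role, gene) into a DrugGeneCatalog.

    Gene symbols are upper-cased; duplicate (drug, role, gene) triples and
    rows for drugs outside the list are removed with a logged count.
    """
    df = _read_tsv(path, ["drug", "role", "gene"])
    known = {d.name for d in drug_list}
    entries: set[tuple[str, str, str]] = set()
    n_dup = n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        role = row.role.strip()
        if role not in CTET_ROLES:
            raise CatalogError(f"{path}: unknown role token {role!r} at line {i}")
        if row.drug not in known:
            n_dropped += 1
            continue
        triple = (row.drug, role, row.gene.strip().upper())
        if triple in entries:
            n_dup += 1
        entries.add(triple)
    if n_dup:
        log.info("read_ctet_catalog: %d duplicated element(s) removed", n_dup)
    if n_dropped:
        log.info("read_ctet_catalog: %d row(s) for unlisted drugs dropped", n_dropped)
    return DrugGeneCatalog(entries=frozenset(entries))


def read_deleteriousness(path: str | Path) -> list[DeleteriousnessAnnotation]:
    """Read deleterious.tsv with per-variant categorical predictor calls."""
    df = _read_tsv(
        path, ["variant_id", "gene", "functional_class", "sift", "polyphen", "mutation_taster"]
    )
    return [
        DeleteriousnessAnnotation(
            variant_id=r.variant_id,
            gene=r.gene.strip().upper(),
            functional_class=r.functional_class,
            sift=r.sift or "missing",
            polyphen=r.polyphen or "missing",
            mutation_taster=r.mutation_taster or "missing",
        )
        for r in df.itertuples(index=False)
    ]


def read_diplotypes(path: str | Path) -> list[DiplotypeCall]:
    """Read diplotypes.tsv (sample_id, gene, allele1, allele2)."""
    df = _read_tsv(path, ["sample_id", "gene", "allele1", "allele2"])
    calls = [
        DiplotypeCall(r.sample_id, r.gene, r.allele1, r.allele2)
        for r in df.itertuples(index=False)
    ]
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.sample_id, c.gene)
        if key in seen:
            raise CatalogError(f"{path}: more than one diplotype call for {key}")
        seen.add(key)
    return calls


def read_regimens(path: str | Path, drug_list: Sequence[Drug]) -> list[Regimen]:
    """Read regimens.tsv (name, drugs semicolon-separated, order preserved)."""
    df = _read_tsv(path, ["name", "drugs"])
    known = {d.name for d in drug_list}
    regimens = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        drugs = tuple(d.strip() for d in row.drugs.split(";") if d.strip())
        unknown = [d for d in drugs if d not in known]
        if unknown:
            raise CatalogError(f"{path}: line {i}: unresolvable drug(s) {unknown}")
        regimens.append(Regimen(name=row.name, drugs=drugs))
    return regimens


# ---------------------------------------------------------------------------
# writers (round-trip inverses of the readers, canonical form)
# ---------------------------------------------------------------------------

def write_drug_list(drugs: Iterable[Drug], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": d.name, "groups": ";".join(d.groups)} for d in drugs]
    ).reindex(columns=["name", "groups"]).to_csv(path, sep="\t", index=False)


def write_clinical_annotations(records: Iterable[ClinicalAnnotation], path: str | Path) -> None:
    cols = ["allele_id", "allele_type", "gene", "drug", "level", "risk_allele",
            "phenotype_category"]
    pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records]).reindex(
        columns=cols
    ).to_csv(path, sep="\t", index=False)


def write_ctet_catalog(catalog: DrugGeneCatalog, path: str | Path) -> None:
    rows = sorted(catalog.entries)
    pd.DataFrame(rows, columns=["drug", "role", "gene"]).to_csv(path, sep="\t", index=False)


def write_deleteriousness(records: Iterable[DeleteriousnessAnnotation], path: str | Path) -> None:
    cols = ["variant_id", "gene", "functional_class", "sift", "polyphen", "mutation_taster"]
    pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records]).reindex(
        columns=cols
    ).to_csv(path, sep="\t", index=False)


def write_diplotypes(calls: Iterable[DiplotypeCall], path: str | Path) -> None:
    cols = ["sample_id", "gene", "allele1", "allele2"]
    pd.DataFrame([{c: getattr(r, c) for c in cols} for r in calls]).reindex(
        columns=cols
    ).to_csv(path, sep="\t", index=False)


def write_regimens(regimens: Iterable[Regimen], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": r.name, "drugs": ";".join(r.drugs)} for r in regimens]
    ).reindex(columns=["name", "drugs"]).to_csv(path, sep="\t", index=False)
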