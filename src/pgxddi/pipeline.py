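"""End-to-end pipeline: inputs -> landscape -> population comparison ->
candidate filter -> DDI model -> network, assembled into a report bundle.

A run is fully described by one PipelineConfig (either file paths or a
simulation block, never both) and is deterministic given the config and its
seed: running twice into two directories produces byte-identical bundles.
Scientifically meaningful parameters (evidence-level filter, AF threshold,
test alpha, DDI vector gating) have no hidden defaults — the config must
state them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import catalog_io, cohort_io, ddi_model, pgx_landscape, popgen_compare
from . import synthetic_data, variant_filter
from .catalog_io import Drug, Regimen

log = logging.getLogger("pgxddi.pipeline")

_FLOAT_FMT = "%.10g"


class PipelineStageError(RuntimeError):
    """Error in a named pipeline stage (the stage name is machine-readable)."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SimulationBlock(BaseModel):
    """Parameters for fully synthetic inputs."""

    n_variants: int = 500
    pop_sizes: dict[str, int] = Field(default_factory=lambda: {"POP_A": 150, "POP_B": 150, "POP_C": 150})
    divergence_F: float = 0.05
    n_drugs: int = 20
    n_genes: int = 60
    role_density: float = 0.03
    n_planted_pairs: int = 8
    n_annotated_drugs: int = 14
    annotations_per_drug: int = 8
    level_mix: dict[str, float] = Field(
        default_factory=lambda: {"1A": 0.1, "1B": 0.1, "2A": 0.2, "2B": 0.2, "3": 0.2, "4": 0.2}
    )


class InputPaths(BaseModel):
    """Paths to real inputs in the standard file formats."""

    vcf: str
    popmap: str
    drugs: str
    ctet_catalog: str
    clinical_annotations: str
    deleterious: str
    diplotypes: str | None = None
    regimens: str | None = None


class PipelineConfig(BaseModel):
    """One fully explicit pipeline run description."""

    simulate: SimulationBlock | None = None
    inputs: InputPaths | None = None
    study_population: str | None = None  # landscape/filter cohort; default: first label
    level_filter: list[str] | None  # None = all levels, but must be stated
    alpha: float
    af_threshold: float
    ddi_vector_type: str = "hybrid"
    hybrid_keying: str = "role_gene"
    regimens: list[dict] | None = None  # [{"name": ..., "drugs": [...]}]
    seed: int

    @model_validator(mode="after")
    def _one_input_source(self) -> "PipelineConfig":
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be given")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0,1]")
        if not 0.0 <= self.af_threshold < 1.0:
            raise ValueError("af_threshold must be in [0,1)")
        if self.ddi_vector_type not in ddi_model.VECTOR_TYPES:
            raise ValueError(f"unknown ddi_vector_type {self.ddi_vector_type!r}")
        if self.level_filter is not None:
            bad = set(self.level_filter) - set(catalog_io.EVIDENCE_LEVELS)
            if bad:
                raise ValueError(f"unknown evidence level(s) in level_filter: {sorted(bad)}")
        return self


def _simulate_inputs(block: SimulationBlock, seed: int, runlog: list[str]):
    """Generate the full input set from the simulation block."""
    rng_seeds = {k: (seed * 1000 + i) % (2**31) for i, k in enumerate(
        ["pops", "catalog", "annotations", "deleterious", "diplotypes", "misc"])}
    cohorts, pop_truth = synthetic_data.simulate_populations(
        n_variants=block.n_variants, pop_sizes=block.pop_sizes,
        F=block.divergence_F, seed=rng_seeds["pops"],
    )
    group_cycle = ["cause_treatment", "corticoid", "antithrombotic", "superinfection",
                   "comorbidity_t2d", "comorbidity_cvd", "comorbidity_cancer"]
    drugs = [
        Drug(name=f"drug{i + 1:02d}", groups=(group_cycle[i % len(group_cycle)],))
        for i in range(block.n_drugs)
    ]
    names = [d.name for d in drugs]
    planted = [
        (names[2 * i % len(names)], names[(2 * i + 1) % len(names)])
        for i in range(block.n_planted_pairs)
        if names[2 * i % len(names)] != names[(2 * i + 1) % len(names)]
    ]
    catalog, cat_truth = synthetic_data.simulate_ctet_catalog(
        n_drugs=block.n_drugs, n_genes=block.n_genes, role_density=block.role_density,
        planted_pairs=planted, seed=rng_seeds["catalog"], drug_names=names,
    )
    study = sorted(cohorts)[0]
    per_drug = {n: block.annotations_per_drug for n in names[: block.n_annotated_drugs]}
    annotations, ann_truth = synthetic_data.simulate_annotations(
        drugs=drugs, cohort=cohorts[study], per_drug_counts=per_drug,
        level_mix=block.level_mix, seed=rng_seeds["annotations"],
    )
    variant_ids = [v.allele_id for v in cohorts[study].variants]
    genes = sorted(catalog.all_genes()) or ["GENE0001"]
    deleterious = synthetic_data.simulate_deleteriousness(
        variant_ids=variant_ids,
        genes=[genes[i % len(genes)] for i in range(len(variant_ids))],
        seed=rng_seeds["deleterious"],
    )
    diplotypes, dip_truth = synthetic_data.simulate_diplotypes(
        sample_ids=cohorts[study].samples,
        allele_freqs={"CYP2C19": {"*1": 0.65, "*2": 0.30, "*3": 0.05}},
        seed=rng_seeds["diplotypes"],
    )
    truth = synthetic_data.SimulationTruth(
        seed=seed,
        divergence_F=pop_truth.divergence_F,
        true_afs=pop_truth.true_afs,
        true_ddi_pairs=cat_truth.true_ddi_pairs,
        planted_carrier_counts=ann_truth.planted_carrier_counts,
        diplotype_afs=dip_truth.diplotype_afs,
    )
    runlog.append(f"simulated {block.n_variants} variants across {len(cohorts)} populations "
                  f"(F={block.divergence_F}), {len(drugs)} drugs, "
                  f"{len(catalog.entries)} catalog entries, {len(annotations)} annotations")
    return cohorts, drugs, catalog, annotations, deleterious, diplotypes, truth


def _load_inputs(paths: InputPaths, runlog: list[str]):
    drugs = catalog_io.read_drug_list(paths.drugs)
    catalog = catalog_io.read_ctet_catalog(paths.ctet_catalog, drugs)
    annotations = catalog_io.read_clinical_annotations(paths.clinical_annotations, drugs)
    deleterious = catalog_io.read_deleteriousness(paths.deleterious)
    diplotypes = catalog_io.read_diplotypes(paths.diplotypes) if paths.diplotypes else []
    full = cohort_io.read_vcf(paths.vcf)
    popmap = cohort_io.read_population_map(paths.popmap)
    cohorts = cohort_io.split_by_population(full, popmap)
    runlog.append(f"loaded {full.n_variants} variants, {full.n_samples} samples "
                  f"across {len(cohorts)} populations, {len(drugs)} drugs")
    return cohorts, drugs, catalog, annotations, deleterious, diplotypes, None


def _resolve_regimens(config: PipelineConfig, drugs: Sequence[Drug]) -> list[Regimen]:
    if config.regimens:
        known = {d.name for d in drugs}
        out = []
        for r in config.regimens:
            unknown = [d for d in r["drugs"] if d not in known]
            if unknown:
                raise ValueError(f"regimen {r['name']!r}: unresolvable drug(s) {unknown}")
            out.append(Regimen(name=r["name"], drugs=tuple(r["drugs"])))
        return out
    if config.inputs and config.inputs.regimens:
        return catalog_io.read_regimens(config.inputs.regimens, drugs)
    # default: one regimen per therapeutic group
    by_group: dict[str, list[str]] = {}
    for d in drugs:
        for g in d.groups:
            by_group.setdefault(g, []).append(d.name)
    return [Regimen(name=g, drugs=tuple(names)) for g, names in sorted(by_group.items())]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute every stage and write the report bundle into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog: list[str] = []
    bundle: dict[str, Path] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    record = {"stage": name, "error": str(exc)}
                    (outdir / "error.json").write_text(json.dumps(record, indent=1))
                    raise PipelineStageError(name, exc) from exc
                return False
        return _Ctx()

    with stage("inputs"):
        if config.simulate is not None:
            cohorts, drugs, catalog, annotations, deleterious, diplotypes, truth = \
                _simulate_inputs(config.simulate, config.seed, runlog)
        else:
            cohorts, drugs, catalog, annotations, deleterious, diplotypes, truth = \
                _load_inputs(config.inputs, runlog)
        if not drugs:
            raise ValueError("drug list is empty")
        if not cohorts:
            raise ValueError("no populations loaded")
        study = config.study_population or sorted(cohorts)[0]
        if study not in cohorts:
            raise ValueError(f"study population {study!r} not among {sorted(cohorts)}")
        if truth is not None:
            truth.to_json(outdir / "truth.json")
            bundle["truth"] = outdir / "truth.json"

    with stage("landscape"):
        summaries, no_info = pgx_landscape.landscape_table(
            cohorts[study], annotations, drugs, diplotypes,
            level_filter=config.level_filter,
        )
        _write_tsv(pgx_landscape.landscape_to_frame(summaries), outdir / "landscape.tsv")
        (outdir / "no_information_drugs.txt").write_text(
            "".join(f"{n}\n" for n in no_info)
        )
        bundle["landscape"] = outdir / "landscape.tsv"
        bundle["no_information_drugs"] = outdir / "no_information_drugs.txt"
        runlog.append(f"landscape: {len(summaries)} drugs summarised, "
                      f"{len(no_info)} without usable annotations "
                      f"(level filter: {config.level_filter})")

    with stage("af_compare"):
        af_tables = {p: cohort_io.allele_frequencies(c) for p, c in sorted(cohorts.items())}
        frames = []
        for pop, table in af_tables.items():
            if pop == study:
                continue
            frames.append(popgen_compare.compare_allele_frequencies(
                af_tables[study], table, alpha=config.alpha
            ))
        comparison = (pd.concat(frames, ignore_index=True)
                      if frames else pd.DataFrame())
        _write_tsv(comparison, outdir / "af_comparison.tsv")
        bundle["af_comparison"] = outdir / "af_comparison.tsv"
        n_sig = int(comparison["significant"].sum()) if "significant" in comparison else 0
        runlog.append(f"af_compare: {len(comparison)} tests vs {study}, "
                      f"{n_sig} significant at alpha={config.alpha}")

    with stage("fst"):
        if len(cohorts) >= 2:
            matrix = popgen_compare.fst_matrix([cohorts[p] for p in sorted(cohorts)])
            matrix.to_csv(outdir / "fst_matrix.tsv", sep="\t", float_format=_FLOAT_FMT,
                          index_label="population")
            _write_tsv(popgen_compare.fst_matrix_long(matrix), outdir / "fst_pairs.tsv")
            bundle["fst_matrix"] = outdir / "fst_matrix.tsv"
            bundle["fst_pairs"] = outdir / "fst_pairs.tsv"
            runlog.append(f"fst: {len(cohorts)}x{len(cohorts)} population matrix")
        else:
            runlog.append("fst: skipped (single population)")

    with stage("filter"):
        decisions = variant_filter.filter_candidates(
            deleterious, cohort_io.allele_frequencies(cohorts[study]),
            catalog, drugs, af_threshold=config.af_threshold,
        )
        _write_tsv(variant_filter.decisions_to_frame(decisions), outdir / "filter_decisions.tsv")
        bundle["filter_decisions"] = outdir / "filter_decisions.tsv"
        n_kept = sum(d.retained for d in decisions)
        runlog.append(f"filter: {n_kept}/{len(decisions)} variants retained "
                      f"(AF > {config.af_threshold})")

    with stage("ddi"):
        names = [d.name for d in drugs]
        results, dropped = ddi_model.detect_ddis(names, catalog, config.hybrid_keying)
        _write_tsv(ddi_model.ddi_results_to_frame(results), outdir / "ddi_pairs.tsv")
        bundle["ddi_pairs"] = outdir / "ddi_pairs.tsv"
        regimens = _resolve_regimens(config, drugs)
        rows = []
        for i, ra in enumerate(regimens):
            single = ddi_model.count_regimen_ddis(ra, None, catalog, config.hybrid_keying)
            rows.append({"regimen_a": ra.name, "regimen_b": "", "within_a": single.within_a,
                         "within_b": 0, "cross": 0, "union_count": single.union_count})
            for rb in regimens[i + 1:]:
                both = ddi_model.count_regimen_ddis(ra, rb, catalog, config.hybrid_keying)
                rows.append({"regimen_a": ra.name, "regimen_b": rb.name,
                             "within_a": both.within_a, "within_b": both.within_b,
                             "cross": both.cross, "union_count": both.union_count})
        _write_tsv(pd.DataFrame(rows, columns=["regimen_a", "regimen_b", "within_a",
                                               "within_b", "cross", "union_count"]),
                   outdir / "regimen_counts.tsv")
        bundle["regimen_counts"] = outdir / "regimen_counts.tsv"
        n_ddi = sum(r.is_ddi for r in results)
        runlog.append(f"ddi: {n_ddi} potential DDI pairs among {len(names) - len(dropped)} "
                      f"drugs ({len(dropped)} zero-vector drugs eliminated)")

    with stage("network"):
        g, degrees = ddi_model.build_drug_gene_network(catalog, [d.name for d in drugs])
        _write_tsv(ddi_model.network_edges_to_frame(g), outdir / "network_edges.tsv")
        _write_tsv(degrees, outdir / "network_nodes.tsv")
        bundle["network_edges"] = outdir / "network_edges.tsv"
        bundle["network_nodes"] = outdir / "network_nodes.tsv"
        runlog.append(f"network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")

    with stage("finalize"):
        (outdir / "run_log.txt").write_text("".join(f"{line}\n" for line in runlog))
        (outdir / "config_resolved.json").write_text(
            json.dumps(config.model_dump(), indent=1, sort_keys=True)
        )
        bundle["run_log"] = outdir / "run_log.txt"
        bundle["config"] = outdir / "config_resolved.json"
    return bundle


def generate_report(bundle_dir: str | Path) -> str:
    """Human-readable summary; every number is recomputed from bundle files."""
    bundle_dir = Path(bundle_dir)
    required = ["landscape.tsv", "no_information_drugs.txt", "filter_decisions.tsv",
                "ddi_pairs.tsv", "regimen_counts.tsv", "network_nodes.tsv",
                "config_resolved.json"]
    for name in required:
        if not (bundle_dir / name).exists():
            raise FileNotFoundError(f"bundle member missing: {name}")
    landscape = pd.read_csv(bundle_dir / "landscape.tsv", sep="\t")
    no_info = [l for l in (bundle_dir / "no_information_drugs.txt").read_text().splitlines() if l]
    decisions = pd.read_csv(bundle_dir / "filter_decisions.tsv", sep="\t")
    ddi = pd.read_csv(bundle_dir / "ddi_pairs.tsv", sep="\t")
    regimens = pd.read_csv(bundle_dir / "regimen_counts.tsv", sep="\t", keep_default_na=False)
    lines = ["# Pipeline report", ""]
    lines.append(f"Drugs with annotation-based landscape: {len(landscape)}")
    lines.append(f"Drugs without pharmacogenomic information: {len(no_info)}")
    if len(landscape):
        top = landscape.sort_values(["median", "drug"], ascending=[False, True]).iloc[0]
        lines.append(f"Highest median risk-variant count: {top['drug']} "
                     f"({top['median']:g}; range {int(top['min'])}-{int(top['max'])})")
    lines.append(f"Candidate variants retained by the deleteriousness filter: "
                 f"{int(decisions['retained'].sum())} of {len(decisions)}")
    n_pairs = len(ddi)
    n_ddi = int(ddi["is_ddi"].sum()) if n_pairs else 0
    lines.append(f"Potential DDI pairs: {n_ddi} of {n_pairs} scored pairs")
    fst_path = bundle_dir / "fst_pairs.tsv"
    if fst_path.exists():
        fst = pd.read_csv(fst_path, sep="\t")
        if len(fst):
            top = fst.sort_values(["weighted_fst", "pop_a", "pop_b"],
                                  ascending=[False, True, True]).iloc[0]
            lines.append(f"Most differentiated population pair: "
                         f"{top['pop_a']} vs {top['pop_b']} "
                         f"(weighted Fst {top['weighted_fst']:.4f})")
    lines.append("")
    lines.append("Regimen DDI counts (within_a + within_b + cross = union):")
    for r in regimens.itertuples(index=False):
        pair = f"{r.regimen_a}" + (f" + {r.regimen_b}" if r.regimen_b else "")
        lines.append(f"  {pair}: {r.within_a} + {r.within_b} + {r.cross} = {r.union_count}")
    return "".join(f"{l}\n" for l in lines)
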