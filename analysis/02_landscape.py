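"""Per-drug pharmacogenomic risk landscape of the study cohort.

For every drug with clinical annotations, counts the annotated risk
variants each study individual carries and summarises the distribution
(median, range, quartiles, carrier fraction) — the tabular form of the
violin-plot view of per-drug genetic risk. Drugs with no usable annotation
are listed separately.

Run after 01_simulate_inputs.py:  python analysis/02_landscape.py
"""

from pathlib import Path

from pgxddi import catalog_io, cohort_io, pgx_landscape

IN = Path("results/inputs")
OUT = Path("results")

# All evidence levels enter this landscape; rerun with e.g. {"1A","1B","2A","2B"}
# to restrict to actionable annotations.
LEVEL_FILTER = None


def main() -> None:
    drugs = catalog_io.read_drug_list(IN / "drugs.tsv")
    annotations = catalog_io.read_clinical_annotations(IN / "clinical_annotations.tsv", drugs)
    diplotypes = catalog_io.read_diplotypes(IN / "diplotypes.tsv")
    cohorts = cohort_io.split_by_population(
        cohort_io.read_vcf(IN / "cohort.vcf"),
        cohort_io.read_population_map(IN / "populations.tsv"),
    )
    study = cohorts["STUDY"]
    summaries, no_info = pgx_landscape.landscape_table(
        study, annotations, drugs, diplotypes, level_filter=LEVEL_FILTER
    )
    frame = pgx_landscape.landscape_to_frame(summaries)
    frame.to_csv(OUT / "landscape.tsv", sep="\t", index=False)
    (OUT / "no_information_drugs.txt").write_text("".join(f"{n}\n" for n in no_info))

    print(f"{len(summaries)} drugs summarised over {study.n_samples} individuals; "
          f"{len(no_info)}/{len(drugs)} drugs without pharmacogenomic information")
    top = frame.sort_values(["median", "drug"], ascending=[False, True]).head(3)
    for r in top.itertuples(index=False):
        print(f"  {r.drug}: median {r.median:g} (range {r.min}-{r.max}), "
              f"carrier fraction {r.carrier_fraction:.2f}")
    print(f"wrote {OUT}/landscape.tsv")


if __name__ == "__main__":
    main()
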