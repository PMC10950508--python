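"""Candidate deleterious variants beyond the clinically annotated set.

Screens every variant with predictor calls through the four-way rule:
nonsynonymous exonic, gene encodes a CTET element of a listed drug, called
damaging by at least two of SIFT / PolyPhen-2 / MutationTaster, and study
cohort allele frequency strictly above 1%. Each variant gets a full
decision row so the filter is auditable flag by flag.

Run after 01_simulate_inputs.py:  python analysis/04_filter_candidates.py
"""

from pathlib import Path

from pgxddi import catalog_io, cohort_io, variant_filter

IN = Path("results/inputs")
OUT = Path("results")
AF_THRESHOLD = 0.01


def main() -> None:
    drugs = catalog_io.read_drug_list(IN / "drugs.tsv")
    catalog = catalog_io.read_ctet_catalog(IN / "ctet_catalog.tsv", drugs)
    deleterious = catalog_io.read_deleteriousness(IN / "deleterious.tsv")
    cohorts = cohort_io.split_by_population(
        cohort_io.read_vcf(IN / "cohort.vcf"),
        cohort_io.read_population_map(IN / "populations.tsv"),
    )
    af = cohort_io.allele_frequencies(cohorts["STUDY"])
    decisions = variant_filter.filter_candidates(
        deleterious, af, catalog, drugs, af_threshold=AF_THRESHOLD
    )
    frame = variant_filter.decisions_to_frame(decisions)
    frame.to_csv(OUT / "filter_decisions.tsv", sep="\t", index=False)

    kept = frame[frame["retained"]]
    print(f"{len(kept)}/{len(frame)} variants retained "
          f"(class AND CTET gene AND >=2 damaging votes AND AF > {AF_THRESHOLD})")
    for col in ("passed_class", "passed_gene", "passed_votes", "passed_af"):
        print(f"  {col}: {int(frame[col].sum())}/{len(frame)}")
    print(f"wrote {OUT}/filter_decisions.tsv")


if __name__ == "__main__":
    main()
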