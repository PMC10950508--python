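"""Cross-population comparison of the pharmacogenomic variant set.

Two views of population differentiation over the annotated variants:
per-variant two-sided Fisher exact tests on allele counts (study cohort vs
each comparison population), and the pairwise weighted Weir-Cockerham Fst
matrix across all populations. Since the cohorts were simulated at a known
divergence F, the recovered Fst values should sit near F.

Run after 01_simulate_inputs.py:  python analysis/03_population_comparison.py
"""

import json
from pathlib import Path

import pandas as pd

from pgxddi import catalog_io, cohort_io, popgen_compare

IN = Path("results/inputs")
OUT = Path("results")
ALPHA = 0.05


def main() -> None:
    cohorts = cohort_io.split_by_population(
        cohort_io.read_vcf(IN / "cohort.vcf"),
        cohort_io.read_population_map(IN / "populations.tsv"),
    )
    drugs = catalog_io.read_drug_list(IN / "drugs.tsv")
    annotations = catalog_io.read_clinical_annotations(IN / "clinical_annotations.tsv", drugs)
    annotated = sorted({a.allele_id for a in annotations if a.allele_type == "snp"})

    af = {p: cohort_io.allele_frequencies(c) for p, c in cohorts.items()}
    study_af = af["STUDY"][af["STUDY"]["allele_id"].isin(annotated)]
    frames = []
    for pop in sorted(cohorts):
        if pop == "STUDY":
            continue
        other = af[pop][af[pop]["allele_id"].isin(annotated)]
        frames.append(popgen_compare.compare_allele_frequencies(study_af, other, alpha=ALPHA))
    comparison = pd.concat(frames, ignore_index=True)
    comparison.to_csv(OUT / "af_comparison.tsv", sep="\t", index=False)

    matrix = popgen_compare.fst_matrix(
        [cohorts[p] for p in sorted(cohorts)], variant_subset=annotated
    )
    matrix.to_csv(OUT / "fst_matrix.tsv", sep="\t", index_label="population")

    truth = json.loads((IN / "truth.json").read_text())
    n_sig = int(comparison["significant"].sum())
    print(f"{n_sig}/{len(comparison)} allele-frequency tests significant at "
          f"alpha={ALPHA} over {len(annotated)} annotated variants")
    print(f"weighted Fst matrix (simulated divergence F={truth['divergence_F']}):")
    print(matrix.round(4).to_string())
    print(f"wrote {OUT}/af_comparison.tsv and {OUT}/fst_matrix.tsv")


if __name__ == "__main__":
    main()
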