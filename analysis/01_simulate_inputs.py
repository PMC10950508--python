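"""Generate the synthetic study inputs for the downstream analyses.

Emulates the shape of a population-pharmacogenomics study: one study cohort
plus comparison populations diverged by a known F, a drug list spanning the
therapeutic groups, a drug->CTET gene catalog with planted interacting
pairs, clinical annotations tied to real cohort variants, deleteriousness
predictions and star-allele diplotypes. Everything is written in the
standard file formats under results/inputs/, with a truth.json sidecar
recording the planted ground truth.

Run:  python analysis/01_simulate_inputs.py [seed]
"""

import sys
from pathlib import Path

from pgxddi import synthetic_data
from pgxddi.catalog_io import Drug

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240925
OUT = Path("results/inputs")

# Study conditions: a study population (VN1K-like, scaled down) and two
# comparison populations at moderate continental-scale divergence.
N_VARIANTS = 400
POP_SIZES = {"STUDY": 160, "POP_EAST": 120, "POP_WEST": 120}
DIVERGENCE_F = 0.05

N_DRUGS, N_GENES = 20, 60
ROLE_DENSITY = 0.03
N_ANNOTATED_DRUGS, ANNOTATIONS_PER_DRUG = 14, 8
LEVEL_MIX = {"1A": 0.1, "1B": 0.1, "2A": 0.2, "2B": 0.2, "3": 0.2, "4": 0.2}

GROUPS = ["cause_treatment", "corticoid", "antithrombotic", "superinfection",
          "comorbidity_t2d", "comorbidity_cvd", "comorbidity_cancer"]


def main() -> None:
    cohorts, pop_truth = synthetic_data.simulate_populations(
        N_VARIANTS, POP_SIZES, DIVERGENCE_F, seed=SEED
    )
    drugs = [Drug(f"drug{i + 1:02d}", (GROUPS[i % len(GROUPS)],)) for i in range(N_DRUGS)]
    names = [d.name for d in drugs]
    planted = [(names[0], names[5]), (names[2], names[9]), (names[4], names[13])]
    catalog, cat_truth = synthetic_data.simulate_ctet_catalog(
        N_DRUGS, N_GENES, ROLE_DENSITY, planted, seed=SEED + 1, drug_names=names
    )
    annotations, ann_truth = synthetic_data.simulate_annotations(
        drugs, cohorts["STUDY"],
        {n: ANNOTATIONS_PER_DRUG for n in names[:N_ANNOTATED_DRUGS]},
        LEVEL_MIX, seed=SEED + 2,
    )
    variant_ids = [v.allele_id for v in cohorts["STUDY"].variants]
    genes = sorted(catalog.all_genes())
    deleterious = synthetic_data.simulate_deleteriousness(
        variant_ids, [genes[i % len(genes)] for i in range(len(variant_ids))],
        seed=SEED + 3,
    )
    diplotypes, dip_truth = synthetic_data.simulate_diplotypes(
        cohorts["STUDY"].samples,
        {"CYP2C19": {"*1": 0.65, "*2": 0.30, "*3": 0.05}},
        seed=SEED + 4,
    )
    truth = synthetic_data.SimulationTruth(
        seed=SEED, divergence_F=DIVERGENCE_F, true_afs=pop_truth.true_afs,
        true_ddi_pairs=cat_truth.true_ddi_pairs,
        planted_carrier_counts=ann_truth.planted_carrier_counts,
        diplotype_afs=dip_truth.diplotype_afs,
    )
    paths = synthetic_data.write_simulated_inputs(
        OUT, cohorts, drugs, catalog, annotations, deleterious, diplotypes, truth
    )
    print(f"seed {SEED}: wrote {len(paths)} input files under {OUT}/")
    print(f"  {N_VARIANTS} variants x {sum(POP_SIZES.values())} samples "
          f"in {len(POP_SIZES)} populations (F={DIVERGENCE_F})")
    print(f"  {len(catalog.entries)} catalog entries; "
          f"{len(cat_truth.true_ddi_pairs)} truly interacting drug pairs")
    print(f"  {len(annotations)} clinical annotations across "
          f"{N_ANNOTATED_DRUGS}/{N_DRUGS} drugs")


if __name__ == "__main__":
    main()
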