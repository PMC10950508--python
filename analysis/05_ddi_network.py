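"""Drug-drug interaction prediction and the drug-gene network.

Builds the five binary CTET vectors per drug, scores every surviving pair
with Russell-Rao similarity, flags potential DDIs (hybrid S > 0), counts
DDI pairs within and across the therapeutic-group regimens (the
comorbidity-style table: adding a second condition's drugs inflates the
interaction count), and exports the bipartite drug-gene network. Predicted
pairs are checked against the generator's planted interaction truth.

Run after 01_simulate_inputs.py:  python analysis/05_ddi_network.py
"""

import json
from pathlib import Path

import pandas as pd

from pgxddi import catalog_io, ddi_model
from pgxddi.catalog_io import Regimen

IN = Path("results/inputs")
OUT = Path("results")


def main() -> None:
    drugs = catalog_io.read_drug_list(IN / "drugs.tsv")
    catalog = catalog_io.read_ctet_catalog(IN / "ctet_catalog.tsv", drugs)
    names = [d.name for d in drugs]

    results, dropped = ddi_model.detect_ddis(names, catalog)
    ddi_model.ddi_results_to_frame(results).to_csv(OUT / "ddi_pairs.tsv", sep="\t", index=False)
    flagged = {frozenset((r.drug_a, r.drug_b)) for r in results if r.is_ddi}
    truth = json.loads((IN / "truth.json").read_text())
    true_pairs = {frozenset(p) for p in truth["true_ddi_pairs"]}
    print(f"{len(flagged)} potential DDI pairs among {len(names) - len(dropped)} drugs "
          f"({len(dropped)} zero-vector drugs eliminated)")
    print(f"agreement with planted truth: {'exact' if flagged == true_pairs else 'MISMATCH'}")

    by_group: dict[str, list[str]] = {}
    for d in drugs:
        for g in d.groups:
            by_group.setdefault(g, []).append(d.name)
    regimens = [Regimen(g, tuple(ns)) for g, ns in sorted(by_group.items())]
    rows = []
    covid = next(r for r in regimens if r.name == "cause_treatment")
    for other in regimens:
        if other.name == covid.name:
            single = ddi_model.count_regimen_ddis(other, None, catalog)
            rows.append({"condition": other.name, "alone": single.union_count,
                         "with_covid_drugs": single.union_count})
            continue
        alone = ddi_model.count_regimen_ddis(other, None, catalog)
        combined = ddi_model.count_regimen_ddis(other, covid, catalog)
        rows.append({"condition": other.name, "alone": alone.union_count,
                     "with_covid_drugs": combined.union_count})
    table = pd.DataFrame(rows, columns=["condition", "alone", "with_covid_drugs"])
    table.to_csv(OUT / "regimen_counts.tsv", sep="\t", index=False)
    print("DDI burden per condition regimen (alone -> plus antiviral drugs):")
    for r in table.itertuples(index=False):
        print(f"  {r.condition}: {r.alone} -> {r.with_covid_drugs}")

    g, degrees = ddi_model.build_drug_gene_network(catalog, names)
    ddi_model.network_edges_to_frame(g).to_csv(OUT / "network_edges.tsv", sep="\t", index=False)
    degrees.to_csv(OUT / "network_nodes.tsv", sep="\t", index=False)
    hubs = degrees[degrees["kind"] == "gene"].nlargest(3, "degree")
    print("most shared pharmacogenes: "
          + ", ".join(f"{r.name} (degree {r.degree})" for r in hubs.itertuples(index=False)))
    print(f"wrote {OUT}/ddi_pairs.tsv, regimen_counts.tsv, network_edges.tsv, network_nodes.tsv")


if __name__ == "__main__":
    main()
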