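"""Shared fixtures: tiny hand-built inputs with known properties."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pgxddi.catalog_io import Drug, DrugGeneCatalog
from pgxddi.cohort_io import MISSING, CohortGenotypes, VariantKey


def fisher_oracle(table, tie_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums point probabilities of every table with the observed margins whose
    probability is no larger than the observed table's (with a small
    relative tolerance for floating-point ties). Independent of any library
    implementation.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)

    def point(k: int) -> float:
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p for k in range(lo, hi + 1) if (p := point(k)) <= p_obs * (1 + tie_tol))


def make_cohort(dosages, population="pop", rsids=None) -> CohortGenotypes:
    """Cohort from a samples x variants dosage list (None -> missing)."""
    arr = np.array(
        [[MISSING if g is None else g for g in row] for row in dosages], dtype=np.int8
    )
    n_samples, n_variants = arr.shape
    variants = [
        VariantKey(chrom="1", pos=100 + 10 * j, ref="A", alt="G",
                   rsid=(rsids[j] if rsids else f"rs{j + 1}"))
        for j in range(n_variants)
    ]
    return CohortGenotypes(
        population=population,
        samples=[f"{population}_s{i}" for i in range(n_samples)],
        variants=variants,
        dosage=arr,
    )


@pytest.fixture
def two_drugs() -> list[Drug]:
    return [
        Drug(name="warfarin", groups=("antithrombotic",)),
        Drug(name="ritonavir", groups=("cause_treatment",)),
    ]


@pytest.fixture
def small_catalog() -> DrugGeneCatalog:
    return DrugGeneCatalog(entries=frozenset({
        ("warfarin", "enzyme", "CYP2C9"),
        ("warfarin", "target", "VKORC1"),
        ("ritonavir", "enzyme", "CYP3A4"),
        ("ritonavir", "transporter", "ABCB1"),
        ("warfarin", "enzyme", "CYP3A4"),  # shared with ritonavir -> DDI
    }))


TINY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=MT>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t./.\t1/1
1\t300\trs3\tG\tA,C\t.\t.\t.\tGT\t0/1\t0/2\t0/0
1\t400\trs4\tT\tTA\t.\t.\t.\tGT\t0/0\t0/1\t0/0
MT\t500\trs5\tA\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/1
1\t600\trs6\tG\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(TINY_VCF)
    return p
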