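import numpy as np
import pandas as pd
import pytest

from isomirdisp.reference_io import (
    Hairpin,
    MatureAnnotation,
    ReferenceBundle,
    VariantRecord,
)

# Hand-constructed hairpin: 10 nt upstream, a 22-nt mature at [10, 32),
# 28 nt downstream. The downstream continuation starts with "TC".
UPSTREAM = "ACGTACGTAC"
MATURE_SEQ = "TGAGGTAGTAGGTTGTATAGTT"  # A at mature positions 3, 7, 9, 10, 18
DOWNSTREAM = "TCCTGCGGAAGCTAGGAGGCCTGCAGTG"
HAIRPIN_SEQ = UPSTREAM + MATURE_SEQ + DOWNSTREAM


@pytest.fixture(scope="session")
def toy_bundle() -> ReferenceBundle:
    hp = Hairpin(id="hp1", sequence=HAIRPIN_SEQ, chrom="chr19",
                 genome_start=13836509)
    mature = MatureAnnotation(
        name="miR-X-3p", hairpin_id="hp1", start=10, end=32, arm="3p"
    )
    variants = (
        VariantRecord("miR-X-3p", 3, "A", "G", "EDITING"),
        VariantRecord("miR-X-3p", 10, "A", "C", "SNP"),
        VariantRecord("miR-X-3p", 12, "G", "T", "SOMATIC"),
    )
    return ReferenceBundle(
        hairpins={"hp1": hp}, matures={"miR-X-3p": mature}, variants=variants
    )


@pytest.fixture()
def four_group_design():
    def make(n_per_group=4):
        design = {}
        for g in ("W_N", "W_T", "BAA_N", "BAA_T"):
            for k in range(n_per_group):
                design[f"{g}_{k}"] = g
        return design

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_counts(rng):
    from isomirdisp.quantify import CountMatrix

    counts = rng.negative_binomial(5, 0.05, size=(50, 6))
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"iso-{i:03d}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
    )
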