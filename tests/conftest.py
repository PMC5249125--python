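import numpy as np
import pytest

from barcodeaudit import BarcodeLibrary, SpecimenRecord


def make_library(seqs, labels=None, divisions=None):
    """Small helper: build a library from parallel lists."""
    labels = labels or [f"Sp a{i}" for i in range(len(seqs))]
    divisions = divisions or [""] * len(seqs)
    records = [
        SpecimenRecord(
            specimen_id=f"S{i + 1}",
            sequence=s,
            morph_label=lab,
            division=div,
        )
        for i, (s, lab, div) in enumerate(zip(seqs, labels, divisions))
    ]
    return BarcodeLibrary(records, alignment_length=len(seqs[0]))


@pytest.fixture
def two_species_library():
    """Two clearly separated species, three specimens each."""
    base_a = "ACGTAC" * 10
    base_b = "TGCATG" * 10
    seqs = [base_a, base_a, base_a[:-1] + "A", base_b, base_b, base_b[:-1] + "C"]
    labels = ["Genus alpha"] * 3 + ["Genus beta"] * 3
    return make_library(seqs, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
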