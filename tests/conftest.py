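import numpy as np
import pytest

from heatmir.simdata import (
    ExpressionTruth,
    LibraryDesign,
    plant_hairpin,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_genome():
    seq, chrom = simulate_genome(5000, 0.4, 7)
    return {chrom: seq}


@pytest.fixture(scope="session")
def planted_small():
    """A 5-kb genome with one planted 5p hairpin at position 500."""
    genome, _ = simulate_genome(5000, 0.4, 7)
    mature = "TGACAGAAGAGAGTGAGCACA"
    genome, hp = plant_hairpin(genome, mature, 500, "5p", seed=11)
    return genome, hp


@pytest.fixture
def two_designs():
    return [
        LibraryDesign(
            library_id=f"stamen_{cond}_2d_r1",
            tissue="stamen",
            condition=cond,
            timepoint="2d",
            replicate=1,
            depth=2000,
            contaminant_fraction=0.0,
        )
        for cond in ("CK", "HS")
    ]


def make_truth(hairpins, designs, tpm=500.0, fc=1.0):
    expected = {}
    true_fc = {}
    for h in hairpins:
        for d in designs:
            t = tpm * (fc if d.condition == "HS" else 1.0)
            expected[(h.locus_id, d.library_id)] = t
        for tissue in ("stamen", "pistil"):
            for tp in ("2d", "12d"):
                true_fc[(h.locus_id, tissue, tp)] = fc
    return ExpressionTruth(expected_tpm=expected, true_fc=true_fc)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
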