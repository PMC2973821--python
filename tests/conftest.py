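import numpy as np
import pytest

from divsel import (
    GenotypePanel,
    MarkerMap,
    SweepSpec,
    SynthConfig,
    generate_dataset,
)


@pytest.fixture
def toy_map() -> MarkerMap:
    return MarkerMap(
        snp_id=np.array(["s1", "s2", "s3"], dtype=object),
        chromosome=np.array(["1", "1", "2"], dtype=object),
        position_bp=np.array([1_000_000, 1_500_000, 500_000]),
        cm_per_mb={"1": 3.0, "2": 10.0},
        ref_allele=np.array(["A", "C", "G"], dtype=object),
        alt_allele=np.array(["G", "T", "A"], dtype=object),
    )


@pytest.fixture
def toy_panel(toy_map) -> GenotypePanel:
    return GenotypePanel(
        sample_ids=["h1", "h2", "l1", "l2"],
        line=np.array(["HIGH", "HIGH", "LOW", "LOW"], dtype=object),
        generation=np.array([40, 40, 40, 40]),
        genotypes=np.array(
            [[2, 1, 0],
             [2, -1, 1],
             [0, 0, 2],
             [0, 1, 2]], dtype=np.int8),
        snp_ids=["s1", "s2", "s3"],
    )


@pytest.fixture(scope="session")
def sweep_dataset():
    """Small panel with one sweep fixed by generation 40 (no escapes at core)."""
    cfg = SynthConfig(
        n_snps=800,
        sweeps=[
            SweepSpec(chromosome="1", center_bp=2_000_000, half_width_bp=200_000,
                      line_favoured="HIGH", fixation_generation=40),
        ],
        seed=11,
    )
    return cfg, generate_dataset(cfg)
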