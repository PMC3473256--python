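import dataclasses

import pytest

from twindiff import pipeline
from twindiff.core import ReferenceGenome
from twindiff.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(default_cfg):
    """Default simulated twin bundle (with unmapped reads)."""
    return simulate_bundle(default_cfg)


@pytest.fixture(scope="session")
def bundle_noreads(default_cfg):
    return simulate_bundle(default_cfg, with_reads=False)


@pytest.fixture(scope="session")
def calibration():
    """SomaticScore calibration from an independent simulation seed."""
    return pipeline.build_calibration(pipeline.PipelineConfig(seed=1))


@pytest.fixture()
def tiny_ref() -> ReferenceGenome:
    """A handmade 60 bp contig for constructed superlocus tests."""
    seq = "ACGTACGTTGCAGGCTTAACCGGATCCATGGTACTAAGATCCTAGCATGCAAGGTTCCAA"
    return ReferenceGenome(
        contigs={"chr1": seq}, contig_class={"chr1": "autosome"}
    )
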