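import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from methylosip.io_tables import FractionMeta, OtuTable, PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_table() -> OtuTable:
    return OtuTable(
        taxon_ids=["A", "B", "C"],
        sample_ids=["s1", "s2", "s3", "s4", "s5", "s6"],
        counts=np.array(
            [
                [50, 10, 40, 12, 30, 20],
                [30, 60, 35, 55, 40, 50],
                [20, 30, 25, 33, 30, 30],
            ]
        ),
    )


def minimal_meta() -> list[FractionMeta]:
    """Two gradients (13C treatment + 12C control), heavy and light each."""

    def frac(sid, iso, gid, idx, bd):
        return FractionMeta(
            sample_id=sid, isotope=iso, gradient_id=gid, fraction_index=idx,
            buoyant_density=bd, compartment="phyllosphere", timepoint_h=8.0,
            species="T_officinale",
        )

    return [
        frac("s1", "C13", "g13", 1, 1.805),
        frac("s2", "C13", "g13", 2, 1.770),
        frac("s3", "C12", "g12", 1, 1.805),
        frac("s4", "C12", "g12", 2, 1.770),
        frac("s5", "C13", "g13", 3, 1.815),
        frac("s6", "C12", "g12", 3, 1.775),
    ]


@pytest.fixture
def paired_meta() -> list[FractionMeta]:
    return minimal_meta()
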