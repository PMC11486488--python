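import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from monolens import synthetic_data as synth
from monolens.dosage import CountsTable


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    """Four equal-length genes on two chromosomes plus two spikes."""
    return pd.DataFrame(
        {
            "chrom": ["I", "I", "II", "II", "spike", "spike"],
            "start": [1, 1001, 1, 1001, 1, 1],
            "end": [500, 1500, 500, 1500, 300, 300],
            "length": [500, 500, 500, 500, 300, 300],
            "is_spike": [False, False, False, False, True, True],
            "is_rp": [False] * 6,
        },
        index=pd.Index(
            ["gA", "gB", "gC", "gD", "ERCC-1", "ERCC-2"], name="gene_id"
        ),
    )


@pytest.fixture
def tiny_counts(tiny_annotation) -> CountsTable:
    counts = pd.DataFrame(
        {
            "ctrl": [100, 100, 100, 100, 10, 10],
            "mono": [50, 50, 100, 100, 10, 10],
        },
        index=tiny_annotation.index,
    )
    return CountsTable(
        counts=counts,
        annotation=tiny_annotation,
        conditions={"ctrl": "control", "mono": "monosomic:I"},
    )


@pytest.fixture
def genome_annotation() -> pd.DataFrame:
    """Full 16-chromosome synthetic annotation, fixed seed."""
    return synth.make_annotation(seed=11)


def make_noiseless_curve(dr=1.0, a=0.05, blank=0.0, t_end=5.0, dt=0.5, k=1.6):
    """Exponential-with-ceiling OD curve, no noise (shared helper)."""
    from monolens.growth import GrowthCurve

    t = np.arange(0.0, t_end + dt / 2, dt)
    od = blank + a * np.minimum(np.exp2(dr * t), k / a)
    return GrowthCurve(
        plate_id="P1",
        well="B2",
        strain_id="s",
        well_class="test",
        times=t,
        od=od,
    )
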