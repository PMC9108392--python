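import numpy as np
import pytest

from causalmr import HarmonizedSet


def make_harmonized(bx, by, sex=0.01, sey=0.02, eaf=0.3, outcome_type="continuous",
                    **kwargs):
    """Small helper: build a HarmonizedSet from plain lists."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    k = bx.size
    return HarmonizedSet(
        exposure_name=kwargs.pop("exposure_name", "exposure"),
        outcome_name=kwargs.pop("outcome_name", "outcome"),
        snp_ids=kwargs.pop("snp_ids", [f"rs{i}" for i in range(k)]),
        bx=bx, sex=np.broadcast_to(np.asarray(sex, dtype=float), (k,)).copy(),
        by=by, sey=np.broadcast_to(np.asarray(sey, dtype=float), (k,)).copy(),
        eaf_x=np.broadcast_to(np.asarray(eaf, dtype=float), (k,)).copy(),
        outcome_type=outcome_type,
        **kwargs,
    )


@pytest.fixture
def toy_a():
    """Exact proportionality: by = 0.5 * bx, equal outcome SEs."""
    return make_harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], sey=0.02)


@pytest.fixture
def toy_b():
    """Heterogeneous ratios 0.5 / 0.6 / 0.3 with equal outcome SEs."""
    return make_harmonized([0.1, 0.2, 0.3], [0.05, 0.12, 0.09], sey=0.02)
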