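"""Shared fixtures: small seeded cohorts and single-sample param tables."""

import numpy as np
import pandas as pd
import pytest

from nmrprep import CohortSpec, FidSet, simulate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_samples=3, seed=42, td=2048)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """(FidSet, AcqusTable, GroundTruthLedger) for a tiny seeded cohort."""
    return simulate_cohort(small_spec)


@pytest.fixture
def make_params():
    """Factory for a minimal single/multi-sample acqus table."""

    def _make(sample_ids=("s0",), sw_h=7201.56, sfo1=600.13, o1=2820.611,
              **extra):
        rows = {sid: {"SW_h": sw_h, "SFO1": sfo1, "O1": o1, **extra}
                for sid in sample_ids}
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "sample_id"
        return table

    return _make


@pytest.fixture
def make_fidset():
    def _make(rows, sw_h=7201.56, ids=None):
        rows = np.atleast_2d(np.asarray(rows, dtype=np.complex128))
        ids = ids or [f"s{i}" for i in range(rows.shape[0])]
        return FidSet(rows, 1.0 / sw_h, ids)

    return _make
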