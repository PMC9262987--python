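"""Shared fixtures: one default synthetic experiment reused across the
suite (session-scoped; generation plus the three contrasts takes a few
seconds) and small handcrafted contrast tables for the rule-level tests."""

import numpy as np
import pandas as pd
import pytest

import adipomir as am

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_sim():
    """Default-design synthetic experiment with planted truth."""
    spec = am.SimulationSpec(seed=DEFAULT_SEED)
    cm, truth = am.generate_counts(spec)
    return spec, cm, truth


@pytest.fixture(scope="session")
def default_contrasts(default_sim):
    _, cm, _ = default_sim
    return am.call_standard_contrasts(cm)


@pytest.fixture(scope="session")
def default_categories(default_contrasts):
    return am.classify_dems(default_contrasts["L_Ag"], default_contrasts["O_Ag"])


def make_contrast(records: dict, contrast: str = "test",
                  q_threshold: float = 0.01) -> am.ContrastResult:
    """Build a ContrastResult from {mirna_id: (log2fc, qvalue)} pairs."""
    idx = list(records)
    fc = np.array([records[m][0] for m in idx], dtype=float)
    q = np.array([records[m][1] for m in idx], dtype=float)
    sig = np.nan_to_num(q, nan=1.0) < q_threshold
    direction = np.where(sig & (fc > 0), "up",
                         np.where(sig & (fc < 0), "down", "none"))
    table = pd.DataFrame(
        {
            "base_mean": np.full(len(idx), 100.0),
            "log2fc": fc,
            "se": np.full(len(idx), 0.1),
            "pvalue": q / 2,
            "qvalue": q,
            "direction": direction,
        },
        index=pd.Index(idx, name="mirna_id"),
    )
    return am.ContrastResult(contrast=contrast, table=table,
                             q_threshold=q_threshold)
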