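"""Shared fixtures: small synthetic populations and random feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgbp.features import build_feature_table, feature_names
from ppgbp.population import PopulationConfig, generate_population


@pytest.fixture(scope="session")
def cohort_config():
    """Short-recording study cohort: 56 subjects, one 30 s segment each."""
    return PopulationConfig(seed=7, duration=30.0)


@pytest.fixture(scope="session")
def cohort(cohort_config):
    params, recordings = generate_population(cohort_config)
    return params, recordings


@pytest.fixture(scope="session")
def table56(cohort):
    """Segment-level feature table: 56 rows (one per subject)."""
    _, recordings = cohort
    return build_feature_table(recordings)


@pytest.fixture(scope="session")
def table224():
    """Larger table for model evaluation: 56 subjects x 4 segments (45 s)."""
    cfg = PopulationConfig(seed=11, duration=45.0)
    _, recordings = generate_population(cfg)
    return build_feature_table(recordings)


def random_feature_table(
    n: int, p: int, seed: int, target_from: int | None = 0
) -> pd.DataFrame:
    """A random table with ``p`` canonical feature columns, both BP targets
    and a 4-level category column (balanced).  If ``target_from`` is an
    int, sbp_ref is that feature plus noise; if None, targets are
    independent noise."""
    rng = np.random.default_rng(seed)
    names = feature_names()[:p]
    data = {f: rng.normal(size=n) for f in names}
    df = pd.DataFrame(data)
    df["subject_id"] = [f"S{i:03d}" for i in range(n)]
    df["segment_index"] = 0
    if target_from is None:
        df["sbp_ref"] = 120 + 10 * rng.normal(size=n)
    else:
        df["sbp_ref"] = 120 + 10 * df[names[target_from]] + rng.normal(size=n)
    df["dbp_ref"] = df["sbp_ref"] - 40 + rng.normal(size=n)
    cats = ["normal", "elevated", "stage1", "stage2"]
    df["category"] = [cats[i % 4] for i in range(n)]
    return df
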