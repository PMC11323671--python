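"""Shared fixtures: small cohorts, fast training configs, tiny datasets."""

from __future__ import annotations

import pandas as pd
import pytest

import ehrsyneval as ev
from ehrsyneval.models import TrainConfig


@pytest.fixture(scope="session")
def schema():
    return ev.default_schema()


@pytest.fixture(scope="session")
def tiny_dataset(schema):
    """Three hand-built patients with sequence lengths 5, 6, 7."""
    static = pd.DataFrame(
        {
            "age": [50.0, 60.0, 70.0],
            "gender": ["M", "F", "F"],
            "race": ["white", "black", "unknown"],
            "deceased": ["no", "no", "yes"],
        },
        index=pd.Index(["a", "b", "c"], name="patient_id"),
    )
    sequences = {
        "a": ["circulatory"] * 5,
        "b": ["circulatory", "respiratory", "digestive", "circulatory", "mental", "injury"],
        "c": ["endocrine"] * 7,
    }
    return ev.LongitudinalDataset(schema=schema, static=static, sequences=sequences)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient default cohort shared across cheap tests."""
    return ev.generate_cohort(ev.default_config(300), seed=42)


@pytest.fixture(scope="session")
def large_cohort():
    """A 5000-patient default cohort for sampling-oracle checks."""
    return ev.generate_cohort(ev.default_config(5000), seed=7)


@pytest.fixture(scope="session")
def fast_train():
    """Training config sized for unit-test fixtures."""
    return TrainConfig(max_epochs=15, patience=3, seed=0)
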