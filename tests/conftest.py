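"""Shared fixtures: small synthetic cohorts and feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from distractnet.pipeline import extract_features
from distractnet.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> CohortSpec:
    """2 subjects x 3 epochs/state x 8 channels x 4 s — fast but full-shape."""
    return CohortSpec(
        n_subjects=2, epochs_per_state=3, n_channels=8, epoch_seconds=4.0, seed=7
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_spec):
    return generate_cohort(tiny_cohort_spec)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_cohort) -> pd.DataFrame:
    """Full 60-feature table of the tiny cohort (computed once per session)."""
    cohort = generate_cohort(
        CohortSpec(n_subjects=2, epochs_per_state=3, n_channels=8, epoch_seconds=4.0, seed=7)
    )
    table, _ = extract_features(cohort, decomposition="fir")
    return table


@pytest.fixture()
def separable_table() -> pd.DataFrame:
    """Synthetic 60-column feature table with three well-separated classes.

    Within-class values are drawn from a small discrete set so the class
    extremes are (almost surely) represented in any training split; greedy
    axis-aligned learners then place boundaries in the inter-class gaps and
    every classifier can be held to exact perfect accuracy.
    """
    rng = np.random.default_rng(0)
    rows = []
    centers = {"normal": 0.0, "cognitive": 20.0, "visual": 40.0}
    levels = np.array([-0.3, -0.15, 0.0, 0.15, 0.3])
    names = [
        f"{est}_{band}_{feat}"
        for est in ("SL", "PLV", "COH")
        for band in ("delta", "theta", "alpha", "beta")
        for feat in ("V", "Cg", "Lg", "Eg", "El")
    ]
    for subject in range(6):
        for state, mu in centers.items():
            for k in range(5):
                vals = mu + rng.choice(levels, size=len(names))
                row = dict(zip(names, vals))
                row.update({"state": state, "subject": subject, "epoch": k})
                rows.append(row)
    return pd.DataFrame(rows)
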