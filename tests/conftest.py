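"""Shared fixtures.

The heavy end-to-end objects (the ablation grid on the reference synthetic
cohort, and its null-signal counterpart) are session-scoped so the
pipeline-level tests share one training run instead of refitting per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from radiogcn.config import tables_to_xy
from radiogcn.evaluate import run_ablation
from radiogcn.synthetic import CohortSpec, simulate_cohort


def make_dataset(effect_size: float = 2.0, n_train: int = 30, n_test: int = 10,
                 n_features: int = 1290, seed: int = 0, **spec_kw) -> dict:
    """Train/test cohorts sharing class structure but not sampling noise."""
    tr_spec = CohortSpec(n_patients_per_class=(n_train,) * 3,
                         effect_size=effect_size, n_features=n_features,
                         seed=seed, **spec_kw)
    te_spec = CohortSpec(n_patients_per_class=(n_test,) * 3,
                         effect_size=effect_size, n_features=n_features,
                         seed=seed + 10_000, **spec_kw)
    tr_tabs, tr_man = simulate_cohort(tr_spec)
    te_tabs, te_man = simulate_cohort(te_spec)
    Xtr, ytr, ptr = tables_to_xy(tr_tabs, tr_man)
    Xte, yte, pte = tables_to_xy(te_tabs, te_man)
    return {"sequences": list(tr_tabs),
            "train": {"X": Xtr, "y": ytr, "patient_ids": ptr},
            "test": {"X": Xte, "y": yte, "patient_ids": pte}}


@pytest.fixture(scope="session")
def ablation_report():
    """Component x sequence-set ablation on the reference synthetic cohort
    (30 patients/class train, 10/class held out, effect size 2)."""
    return run_ablation(make_dataset(), seed=0, B=200)


@pytest.fixture(scope="session")
def null_ablation_report():
    """Same grid with zero effect size: no class signal anywhere.

    The larger held-out cohort keeps the chance-level AUC estimate tight.
    """
    return run_ablation(make_dataset(effect_size=0.0, n_test=30), seed=0, B=10)


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap low-dimensional cohort for model-level unit tests."""
    return make_dataset(n_train=12, n_test=6, n_features=300)
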