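from __future__ import annotations

import numpy as np
import pytest

from fflscan.expression import ExpressionStudy


def build_study(
    values: dict[str, np.ndarray],
    classes: dict[str, str],
    n_case: int,
    n_control: int,
) -> ExpressionStudy:
    """Assemble a study from per-feature rows (case columns first)."""
    features = list(values)
    mat = np.vstack([np.asarray(values[f], dtype=float) for f in features])
    n = mat.shape[1]
    assert n == n_case + n_control
    return ExpressionStudy(
        features=features,
        samples=[f"s{i}" for i in range(n)],
        values=mat,
        labels=["case"] * n_case + ["control"] * n_control,
        feature_class=classes,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_study(rng):
    """12 features (4 per class), 10 + 10 samples, pure noise."""
    feats = (
        [f"miR-{i}" for i in range(4)]
        + [f"G{i}" for i in range(4)]
        + [f"TF{i}" for i in range(4)]
    )
    classes = {f: ("miRNA" if f.startswith("miR") else "TF" if f.startswith("TF") else "gene") for f in feats}
    values = {f: rng.normal(8.0, 1.0, size=20) for f in feats}
    return build_study(values, classes, n_case=10, n_control=10)
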