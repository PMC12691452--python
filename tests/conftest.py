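"""Shared fixtures: small synthetic cohorts and fast in-memory feature bags."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wsip2p.synthetic import CLASSES


@pytest.fixture(scope="session")
def table1_manifest() -> pd.DataFrame:
    """A 513-WSI cohort manifest with the published per-class counts
    (41 MC, 42 LGSC, 94 CC, 119 EC, 217 HGSC)."""
    counts = {"MC": 41, "LGSC": 42, "CC": 94, "EC": 119, "HGSC": 217}
    rows = []
    for label, n in counts.items():
        for i in range(n):
            rows.append({
                "image_id": f"{label}_{i:04d}", "label": label,
                "image_width": 2048, "image_height": 2048,
                "is_tma": False, "domain_id": 0, "path": "",
            })
    return pd.DataFrame(rows)


def gaussian_feature_bags(
    n_per_class: int = 8,
    n_instances: int = 20,
    n_informative: int = 3,
    d: int = 16,
    n_domains: int = 2,
    separation: float = 3.0,
    seed: int = 0,
) -> list[dict]:
    """Fast MIL feature bags without the image pipeline.

    Each bag holds ``n_instances`` rows: ``n_informative`` are drawn
    around a class-specific mean, the rest around a shared background
    mean — the dilution structure the aggregators are built for.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, separation, (len(CLASSES), d))
    background = rng.normal(0, 0.5, d)
    bags = []
    idx = 0
    for ci, label in enumerate(CLASSES):
        for i in range(n_per_class):
            F = background + rng.normal(0, 1.0, (n_instances, d))
            pos = rng.choice(n_instances, size=n_informative, replace=False)
            F[pos] = centers[ci] + rng.normal(0, 1.0, (n_informative, d))
            bags.append({
                "wsi_id": f"{label}_{i}", "label": label,
                "domain_id": (i % n_domains) + 1, "features": F,
            })
            idx += 1
    return bags


@pytest.fixture()
def feature_bags() -> list[dict]:
    return gaussian_feature_bags()
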