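"""Bag construction, augmentation determinism, and split contracts."""

import numpy as np
import pandas as pd
import pytest

from wsip2p.bags import (
    AugmentConfig,
    augment,
    build_bags,
    make_domain_splits,
    make_split,
)


def tile_manifest_for(wsi_specs: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """{wsi_id: (n_kept, n_dropped)} -> a minimal tile manifest."""
    rows = []
    for wsi, (n_kept, n_drop) in wsi_specs.items():
        for i in range(n_kept):
            rows.append({"image_id": wsi, "x": i, "y": 0,
                         "mean_intensity": 100.0, "kept": True, "path": None})
        for i in range(n_drop):
            rows.append({"image_id": wsi, "x": i, "y": 1,
                         "mean_intensity": 3.0, "kept": False, "path": None})
    return pd.DataFrame(rows)


def cohort_for(wsi_ids) -> pd.DataFrame:
    return pd.DataFrame([
        {"image_id": w, "label": "CC", "domain_id": 1} for w in wsi_ids
    ])


def test_bags_sample_kept_tiles_without_replacement_when_possible():
    tm = tile_manifest_for({"w1": (961, 10)})
    bags, excluded = build_bags(tm, cohort_for(["w1"]), n=50, seed=1)
    assert excluded == []
    bag = bags[0]
    assert bag.n == 50 and not bag.sampled_with_replacement
    assert len(set(bag.tile_indices)) == 50
    assert tm.loc[bag.tile_indices, "kept"].all()
    # deterministic under seed
    bags2, _ = build_bags(tm, cohort_for(["w1"]), n=50, seed=1)
    assert np.array_equal(bag.tile_indices, bags2[0].tile_indices)
    bags3, _ = build_bags(tm, cohort_for(["w1"]), n=50, seed=2)
    assert not np.array_equal(bag.tile_indices, bags3[0].tile_indices)


def test_exactly_n_kept_tiles_takes_all_of_them():
    tm = tile_manifest_for({"w1": (50, 5)})
    for seed in (0, 99):
        bags, _ = build_bags(tm, cohort_for(["w1"]), n=50, seed=seed)
        kept_idx = tm.index[tm["kept"]].to_numpy()
        assert sorted(bags[0].tile_indices) == sorted(kept_idx)


def test_undersized_wsi_sampled_with_replacement_and_empty_excluded():
    tm = tile_manifest_for({"small": (7, 2), "empty": (0, 4)})
    bags, excluded = build_bags(tm, cohort_for(["small", "empty"]), n=50, seed=0)
    assert excluded == ["empty"]
    assert len(bags) == 1
    assert bags[0].sampled_with_replacement and bags[0].n == 50


def test_augment_eval_mode_is_pure_resize():
    tile = np.random.default_rng(0).integers(0, 256, (256, 256, 3), dtype=np.uint8)
    out1 = augment(tile, training=False)
    out2 = augment(tile, training=False)
    assert out1.shape == (224, 224, 3)
    assert np.array_equal(out1, out2)


def test_augment_zero_probabilities_equals_eval_mode():
    tile = np.random.default_rng(1).integers(0, 256, (256, 256, 3), dtype=np.uint8)
    off = AugmentConfig(p_rotate=0, p_flip=0, p_jitter=0, p_crop=0, p_blur=0)
    assert np.array_equal(augment(tile, training=True, seed=5, config=off),
                          augment(tile, training=False))


def test_augment_training_reproducible_under_seed():
    tile = np.random.default_rng(2).integers(0, 256, (256, 256, 3), dtype=np.uint8)
    a = augment(tile, training=True, seed=42)
    b = augment(tile, training=True, seed=42)
    c = augment(tile, training=True, seed=43)
    assert np.array_equal(a, b)
    assert a.shape == (224, 224, 3)
    assert not np.array_equal(a, c)


def test_published_count_split_is_exact(table1_manifest):
    split = make_split(table1_manifest, mode=(328, 82, 103), seed=0)
    assert split.sizes() == (328, 82, 103)
    ids = split.train + split.validation + split.test
    assert len(set(ids)) == 513  # disjoint and covering


def test_ratio_split_all_train(table1_manifest):
    split = make_split(table1_manifest, mode=(1.0, 0.0), seed=0)
    assert split.sizes() == (513, 0, 0)


def test_stratified_split_of_balanced_cohort_has_equal_histograms():
    rows = [{"image_id": f"{c}{i}", "label": c}
            for c in "ABCDE" for i in range(20)]
    manifest = pd.DataFrame(rows)
    split = make_split(manifest, mode=(0.5, 0.5), stratify=True, seed=3)
    for part in (split.train, split.test):
        hist = pd.Series([i[0] for i in part]).value_counts()
        assert (hist == 10).all()


def test_infeasible_counts_rejected(table1_manifest):
    with pytest.raises(ValueError, match="infeasible"):
        make_split(table1_manifest, mode=(400, 100, 100))


def test_domain_split_balanced_cohort_one_per_class(table1_manifest):
    rows = [{"image_id": f"{c}{i}", "label": c} for c in "ABCDE" for i in range(4)]
    ds = make_domain_splits(pd.DataFrame(rows), n_domains=4, seed=0)
    assert ds.domain_sizes() == [5, 5, 5, 5]
    assert (ds.class_histograms == 1).all().all()


def test_domain_split_conservation_and_stratification(table1_manifest):
    ds = make_domain_splits(table1_manifest, n_domains=4, seed=1)
    all_ids = [i for dom in ds.domains for i in dom]
    assert len(all_ids) == 513 and len(set(all_ids)) == 513
    assert ds.domain_sizes() == [128, 128, 128, 129]  # last absorbs remainder
    # per-domain class proportions within one WSI of proportional share
    global_counts = table1_manifest["label"].value_counts()
    for d, size in enumerate(ds.domain_sizes()):
        for cls, total in global_counts.items():
            expected = total * size / 513
            assert abs(ds.class_histograms.iloc[d][cls] - expected) <= 1
    # within-domain train/test conserves each domain
    for dom, tr, te in zip(ds.domains, ds.train, ds.test):
        assert sorted(tr + te) == sorted(dom)


def test_domain_split_published_accounting(table1_manifest):
    """Explicit per-domain sizes reproduce the published 410 + 103 = 513."""
    ds = make_domain_splits(
        table1_manifest, n_domains=4, seed=0,
        domain_sizes=[127, 127, 127, 132], test_counts=[25, 25, 25, 28],
    )
    acct = ds.accounting().set_index("domain")
    assert acct.loc["Overall", "total_wsi"] == 513
    assert acct.loc["Overall", "training_wsi"] == 410
    assert acct.loc["Overall", "testing_wsi"] == 103
    assert acct.loc["D4", "total_wsi"] == 132


def test_domain_split_deficient_class_named():
    rows = [{"image_id": f"A{i}", "label": "A"} for i in range(8)]
    rows += [{"image_id": "B0", "label": "B"}, {"image_id": "B1", "label": "B"}]
    with pytest.raises(ValueError, match="'B'"):
        make_domain_splits(pd.DataFrame(rows), n_domains=4, seed=0,
                           domain_sizes=[3, 3, 2, 2])
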