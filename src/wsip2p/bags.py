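"""MIL bag assembly, training augmentations, and dataset/domain splits.

One WSI becomes one *bag* of N tiles (default N = 50) carrying a single
weak label — the "one-vs-N" representation. Tiles are chosen uniformly at
random from the brightness-passing tiles of the slide; a slide with fewer
than N kept tiles is sampled with replacement and flagged. Splits come in
three flavors: ratio (e.g. 80/20), explicit cardinalities (e.g. the
328/82/103 train/val/test configuration), and stratified multi-domain
partitions used by the leave-one-domain-out generalization protocol.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance, ImageFilter

logger = logging.getLogger(__name__)

DEFAULT_BAG_SIZE = 50


@dataclass
class Bag:
    """One WSI's instance set with its single bag-level label."""

    wsi_id: str
    label: str
    domain_id: int
    tile_indices: np.ndarray  # row indices into the WSI's kept-tile table
    sampled_with_replacement: bool = False
    instances: np.ndarray | None = field(default=None, repr=False)  # (N,h,w,3)

    @property
    def n(self) -> int:
        return len(self.tile_indices)


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    provenance: dict = field(default_factory=dict)

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


@dataclass
class DomainSplit:
    """Stratified assignment of WSIs to domains, with within-domain splits.

    ``domains[d]`` lists the WSI ids of domain ``d + 1``; ``train[d]`` /
    ``test[d]`` is an 80/20-style split *within* each domain (the
    accounting convention of the generalization protocol), while the
    leave-one-domain-out folds used for cross-domain training treat each
    whole domain as the test set in turn.
    """

    domains: list[list[str]]
    train: list[list[str]]
    test: list[list[str]]
    class_histograms: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def domain_sizes(self) -> list[int]:
        return [len(d) for d in self.domains]

    def accounting(self) -> pd.DataFrame:
        """Per-domain (training, testing, total) WSI counts plus overall row."""
        rows = [
            {"domain": f"D{i + 1}", "training_wsi": len(tr),
             "testing_wsi": len(te), "total_wsi": len(dom)}
            for i, (dom, tr, te) in enumerate(zip(self.domains, self.train, self.test))
        ]
        rows.append({
            "domain": "Overall",
            "training_wsi": sum(r["training_wsi"] for r in rows),
            "testing_wsi": sum(r["testing_wsi"] for r in rows),
            "total_wsi": sum(r["total_wsi"] for r in rows),
        })
        return pd.DataFrame(rows)


def build_bags(
    tile_manifest: pd.DataFrame,
    cohort_manifest: pd.DataFrame,
    n: int = DEFAULT_BAG_SIZE,
    seed: int = 0,
) -> tuple[list[Bag], list[str]]:
    """Assemble one bag per WSI from its kept tiles.

    ``tile_manifest`` needs columns image_id and kept (one row per tile);
    ``cohort_manifest`` supplies label and domain_id per image_id. Returns
    the bags plus an exclusion report of WSIs with zero kept tiles.
    Selection is uniform without replacement when at least ``n`` kept
    tiles exist, with replacement (flagged) otherwise. Deterministic in
    (manifests, n, seed).
    """
    if n < 1:
        raise ValueError(f"bag size must be >= 1, got {n}")
    meta = cohort_manifest.set_index("image_id")
    bags, excluded = [], []
    for wsi_id, group in tile_manifest.groupby("image_id", sort=True):
        kept_rows = np.flatnonzero(group["kept"].to_numpy())
        # crc32 gives a process-independent per-WSI stream (str hash is salted)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=seed, spawn_key=(zlib.crc32(str(wsi_id).encode()),)
            )
        )
        if len(kept_rows) == 0:
            logger.warning("WSI %s has no kept tiles; excluded from bagging", wsi_id)
            excluded.append(wsi_id)
            continue
        replace = len(kept_rows) < n
        chosen = rng.choice(kept_rows, size=n, replace=replace)
        if not replace:
            chosen = np.sort(chosen)
        bags.append(Bag(
            wsi_id=str(wsi_id),
            label=str(meta.loc[wsi_id, "label"]),
            domain_id=int(meta.loc[wsi_id, "domain_id"]),
            tile_indices=group.index.to_numpy()[chosen],
            sampled_with_replacement=replace,
        ))
    return bags, excluded


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation recipe (names per the training protocol;
    strengths are package defaults, configurable)."""

    out_size: int = 224
    p_rotate: float = 0.5
    rotation_range: float = 90.0  # degrees, symmetric
    p_flip: float = 0.5
    p_jitter: float = 0.5
    jitter_strength: float = 0.2  # brightness/contrast/saturation factor range
    p_crop: float = 0.5
    crop_scale: tuple[float, float] = (0.7, 1.0)
    p_blur: float = 0.5
    blur_sigma: tuple[float, float] = (0.1, 1.0)


def augment(
    tile: np.ndarray,
    training: bool = False,
    seed: int = 0,
    config: AugmentConfig = AugmentConfig(),
) -> np.ndarray:
    """Resize a (downscaled) tile to the model input size, with optional
    stochastic training transforms.

    Evaluation mode only resizes to ``config.out_size``. Training mode
    applies, under ``seed``: random rotation, horizontal/vertical flips,
    color jitter, random crop and Gaussian blur, then the resize. With all
    probabilities at 0 the training path equals the evaluation path.
    Output stays uint8 in [0, 255]; normalization is the model's concern.
    """
    img = Image.fromarray(np.asarray(tile, dtype=np.uint8))
    if training:
        rng = np.random.default_rng(seed)
        if rng.random() < config.p_rotate:
            angle = float(rng.uniform(-config.rotation_range, config.rotation_range))
            img = img.rotate(angle, resample=Image.BILINEAR)
        if rng.random() < config.p_flip:
            img = img.transpose(Image.FLIP_LEFT_RIGHT)
        if rng.random() < config.p_flip:
            img = img.transpose(Image.FLIP_TOP_BOTTOM)
        if rng.random() < config.p_jitter:
            s = config.jitter_strength
            for enhancer in (ImageEnhance.Brightness, ImageEnhance.Contrast,
                             ImageEnhance.Color):
                img = enhancer(img).enhance(float(rng.uniform(1 - s, 1 + s)))
        if rng.random() < config.p_crop:
            w, h = img.size
            scale = float(rng.uniform(*config.crop_scale))
            cw, ch = max(1, int(w * scale)), max(1, int(h * scale))
            x0 = int(rng.integers(0, w - cw + 1))
            y0 = int(rng.integers(0, h - ch + 1))
            img = img.crop((x0, y0, x0 + cw, y0 + ch))
        if rng.random() < config.p_blur:
            sigma = float(rng.uniform(*config.blur_sigma))
            img = img.filter(ImageFilter.GaussianBlur(sigma))
    if img.size != (config.out_size, config.out_size):
        img = img.resize((config.out_size, config.out_size), Image.LANCZOS)
    return np.asarray(img, dtype=np.uint8)


def _stratified_allocation(counts: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``counts`` items into parts, per row.

    Guarantees exact part totals per class up to the rounding rule and
    keeps each part within one item of proportionality.
    """
    alloc = np.zeros((len(counts), len(fractions)), dtype=int)
    for i, c in enumerate(counts):
        ideal = fractions * c
        base = np.floor(ideal).astype(int)
        rem = c - base.sum()
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:rem]] += 1
        alloc[i] = base
    return alloc


def make_split(
    manifest: pd.DataFrame,
    mode: tuple = (0.8, 0.2),
    stratify: bool = True,
    seed: int = 0,
) -> DatasetSplit:
    """Partition a cohort into train/validation/test WSI id lists.

    ``mode`` is either a ratio pair ``(train_fraction, test_fraction)``
    (validation gets the remainder) or an explicit count triple
    ``(n_train, n_val, n_test)`` reproduced exactly. Stratified mode keeps
    per-class proportions within one WSI per split.
    """
    ids = manifest["image_id"].to_numpy()
    labels = manifest["label"].to_numpy()
    total = len(ids)
    if len(mode) == 2:
        tr_f, ts_f = float(mode[0]), float(mode[1])
        if tr_f < 0 or ts_f < 0 or tr_f + ts_f > 1 + 1e-12:
            raise ValueError(f"invalid ratio mode {mode}")
        fractions = np.asarray([tr_f, max(0.0, 1.0 - tr_f - ts_f), ts_f])
        counts_mode = None
    elif len(mode) == 3:
        counts_mode = tuple(int(v) for v in mode)
        if any(v < 0 for v in counts_mode) or sum(counts_mode) > total:
            raise ValueError(f"infeasible counts {mode} for cohort of {total}")
        fractions = np.asarray(counts_mode, dtype=float) / max(sum(counts_mode), 1)
    else:
        raise ValueError(f"mode must be a 2-ratio or 3-count tuple, got {mode}")

    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], [], []]
    if stratify:
        classes, class_counts = np.unique(labels, return_counts=True)
        alloc = _stratified_allocation(class_counts, fractions)
        for ci, cls in enumerate(classes):
            members = ids[labels == cls]
            members = members[rng.permutation(len(members))]
            start = 0
            for p in range(3):
                parts[p].extend(members[start: start + alloc[ci, p]])
                start += alloc[ci, p]
    else:
        order = ids[rng.permutation(total)]
        cuts = np.floor(np.cumsum(fractions) * total + 1e-9).astype(int)
        parts = [list(order[:cuts[0]]), list(order[cuts[0]:cuts[1]]),
                 list(order[cuts[1]:cuts[2]])]

    if counts_mode is not None:
        # trim/borrow so the explicit cardinalities are met exactly
        pool = [x for p, part in enumerate(parts)
                for x in part[counts_mode[p]:]]
        parts = [part[:counts_mode[p]] for p, part in enumerate(parts)]
        for p in range(3):
            while len(parts[p]) < counts_mode[p]:
                parts[p].append(pool.pop())
    return DatasetSplit(
        train=sorted(parts[0]), validation=sorted(parts[1]), test=sorted(parts[2]),
        provenance={"mode": tuple(mode), "stratify": stratify, "seed": seed},
    )


def make_domain_splits(
    manifest: pd.DataFrame,
    n_domains: int = 4,
    seed: int = 0,
    domain_sizes: list[int] | None = None,
    test_counts: list[int] | None = None,
    test_fraction: float = 0.2,
) -> DomainSplit:
    """Stratified assignment of a cohort into ``n_domains`` disjoint domains.

    Per-domain class proportions stay within one WSI of the cohort's
    (largest-remainder stratification). By default domains are as equal as
    possible with the last domain absorbing the remainder; explicit
    ``domain_sizes`` (and per-domain ``test_counts``) may be supplied to
    reproduce a published accounting exactly. Within each domain a
    train/test split of ``test_fraction`` (stratified) is recorded.
    """
    ids = manifest["image_id"].to_numpy()
    labels = manifest["label"].to_numpy()
    total = len(ids)
    classes, class_counts = np.unique(labels, return_counts=True)
    if total < n_domains * len(classes):
        raise ValueError(
            f"cohort of {total} too small for {n_domains} domains x "
            f"{len(classes)} classes"
        )
    if domain_sizes is None:
        base = total // n_domains
        domain_sizes = [base] * (n_domains - 1) + [total - base * (n_domains - 1)]
    if len(domain_sizes) != n_domains or sum(domain_sizes) != total:
        raise ValueError(f"domain_sizes {domain_sizes} must sum to cohort size {total}")

    fractions = np.asarray(domain_sizes, dtype=float) / total
    alloc = _stratified_allocation(class_counts, fractions)
    ideal = np.outer(class_counts, fractions)
    # repair per-domain totals to match domain_sizes exactly, moving the
    # class whose move best restores proportionality (keeps the +-1 bound)
    for _ in range(total):
        diff = alloc.sum(axis=0) - np.asarray(domain_sizes)
        if not diff.any():
            break
        src, dst = int(np.argmax(diff)), int(np.argmin(diff))
        movable = np.flatnonzero(alloc[:, src] > 0)
        if len(movable) == 0:
            raise ValueError(f"infeasible stratification for domain sizes {domain_sizes}")
        gain = (alloc[movable, src] - ideal[movable, src]) + (
            ideal[movable, dst] - alloc[movable, dst]
        )
        ci = movable[int(np.argmax(gain))]
        alloc[ci, src] -= 1
        alloc[ci, dst] += 1

    rng = np.random.default_rng(seed)
    domains: list[list[str]] = [[] for _ in range(n_domains)]
    for ci, cls in enumerate(classes):
        if alloc[ci].min() < 1:
            raise ValueError(
                f"class {cls!r} cannot cover all {n_domains} domains "
                f"(only {class_counts[ci]} WSIs)"
            )
        members = ids[labels == cls]
        members = members[rng.permutation(len(members))]
        start = 0
        for d in range(n_domains):
            domains[d].extend(members[start: start + alloc[ci, d]])
            start += alloc[ci, d]
    domains = [sorted(d) for d in domains]

    label_of = dict(zip(ids, labels))
    train, test = [], []
    for d, dom in enumerate(domains):
        n_test = (int(test_counts[d]) if test_counts is not None
                  else int(round(test_fraction * len(dom))))
        if not 0 <= n_test <= len(dom):
            raise ValueError(f"infeasible test count {n_test} for domain of {len(dom)}")
        sub = pd.DataFrame({"image_id": dom, "label": [label_of[i] for i in dom]})
        split = make_split(sub, mode=(len(dom) - n_test, 0, n_test),
                           stratify=True, seed=seed + d + 1)
        train.append(split.train)
        test.append(split.test)

    hist = pd.DataFrame(
        [{c: sum(1 for i in dom if label_of[i] == c) for c in classes}
         for dom in domains],
        index=[f"D{d + 1}" for d in range(n_domains)],
    )
    return DomainSplit(
        domains=domains, train=train, test=test, class_histograms=hist,
        provenance={"n_domains": n_domains, "seed": seed,
                    "domain_sizes": list(domain_sizes),
                    "test_counts": None if test_counts is None else list(test_counts),
                    "test_fraction": test_fraction},
    )
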