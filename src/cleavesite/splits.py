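"""Train/test splitting, cross-validation folds, and seed fan-out."""

from __future__ import annotations

import math
import zlib

import numpy as np

from .records import LabeledDataset


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed, deterministically.

    Stages of the pipeline draw from independent streams so each stage is
    reproducible in isolation (e.g. re-running only training).
    """
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def split_dataset(
    ds: LabeledDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    group_by_guide: bool = False,
) -> LabeledDataset:
    """Assign each site to train or test by uniform random shuffle.

    Train size is floor(train_fraction * N). With ``group_by_guide`` all
    sites of a guide travel together (train size then only approximates
    the fraction); the default splits by site record.
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(ds)
    n_train = math.floor(train_fraction * n)
    rng = np.random.default_rng(seed)
    assignment = {}
    if group_by_guide:
        gids = sorted({s.guide_id for s in ds.sites})
        rng.shuffle(gids)
        taken = 0
        train_guides = set()
        per_guide = {g: 0 for g in gids}
        for s in ds.sites:
            per_guide[s.guide_id] += 1
        for g in gids:
            if taken >= n_train:
                break
            train_guides.add(g)
            taken += per_guide[g]
        for s in ds.sites:
            assignment[s.site_id] = "train" if s.guide_id in train_guides else "test"
    else:
        order = rng.permutation(n)
        ids = ds.site_ids
        for rank, idx in enumerate(order):
            assignment[ids[idx]] = "train" if rank < n_train else "test"
    ds.split_assignment = assignment
    return ds


def make_cv_folds(site_ids, k: int = 5, seed: int = 0) -> list:
    """Partition ids into k shuffled folds with sizes differing by <= 1."""
    ids = list(site_ids)
    n = len(ids)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds number of records ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    folds, pos = [], 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        folds.append([ids[i] for i in order[pos : pos + size]])
        pos += size
    return folds
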