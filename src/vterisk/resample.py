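"""Random equal-size splits and per-replicate hot-deck imputation.

Replicate seeds are derived from the master seed as
``rep_seed = (master_seed XOR replicate_index) & 0x7FFFFFFF``; one numpy
Generator per replicate is consumed sequentially (imputation first, then
splitting), so any two pipelines run on the same cohort with the same
master seed share identical imputations and splits replicate-for-replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, CohortError


def replicate_seed(master_seed: int, replicate_index: int) -> int:
    return (int(master_seed) ^ int(replicate_index)) & 0x7FFFFFFF


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SplitPlan:
    """One replicate's train/test partition (disjoint, covering the cohort)."""

    replicate_index: int
    seed: int
    train_ids: list[str]
    test_ids: list[str]


def random_split(
    cohort: Cohort,
    seed,
    replicate_index: int = 0,
    stratified: bool = False,
) -> SplitPlan:
    """Uniform random partition into halves of sizes ceil(n/2) / floor(n/2).

    With ``stratified=True`` cases and controls are halved separately
    (non-default; the study protocol splits unstratified).
    """
    n = cohort.n_samples
    if n < 2:
        raise CohortError("need at least 2 samples to split")
    rng = _as_rng(seed)
    ids = np.asarray(cohort.sample_ids, dtype=object)
    if stratified:
        train_idx: list[int] = []
        for label in (1, 0):
            grp = np.where(cohort.status == label)[0]
            perm = rng.permutation(grp)
            train_idx.extend(perm[: (len(grp) + 1) // 2])
        train = set(train_idx)
        order = rng.permutation(n)  # keep stream length comparable
        train_ids = [str(s) for s in ids[sorted(train)]]
        test_ids = [str(s) for s in ids[sorted(set(range(n)) - train)]]
    else:
        order = rng.permutation(n)
        k = (n + 1) // 2  # odd n: train gets the extra sample
        train_ids = [str(s) for s in ids[np.sort(order[:k])]]
        test_ids = [str(s) for s in ids[np.sort(order[k:])]]
    seed_val = int(seed) if isinstance(seed, (int, np.integer)) else -1
    return SplitPlan(replicate_index, seed_val, train_ids, test_ids)


def hot_deck_impute(cohort: Cohort, seed, donor_ids: list[str] | None = None) -> Cohort:
    """Fill every missing cell from that variable's control donor pool.

    Each missing value (in cases and controls alike) is replaced by a
    uniform draw, with replacement, from the non-missing values observed
    in control samples for the same variable.  ``donor_ids`` optionally
    restricts the donor pool (e.g. to training-set controls in strict
    mode).  Non-missing cells are never touched.
    """
    rng = _as_rng(seed)
    out = cohort.copy()
    if donor_ids is None:
        donor_rows = ~out.case_mask
    else:
        wanted = set(donor_ids)
        donor_rows = np.array(
            [sid in wanted and st == 0 for sid, st in zip(out.sample_ids, out.status)]
        )
    for j, meta in enumerate(out.schema):
        col = out.values[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        pool = col[donor_rows & ~miss]
        if pool.size == 0:
            raise CohortError(f"variable {meta.name!r}: empty control donor pool")
        col[miss] = rng.choice(pool, size=int(miss.sum()), replace=True)
    return out
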