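"""Train/validation/test partitioning and the consistent/inconsistent test
variants.

Training targets are always the primary labeller's labels; the test set is
split post hoc into the consistent part (both labellers agree — the truth is
unambiguous) and the inconsistent part, which is evaluated twice: once with
the secondary labeller's labels as ground truth and once with the primary's.
The consistent test set is additionally subsampled to the size of the
inconsistent one so headline metrics are compared at matched cardinality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import LABELS, LabelledCorpus
from ._seeding import rng_for


@dataclass
class SplitPlan:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    val_fraction: float = 0.10
    test_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("train/val/test id sets must be disjoint")

    def to_dict(self):
        return {
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
            "test_ids": list(self.test_ids),
            "val_fraction": self.val_fraction,
            "test_fraction": self.test_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class TestVariants:
    """The three evaluation views of one test split.

    cons_test: ids where the labellers agree (truth = the shared label);
    the two inconsistent variants share one id set (primary != secondary) and
    differ only in which labeller is taken as ground truth.  ``cons_subsample``
    is the size-matched random subset of cons_test used for headline metrics.
    """

    cons_test: list[str]
    incons_test: list[str]
    cons_subsample: list[str]
    truth_cons: dict[str, str] = field(repr=False)
    truth_neg_incons: dict[str, str] = field(repr=False)  # secondary labels
    truth_chex_incons: dict[str, str] = field(repr=False)  # primary labels
    cons_subsample_seed: int = 0

    def variant_items(self):
        """(name, ids, truth-map) triples in canonical order."""
        return [
            ("CONSTest", self.cons_subsample, self.truth_cons),
            ("NegINCONSTest", self.incons_test, self.truth_neg_incons),
            ("CheXINCONSTest", self.incons_test, self.truth_chex_incons),
        ]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights`."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    return base


def make_split(
    corpus: LabelledCorpus,
    val_fraction: float = 0.10,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> SplitPlan:
    """Stratified (by primary label) deterministic split.

    Validation and test receive ``round(n * fraction)`` reports each, with
    per-class counts by largest-remainder rounding so both preserve the corpus
    class proportions to within one report per class.
    """
    by_class: dict[str, list[str]] = {lab: [] for lab in LABELS}
    for r in corpus:
        by_class[r.primary_label].append(r.report_id)
    for lab, ids in by_class.items():
        if len(ids) < 10:
            raise ValueError(f"class {lab!r} has only {len(ids)} reports; need >= 10 to stratify")

    n = len(corpus)
    counts = np.array([len(by_class[lab]) for lab in LABELS], dtype=float)
    val_counts = _largest_remainder(counts, int(round(n * val_fraction)))
    test_counts = _largest_remainder(counts, int(round(n * test_fraction)))

    rng = rng_for(seed, "split")
    train_ids, val_ids, test_ids = [], [], []
    for lab, nv, nt in zip(LABELS, val_counts, test_counts):
        ids = list(by_class[lab])
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        val_ids.extend(shuffled[:nv])
        test_ids.extend(shuffled[nv:nv + nt])
        train_ids.extend(shuffled[nv + nt:])
    return SplitPlan(train_ids=train_ids, val_ids=val_ids, test_ids=test_ids,
                     val_fraction=val_fraction, test_fraction=test_fraction, seed=seed)


def make_test_variants(corpus: LabelledCorpus, split: SplitPlan, seed: int = 0) -> TestVariants:
    by_id = {r.report_id: r for r in corpus}
    cons, incons = [], []
    for rid in split.test_ids:
        r = by_id[rid]
        (incons if r.primary_label != r.secondary_label else cons).append(rid)

    truth_cons = {rid: by_id[rid].primary_label for rid in cons}
    truth_neg = {rid: by_id[rid].secondary_label for rid in incons}
    truth_chex = {rid: by_id[rid].primary_label for rid in incons}

    if incons:
        rng = rng_for(seed, "cons-subsample")
        take = rng.choice(len(cons), size=min(len(incons), len(cons)), replace=False)
        subsample = [cons[i] for i in sorted(take)]
    else:
        subsample = list(cons)  # degenerate: no disagreements in this test split
    return TestVariants(
        cons_test=cons, incons_test=incons, cons_subsample=subsample,
        truth_cons=truth_cons, truth_neg_incons=truth_neg, truth_chex_incons=truth_chex,
        cons_subsample_seed=seed,
    )
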