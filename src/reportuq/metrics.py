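"""Uncertainty-quality metrics and the evaluation report.

Headline metrics per test variant: accuracy, negative log predictive
probability NLPP = mean over examples of -ln p(true class | x) (natural log,
probabilities floored at 1e-12), and the mean maximum predicted confidence
level MMPCL = mean over examples of max_j p(C_j | x).  The group-wise view
compares MMPCL between false negatives and true positives of the *positive*
and *uncertain* classes (negative-class groups are ignored: a missed positive
is the costly error).  Empty groups are reported as explicit undefined
markers with their counts, never as silent zeros.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import LABELS

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


def _validate(probs, truth=None):
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("probs must be a non-empty n x C matrix")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must lie on the simplex")
    if truth is not None:
        truth = np.asarray(truth)
        if truth.shape[0] != probs.shape[0]:
            raise ValueError("probs and truth lengths differ")
        return probs, truth
    return probs


def accuracy(probs, truth) -> float:
    """Fraction of rows whose argmax matches truth; argmax ties break toward
    the lower class index (ties are logged)."""
    probs, truth = _validate(probs, truth)
    pred = np.argmax(probs, axis=1)  # numpy argmax takes the first maximum
    n_ties = int(np.sum((probs == probs.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_ties:
        logger.info("accuracy: %d argmax ties broken toward the lower class index", n_ties)
    return float(np.mean(pred == truth))


def nlpp(probs, truth) -> float:
    """Mean over examples of -ln p(true class | x), floored at 1e-12."""
    probs, truth = _validate(probs, truth)
    p_true = probs[np.arange(len(truth)), truth]
    n_floored = int(np.sum(p_true < PROB_FLOOR))
    if n_floored:
        logger.info("nlpp: probability floor triggered on %d rows", n_floored)
    return float(np.mean(-np.log(np.maximum(p_true, PROB_FLOOR))))


@dataclass(frozen=True)
class GroupStat:
    """MMPCL of one group, or an explicit undefined marker when the group is
    empty (mirrors a dash in a results table); the count is always reported."""

    value: float | None
    count: int

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __str__(self):
        if not self.defined:
            return f"- (n=0)"
        flag = "*" if self.count == 1 else ""
        return f"{self.value:.3f}{flag} (n={self.count})"


def mmpcl(probs) -> GroupStat:
    """Mean of the per-row maximum probability; undefined marker on an empty
    set.  For C classes the value lies in [1/C, 1]."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        return GroupStat(value=None, count=0)
    probs = _validate(probs)
    return GroupStat(value=float(np.mean(probs.max(axis=1))), count=probs.shape[0])


def groupwise_mmpcl(probs, truth, predicted, class_index: int) -> dict[str, GroupStat]:
    """MMPCL of the false-negative and true-positive groups of one class.

    FN: truth == class and prediction != class; TP: truth == prediction ==
    class.  Their counts always add up to the class's support in ``truth``.
    """
    probs, truth = _validate(probs, truth)
    predicted = np.asarray(predicted)
    is_class = truth == class_index
    fn_mask = is_class & (predicted != class_index)
    tp_mask = is_class & (predicted == class_index)
    return {"FN": mmpcl(probs[fn_mask]), "TP": mmpcl(probs[tp_mask])}


def reliability_analysis(probs, truth, n_bins: int = 10) -> dict:
    """Equal-width reliability table on the maximum probability plus the
    expected calibration error ECE = sum_b (n_b/n) |acc_b - conf_b|."""
    probs, truth = _validate(probs, truth)
    n = probs.shape[0]
    if n < n_bins:
        raise ValueError("need at least n_bins examples")
    conf = probs.max(axis=1)
    correct = (np.argmax(probs, axis=1) == truth).astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(conf, edges[1:-1], right=False), 0, n_bins - 1)
    rows, ece = [], 0.0
    for b in range(n_bins):
        mask = which == b
        count = int(mask.sum())
        if count:
            bin_conf = float(conf[mask].mean())
            bin_acc = float(correct[mask].mean())
            ece += count / n * abs(bin_acc - bin_conf)
        else:
            bin_conf = bin_acc = None
        rows.append({"bin_low": float(edges[b]), "bin_high": float(edges[b + 1]),
                     "count": count, "confidence": bin_conf, "accuracy": bin_acc})
    return {"bins": rows, "ece": float(ece)}


def expected_calibration_error(probs, truth, n_bins: int = 10) -> float:
    return reliability_analysis(probs, truth, n_bins)["ece"]


def plot_reliability(analysis: dict, ax=None):
    """Reliability diagram for the output of :func:`reliability_analysis`."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mids = [(b["bin_low"] + b["bin_high"]) / 2 for b in analysis["bins"]]
    accs = [b["accuracy"] if b["accuracy"] is not None else np.nan for b in analysis["bins"]]
    ax.bar(mids, accs, width=mids[1] - mids[0] if len(mids) > 1 else 0.1,
           edgecolor="k", alpha=0.7, label="accuracy")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    ax.set_xlabel("confidence")
    ax.set_ylabel("accuracy")
    ax.set_title(f"ECE = {analysis['ece']:.3f}")
    ax.legend()
    return ax


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

GROUPWISE_CLASSES = ("positive", "uncertain")  # the negative class is ignored


@dataclass
class EvalReport:
    """Per-variant metrics averaged over split repetitions, with every raw
    per-repeat value retained, plus the group-wise FN/TP MMPCL tables."""

    model_name: str
    per_repeat: list[dict] = field(default_factory=list)  # repeat -> variant -> metrics
    n_repeats: int = 0

    # -- aggregation -------------------------------------------------------
    def variant_names(self) -> list[str]:
        names = []
        for rep in self.per_repeat:
            for v in rep:
                if v not in names:
                    names.append(v)
        return names

    def mean_metric(self, variant: str, metric: str) -> float | None:
        vals = [rep[variant][metric] for rep in self.per_repeat
                if variant in rep and rep[variant][metric] is not None]
        return float(np.mean(vals)) if vals else None

    def mean_groupwise(self, variant: str, class_name: str, group: str) -> GroupStat:
        vals, counts = [], []
        for rep in self.per_repeat:
            if variant not in rep:
                continue
            gs = rep[variant]["groupwise"][class_name][group]
            counts.append(gs["count"])
            if gs["value"] is not None:
                vals.append(gs["value"])
        if not vals:
            return GroupStat(value=None, count=int(np.sum(counts)) if counts else 0)
        return GroupStat(value=float(np.mean(vals)), count=int(np.sum(counts)))

    # -- tables -----------------------------------------------------------
    def headline_table(self) -> pd.DataFrame:
        rows = []
        for variant in self.variant_names():
            rows.append({
                "model": self.model_name, "variant": variant,
                "accuracy": self.mean_metric(variant, "accuracy"),
                "nlpp": self.mean_metric(variant, "nlpp"),
                "mmpcl": self.mean_metric(variant, "mmpcl"),
                "n": int(np.mean([rep[variant]["n"] for rep in self.per_repeat
                                  if variant in rep])),
            })
        return pd.DataFrame(rows)

    def groupwise_table(self) -> pd.DataFrame:
        rows = []
        for variant in self.variant_names():
            for cls in GROUPWISE_CLASSES:
                for group in ("FN", "TP"):
                    gs = self.mean_groupwise(variant, cls, group)
                    rows.append({"model": self.model_name, "variant": variant,
                                 "class": cls, "group": group,
                                 "mmpcl": gs.value, "count": gs.count})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Evaluation report: {self.model_name} "
                 f"(mean of {self.n_repeats} split repetition(s))", "=" * 60]
        lines.append(self.headline_table().to_string(index=False,
                                                     float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append("Group-wise MMPCL (FN vs TP; '-' marks an empty group):")
        df = self.groupwise_table()
        df["mmpcl"] = [f"{v:.3f}" if v == v and v is not None else "-"
                       for v in df["mmpcl"]]
        lines.append(df.to_string(index=False))
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"model_name": self.model_name, "n_repeats": self.n_repeats,
                "per_repeat": self.per_repeat}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(model_name=d["model_name"], per_repeat=d["per_repeat"],
                   n_repeats=d["n_repeats"])


def _class_index(name: str) -> int:
    return LABELS.index(name)


def evaluate_variant(probs: np.ndarray, truth: np.ndarray) -> dict:
    """All metrics of one model on one test variant (one repeat)."""
    if len(truth) == 0:
        return {"n": 0, "accuracy": None, "nlpp": None, "mmpcl": None,
                "groupwise": {c: {"FN": {"value": None, "count": 0},
                                  "TP": {"value": None, "count": 0}}
                              for c in GROUPWISE_CLASSES}}
    pred = np.argmax(probs, axis=1)
    out = {
        "n": int(len(truth)),
        "accuracy": accuracy(probs, truth),
        "nlpp": nlpp(probs, truth),
        "mmpcl": mmpcl(probs).value,
        "groupwise": {},
    }
    for cls in GROUPWISE_CLASSES:
        stats = groupwise_mmpcl(probs, truth, pred, _class_index(cls))
        out["groupwise"][cls] = {g: {"value": s.value, "count": s.count}
                                 for g, s in stats.items()}
    return out


def evaluate_run(model_name: str, repeats: list[dict]) -> EvalReport:
    """Aggregate per-repeat variant predictions into an :class:`EvalReport`.

    ``repeats`` is a list (one entry per split repetition) of mappings
    ``variant name -> (probs, truth_indices)``; every repeat must supply the
    same variants.
    """
    if not repeats:
        raise ValueError("need at least one repeat")
    expected = set(repeats[0])
    per_repeat = []
    for k, rep in enumerate(repeats):
        missing = expected - set(rep)
        if missing:
            raise ValueError(f"repeat {k} is missing variant(s): {sorted(missing)}")
        per_repeat.append({variant: evaluate_variant(np.asarray(p), np.asarray(t))
                           for variant, (p, t) in rep.items()})
    return EvalReport(model_name=model_name, per_repeat=per_repeat,
                      n_repeats=len(repeats))
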