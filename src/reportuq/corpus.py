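"""Synthetic dual-labeller radiology-report corpus.

Emulates the statistical structure of a corpus of short free-text reports
annotated by two deterministic rule-based labellers of different
conservativeness over the three ordered risk classes *positive* / *uncertain*
/ *negative*.  Each document carries a latent severity ``s ~ Uniform(0, 1)``
mapped to a class by two thresholds placed to match the target class
proportions; token emission encodes the class via four token roles
(affirmative findings, negation cues, hedging cues, filler).  The two
labellers share the rule structure — hedging-count threshold first, then
negated-mention resolution — but differ in hedging threshold and negation
scope, so their disagreements (targeting ~4% of documents by default)
concentrate on documents whose severity lies within ``boundary_width`` of a
class threshold, with the primary labeller the more conservative one (it emits
"uncertain" more readily).

The latent severity is persisted per report for diagnostics only; no model
stage may consume it (the feature module rejects it by construction, operating
on tokens alone).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np

LABELS: tuple[str, str, str] = ("positive", "uncertain", "negative")

#: consistent-partition class counts of the real dual-labelled Oedema corpus
#: (positive, uncertain, negative) that the generator defaults emulate.
CONSISTENT_CLASS_COUNTS: tuple[int, int, int] = (26455, 11781, 25246)

DEFAULT_MEAN_DOC_LENGTH = 43.5

_DEFAULT_VOCAB: dict[str, tuple[str, ...]] = {
    "affirmative": (
        "edema", "oedema", "effusion", "congestion", "opacity",
        "consolidation", "infiltrate", "haziness",
    ),
    "negation": ("no", "without", "not"),
    "hedging": (
        "possible", "possibly", "may", "suggest", "suggests", "borderline",
        "questionable", "equivocal", "likely", "perhaps",
    ),
    "filler": (
        "the", "lung", "lungs", "chest", "radiograph", "heart", "silhouette",
        "stable", "unchanged", "comparison", "view", "frontal", "lateral",
        "is", "are", "within", "normal", "limits", "seen", "noted", "prior",
        "study", "patient", "mild", "moderate", "bilateral", "right", "left",
        "lower", "upper", "zone", "pleural", "cardiac", "size", "contour",
        "interval", "again", "demonstrated", "well", "expanded",
    ),
}


class ConfigurationError(ValueError):
    pass


def default_class_proportions() -> tuple[float, float, float]:
    total = sum(CONSISTENT_CLASS_COUNTS)
    return tuple(c / total for c in CONSISTENT_CLASS_COUNTS)


@dataclass(frozen=True)
class SeverityModel:
    """Generative description of the corpus: class mix, boundary geometry,
    document length and the token vocabulary by role."""

    class_proportions: tuple[float, float, float] = field(default_factory=default_class_proportions)
    boundary_width: float = 0.05
    mean_doc_length: float = DEFAULT_MEAN_DOC_LENGTH
    target_disagreement: float = 0.04
    vocab_spec: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(_DEFAULT_VOCAB))

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1 within 1e-9")
        if self.mean_doc_length <= 0:
            raise ConfigurationError("mean_doc_length must be positive")
        if self.boundary_width < 0:
            raise ConfigurationError("boundary_width must be non-negative")
        for role in ("affirmative", "negation", "hedging", "filler"):
            if not self.vocab_spec.get(role):
                raise ConfigurationError(f"token group {role!r} must be non-empty")

    # class layout along the severity axis: negative low, uncertain middle,
    # positive high — "uncertain" is the intermediate risk level.
    @property
    def thresholds(self) -> tuple[float, float]:
        p_pos, p_unc, p_neg = self.class_proportions
        return (p_neg, p_neg + p_unc)

    def class_of_severity(self, s: float) -> str:
        t_low, t_high = self.thresholds
        if s < t_low:
            return "negative"
        if s < t_high:
            return "uncertain"
        return "positive"

    def borderline_probability(self) -> float:
        """Lebesgue measure of severities within boundary_width of a threshold."""
        w = self.boundary_width
        intervals = []
        for t in self.thresholds:
            intervals.append((max(0.0, t - w), min(1.0, t + w)))
        intervals.sort()
        total, cur_lo, cur_hi = 0.0, *intervals[0]
        for lo, hi in intervals[1:]:
            if lo > cur_hi:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        total += cur_hi - cur_lo
        return total


@dataclass(frozen=True)
class LabellerRule:
    """Deterministic rule labeller.

    Order of evaluation: a document with at least ``hedging_threshold``
    hedging tokens is "uncertain"; otherwise an affirmative token not
    neutralized by a preceding negation token within ``negation_scope``
    positions makes it "positive"; otherwise "negative".
    ``conservativeness`` quantifies how readily the rule calls borderline
    documents "uncertain" (used by the generator to orient disagreement
    patterns; it does not enter the token-level decision).
    """

    hedging_threshold: int = 2
    negation_scope: int = 3
    conservativeness: float = 0.7

    def __post_init__(self):
        if self.hedging_threshold < 0 or self.negation_scope < 0:
            raise ConfigurationError("rule thresholds must be non-negative")
        if not 0.0 <= self.conservativeness <= 1.0:
            raise ConfigurationError("conservativeness must lie in [0, 1]")


#: defaults mirroring the primary labeller being the more conservative one.
DEFAULT_PRIMARY_RULE = LabellerRule(hedging_threshold=2, negation_scope=3, conservativeness=0.7)
DEFAULT_SECONDARY_RULE = LabellerRule(hedging_threshold=3, negation_scope=1, conservativeness=0.3)


@dataclass(frozen=True)
class Report:
    report_id: str
    tokens: tuple[str, ...]
    severity: float
    primary_label: str
    secondary_label: str

    def __post_init__(self):
        if not self.tokens:
            raise ValueError("tokens must be non-empty")
        for lab in (self.primary_label, self.secondary_label):
            if lab not in LABELS:
                raise ValueError(f"label {lab!r} not in {LABELS}")


class LabelledCorpus:
    """Ordered collection of :class:`Report` with provenance metadata."""

    def __init__(self, reports: list[Report], metadata: dict | None = None):
        self.reports = list(reports)
        self.metadata = dict(metadata or {})

    def __len__(self):
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __getitem__(self, i):
        return self.reports[i]

    def __eq__(self, other):
        return isinstance(other, LabelledCorpus) and self.reports == other.reports

    # -- JSONL serialization ----------------------------------------------
    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.dumps())

    def dumps(self) -> str:
        buf = io.StringIO()
        for r in self.reports:
            buf.write(json.dumps({
                "report_id": r.report_id,
                "tokens": list(r.tokens),
                "severity": r.severity,
                "primary_label": r.primary_label,
                "secondary_label": r.secondary_label,
            }, sort_keys=True))
            buf.write("\n")
        return buf.getvalue()

    @classmethod
    def from_jsonl(cls, path) -> "LabelledCorpus":
        reports = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    reports.append(Report(
                        report_id=rec["report_id"],
                        tokens=tuple(rec["tokens"]),
                        severity=float(rec.get("severity", float("nan"))),
                        primary_label=rec["primary_label"],
                        secondary_label=rec["secondary_label"],
                    ))
                except (KeyError, ValueError, json.JSONDecodeError) as exc:
                    raise ValueError(f"malformed corpus record on line {lineno}: {exc}") from exc
        return cls(reports)


# ---------------------------------------------------------------------------
# labeller
# ---------------------------------------------------------------------------

def apply_labeller(rule: LabellerRule, tokens, vocab_spec: dict | None = None) -> str:
    """Deterministically label a token list under ``rule``.

    An affirmative token at position j counts as evidence unless a negation
    token sits at some position i < j with j - i <= rule.negation_scope.
    """
    if not tokens:
        raise ValueError("cannot label an empty token list")
    vocab = vocab_spec or _DEFAULT_VOCAB
    hedging = set(vocab["hedging"])
    affirmative = set(vocab["affirmative"])
    negation = set(vocab["negation"])

    n_hedge = sum(1 for t in tokens if t in hedging)
    if n_hedge >= rule.hedging_threshold:
        return "uncertain"

    last_negation = -10**9
    for j, t in enumerate(tokens):
        if t in negation:
            last_negation = j
        elif t in affirmative and (j - last_negation) > rule.negation_scope:
            return "positive"
    return "negative"


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _insert(tokens: list[str], items: list[str], rng: np.random.Generator) -> None:
    """Insert items (kept contiguous per call) at a random position."""
    pos = int(rng.integers(0, len(tokens) + 1))
    for k, it in enumerate(items):
        tokens.insert(pos + k, it)


def _base_filler(length: int, vocab, rng) -> list[str]:
    filler = vocab["filler"]
    idx = rng.integers(0, len(filler), size=length)
    return [filler[i] for i in idx]


def _render_consistent(cls: str, length: int, vocab, rule_s: LabellerRule, rng) -> list[str]:
    tokens = _base_filler(length, vocab, rng)
    hedging, affirm, neg = vocab["hedging"], vocab["affirmative"], vocab["negation"]
    if cls == "positive":
        for _ in range(int(rng.integers(1, 3))):
            _insert(tokens, [affirm[int(rng.integers(0, len(affirm)))]], rng)
        if rng.random() < 0.4:
            _insert(tokens, [hedging[int(rng.integers(0, len(hedging)))]], rng)
    elif cls == "uncertain":
        k = rule_s.hedging_threshold + int(rng.integers(0, 2))
        for _ in range(k):
            _insert(tokens, [hedging[int(rng.integers(0, len(hedging)))]], rng)
        if rng.random() < 0.3:
            _insert(tokens, [affirm[int(rng.integers(0, len(affirm)))]], rng)
    else:  # negative: either no finding mention, or an immediately negated one
        # hedge first: a later insertion must never split the negation pair,
        # which would push the finding outside the narrower negation scope
        if rng.random() < 0.4:
            _insert(tokens, [hedging[int(rng.integers(0, len(hedging)))]], rng)
        if rng.random() < 0.5:
            _insert(tokens, [neg[int(rng.integers(0, len(neg)))],
                             affirm[int(rng.integers(0, len(affirm)))]], rng)
    return tokens


def _render_disagreement(near_high: bool, length: int, vocab,
                         rule_p: LabellerRule, rng) -> list[str]:
    """Emit an ambiguous document the two rules resolve differently.

    near the negative/uncertain threshold: hedging count equal to the primary
    threshold (below the secondary's) and no finding → primary "uncertain",
    secondary "negative".  Near the uncertain/positive threshold: either the
    same hedging ambiguity plus a clean finding (primary "uncertain",
    secondary "positive") or a finding negated at a distance inside only the
    primary's wider negation scope (primary "negative", secondary "positive").
    """
    tokens = _base_filler(length, vocab, rng)
    hedging, affirm, neg = vocab["hedging"], vocab["affirmative"], vocab["negation"]

    def add_hedges(k):
        for _ in range(k):
            _insert(tokens, [hedging[int(rng.integers(0, len(hedging)))]], rng)

    if not near_high:
        add_hedges(rule_p.hedging_threshold)
    elif rng.random() < rule_p.conservativeness:
        add_hedges(rule_p.hedging_threshold)
        _insert(tokens, [affirm[int(rng.integers(0, len(affirm)))]], rng)
    else:
        gap_filler = vocab["filler"][int(rng.integers(0, len(vocab["filler"])))]
        _insert(tokens, [neg[int(rng.integers(0, len(neg)))], gap_filler,
                         affirm[int(rng.integers(0, len(affirm)))]], rng)
    return tokens


def generate_corpus(
    model: SeverityModel = SeverityModel(),
    rule_primary: LabellerRule = DEFAULT_PRIMARY_RULE,
    rule_secondary: LabellerRule = DEFAULT_SECONDARY_RULE,
    n: int = 1000,
    seed: int = 0,
) -> LabelledCorpus:
    """Generate ``n`` reports; bit-identical under a fixed seed.

    Disagreements between the two labellers occur only on documents whose
    latent severity lies within ``model.boundary_width`` of a class threshold.
    ``boundary_width == 0`` yields an idealized fully consistent corpus.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rule_primary.hedging_threshold >= rule_secondary.hedging_threshold:
        raise ConfigurationError(
            "the primary (more conservative) labeller must have the lower hedging_threshold")

    p_border = model.borderline_probability() if model.boundary_width > 0 else 0.0
    if model.boundary_width > 0:
        if model.target_disagreement > p_border:
            raise ConfigurationError(
                f"target_disagreement={model.target_disagreement} unreachable with "
                f"boundary_width={model.boundary_width} (borderline mass {p_border:.4f})")
        p_disagree_given_border = model.target_disagreement / p_border
    else:
        p_disagree_given_border = 0.0

    rng = np.random.default_rng(seed)
    t_low, t_high = model.thresholds
    reports: list[Report] = []
    for i in range(n):
        s = float(rng.uniform())
        length = max(3, int(rng.poisson(model.mean_doc_length)))
        dist_low, dist_high = abs(s - t_low), abs(s - t_high)
        borderline = min(dist_low, dist_high) <= model.boundary_width
        if borderline and rng.random() < p_disagree_given_border:
            tokens = _render_disagreement(dist_high < dist_low, length,
                                          model.vocab_spec, rule_primary, rng)
        else:
            tokens = _render_consistent(model.class_of_severity(s), length,
                                        model.vocab_spec, rule_secondary, rng)
        reports.append(Report(
            report_id=f"r{i:06d}",
            tokens=tuple(tokens),
            severity=s,
            primary_label=apply_labeller(rule_primary, tokens, model.vocab_spec),
            secondary_label=apply_labeller(rule_secondary, tokens, model.vocab_spec),
        ))
    meta = {
        "n": n, "seed": seed,
        "class_proportions": list(model.class_proportions),
        "boundary_width": model.boundary_width,
        "target_disagreement": model.target_disagreement,
        "mean_doc_length": model.mean_doc_length,
    }
    return LabelledCorpus(reports, metadata=meta)


def corpus_stats(corpus: LabelledCorpus) -> dict:
    """Summary statistics: size, per-labeller class proportions, disagreement
    rate and mean token length."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    n = len(corpus)
    out = {"n": n}
    for which in ("primary", "secondary"):
        counts = {lab: 0 for lab in LABELS}
        for r in corpus:
            counts[getattr(r, f"{which}_label")] += 1
        out[f"{which}_proportions"] = {lab: counts[lab] / n for lab in LABELS}
    out["disagreement_rate"] = sum(
        1 for r in corpus if r.primary_label != r.secondary_label) / n
    out["mean_token_length"] = float(np.mean([len(r.tokens) for r in corpus]))
    return out


def with_overrides(model: SeverityModel, **kwargs) -> SeverityModel:
    return replace(model, **kwargs)
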