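"""Cutoff selection along the ranked score list.

Quality measures (sensitivity, specificity, precision, accuracy and the
Matthews correlation coefficient) are evaluated at every rank against
held-out benchmark gene sets; the two positive benchmarks per TF are
combined by geometric mean.  The cutoff is the rank that maximizes the
combined MCC among ranks that simultaneously satisfy accuracy >= 80%,
precision >= 80% and specificity >= 90%; ties go to the larger (more
sensitive) rank.  If no rank is feasible the unconstrained MCC argmax is
returned with a warning flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import normalize_gene_name
from .errors import ValidationError

DEFAULT_CONSTRAINTS = {"accuracy": 0.80, "precision": 0.80, "specificity": 0.90}
#: Alternative constraint wording (specificity and precision > 80%).
MATERIALS_CONSTRAINTS = {"precision": 0.80, "specificity": 0.80}

METRICS = ("sensitivity", "specificity", "precision", "accuracy", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("negative confusion count")


@dataclass(frozen=True)
class BenchmarkSet:
    """One positive benchmark plus the shared negative benchmark for a TF."""

    positives: frozenset
    negatives: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", frozenset(map(normalize_gene_name, self.positives)))
        object.__setattr__(self, "negatives", frozenset(map(normalize_gene_name, self.negatives)))
        if not self.positives or not self.negatives:
            raise ValidationError("empty benchmark class")


@dataclass
class Classification:
    """A TF's final target call: ranked list, cutoff rank and target set."""

    tf: str
    ranked: list
    cutoff: int
    metrics: dict
    constrained: bool = True
    warning: str | None = None
    targets: frozenset = field(init=False)

    def __post_init__(self) -> None:
        self.ranked = [normalize_gene_name(g) for g in self.ranked]
        if not 1 <= self.cutoff <= len(self.ranked):
            raise ValidationError("cutoff outside 1..N")
        self.targets = frozenset(self.ranked[: self.cutoff])


def confusion_at_cutoff(ranked, cutoff: int, positives, negatives) -> ConfusionCounts:
    """Counts over benchmark genes only; predicted positive = rank <= cutoff."""
    ranked = [normalize_gene_name(g) for g in ranked]
    if not 1 <= cutoff <= len(ranked):
        raise ValidationError(f"cutoff {cutoff} outside 1..{len(ranked)}")
    scored = set(ranked)
    pos = {normalize_gene_name(g) for g in positives} & scored
    neg = {normalize_gene_name(g) for g in negatives} & scored
    called = set(ranked[:cutoff])
    tp = len(pos & called)
    fp = len(neg & called)
    return ConfusionCounts(tp=tp, fp=fp, tn=len(neg) - fp, fn=len(pos) - tp)


def quality_metrics(c: ConfusionCounts) -> dict:
    """Standard confusion-matrix measures; undefined ratios are NaN, never 0.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); precision =
    TP/(TP+FP); accuracy = (TP+TN)/total; MCC = (TP*TN - FP*FN) /
    sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), NaN when any factor is zero.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    total = tp + fp + tn + fn
    if total == 0:
        raise ValidationError("no benchmark genes in the scored universe")

    def ratio(num, den):
        return num / den if den else float("nan")

    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom2) if denom2 else float("nan")
    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "accuracy": (tp + tn) / total,
        "mcc": mcc,
    }


def _metric_curves(ranked, positives, negatives) -> dict:
    """Vectorized metrics at every rank 1..N for one benchmark."""
    n = len(ranked)
    pos = {normalize_gene_name(g) for g in positives}
    neg = {normalize_gene_name(g) for g in negatives}
    in_pos = np.fromiter((g in pos for g in ranked), bool, n)
    in_neg = np.fromiter((g in neg for g in ranked), bool, n)
    tp = np.cumsum(in_pos).astype(float)
    fp = np.cumsum(in_neg).astype(float)
    npos, nneg = in_pos.sum(), in_neg.sum()
    fn, tn = npos - tp, nneg - fp
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        prec = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        acc = (tp + tn) / (npos + nneg)
        d2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = np.where(d2 > 0, (tp * tn - fp * fn) / np.sqrt(np.where(d2 > 0, d2, 1)), np.nan)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "mcc": mcc}


def metric_profile(ranked, bench_a: BenchmarkSet, bench_b: BenchmarkSet) -> pd.DataFrame:
    """Per-rank metric curves for both positive benchmarks and their
    geometric-mean combination.

    The MCC is signed, so its geometric mean is taken on the shifted scale
    (m+1)/2 in [0,1] and mapped back; rate metrics are combined directly.
    """
    ranked = [normalize_gene_name(g) for g in ranked]
    curves_a = _metric_curves(ranked, bench_a.positives, bench_a.negatives)
    curves_b = _metric_curves(ranked, bench_b.positives, bench_b.negatives)
    out = {"rank": np.arange(1, len(ranked) + 1)}
    for m in METRICS:
        a, b = curves_a[m], curves_b[m]
        out[f"{m}_a"], out[f"{m}_b"] = a, b
        if m == "mcc":
            out[m] = 2.0 * np.sqrt(((a + 1) / 2) * ((b + 1) / 2)) - 1.0
        else:
            out[m] = np.sqrt(a * b)
    return pd.DataFrame(out).set_index("rank")


def select_cutoff(profile: pd.DataFrame, ranked, tf: str,
                  constraints: dict | None = None) -> Classification:
    """Constrained-MCC cutoff selection (see module docstring)."""
    constraints = DEFAULT_CONSTRAINTS if constraints is None else constraints
    feasible = np.ones(len(profile), dtype=bool)
    for metric, floor in constraints.items():
        col = profile[metric].to_numpy(dtype=float)
        feasible &= ~np.isnan(col) & (col >= floor)
    mcc = profile["mcc"].to_numpy(dtype=float)
    ranks = profile.index.to_numpy()
    if feasible.any():
        cand = np.flatnonzero(feasible)
        best = np.nanmax(mcc[cand])
        # ties -> largest rank (more sensitive)
        cutoff = int(ranks[cand[mcc[cand] >= best - 1e-12]].max())
        constrained, warning = True, None
    else:
        if np.isnan(mcc).all():
            raise ValidationError("MCC undefined at every rank")
        best = np.nanmax(mcc)
        cutoff = int(ranks[np.flatnonzero(mcc >= best - 1e-12)].max())
        constrained = False
        warning = "no rank satisfies the quality constraints; unconstrained MCC argmax"
    at = profile.loc[cutoff]
    return Classification(
        tf=tf,
        ranked=[normalize_gene_name(g) for g in ranked],
        cutoff=cutoff,
        metrics={m: float(at[m]) for m in METRICS},
        constrained=constrained,
        warning=warning,
    )
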