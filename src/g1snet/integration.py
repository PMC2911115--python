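"""Naive additive log-likelihood scoring.

Continuous classifiers are discretized into four bins whose boundaries are
averaged order statistics of random candidate subsets: three random sets
of 40 genes are drawn from the candidate list, each set is sorted within
the classifier, and the 10th, 20th and 30th ranked values are averaged
across sets to give the three cut points.  Each bin then receives a log
likelihood score

    LLS = ln( P(bin | positive) / P(bin | negative) )

estimated from positive/negative control genes (with add-pseudocount
smoothing so empty bins stay finite), and a gene's total score is the sum
of its nine bin weights.  Categorical classifiers (wild-type peak time,
motif presence, binding category) use their categories as bins directly.
Missing evidence falls in a "missing" pseudo-bin whose weight is fixed at
zero, i.e. it is neutral rather than disqualifying.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import CONTINUOUS, declared_bins
from .datatypes import normalize_gene_name
from .errors import ParameterError, ValidationError

MISSING_BIN = "missing"


@dataclass(frozen=True)
class BinThresholds:
    """Three ordered cuts defining four half-open bins."""

    cuts: tuple
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t1, t2, t3 = self.cuts
        if not (t1 <= t2 <= t3):
            raise ValidationError(f"thresholds not ordered: {self.cuts}")


@dataclass(frozen=True)
class ControlSet:
    """Training positives and negatives for one TF."""

    tf: str
    positives: frozenset
    negatives: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", frozenset(map(normalize_gene_name, self.positives)))
        object.__setattr__(self, "negatives", frozenset(map(normalize_gene_name, self.negatives)))
        if self.positives & self.negatives:
            raise ValidationError(f"{self.tf}: control positives and negatives overlap")
        if not self.positives or not self.negatives:
            raise ValidationError(f"{self.tf}: empty control class")


@dataclass
class LLSWeightTable:
    """Per (classifier, bin) log-likelihood weights plus provenance."""

    weights: dict  # classifier id -> {bin label: float}
    pseudocount: float
    n_positives: int
    n_negatives: int

    def weight(self, classifier: str, bin_label: str) -> float:
        if classifier not in self.weights:
            raise ValidationError(f"classifier {classifier!r} absent from weight table")
        if bin_label == MISSING_BIN:
            return 0.0
        return self.weights[classifier][bin_label]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"classifier": c, "bin": b, "lls": w}
            for c, bins in self.weights.items()
            for b, w in bins.items()
        ]
        return pd.DataFrame(rows, columns=["classifier", "bin", "lls"])


def derive_bin_thresholds(values: pd.Series, n_sets: int = 3, set_size: int = 40,
                          ranks=(10, 20, 30), seed=None, rng=None) -> BinThresholds:
    """Averaged order statistics of random candidate subsets.

    Genes with missing values are excluded before drawing.  Each draw is a
    without-replacement sample of ``set_size`` genes; the cut for rank k is
    the mean over draws of the draw's k-th smallest value (1-based).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    avail = values.dropna()
    # sorted gene order makes the draw sequence reproducible across platforms
    avail = avail.loc[sorted(avail.index)]
    if len(avail) < set_size:
        raise ParameterError(
            f"only {len(avail)} genes with values; need at least {set_size}"
        )
    stats = np.empty((n_sets, len(ranks)))
    vals = avail.to_numpy(dtype=float)
    for i in range(n_sets):
        draw = rng.choice(len(vals), size=set_size, replace=False)
        ordered = np.sort(vals[draw])
        stats[i] = [ordered[r - 1] for r in ranks]
    cuts = tuple(float(x) for x in stats.mean(axis=0))
    return BinThresholds(
        cuts=cuts,
        provenance={"n_sets": n_sets, "set_size": set_size, "ranks": tuple(ranks)},
    )


def assign_bin(value, thresholds: BinThresholds):
    """Half-open binning: bin1 = (-inf, t1], bin2 = (t1, t2], bin3 = (t2, t3],
    bin4 = (t3, inf); missing values go to the 'missing' pseudo-bin."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING_BIN
    t1, t2, t3 = thresholds.cuts
    v = float(value)
    if v <= t1:
        return 1
    if v <= t2:
        return 2
    if v <= t3:
        return 3
    return 4


def bin_matrix(matrix: pd.DataFrame, specs, thresholds: dict, tf: str) -> pd.DataFrame:
    """Map a raw classifier matrix to bin labels (strings; 'missing' for NaN)."""
    out = {}
    for spec in specs:
        col = matrix[spec.id]
        if spec.kind == CONTINUOUS:
            th = thresholds[spec.id]
            out[spec.id] = [
                b if (b := assign_bin(v, th)) == MISSING_BIN else f"bin{b}" for v in col
            ]
        else:
            labels = set(declared_bins(spec, tf))
            vals = []
            for v in col:
                if isinstance(v, float) and math.isnan(v):
                    vals.append(MISSING_BIN)
                elif str(v) in labels:
                    vals.append(str(v))
                else:
                    raise ValidationError(f"{spec.id}: undeclared category {v!r}")
            out[spec.id] = vals
    return pd.DataFrame(out, index=matrix.index)


def estimate_lls_weights(binned: pd.DataFrame, specs, controls: ControlSet,
                         pseudocount: float = 0.5, tf: str | None = None) -> LLSWeightTable:
    """LLS = ln(P(bin|positive) / P(bin|negative)) per (classifier, bin).

    Frequencies are smoothed: P(bin|class) = (n_bin + c) / (N + c * n_bins)
    with pseudocount c and n_bins the classifier's declared bin count.  The
    class size N counts control genes with non-missing evidence for that
    classifier.  The missing pseudo-bin is fixed at weight zero.
    """
    tf = tf or controls.tf
    pos = [g for g in controls.positives if g in binned.index]
    neg = [g for g in controls.negatives if g in binned.index]
    if not pos or not neg:
        raise ValidationError("control genes absent from the binned matrix")
    weights: dict = {}
    for spec in specs:
        bins = declared_bins(spec, tf)
        col = binned[spec.id]
        pos_labels = col.loc[pos]
        neg_labels = col.loc[neg]
        n_pos = int((pos_labels != MISSING_BIN).sum())
        n_neg = int((neg_labels != MISSING_BIN).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValidationError(f"{spec.id}: a control class has no binned genes")
        k = len(bins)
        weights[spec.id] = {}
        for b in bins:
            p_pos = (int((pos_labels == b).sum()) + pseudocount) / (n_pos + pseudocount * k)
            p_neg = (int((neg_labels == b).sum()) + pseudocount) / (n_neg + pseudocount * k)
            if p_pos == 0 and p_neg == 0:
                # bin unobserved in both classes (possible only without
                # smoothing): carries no evidence
                weights[spec.id][b] = 0.0
                continue
            if p_pos <= 0 or p_neg <= 0:
                raise ValidationError(
                    f"{spec.id}/{b}: one-sided zero frequency; "
                    f"use pseudocount > 0 (got {pseudocount})"
                )
            weights[spec.id][b] = math.log(p_pos / p_neg)
    return LLSWeightTable(
        weights=weights,
        pseudocount=pseudocount,
        n_positives=len(controls.positives),
        n_negatives=len(controls.negatives),
    )


def total_scores(matrix: pd.DataFrame, specs, thresholds: dict,
                 weights: LLSWeightTable, tf: str) -> pd.DataFrame:
    """Per-gene LLS contributions, their SUM, and a deterministic ranking.

    Ranks run 1..N by descending SUM; exact ties are broken by
    lexicographic systematic name so output is platform-independent.
    """
    binned = bin_matrix(matrix, specs, thresholds, tf)
    contrib = {}
    for spec in specs:
        if spec.id not in weights.weights:
            raise ValidationError(f"classifier {spec.id!r} missing from weight table")
        contrib[spec.id] = [weights.weight(spec.id, b) for b in binned[spec.id]]
    table = pd.DataFrame(contrib, index=matrix.index)
    table["SUM"] = table.sum(axis=1)
    order = sorted(table.index, key=lambda g: (-table.at[g, "SUM"], g))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def ranked_genes(score_table: pd.DataFrame) -> list:
    return list(score_table.sort_values("rank").index)


def build_control_sets(universe, prior_a: dict, prior_b: dict, other_tf_genes,
                       n_pos: dict, seed=None, rng=None, n_groups: int = 5,
                       exclude_from_negatives: dict | None = None) -> dict:
    """Training controls from two prior target classifications.

    Positives come first from genes called targets of the TF by *both*
    prior classifications, excluding genes annotated for both TFs and
    genes annotated to other cell-cycle TFs; if short of ``n_pos`` they
    are topped up from the best-ranked single-study calls under the same
    exclusions.  Negatives are ``n_groups`` random draws of ``n_pos``
    genes unannotated for the TF in either prior, merged (duplicates
    removed).  ``exclude_from_negatives`` optionally bars further genes per
    TF from the negative pool (e.g. known targets in a simulation).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    universe = [normalize_gene_name(g) for g in universe]
    uniset = set(universe)
    sets_a = {tf: [normalize_gene_name(g) for g in lst] for tf, lst in prior_a.items()}
    sets_b = {tf: [normalize_gene_name(g) for g in lst] for tf, lst in prior_b.items()}
    other = {normalize_gene_name(g) for g in other_tf_genes}
    tfs = sorted(n_pos)
    dual = set()
    for tf in tfs:
        for tf2 in tfs:
            if tf2 != tf:
                dual |= (set(sets_a[tf]) | set(sets_b[tf])) & (set(sets_a[tf2]) | set(sets_b[tf2]))
    out = {}
    for tf in tfs:
        a, b = sets_a[tf], sets_b[tf]
        annotated = set(a) | set(b)
        eligible = (set(a) & set(b)) - dual - other
        core = sorted(eligible & uniset)
        need = n_pos[tf]
        if len(core) >= need:
            chosen = sorted(core, key=lambda g: (min(_rank(a, g), _rank(b, g)), g))[:need]
        else:
            chosen = list(core)
            singles = (annotated - (set(a) & set(b)) - dual - other) & uniset
            topup = sorted(singles, key=lambda g: (min(_rank(a, g), _rank(b, g)), g))
            chosen += topup[: need - len(chosen)]
            if len(chosen) < need:
                raise ParameterError(
                    f"{tf}: cannot reach {need} positives "
                    f"(short by {need - len(chosen)})"
                )
        barred = set()
        if exclude_from_negatives:
            barred = {normalize_gene_name(g) for g in exclude_from_negatives.get(tf, ())}
        unannotated = sorted(uniset - annotated - set(chosen) - barred)
        if len(unannotated) < need:
            raise ParameterError(f"{tf}: too few unannotated genes for negatives")
        merged: set = set()
        for _ in range(n_groups):
            draw = rng.choice(len(unannotated), size=need, replace=False)
            merged |= {unannotated[i] for i in draw}
        out[tf] = ControlSet(tf=tf, positives=frozenset(chosen), negatives=frozenset(merged))
    return out


def _rank(lst, gene) -> int:
    try:
        return lst.index(gene) + 1
    except ValueError:
        return 10 ** 9
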