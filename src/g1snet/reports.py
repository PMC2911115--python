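"""Validation and benchmarking analyses over a finished classification.

Covers: the consensus cell-cycle-regulated (CCR) gene rule, overlap
(Venn) reports between target lists, cell-cycle peak-phase histograms,
positional summaries of promoter motifs, leave-one-classifier-out
rescoring, MCC benchmarking of individual genome-wide location datasets
against a binding-free classification, divergently transcribed gene-pair
evaluation, and Fisher-exact functional-class enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import scan_motif
from .datatypes import normalize_gene_name
from .errors import ValidationError
from .integration import total_scores
from .thresholds import ConfusionCounts, quality_metrics

#: Functional classes adapted to be non-overlapping.
FUNCTIONAL_CLASSES = (
    "cell wall & glycosylation", "budding & polarity", "SPB", "cytoskeleton",
    "DNA conformation modification", "DNA RRR", "cell cycle", "others", "unknown",
)


@dataclass(frozen=True)
class DivergentPair:
    """Two genes sharing one intergenic promoter region, with external
    regulation truth labels in {'regulated', 'not_regulated', 'unknown'}."""

    gene_a: str
    gene_b: str
    label_a: str = "unknown"
    label_b: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_a", normalize_gene_name(self.gene_a))
        object.__setattr__(self, "gene_b", normalize_gene_name(self.gene_b))
        if self.gene_a == self.gene_b:
            raise ValidationError("divergent pair must contain two distinct genes")
        for lab in (self.label_a, self.label_b):
            if lab not in ("regulated", "not_regulated", "unknown"):
                raise ValidationError(f"unknown truth label {lab!r}")


def consensus_ccr(ranked_lists, top_n: int = 800, min_lists: int = 3) -> set:
    """Genes appearing within the first ``top_n`` entries of at least
    ``min_lists`` of the given rankings."""
    counts: dict = {}
    for lst in ranked_lists:
        lst = [normalize_gene_name(g) for g in lst]
        if len(set(lst)) != len(lst):
            raise ValidationError("duplicate gene within one ranked list")
        for g in lst[:top_n]:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_lists}


def overlap_report(sets: dict) -> pd.DataFrame:
    """All 2^k - 1 region cardinalities for 2 or 3 named gene sets, with
    percentages relative to each input set."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValidationError("overlap report takes two or three sets")
    norm = {n: {normalize_gene_name(g) for g in s} for n, s in sets.items()}
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(norm[n] for n in combo))
            outside = set.union(*(norm[n] for n in names if n not in combo), set())
            region = inside - outside
            row = {"region": "&".join(combo), "exclusive_size": len(region),
                   "intersection_size": len(inside)}
            for n in combo:
                row[f"pct_of_{n}"] = 100.0 * len(inside) / len(norm[n]) if norm[n] else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def peak_phase_distribution(targets, peaks, bin_width: float = 5.0,
                            ccr_genes=None) -> dict:
    """Histogram of cell-cycle peak percentages for a target set.

    Returns bin edges/counts over [0, 100), the count of targets with no
    determined peak (ND), and — when a consensus CCR set is supplied — the
    fraction of targets that are CCR.
    """
    targets = {normalize_gene_name(g) for g in targets}
    vals = np.array([peaks.get(g) for g in sorted(targets)], dtype=float)
    nd = int(np.isnan(vals).sum())
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, edges = np.histogram(vals[~np.isnan(vals)], bins=edges)
    out = {"bin_edges": edges, "counts": counts, "n_nd": nd, "n_targets": len(targets)}
    if ccr_genes is not None:
        ccr = {normalize_gene_name(g) for g in ccr_genes}
        out["ccr_fraction"] = len(targets & ccr) / len(targets) if targets else np.nan
    return out


def motif_position_summary(targets, promoters, motif: str,
                           boundaries=(200, 500)) -> dict:
    """Positional accounting of motif occurrences in target promoters.

    Zone 1 is positions 1..b1 upstream of the TSS (boundary inclusive),
    zone 2 is b1+1..b2, zone 3 beyond b2.  Reports both the per-occurrence
    zone fractions and the per-gene breakdown (at least one proximal site,
    sites only beyond zone 1, or no site at all).
    """
    b1, b2 = boundaries
    targets = sorted({normalize_gene_name(g) for g in targets})
    occ = np.zeros(3, dtype=int)
    gene_proximal = gene_distal_only = gene_none = 0
    per_gene = {}
    for g in targets:
        seq = promoters.sequence(g)
        if seq is None:
            continue
        _, positions = scan_motif(seq, motif, window=len(seq))
        zones = [0 if p <= b1 else (1 if p <= b2 else 2) for p in positions]
        for z in zones:
            occ[z] += 1
        if 0 in zones:
            gene_proximal += 1
            per_gene[g] = "proximal"
        elif zones:
            gene_distal_only += 1
            per_gene[g] = "distal_only"
        else:
            gene_none += 1
            per_gene[g] = "none"
    n_occ = int(occ.sum())
    n_genes = gene_proximal + gene_distal_only + gene_none
    return {
        "zone_occurrences": occ,
        "zone_fractions": occ / n_occ if n_occ else np.full(3, np.nan),
        "n_genes": n_genes,
        "gene_fractions": {
            "proximal": gene_proximal / n_genes if n_genes else np.nan,
            "distal_only": gene_distal_only / n_genes if n_genes else np.nan,
            "none": gene_none / n_genes if n_genes else np.nan,
        },
        "per_gene": per_gene,
        "boundaries": (b1, b2),
    }


def rescore_without(classifier_id: str, matrix, specs, thresholds, weights, tf: str):
    """Rerun scoring with one classifier removed.

    Because scoring is a plain sum of bin weights, this equals subtracting
    the removed classifier's contribution column from the full totals.
    """
    kept = [s for s in specs if s.id != classifier_id]
    if len(kept) == len(specs):
        raise ValidationError(f"classifier {classifier_id!r} not active")
    sub_weights = type(weights)(
        weights={k: v for k, v in weights.weights.items() if k != classifier_id},
        pseudocount=weights.pseudocount,
        n_positives=weights.n_positives,
        n_negatives=weights.n_negatives,
    )
    return total_scores(matrix, kept, thresholds, sub_weights, tf)


def benchmark_location_dataset(calls, reference_ranked, cutoffs=None) -> pd.DataFrame:
    """MCC of one binding-call set against a binding-free classification.

    At each cutoff the reference's top-ranked genes are taken as positives
    and the remaining candidates as negatives; the study's bound/unbound
    status is the prediction.  MCC is NaN where any confusion-margin factor
    is zero (e.g. an empty call set).
    """
    ranked = [normalize_gene_name(g) for g in reference_ranked]
    bound = {normalize_gene_name(g) for g in calls.bound_genes}
    n = len(ranked)
    if cutoffs is None:
        cutoffs = range(1, n + 1)
    is_bound = np.fromiter((g in bound for g in ranked), bool, n)
    tp = np.cumsum(is_bound).astype(float)  # bound among top-r
    r = np.arange(1, n + 1, dtype=float)
    fn = r - tp
    total_bound = float(is_bound.sum())
    fp = total_bound - tp
    tn = (n - r) - fp
    with np.errstate(invalid="ignore"):
        d2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = np.where(d2 > 0, (tp * tn - fp * fn) / np.sqrt(np.where(d2 > 0, d2, 1)), np.nan)
    idx = [c - 1 for c in cutoffs]
    return pd.DataFrame({
        "cutoff": [c for c in cutoffs],
        "mcc": mcc[idx],
        "study": calls.study_id,
        "tf": calls.tf,
    })


def divergent_pair_mcc(pairs, classification) -> dict:
    """Confusion metrics over labeled members of divergently transcribed
    gene pairs; 'unknown' labels contribute nothing."""
    targets = classification.targets
    tp = fp = tn = fn = 0
    for pair in pairs:
        for gene, label in ((pair.gene_a, pair.label_a), (pair.gene_b, pair.label_b)):
            if label == "unknown":
                continue
            predicted = gene in targets
            actual = label == "regulated"
            if predicted and actual:
                tp += 1
            elif predicted:
                fp += 1
            elif actual:
                fn += 1
            else:
                tn += 1
    return quality_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))


def functional_enrichment(targets, classes: dict, universe) -> pd.DataFrame:
    """Two-tailed Fisher exact test per functional class.

    ``classes`` maps gene -> class label; genes of class 'unknown' are
    excluded from percentages (but kept in the 2x2 tables under their own
    class row).  Empty classes are skipped.  A Bonferroni column is added
    for transparency; the primary values are raw p-values.
    """
    universe = {normalize_gene_name(g) for g in universe}
    targets = {normalize_gene_name(g) for g in targets}
    if not targets <= universe:
        raise ValidationError("targets must be a subset of the universe")
    cls = {normalize_gene_name(g): c for g, c in classes.items()}
    labels = [c for c in FUNCTIONAL_CLASSES if any(cls.get(g) == c for g in universe)]
    known = {g for g in universe if cls.get(g, "unknown") != "unknown"}
    rows = []
    for label in labels:
        in_class = {g for g in universe if cls.get(g, "unknown") == label}
        a = len(targets & in_class)
        b = len(targets - in_class)
        c = len(in_class - targets)
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        frac_t = a / len(targets & known) if label != "unknown" and targets & known else np.nan
        frac_u = len(in_class) / len(known) if label != "unknown" and known else np.nan
        fold = frac_t / frac_u if frac_u else np.nan
        rows.append({
            "class": label, "n_class": len(in_class), "n_target_in_class": a,
            "pct_targets": 100 * frac_t if frac_t == frac_t else np.nan,
            "pct_universe": 100 * frac_u if frac_u == frac_u else np.nan,
            "fold_enrichment": fold, "p_value": p,
            "p_bonferroni": min(1.0, p * len(labels)),
        })
    return pd.DataFrame(rows)
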