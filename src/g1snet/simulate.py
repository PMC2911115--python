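"""Synthetic datasets with planted MBF/SBF targets.

The generator emulates the statistical structure the analysis assumes: a
candidate list of 445 genes of which 111 are MBF targets and 94 SBF
targets (36 shared); Cln3-induction time courses where targets respond in
wild type, lose the response in the cognate single deletion, and are flat
in swi6 and swi4 mbp1 double mutants and in the no-induction control;
four binding studies with study-specific sensitivity (the Swi4-rich study
being the most sensitive for Swi4) and a common false-positive rate;
promoters with MCB/SCB consensus sites planted preferentially close to
the TSS of the cognate targets (0.65 vs 0.045 proximal MCB, 0.78 vs 0.33
proximal SCB); unimodal early cell-cycle peaks for MBF targets and a
bimodal distribution for SBF targets; and overexpression responses that
separate targets from background.  Ground truth is returned alongside the
data so recovery can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    BINDING_STUDIES,
    STRAINS,
    TIMEPOINTS,
    BindingCallSet,
    CellCyclePeakMap,
    ExpressionPanel,
    OverexpressionResponse,
    PromoterRecord,
    PromoterSet,
)
from .errors import ParameterError
from .integration import build_control_sets
from .thresholds import BenchmarkSet


def _default_sensitivity() -> dict:
    # the multi-condition study is the most sensitive for Mbp1,
    # the Swi4-rich study for Swi4
    return {
        ("iyer", "Mbp1"): 0.30, ("simon", "Mbp1"): 0.35,
        ("lee", "Mbp1"): 0.45, ("harbison", "Mbp1"): 0.70,
        ("iyer", "Swi4"): 0.70, ("simon", "Swi4"): 0.35,
        ("lee", "Swi4"): 0.40, ("harbison", "Swi4"): 0.45,
    }


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters of the synthetic dataset (defaults mirror the
    445-candidate design with 111/94 targets, 36 shared)."""

    n_genes: int = 445
    n_mbf_true: int = 111
    n_sbf_true: int = 94
    n_shared: int = 36

    # induction model (log2 units)
    amplitude_median: float = 2.0
    amplitude_sigma: float = 0.35
    noise_sd: float = 0.25
    peak_probs: tuple = ((20, 0.30), (40, 0.55), (60, 0.15), (80, 0.0))
    #: residual response fraction: cognate single deletion, shared target in
    #: either single deletion, swi6 deletion, swi4 mbp1 double deletion
    atten_cognate: float = 0.15
    atten_shared_single: float = 0.5
    atten_swi6: float = 0.05
    atten_double: float = 0.05

    # binding studies
    binding_sensitivity: dict = field(default_factory=_default_sensitivity)
    binding_fpr: float = 0.03

    # promoters
    promoter_length: int = 1000
    promoter_gc: float = 0.38
    mbf_motif: str = "ACGCGT"
    sbf_motif: str = "CRCGAA"
    mbf_window: int = 200
    sbf_window: int = 400
    p_mbf_target_proximal: float = 0.65
    p_mbf_background_proximal: float = 0.045
    p_sbf_target_proximal: float = 0.78
    p_sbf_background_proximal: float = 0.33
    p_distal_mcb: float = 0.30
    p_distal_scb: float = 0.30

    # cell-cycle peaks (percent of cycle)
    cc_mbf_mean: float = 20.0
    cc_mbf_sd: float = 5.0
    cc_sbf_means: tuple = (25.0, 40.0)
    cc_sbf_sd: float = 5.0
    non_ccr_fraction: float = 0.3
    target_nd_prob: float = 0.08

    # overexpression responses (mean, sd)
    oe_cln3_target: tuple = (1.5, 0.5)
    oe_cln3_background: tuple = (0.0, 0.4)
    oe_clb2_target: tuple = (-0.5, 0.4)
    oe_clb2_background: tuple = (0.0, 0.4)
    oe_missing_prob: float = 0.05

    # pseudo prior-literature classifications used for controls/benchmarks
    label_noise: float = 0.10
    prior_pad_frac: float = 0.15
    n_other_tf: int = 20

    def validate(self) -> None:
        if self.n_shared > min(self.n_mbf_true, self.n_sbf_true):
            raise ParameterError("n_shared exceeds a target-class size")
        if self.n_mbf_true + self.n_sbf_true - self.n_shared >= self.n_genes:
            raise ParameterError("targets exhaust the candidate list")
        probs = [
            self.p_mbf_target_proximal, self.p_mbf_background_proximal,
            self.p_sbf_target_proximal, self.p_sbf_background_proximal,
            self.binding_fpr, self.label_noise, self.non_ccr_fraction,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ParameterError("probabilities must lie in [0, 1]")
        if self.amplitude_median <= 0:
            raise ParameterError("amplitude must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    mbf_targets: frozenset
    sbf_targets: frozenset
    params: SimulationParams
    seed: int

    @property
    def shared(self) -> frozenset:
        return self.mbf_targets & self.sbf_targets

    def targets(self, tf: str) -> frozenset:
        return self.mbf_targets if tf == "Mbp1" else self.sbf_targets


@dataclass
class SyntheticDataset:
    expression: ExpressionPanel
    binding: dict  # tf -> {study_id: BindingCallSet}
    promoters: PromoterSet
    cc_peaks: CellCyclePeakMap
    overexpression: OverexpressionResponse
    truth: SyntheticTruth
    planted_motifs: dict  # gene -> tuple of (motif, upstream position)

    @property
    def genes(self) -> list:
        return self.expression.genes


@dataclass
class TFBenchmarks:
    """Two positive benchmarks sharing one negative benchmark."""

    pos_a: BenchmarkSet
    pos_b: BenchmarkSet

    @property
    def negatives(self) -> frozenset:
        return self.pos_a.negatives


# --- promoters --------------------------------------------------------------

def generate_promoter(length: int, gc: float, planted, seed=None, rng=None) -> str:
    """Random background at the given GC with consensus motifs planted at
    the requested upstream positions (position = 5'-most base, measured in
    bp upstream of the TSS).  Degenerate letters resolve uniformly."""
    from .classifiers import IUPAC

    if rng is None:
        rng = np.random.default_rng(seed)
    spans = []
    for motif, pos in planted:
        lo, hi = pos - len(motif) + 1, pos
        if lo < 1 or hi > length:
            raise ParameterError(f"motif {motif!r} at {pos} does not fit in {length} bp")
        for lo2, hi2 in spans:
            if lo <= hi2 and lo2 <= hi:
                raise ParameterError("planted motifs overlap")
        spans.append((lo, hi))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length, p=p))
    for motif, pos in planted:
        i0 = length - pos
        for j, ch in enumerate(motif):
            opts = IUPAC[ch]
            seq[i0 + j] = opts if len(opts) == 1 else opts[rng.integers(len(opts))]
    return "".join(seq)


def _plant_nonoverlapping(plants, motif, lo, hi, rng, max_tries=50):
    """Pick an upstream position in [lo, hi] avoiding existing plants."""
    m = len(motif)
    for _ in range(max_tries):
        pos = int(rng.integers(lo, hi + 1))
        lo1, hi1 = pos - m + 1, pos
        clash = any(
            lo1 <= x and (x - len(mo) + 1) <= hi1 for mo, x in plants
        )
        if not clash:
            plants.append((motif, pos))
            return pos
    return None


# --- dataset ----------------------------------------------------------------

_SHAPE_BY_DISTANCE = {0: 1.0, 1: 0.45, 2: 0.15, 3: 0.05}


def _response_shape(peak: int) -> np.ndarray:
    idx = TIMEPOINTS.index(peak)
    return np.array([_SHAPE_BY_DISTANCE[abs(i - idx)] for i in range(4)])


def generate_dataset(params: SimulationParams | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate one complete synthetic dataset; same seed, same bytes."""
    params = params or SimulationParams()
    params.validate()
    rng_truth, rng_expr, rng_bind, rng_prom, rng_peak, rng_oe = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(6)
    )

    genes = [f"G{i:04d}" for i in range(1, params.n_genes + 1)]
    perm = list(rng_truth.permutation(genes))
    shared = set(perm[: params.n_shared])
    mbf_only = set(perm[params.n_shared: params.n_mbf_true])
    sbf_off = params.n_mbf_true
    sbf_only = set(perm[sbf_off: sbf_off + params.n_sbf_true - params.n_shared])
    mbf = frozenset(shared | mbf_only)
    sbf = frozenset(shared | sbf_only)
    truth = SyntheticTruth(mbf_targets=mbf, sbf_targets=sbf, params=params, seed=seed)

    # expression
    peaks_t = [t for t, _ in params.peak_probs]
    peaks_p = np.array([p for _, p in params.peak_probs], dtype=float)
    peaks_p /= peaks_p.sum()
    per_strain = {s: np.zeros((len(genes), 4)) for s in STRAINS}
    for gi, g in enumerate(genes):
        is_mbf, is_sbf = g in mbf, g in sbf
        if is_mbf or is_sbf:
            amp = rng_expr.lognormal(mean=math.log(params.amplitude_median),
                                     sigma=params.amplitude_sigma)
            peak = peaks_t[rng_expr.choice(len(peaks_t), p=peaks_p)]
            shape = amp * _response_shape(peak)
        else:
            shape = np.zeros(4)
        for strain in STRAINS:
            scale = _attenuation(is_mbf, is_sbf, strain, params)
            per_strain[strain][gi] = scale * shape
    for strain in STRAINS:
        per_strain[strain] += rng_expr.normal(0.0, params.noise_sd, size=(len(genes), 4))
    expression = ExpressionPanel.build(genes, per_strain)

    # binding
    binding: dict = {}
    for tf, targets in (("Mbp1", mbf), ("Swi4", sbf)):
        binding[tf] = {}
        for study in BINDING_STUDIES:
            sens = params.binding_sensitivity[(study, tf)]
            bound = set()
            for g in genes:
                p = sens if g in targets else params.binding_fpr
                if rng_bind.random() < p:
                    bound.add(g)
            binding[tf][study] = BindingCallSet(
                study_id=study, tf=tf, bound_genes=frozenset(bound),
                call_threshold_note="synthetic calls at configured sensitivity/FPR",
            )

    # promoters + planted motifs
    promoters = PromoterSet(max_length=params.promoter_length)
    planted_motifs: dict = {}
    L = params.promoter_length
    for g in genes:
        plants: list = []
        p_mcb = params.p_mbf_target_proximal if g in mbf else params.p_mbf_background_proximal
        if rng_prom.random() < p_mcb:
            _plant_nonoverlapping(plants, params.mbf_motif,
                                  len(params.mbf_motif), params.mbf_window, rng_prom)
        p_scb = params.p_sbf_target_proximal if g in sbf else params.p_sbf_background_proximal
        if rng_prom.random() < p_scb:
            _plant_nonoverlapping(plants, params.sbf_motif,
                                  len(params.sbf_motif), params.sbf_window, rng_prom)
        if rng_prom.random() < params.p_distal_mcb:
            _plant_nonoverlapping(plants, "ACGCG", 501, L, rng_prom)
        if rng_prom.random() < params.p_distal_scb:
            _plant_nonoverlapping(plants, params.sbf_motif, params.sbf_window + 1, L, rng_prom)
        seq = generate_promoter(L, params.promoter_gc, plants, rng=rng_prom)
        promoters.add(PromoterRecord(gene=g, sequence=seq, anchor="tss"))
        planted_motifs[g] = tuple(plants)

    # cell-cycle peaks
    peak_vals = {}
    for g in genes:
        if g in mbf or g in sbf:
            if rng_peak.random() < params.target_nd_prob:
                peak_vals[g] = np.nan
                continue
            mbf_like = g in mbf and (g not in sbf or rng_peak.random() < 0.5)
            if mbf_like:
                v = rng_peak.normal(params.cc_mbf_mean, params.cc_mbf_sd)
            else:
                mu = params.cc_sbf_means[int(rng_peak.random() < 0.5)]
                v = rng_peak.normal(mu, params.cc_sbf_sd)
            peak_vals[g] = float(np.clip(v, 0.0, 99.99))
        else:
            if rng_peak.random() < params.non_ccr_fraction:
                peak_vals[g] = np.nan
            else:
                peak_vals[g] = float(rng_peak.uniform(0.0, 100.0))
    cc_peaks = CellCyclePeakMap(pd.Series(peak_vals, dtype=float))

    # overexpression
    oe_rows = {}
    for g in genes:
        is_target = g in mbf or g in sbf
        mu_c, sd_c = params.oe_cln3_target if is_target else params.oe_cln3_background
        mu_b, sd_b = params.oe_clb2_target if is_target else params.oe_clb2_background
        cln3 = rng_oe.normal(mu_c, sd_c)
        clb2 = rng_oe.normal(mu_b, sd_b)
        if rng_oe.random() < params.oe_missing_prob:
            cln3 = np.nan
        if rng_oe.random() < params.oe_missing_prob:
            clb2 = np.nan
        oe_rows[g] = {"cln3_induction": cln3, "clb2_response": clb2}
    overexpression = OverexpressionResponse(pd.DataFrame.from_dict(oe_rows, orient="index"))

    return SyntheticDataset(
        expression=expression, binding=binding, promoters=promoters,
        cc_peaks=cc_peaks, overexpression=overexpression, truth=truth,
        planted_motifs=planted_motifs,
    )


def _attenuation(is_mbf: bool, is_sbf: bool, strain: str, p: SimulationParams) -> float:
    if not (is_mbf or is_sbf) or strain == "cln3control":
        return 0.0
    if strain == "wt":
        return 1.0
    if strain in ("swi6", "swi4mbp1"):
        return p.atten_swi6 if strain == "swi6" else p.atten_double
    if strain == "mbp1":
        if is_mbf and is_sbf:
            return p.atten_shared_single
        return p.atten_cognate if is_mbf else 1.0
    if strain == "swi4":
        if is_mbf and is_sbf:
            return p.atten_shared_single
        return p.atten_cognate if is_sbf else 1.0
    raise ParameterError(f"unknown strain {strain!r}")


# --- pseudo prior literature, controls and benchmarks -----------------------

def simulate_prior_classifications(truth: SyntheticTruth, universe, params, rng) -> dict:
    """One noisy ranked target list per TF, emulating a prior published
    classification: truth labels minus dropouts (label noise) plus a pad of
    non-targets, ordered by a noisy confidence score."""
    out = {}
    for tf in ("Mbp1", "Swi4"):
        targets = sorted(truth.targets(tf))
        non = sorted(set(universe) - set(targets))
        retained = [g for g in targets if rng.random() >= params.label_noise]
        n_pad = int(round(params.prior_pad_frac * len(targets)))
        pad_idx = rng.choice(len(non), size=n_pad, replace=False)
        pad = [non[i] for i in pad_idx]
        scored = [(g, rng.uniform(0.6, 1.0)) for g in retained]
        scored += [(g, rng.uniform(0.3, 0.95)) for g in pad]
        scored.sort(key=lambda t: (-t[1], t[0]))
        out[tf] = [g for g, _ in scored]
    return out


def split_truth_controls(truth: SyntheticTruth, universe, params: SimulationParams | None = None,
                         seed: int = 0):
    """Derive training controls and held-out benchmarks from planted truth.

    Two pseudo prior classifications play the role of the prior literature;
    training positives (40 for Mbp1, 32 for Swi4) come from their
    intersection excluding dual-regulated genes, negatives from five merged
    random draws of unannotated genes.  Each positive benchmark holds ten
    dual-regulated plus thirty single-TF literature targets disjoint from
    the training positives; the negative benchmark merges two draws of 40
    (so somewhat fewer than 80 after de-duplication).
    """
    params = params or truth.params
    universe = list(universe)
    missing = (truth.mbf_targets | truth.sbf_targets) - set(universe)
    if missing:
        raise ParameterError("universe does not contain all truth genes")
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_prior = np.random.default_rng(ss[0])
    rng_ctrl = np.random.default_rng(ss[1])
    rng_bench = np.random.default_rng(ss[2])

    prior_a = simulate_prior_classifications(truth, universe, params, rng_prior)
    prior_b = simulate_prior_classifications(truth, universe, params, rng_prior)
    non_targets = sorted(set(universe) - truth.mbf_targets - truth.sbf_targets)
    other_idx = rng_prior.choice(len(non_targets), size=min(params.n_other_tf, len(non_targets)),
                                 replace=False)
    other_tf = {non_targets[i] for i in other_idx}

    controls = build_control_sets(
        universe, prior_a, prior_b, other_tf,
        n_pos={"Mbp1": 40, "Swi4": 32}, rng=rng_ctrl,
        # training negatives must not hide a planted target of the same TF
        exclude_from_negatives={"Mbp1": truth.mbf_targets, "Swi4": truth.sbf_targets},
    )

    lit = {tf: set(prior_a[tf]) | set(prior_b[tf]) for tf in ("Mbp1", "Swi4")}
    dual = lit["Mbp1"] & lit["Swi4"]
    benchmarks = {}
    for tf in ("Mbp1", "Swi4"):
        training = controls[tf].positives
        dual_pool = sorted(dual - training)
        single_pool = sorted(lit[tf] - dual - training)
        if len(dual_pool) < 10 or len(single_pool) < 30:
            raise ParameterError(
                f"{tf}: benchmark pools too small "
                f"(dual {len(dual_pool)}, single {len(single_pool)})"
            )
        pos_sets = []
        for _ in range(2):
            d = rng_bench.choice(len(dual_pool), size=10, replace=False)
            s = rng_bench.choice(len(single_pool), size=30, replace=False)
            pos_sets.append(frozenset({dual_pool[i] for i in d} | {single_pool[i] for i in s}))
        unannotated = sorted(set(universe) - lit[tf])
        negs: set = set()
        for _ in range(2):
            d = rng_bench.choice(len(unannotated), size=40, replace=False)
            negs |= {unannotated[i] for i in d}
        negs -= set(pos_sets[0]) | set(pos_sets[1])
        benchmarks[tf] = TFBenchmarks(
            pos_a=BenchmarkSet(positives=pos_sets[0], negatives=frozenset(negs)),
            pos_b=BenchmarkSet(positives=pos_sets[1], negatives=frozenset(negs)),
        )
    return controls, benchmarks
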