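"""End-to-end orchestration: simulate -> features -> score -> threshold -> report.

Every run is driven by one RunConfig and one seed.  The global seed
spawns per-stage child seeds through ``numpy.random.SeedSequence(seed)``
in a fixed order (0 simulate, 1 controls/benchmarks, 2 binning), so a
stage can be replayed in isolation.  All artifacts are TSV (or FASTA)
files carrying the config hash in a comment header, and the manifest
records a SHA-256 digest per artifact: identical config and seed give
byte-identical artifacts.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .classifiers import CONTINUOUS, assemble_classifier_matrix, classifier_specs
from .config import RunConfig, validate_config
from .datatypes import BINDING_STUDIES, BindingCallSet
from .errors import G1SNetError
from .integration import (
    ControlSet,
    LLSWeightTable,
    derive_bin_thresholds,
    ranked_genes,
    total_scores,
)
from .reports import (
    benchmark_location_dataset,
    motif_position_summary,
    overlap_report,
    peak_phase_distribution,
    rescore_without,
)
from .simulate import SyntheticDataset, TFBenchmarks, generate_dataset, split_truth_controls
from .thresholds import BenchmarkSet, metric_profile, select_cutoff


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    results: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


class PipelineError(G1SNetError):
    pass


@dataclass
class TFResult:
    """Everything the pipeline computes for one TF."""

    tf: str
    specs: list
    matrix: pd.DataFrame
    thresholds: dict
    weights: LLSWeightTable
    scores: pd.DataFrame
    profile: pd.DataFrame
    classification: object


def classify_tf(dataset, controls, benchmarks, tf: str, rng,
                preset: str = "methods-text", constraints: dict | None = None,
                pseudocount: float = 0.5, epsilon: float = 0.1,
                motif_windows: dict | None = None,
                n_sets: int = 3, set_size: int = 40, ranks=(10, 20, 30)) -> TFResult:
    """Score one TF in memory: features -> bins -> LLS weights -> ranked
    scores -> benchmark metric profile -> constrained-MCC cutoff."""
    from .integration import bin_matrix, estimate_lls_weights

    specs = classifier_specs(tf, preset)
    matrix = assemble_classifier_matrix(
        dataset, tf, specs, epsilon=epsilon, motif_windows=motif_windows
    )
    thresholds = {
        s.id: derive_bin_thresholds(matrix[s.id].astype(float), n_sets=n_sets,
                                    set_size=set_size, ranks=ranks, rng=rng)
        for s in specs if s.kind == CONTINUOUS
    }
    binned = bin_matrix(matrix, specs, thresholds, tf)
    weights = estimate_lls_weights(binned, specs, controls[tf],
                                   pseudocount=pseudocount, tf=tf)
    scores = total_scores(matrix, specs, thresholds, weights, tf)
    ranked = ranked_genes(scores)
    bench = benchmarks[tf]
    profile = metric_profile(ranked, bench.pos_a, bench.pos_b)
    cls = select_cutoff(profile, ranked, tf, constraints=constraints)
    return TFResult(tf=tf, specs=specs, matrix=matrix, thresholds=thresholds,
                    weights=weights, scores=scores, profile=profile,
                    classification=cls)


def run_synthetic(seed: int, params=None, preset: str = "methods-text",
                  constraints: dict | None = None, tfs=("Mbp1", "Swi4")):
    """Generate a synthetic dataset and classify both TFs in memory.

    Returns ``(dataset, controls, benchmarks, {tf: TFResult})``.  The seed
    spawns the same per-stage children as ``run_pipeline``.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    dataset = generate_dataset(params, seed=_seed_of(children[0]))
    controls, benchmarks = split_truth_controls(
        dataset.truth, dataset.genes, params or dataset.truth.params,
        seed=_seed_of(children[1]),
    )
    rng = np.random.default_rng(children[2])
    results = {
        tf: classify_tf(dataset, controls, benchmarks, tf, rng,
                        preset=preset, constraints=constraints)
        for tf in tfs
    }
    return dataset, controls, benchmarks, results


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(verbose: bool, stage: str, msg: str) -> None:
    if verbose:
        print(f"[g1snet:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig | dict | None = None, out_dir=".",
                 verbose: bool = False) -> RunManifest:
    """Run the full analysis and write all artifacts under ``out_dir``."""
    cfg, warns = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash, seed=cfg.seed, warnings=list(warns),
                           started=datetime.datetime.now().isoformat(timespec="seconds"))
    header = [f"config_hash={cfg.config_hash}", f"seed={cfg.seed}", f"preset={cfg.preset}"]
    children = np.random.SeedSequence(cfg.seed).spawn(3)

    def record(stage: str, path: Path) -> None:
        manifest.digests[str(path.name)] = _sha256(path)

    def stage(name):
        manifest.stages.append(name)
        _log(verbose, name, "start")

    try:
        stage("simulate")
        if cfg.mode == "synthetic":
            dataset = generate_dataset(cfg.sim, seed=_seed_of(children[0]))
            write_dataset(dataset, out, header)
            for p in sorted(out.glob("dataset_*")) + [out / "promoters.fasta"]:
                record("simulate", p)
        else:
            dataset = load_dataset_from_paths(cfg.paths)
        _log(verbose, "simulate", f"{len(dataset.genes)} candidate genes")

        stage("controls")
        if cfg.mode == "synthetic":
            controls, benchmarks = split_truth_controls(
                dataset.truth, dataset.genes, cfg.sim, seed=_seed_of(children[1])
            )
            _write_controls(controls, benchmarks, out, header)
            record("controls", out / "controls.tsv")
            record("controls", out / "benchmarks.tsv")
        else:
            controls = load_controls(cfg.paths["controls"])
            benchmarks = load_benchmarks(cfg.paths["benchmarks"])

        rng_bins = np.random.default_rng(children[2])
        results = {}
        for tf in cfg.tfs:
            stage(f"features+score+threshold:{tf}")
            res = classify_tf(
                dataset, controls, benchmarks, tf, rng_bins,
                preset=cfg.preset, constraints=cfg.constraints,
                pseudocount=cfg.pseudocount, epsilon=cfg.epsilon,
                motif_windows=cfg.motif_windows, n_sets=cfg.n_sets,
                set_size=cfg.set_size, ranks=cfg.ranks,
            )
            results[tf] = res
            flat = res.matrix.copy()
            flat.insert(0, "gene", flat.index)
            gio.write_tsv(flat, out / f"matrix_{tf}.tsv", header)
            gio.write_tsv(res.weights.to_frame(), out / f"weights_{tf}.tsv", header)
            gio.write_ranked_scores(res.scores, out / f"scores_{tf}.tsv", header)
            gio.write_tsv(res.profile.reset_index(), out / f"profile_{tf}.tsv", header)
            cls = res.classification
            if cls.warning:
                manifest.warnings.append(f"{tf}: {cls.warning}")
            tdf = res.scores.head(cls.cutoff).copy()
            tdf.insert(0, "gene", tdf.index)
            gio.write_tsv(tdf, out / f"targets_{tf}.tsv", header + [f"cutoff={cls.cutoff}"])
            for name in ("matrix", "weights", "scores", "profile", "targets"):
                record(tf, out / f"{name}_{tf}.tsv")
            manifest.results[tf] = {
                "cutoff": cls.cutoff,
                "n_targets": len(cls.targets),
                "constrained": cls.constrained,
                "metrics_at_cutoff": cls.metrics,
            }
            _log(verbose, f"threshold:{tf}",
                 f"cutoff={cls.cutoff} constrained={cls.constrained}")

        stage("report")
        if len(cfg.tfs) == 2:
            sets = {tf: results[tf].classification.targets for tf in cfg.tfs}
            ov = overlap_report(sets)
            gio.write_tsv(ov, out / "overlap.tsv", header)
            record("report", out / "overlap.tsv")
            manifest.results["overlap_union"] = int(len(sets[cfg.tfs[0]] | sets[cfg.tfs[1]]))
        for tf in cfg.tfs:
            res = results[tf]
            cls = res.classification
            hist = peak_phase_distribution(cls.targets, dataset.cc_peaks, bin_width=5.0)
            hdf = pd.DataFrame({
                "bin_start": hist["bin_edges"][:-1],
                "bin_end": hist["bin_edges"][1:],
                "count": hist["counts"],
            })
            gio.write_tsv(hdf, out / f"peak_hist_{tf}.tsv",
                          header + [f"n_nd={hist['n_nd']}"])
            record("report", out / f"peak_hist_{tf}.tsv")
            zones = motif_position_summary(
                cls.targets, dataset.promoters, cfg.report_motifs[tf]
            )
            zdf = pd.DataFrame({
                "zone": ["proximal", "middle", "distal"],
                "occurrences": hist_arr(zones["zone_occurrences"]),
                "fraction": hist_arr(zones["zone_fractions"]),
            })
            gio.write_tsv(zdf, out / f"motif_zones_{tf}.tsv", header)
            record("report", out / f"motif_zones_{tf}.tsv")
            # location-study benchmarking against a binding-free classification
            scores_nb = rescore_without("binding", res.matrix, res.specs,
                                        res.thresholds, res.weights, tf)
            ranked_nb = ranked_genes(scores_nb)
            frames = [
                benchmark_location_dataset(dataset.binding[tf][study], ranked_nb)
                for study in BINDING_STUDIES
            ]
            gio.write_tsv(pd.concat(frames, ignore_index=True),
                          out / f"location_mcc_{tf}.tsv", header)
            record("report", out / f"location_mcc_{tf}.tsv")

        manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
        (out / "manifest.json").write_text(manifest.to_json())
        return manifest
    except G1SNetError as exc:
        current = manifest.stages[-1] if manifest.stages else "setup"
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc


def hist_arr(a):
    return list(np.asarray(a))


def _seed_of(seed_seq) -> int:
    return int(seed_seq.generate_state(1)[0] % (2 ** 31))


# --- dataset (de)serialization ---------------------------------------------

def write_dataset(dataset: SyntheticDataset, out: Path, header=()) -> None:
    gio.write_expression_panel(dataset.expression, out / "dataset_expression.tsv", header)
    gio.write_promoters_fasta(dataset.promoters, out / "promoters.fasta")
    gio.write_peak_map(dataset.cc_peaks, out / "dataset_cc_peaks.tsv", header)
    gio.write_overexpression(dataset.overexpression, out / "dataset_overexpression.tsv", header)
    binding_sets = {
        f"{tf}:{study}": calls.bound_genes
        for tf, per_study in dataset.binding.items()
        for study, calls in per_study.items()
    }
    gio.write_gene_sets(binding_sets, out / "dataset_binding.tsv", header)
    gio.write_gene_sets(
        {"mbf_truth": dataset.truth.mbf_targets, "sbf_truth": dataset.truth.sbf_targets},
        out / "dataset_truth.tsv", header,
    )


def load_dataset_from_dir(path) -> SyntheticDataset:
    p = Path(path)
    return load_dataset_from_paths({
        "expression": p / "dataset_expression.tsv",
        "promoters": p / "promoters.fasta",
        "cc_peaks": p / "dataset_cc_peaks.tsv",
        "overexpression": p / "dataset_overexpression.tsv",
        "binding": p / "dataset_binding.tsv",
        "truth": p / "dataset_truth.tsv",
    })


def load_dataset_from_paths(paths: dict) -> SyntheticDataset:
    for key, p in paths.items():
        if not Path(p).exists():
            raise PipelineError(f"missing input file for {key!r}: {p}")
    expression = gio.read_expression_panel(paths["expression"])
    promoters = gio.read_promoters_fasta(paths["promoters"])
    cc_peaks = gio.read_peak_map(paths["cc_peaks"])
    overexpression = gio.read_overexpression(paths["overexpression"])
    raw_binding = gio.read_gene_sets(paths["binding"])
    binding: dict = {"Mbp1": {}, "Swi4": {}}
    for key, genes in raw_binding.items():
        tf, study = key.split(":")
        binding[tf][study] = BindingCallSet(study_id=study, tf=tf, bound_genes=frozenset(genes))
    truth = None
    if "truth" in paths and Path(paths["truth"]).exists():
        tsets = gio.read_gene_sets(paths["truth"])
        from .simulate import SimulationParams, SyntheticTruth

        truth = SyntheticTruth(
            mbf_targets=frozenset(tsets.get("mbf_truth", ())),
            sbf_targets=frozenset(tsets.get("sbf_truth", ())),
            params=SimulationParams(), seed=-1,
        )
    return SyntheticDataset(
        expression=expression, binding=binding, promoters=promoters,
        cc_peaks=cc_peaks, overexpression=overexpression, truth=truth,
        planted_motifs={},
    )


def _write_controls(controls: dict, benchmarks: dict, out: Path, header=()) -> None:
    sets = {}
    for tf, cs in controls.items():
        sets[f"{tf}:positives"] = cs.positives
        sets[f"{tf}:negatives"] = cs.negatives
    gio.write_gene_sets(sets, out / "controls.tsv", header)
    bsets = {}
    for tf, b in benchmarks.items():
        bsets[f"{tf}:pos_a"] = b.pos_a.positives
        bsets[f"{tf}:pos_b"] = b.pos_b.positives
        bsets[f"{tf}:negatives"] = b.negatives
    gio.write_gene_sets(bsets, out / "benchmarks.tsv", header)


def load_controls(path) -> dict:
    raw = gio.read_gene_sets(path)
    out = {}
    for tf in ("Mbp1", "Swi4"):
        if f"{tf}:positives" in raw:
            out[tf] = ControlSet(tf=tf, positives=frozenset(raw[f"{tf}:positives"]),
                                 negatives=frozenset(raw[f"{tf}:negatives"]))
    return out


def load_benchmarks(path) -> dict:
    raw = gio.read_gene_sets(path)
    out = {}
    for tf in ("Mbp1", "Swi4"):
        if f"{tf}:pos_a" in raw:
            neg = frozenset(raw[f"{tf}:negatives"])
            out[tf] = TFBenchmarks(
                pos_a=BenchmarkSet(positives=frozenset(raw[f"{tf}:pos_a"]), negatives=neg),
                pos_b=BenchmarkSet(positives=frozenset(raw[f"{tf}:pos_b"]), negatives=neg),
            )
    return out
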