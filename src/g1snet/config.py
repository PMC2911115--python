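"""Run configuration: defaults, validation, canonicalization.

A run is fully determined by one RunConfig (including its seed): the
classifier preset, binning parameters (three random sets of 40 genes,
ranks 10/20/30), LLS pseudocount, cutoff constraints, motif strings and
windows, and the simulation parameters for synthetic mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .classifiers import PRESETS, classifier_specs
from .errors import ConfigError
from .simulate import SimulationParams
from .thresholds import DEFAULT_CONSTRAINTS, MATERIALS_CONSTRAINTS

CONSTRAINT_PRESETS = {
    "results-text": dict(DEFAULT_CONSTRAINTS),
    "materials-text": dict(MATERIALS_CONSTRAINTS),
}


@dataclass
class RunConfig:
    seed: int = 0
    tfs: tuple = ("Mbp1", "Swi4")
    preset: str = "methods-text"
    mode: str = "synthetic"  # "synthetic" or "files"
    n_sets: int = 3
    set_size: int = 40
    ranks: tuple = (10, 20, 30)
    pseudocount: float = 0.5
    epsilon: float = 0.1
    constraint_preset: str = "results-text"
    constraints: dict = field(default_factory=lambda: dict(DEFAULT_CONSTRAINTS))
    #: classifier motif per TF (consensus string, window in bp upstream of TSS)
    motif_windows: dict = field(default_factory=lambda: {
        "Mbp1": ("ACGCGT", 200), "Swi4": ("CRCGAA", 400),
    })
    #: motif used by the positional reporting analyses (core MCB for MBF)
    report_motifs: dict = field(default_factory=lambda: {
        "Mbp1": "ACGCG", "Swi4": "CRCGAA",
    })
    sim: SimulationParams = field(default_factory=SimulationParams)
    paths: dict = field(default_factory=dict)  # input files for "files" mode

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = {k: _plain(v) for k, v in dataclasses.asdict(self.sim).items()}
        return {k: _plain(v) for k, v in d.items()}

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _plain(v):
    if isinstance(v, dict):
        return {("|".join(k) if isinstance(k, tuple) else k): _plain(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_plain(x) for x in v]
    return v


def validate_config(raw: dict | RunConfig | None = None) -> tuple[RunConfig, list]:
    """Fill defaults, resolve presets, and enforce structural invariants.

    Two semantically identical inputs (e.g. differing key order) normalize
    to the same RunConfig and hence the same config hash.
    """
    warnings: list = []
    if raw is None:
        raw = {}
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kw = dict(raw)
        if "sim" in kw and isinstance(kw["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimulationParams)}
            bad = set(kw["sim"]) - sim_known
            if bad:
                raise ConfigError(f"unknown simulation keys: {sorted(bad)}")
            sim_kw = dict(kw["sim"])
            if "binding_sensitivity" in sim_kw:
                sim_kw["binding_sensitivity"] = {
                    tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                    for k, v in sim_kw["binding_sensitivity"].items()
                }
            kw["sim"] = SimulationParams(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim_kw.items()
            })
        for key in ("tfs", "ranks"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "motif_windows" in kw:
            kw["motif_windows"] = {k: tuple(v) for k, v in kw["motif_windows"].items()}
        cfg = RunConfig(**kw)

    if cfg.preset not in PRESETS:
        raise ConfigError(f"unknown classifier preset {cfg.preset!r}")
    if cfg.constraint_preset not in CONSTRAINT_PRESETS:
        raise ConfigError(f"unknown constraint preset {cfg.constraint_preset!r}")
    if cfg.constraints == dict(DEFAULT_CONSTRAINTS) and cfg.constraint_preset != "results-text":
        cfg.constraints = dict(CONSTRAINT_PRESETS[cfg.constraint_preset])
    for name, floor in cfg.constraints.items():
        if not 0 < floor <= 1:
            raise ConfigError(f"constraint {name!r}={floor} outside (0, 1]")
    for tf in cfg.tfs:
        specs = classifier_specs(tf, cfg.preset)  # raises unless exactly nine
        if len(specs) != 9:
            raise ConfigError(f"{tf}: nine classifiers required, got {len(specs)}")
        motif, window = cfg.motif_windows[tf]
        if window <= 0 or window < len(motif):
            raise ConfigError(f"{tf}: invalid motif window {window}")
    if not isinstance(cfg.seed, int):
        raise ConfigError("seed must be set explicitly as an integer")
    cfg.sim.validate()
    if cfg.mode == "files":
        needed = {"expression", "promoters", "cc_peaks", "overexpression",
                  "binding", "controls", "benchmarks"}
        missing = needed - set(cfg.paths)
        if missing:
            raise ConfigError(f"files mode needs paths for {sorted(missing)}")
    elif cfg.mode != "synthetic":
        raise ConfigError(f"unknown mode {cfg.mode!r}")
    return cfg, warnings


def load_config(path) -> tuple[RunConfig, list]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)
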