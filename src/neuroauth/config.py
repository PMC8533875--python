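"""Run configuration: one YAML file mirroring the pipeline dataclasses.

Unknown sections or keys are rejected by name, so typos fail loudly instead
of silently running with defaults.  Every source of randomness flows from
the single global ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .auth import AuthPolicy, AuthTask
from .ensemble import EnsembleConfig
from .features import StftConfig, SubbandScheme
from .learner import LearnerConfig
from .preprocess import PreprocessConfig
from .synth import CohortSpec, ValidationError

__all__ = ["RunConfig", "load_config", "parse_policy", "config_digest"]


def parse_policy(spec) -> AuthPolicy:
    """Parse a policy from {'tasks': ['performed-left', ...], 'rule': ...}."""
    if isinstance(spec, AuthPolicy):
        return spec
    tasks = []
    for name in spec.get("tasks", ["performed-left"]):
        task, _, arm = str(name).partition("-")
        t = AuthTask(task, arm)
        t.validate()
        tasks.append(t)
    policy = AuthPolicy(tasks=tuple(tasks),
                        rule=spec.get("rule", "all_accept"))
    policy.validate()
    return policy


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/out"
    mode: str = "all_channels"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stft: StftConfig = field(default_factory=StftConfig)
    subbands: SubbandScheme = field(default_factory=SubbandScheme)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    policy: AuthPolicy = field(
        default_factory=lambda: parse_policy({}))
    evaluation: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"seed": self.seed, "out_dir": self.out_dir, "mode": self.mode,
               "evaluation": dict(self.evaluation),
               "policy": {"tasks": [t.name for t in self.policy.tasks],
                          "rule": self.policy.rule}}
        for name in ("cohort", "preprocess", "stft", "subbands", "learner"):
            out[name] = dataclasses.asdict(getattr(self, name))
        out["ensemble"] = {
            "M": self.ensemble.M, "seed": self.ensemble.seed,
            "tie_rule": self.ensemble.tie_rule,
            "base": dataclasses.asdict(self.ensemble.base)}
        return out


_SECTION_TYPES = {
    "cohort": CohortSpec,
    "preprocess": PreprocessConfig,
    "stft": StftConfig,
    "subbands": SubbandScheme,
    "learner": LearnerConfig,
}
_EVAL_KEYS = {"n_days", "scenario", "training_group", "fractions", "n_runs",
              "bagging_sizes", "subjects"}


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'")
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v
                for v in coerced[f.name])
    return cls(**coerced)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file; ``overrides`` are applied on top."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValidationError("config file must hold a mapping")
            data = loaded
    if overrides:
        data = {**data, **{k: v for k, v in overrides.items()
                           if v is not None}}

    known = set(_SECTION_TYPES) | {"seed", "out_dir", "mode", "ensemble",
                                   "policy", "evaluation"}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")

    seed = int(data.get("seed", 0))
    cfg = RunConfig(seed=seed,
                    out_dir=str(data.get("out_dir", "runs/out")),
                    mode=str(data.get("mode", "all_channels")))
    if cfg.mode not in ("paper_literal", "all_channels"):
        raise ValidationError(f"unknown mode '{cfg.mode}'")
    for section, cls in _SECTION_TYPES.items():
        sect = dict(data.get(section, {}))
        if section == "cohort" and "seed" not in sect:
            sect["seed"] = seed
        if section == "learner" and "seed" not in sect:
            sect["seed"] = seed
        setattr(cfg, section, _build_section(cls, sect, section))

    ens = dict(data.get("ensemble", {}))
    unknown = set(ens) - {"M", "seed", "tie_rule", "base"}
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in section 'ensemble'")
    base = _build_section(LearnerConfig,
                          {**dataclasses.asdict(cfg.learner),
                           **ens.get("base", {})}, "ensemble.base")
    cfg.ensemble = EnsembleConfig(M=int(ens.get("M", 9)),
                                  seed=int(ens.get("seed", seed)),
                                  tie_rule=ens.get("tie_rule", "reject"),
                                  base=base)
    cfg.policy = parse_policy(data.get("policy", {}))
    ev = dict(data.get("evaluation", {}))
    unknown = set(ev) - _EVAL_KEYS
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in section 'evaluation'")
    cfg.evaluation = ev

    cfg.cohort.validate()
    cfg.preprocess.validate()
    cfg.stft.validate()
    cfg.subbands.validate()
    cfg.ensemble.validate()
    return cfg


def config_digest(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
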