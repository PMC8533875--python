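"""Bootstrap aggregating (bagging) of LSTM weak learners.

Each of the M ensemble members is trained on a bootstrap resample of the
training set — the same number of points, drawn with replacement — and the
majority of the M accept/reject votes decides the outcome.  The bootstrap is
stratified per class: the balanced positive/negative design is tiny (tens of
points), and an unstratified resample can lose a class entirely, which is
untrainable; stratification keeps both class counts fixed while still
resampling with replacement.  Ties (even M only) reject: authentication
fails closed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix
from .learner import (LabeledSet, LearnerConfig, WeakLearner, load_learner,
                      predict, save_learner, train_learner)
from .synth import ValidationError

__all__ = ["EnsembleConfig", "BaggedAuthenticator", "bootstrap_sample",
           "train_ensemble", "vote", "save_ensemble", "load_ensemble"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EnsembleConfig:
    M: int = 9
    base: LearnerConfig = field(default_factory=LearnerConfig)
    seed: int = 0
    tie_rule: str = "reject"

    def validate(self) -> None:
        if self.M < 1:
            raise ValidationError("ensemble size M must be >= 1")
        if self.tie_rule != "reject":
            raise ValidationError(f"unknown tie_rule '{self.tie_rule}'")
        self.base.validate()


@dataclass
class BaggedAuthenticator:
    learners: list  # of WeakLearner, length M
    config: EnsembleConfig
    context: tuple = ()  # (subject_id, task, arm)


def bootstrap_sample(data: LabeledSet, seed: int) -> LabeledSet:
    """Seeded stratified bootstrap: per class, draw as many points as the
    class holds, with replacement.  Output size equals input size and every
    element is an input element."""
    if len(data) == 0:
        raise ValidationError("cannot bootstrap an empty set")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB001]))
    chosen: list[int] = []
    for cls in sorted(set(data.labels.tolist())):
        members = np.flatnonzero(data.labels == cls)
        chosen.extend(rng.choice(members, size=members.size, replace=True))
    chosen.sort()
    return LabeledSet(
        features=[data.features[i] for i in chosen],
        labels=data.labels[chosen],
        provenance=[data.provenance[i] for i in chosen]
        if data.provenance else [])


def train_ensemble(data: LabeledSet, cfg: EnsembleConfig | None = None,
                   context: tuple = ()) -> BaggedAuthenticator:
    """Train M weak learners on independent seeded bootstrap resamples."""
    cfg = cfg or EnsembleConfig()
    cfg.validate()
    learners = []
    for m in range(cfg.M):
        # per-member seeds derived from the ensemble seed by index
        member_seed = int(np.random.SeedSequence(
            [cfg.seed, m]).generate_state(1)[0] % (2 ** 31))
        sample = bootstrap_sample(data, member_seed)
        base = LearnerConfig(**{**asdict(cfg.base), "seed": member_seed})
        learners.append(train_learner(sample, base))
    return BaggedAuthenticator(learners=learners, config=cfg, context=context)


def vote(ensemble: BaggedAuthenticator, features: FeatureMatrix
         ) -> tuple[int, int]:
    """Majority vote: accept iff yes-votes strictly exceed M/2."""
    yes = sum(predict(l, features)[1] for l in ensemble.learners)
    M = len(ensemble.learners)
    if ensemble.config.tie_rule == "reject":
        decision = int(yes > M / 2)
    else:  # pragma: no cover - only "reject" is defined
        raise ValidationError(f"unknown tie_rule '{ensemble.config.tie_rule}'")
    return decision, yes


def save_ensemble(ensemble: BaggedAuthenticator, directory) -> None:
    """Directory container: one file per member plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m, learner in enumerate(ensemble.learners):
        save_learner(learner, directory / f"member_{m:02d}.npz")
    manifest = {
        "format_version": _FORMAT_VERSION,
        "M": len(ensemble.learners),
        "context": list(ensemble.context),
        "config": {"M": ensemble.config.M, "seed": ensemble.config.seed,
                   "tie_rule": ensemble.config.tie_rule,
                   "base": asdict(ensemble.config.base)},
    }
    (directory / "ensemble.manifest").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_ensemble(directory) -> BaggedAuthenticator:
    directory = Path(directory)
    manifest = json.loads((directory / "ensemble.manifest").read_text())
    if manifest["format_version"] != _FORMAT_VERSION:
        raise ValidationError(
            f"unsupported ensemble format {manifest['format_version']}")
    cfg = EnsembleConfig(
        M=manifest["config"]["M"], seed=manifest["config"]["seed"],
        tie_rule=manifest["config"]["tie_rule"],
        base=LearnerConfig(**manifest["config"]["base"]))
    learners = [load_learner(directory / f"member_{m:02d}.npz")
                for m in range(manifest["M"])]
    return BaggedAuthenticator(learners=learners, config=cfg,
                               context=tuple(manifest["context"]))
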