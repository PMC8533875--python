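"""Per-subject authentication models and multi-task decision combination.

One bagged ensemble is trained per (subject, task, arm) on the subject's own
epochs as positives and an equal number of imposter epochs as negatives
(balanced negative sampling).  Two enrolment scenarios are supported:
``known_imposters`` (every other cohort member contributes negatives) and
``unseen_imposters`` (only a training group does; the held-out group attacks
the system without ever being seen during training).

A policy combines one or more (task, arm) authenticators; the combined
decision accepts only if every component accepts (unanimous AND).  Requiring
more tasks therefore can only lower the false acceptance rate and raise the
false rejection rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .ensemble import BaggedAuthenticator, EnsembleConfig, train_ensemble, vote
from .features import FeatureMatrix
from .learner import LabeledSet
from .synth import ValidationError

__all__ = ["AuthTask", "AuthPolicy", "SubjectModel", "EpochFeatures",
           "build_training_set", "fit_subject_model", "authenticate"]

logger = logging.getLogger(__name__)

TASK_VALUES = ("performed", "imagined")
ARM_VALUES = ("left", "right")


class AuthTask(NamedTuple):
    task: str  # "performed" | "imagined"
    arm: str   # "left" | "right"

    def validate(self) -> None:
        if self.task not in TASK_VALUES or self.arm not in ARM_VALUES:
            raise ValidationError(f"invalid AuthTask {self}")

    @property
    def name(self) -> str:
        return f"{self.task}-{self.arm}"


class EpochFeatures(NamedTuple):
    """A feature matrix with its provenance (who, which day, which trial)."""

    subject_id: int
    day_index: int
    task: str
    arm: str
    features: FeatureMatrix


@dataclass(frozen=True)
class AuthPolicy:
    tasks: tuple[AuthTask, ...]
    rule: str = "all_accept"

    def validate(self) -> None:
        if not self.tasks:
            raise ValidationError("policy needs at least one task")
        if len(set(self.tasks)) != len(self.tasks):
            raise ValidationError("policy tasks must be unique")
        if self.rule != "all_accept":
            raise ValidationError(f"unknown combination rule '{self.rule}'")
        for t in self.tasks:
            t.validate()

    @property
    def name(self) -> str:
        return "+".join(t.name for t in self.tasks)


@dataclass
class SubjectModel:
    subject_id: int
    authenticators: dict  # AuthTask -> BaggedAuthenticator
    scenario: str         # "known_imposters" | "unseen_imposters"
    imposter_pool: tuple  # subject ids used as negatives
    policy: AuthPolicy


def build_training_set(pool: list[EpochFeatures], subject_id: int,
                       task: AuthTask, imposter_pool, seed: int
                       ) -> LabeledSet:
    """Balanced positive/negative training set for one (subject, task, arm).

    Positives are all the subject's epochs for the task in ``pool``;
    negatives are an equal number of imposter epochs for the same task,
    sampled uniformly without replacement (with replacement, and a logged
    warning, if the imposter pool is too small).
    """
    task.validate()
    imposter_pool = tuple(imposter_pool)
    if subject_id in imposter_pool:
        raise ValidationError("subject cannot be in its own imposter pool")
    if not imposter_pool:
        raise ValidationError("empty imposter pool")
    pos = [e for e in pool
           if e.subject_id == subject_id and (e.task, e.arm) == task]
    if not pos:
        raise ValidationError(
            f"no positive epochs for subject {subject_id}, task {task.name}")
    neg_candidates = [e for e in pool
                      if e.subject_id in imposter_pool
                      and (e.task, e.arm) == task]
    if not neg_candidates:
        raise ValidationError(
            f"no imposter epochs for task {task.name}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E6]))
    n = len(pos)
    replace = n > len(neg_candidates)
    if replace:
        logger.warning(
            "imposter pool has only %d epochs for %d positives; "
            "sampling negatives with replacement",
            len(neg_candidates), n)
    idx = rng.choice(len(neg_candidates), size=n, replace=replace)
    neg = [neg_candidates[i] for i in sorted(idx.tolist())]
    examples = pos + neg
    return LabeledSet(
        features=[e.features for e in examples],
        labels=np.array([1] * len(pos) + [0] * len(neg)),
        provenance=[(e.subject_id, e.day_index) for e in examples])


def imposter_pool_for(subject_id: int, scenario: str, subjects,
                      training_group=None) -> tuple:
    """Imposter ids used as negatives for one subject under a scenario."""
    subjects = tuple(subjects)
    if scenario == "known_imposters":
        return tuple(s for s in subjects if s != subject_id)
    if scenario == "unseen_imposters":
        if training_group is None:
            raise ValidationError(
                "unseen_imposters scenario needs a training_group")
        if subject_id not in training_group:
            raise ValidationError(
                f"subject {subject_id} not in the training group")
        return tuple(s for s in training_group if s != subject_id)
    raise ValidationError(f"unknown scenario '{scenario}'")


def fit_subject_model(pool: list[EpochFeatures], subject_id: int,
                      policy: AuthPolicy, scenario: str,
                      cfg: EnsembleConfig | None = None,
                      subjects=None, training_group=None) -> SubjectModel:
    """Train one bagged authenticator per policy task for one subject."""
    policy.validate()
    cfg = cfg or EnsembleConfig()
    if subjects is None:
        subjects = sorted({e.subject_id for e in pool})
    imposters = imposter_pool_for(subject_id, scenario, subjects,
                                  training_group)
    authenticators = {}
    for k, task in enumerate(policy.tasks):
        train_seed = int(np.random.SeedSequence(
            [cfg.seed, subject_id, k]).generate_state(1)[0] % (2 ** 31))
        data = build_training_set(pool, subject_id, task, imposters,
                                  train_seed)
        task_cfg = EnsembleConfig(M=cfg.M, base=cfg.base, seed=train_seed,
                                  tie_rule=cfg.tie_rule)
        authenticators[task] = train_ensemble(
            data, task_cfg, context=(subject_id, task.task, task.arm))
    return SubjectModel(subject_id=subject_id, authenticators=authenticators,
                        scenario=scenario, imposter_pool=imposters,
                        policy=policy)


def authenticate(model: SubjectModel, attempt: dict
                 ) -> tuple[int, dict]:
    """Run every policy authenticator on the attempt and combine.

    ``attempt`` maps each policy AuthTask to one FeatureMatrix.  The final
    decision is 1 only if every per-task vote accepts.
    """
    per_task = {}
    for task in model.policy.tasks:
        if task not in attempt:
            raise ValidationError(
                f"attempt is missing features for task {task.name}")
        decision, _ = vote(model.authenticators[task], attempt[task])
        per_task[task] = decision
    combined = int(all(per_task[t] == 1 for t in model.policy.tasks))
    return combined, per_task
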