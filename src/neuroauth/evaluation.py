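"""Leave-one-day-out evaluation, biometric metrics, sweeps, and statistics.

Every fold holds out one full recording day: models are trained on the
remaining days and attacked with the held-out day's epochs, the subject's own
epochs acting as genuine attempts and every other subject's as imposter
attempts.  Metrics follow the standard biometric definitions

    FAR = FP / (FP + TN)        (imposter attempts wrongly accepted)
    FRR = FN / (FN + TP)        (genuine attempts wrongly rejected)
    accuracy = (TP + TN) / (TP + TN + FP + FN)

computed on the full, unbalanced attempt set; all four counts are reported so
any other weighting can be recomputed.  For multi-task policies the component
(single-task) decisions are scored on the same paired attempts as the
combined decision, which makes the conjunction bounds
FAR(combined) <= min FAR(component), FRR(combined) >= max FRR(component)
exact identities of the evaluation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .auth import (AuthPolicy, AuthTask, EpochFeatures, authenticate,
                   build_training_set, fit_subject_model)
from .ensemble import EnsembleConfig, train_ensemble, vote
from .learner import LabeledSet, LearnerConfig, predict, train_learner
from .synth import ValidationError

__all__ = ["ConfusionCounts", "EvalReport", "metrics", "leave_one_day_out",
           "training_fraction_sweep", "bagging_size_sweep",
           "wilcoxon_signed_rank", "pairwise_scheme_tests"]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ConfusionCounts:
    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0

    def record(self, genuine: bool, accepted: bool) -> None:
        if genuine:
            self.TP += accepted
            self.FN += not accepted
        else:
            self.FP += accepted
            self.TN += not accepted


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, FAR, FRR) from confusion counts."""
    if c.TP + c.FN == 0:
        raise ValidationError("no genuine attempts: FRR undefined")
    if c.TN + c.FP == 0:
        raise ValidationError("no imposter attempts: FAR undefined")
    far = c.FP / (c.FP + c.TN)
    frr = c.FN / (c.FN + c.TP)
    acc = (c.TP + c.TN) / (c.TP + c.TN + c.FP + c.FN)
    return acc, far, frr


@dataclass
class EvalReport:
    """Tidy per-(subject, scheme, fold) results with aggregate helpers."""

    rows: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def add(self, subject: int, scheme: str, fold: int,
            c: ConfusionCounts) -> None:
        acc, far, frr = metrics(c)
        self.rows.append({
            "subject": subject, "scheme": scheme, "fold": fold,
            "TP": c.TP, "FN": c.FN, "TN": c.TN, "FP": c.FP,
            "accuracy": acc, "FAR": far, "FRR": frr})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def aggregates(self) -> pd.DataFrame:
        """Mean accuracy/FAR/FRR per scheme over subjects and folds."""
        df = self.to_frame()
        return (df.groupby("scheme")[["accuracy", "FAR", "FRR"]]
                .mean().reset_index())

    def per_subject(self, scheme: str) -> pd.DataFrame:
        df = self.to_frame()
        return (df[df["scheme"] == scheme]
                .groupby("subject")[["accuracy", "FAR", "FRR"]]
                .mean().reset_index())

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "eval_rows.csv", index=False)
        summary = {
            "meta": self.meta,
            "aggregates": self.aggregates().to_dict(orient="records")}
        (outdir / "eval_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _index_pool(pool: list[EpochFeatures]) -> dict:
    by_key: dict = {}
    for e in pool:
        by_key.setdefault((e.subject_id, e.day_index, (e.task, e.arm)),
                          []).append(e)
    return by_key


def _paired_attempts(by_key: dict, candidate: int, day: int,
                     tasks: tuple[AuthTask, ...]) -> list[dict]:
    """Pair the candidate's day-``day`` epochs across tasks by trial index."""
    lists = [by_key.get((candidate, day, (t.task, t.arm)), [])
             for t in tasks]
    n = min(len(lst) for lst in lists)
    return [{t: lst[i].features for t, lst in zip(tasks, lists)}
            for i in range(n)]


def _derived_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0]
               % (2 ** 31))


def leave_one_day_out(pool: list[EpochFeatures], subjects, policy: AuthPolicy,
                      cfg: EnsembleConfig | None = None, n_days: int = 5,
                      scenario: str = "known_imposters",
                      training_group=None, attackers=None) -> EvalReport:
    """Day-wise cross-validation of per-subject authentication models.

    Fold ``d`` trains on every day except ``d`` and tests on day ``d``.
    ``attackers`` (default: every pool subject) are the identities whose
    held-out epochs form imposter attempts; under ``unseen_imposters`` this
    includes subjects whose data never enters training.
    """
    policy.validate()
    cfg = cfg or EnsembleConfig()
    subjects = sorted(subjects)
    pool_subjects = sorted({e.subject_id for e in pool})
    attackers = sorted(attackers) if attackers is not None else pool_subjects
    by_key = _index_pool(pool)
    days = sorted({e.day_index for e in pool})
    if len(days) < n_days:
        missing = n_days - len(days)
        raise ValidationError(f"pool covers {len(days)} days, "
                              f"{missing} short of n_days={n_days}")
    days = days[:n_days]
    for s in subjects:
        for d in days:
            for t in policy.tasks:
                if not by_key.get((s, d, (t.task, t.arm))):
                    raise ValidationError(
                        f"subject {s} has no epochs for day {d}, "
                        f"task {t.name}")

    report = EvalReport(meta={
        "policy": policy.name, "M": cfg.M, "n_days": len(days),
        "scenario": scenario, "subjects": list(subjects)})
    single = len(policy.tasks) == 1
    for s in subjects:
        for fold, d in enumerate(days):
            train_pool = [e for e in pool if e.day_index != d]
            fold_cfg = EnsembleConfig(
                M=cfg.M, base=cfg.base, tie_rule=cfg.tie_rule,
                seed=_derived_seed(cfg.seed, s, fold))
            model = fit_subject_model(
                train_pool, s, policy, scenario, fold_cfg,
                subjects=pool_subjects, training_group=training_group)
            combined = ConfusionCounts()
            per_task = {t: ConfusionCounts() for t in policy.tasks}
            for candidate in attackers:
                genuine = candidate == s
                for attempt in _paired_attempts(by_key, candidate, d,
                                                policy.tasks):
                    decision, task_votes = authenticate(model, attempt)
                    combined.record(genuine, bool(decision))
                    for t, v in task_votes.items():
                        per_task[t].record(genuine, bool(v))
            report.add(s, policy.name, fold, combined)
            if not single:
                for t in policy.tasks:
                    report.add(s, t.name, fold, per_task[t])
    return report


def training_fraction_sweep(pool: list[EpochFeatures], subjects,
                            task: AuthTask,
                            fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1),
                                                     1)),
                            n_runs: int = 5,
                            cfg: EnsembleConfig | None = None,
                            n_days: int = 5, seed: int = 0) -> pd.DataFrame:
    """Single LSTM vs. bagged ensemble at matched training-set fractions.

    For every (subject, fold, run) a per-class subset of the aggregated
    training pool is drawn once and handed to both methods, which are then
    scored on the identical held-out-day test attempts.  Returns a tidy
    frame with one row per (fraction, method, subject, fold, run).
    """
    cfg = cfg or EnsembleConfig(M=5)
    task.validate()
    by_key = _index_pool(pool)
    days = sorted({e.day_index for e in pool})[:n_days]
    pool_subjects = sorted({e.subject_id for e in pool})
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValidationError(f"fraction {frac} outside (0, 1]")
    for s in sorted(subjects):
        imposters = tuple(x for x in pool_subjects if x != s)
        for fold, d in enumerate(days):
            train_pool = [e for e in pool if e.day_index != d]
            base_seed = _derived_seed(seed, s, fold)
            full = build_training_set(train_pool, s, task, imposters,
                                      base_seed)
            pos_idx = np.flatnonzero(full.labels == 1)
            neg_idx = np.flatnonzero(full.labels == 0)
            test_attempts = [
                (candidate == s, att)
                for candidate in pool_subjects
                for att in _paired_attempts(by_key, candidate, d, (task,))]
            for run in range(n_runs):
                run_rng = np.random.default_rng(
                    np.random.SeedSequence([base_seed, run]))
                for frac in fractions:
                    k = int(round(frac * pos_idx.size))
                    if k < 1:
                        logger.warning(
                            "fraction %.2f yields <1 epoch per class; "
                            "skipped", frac)
                        continue
                    sel = np.concatenate([
                        run_rng.choice(pos_idx, size=k, replace=False),
                        run_rng.choice(neg_idx, size=k, replace=False)])
                    subset = LabeledSet(
                        features=[full.features[i] for i in sel],
                        labels=full.labels[sel],
                        provenance=[full.provenance[i] for i in sel])
                    method_seed = _derived_seed(base_seed, run, int(frac * 100))
                    single_cfg = LearnerConfig(
                        **{**cfg.base.__dict__, "seed": method_seed})
                    learner = train_learner(subset, single_cfg)
                    ens = train_ensemble(subset, EnsembleConfig(
                        M=cfg.M, base=cfg.base, seed=method_seed,
                        tie_rule=cfg.tie_rule))
                    for method, decide in (
                            ("single_lstm",
                             lambda f: predict(learner, f)[1]),
                            (f"bagged_M{cfg.M}",
                             lambda f: vote(ens, f)[0])):
                        c = ConfusionCounts()
                        for genuine, att in test_attempts:
                            c.record(genuine, bool(decide(att[task])))
                        acc, far, frr = metrics(c)
                        rows.append({
                            "fraction": float(frac), "method": method,
                            "subject": s, "fold": fold, "run": run,
                            "accuracy": acc, "FAR": far, "FRR": frr})
    return pd.DataFrame(rows)


def bagging_size_sweep(pool: list[EpochFeatures], subjects,
                       policy: AuthPolicy, sizes=(1, 3, 5, 7, 9),
                       cfg: EnsembleConfig | None = None,
                       n_days: int = 5) -> pd.DataFrame:
    """Leave-one-day-out results as a function of the ensemble size M."""
    cfg = cfg or EnsembleConfig()
    frames = []
    for M in sizes:
        if M < 1:
            raise ValidationError("bagging sizes must be >= 1")
        m_cfg = EnsembleConfig(M=M, base=cfg.base, seed=cfg.seed,
                               tie_rule=cfg.tie_rule)
        report = leave_one_day_out(pool, subjects, policy, m_cfg,
                                   n_days=n_days)
        df = report.to_frame()
        df = df[df["scheme"] == policy.name].copy()
        df["M"] = M
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the null distribution is enumerated
    exactly for n <= 12 remaining pairs and normally approximated above.
    Needs at least 5 nonzero differences.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    diffs = a - b
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        raise ValidationError("all differences are zero: degenerate test")
    if nz.size < 5:
        raise ValidationError(
            f"only {nz.size} nonzero differences; need at least 5")
    method = "exact" if nz.size <= 12 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=False,
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_scheme_tests(report: EvalReport, metric: str = "accuracy",
                          alpha: float = ALPHA) -> pd.DataFrame:
    """Pairwise signed-rank comparisons of per-subject means across schemes."""
    df = report.to_frame()
    per = (df.groupby(["scheme", "subject"])[metric].mean().reset_index()
           .pivot(index="subject", columns="scheme", values=metric))
    rows = []
    for s1, s2 in itertools.combinations(sorted(per.columns), 2):
        try:
            statistic, p = wilcoxon_signed_rank(per[s1], per[s2])
        except ValidationError as exc:
            rows.append({"scheme_a": s1, "scheme_b": s2, "metric": metric,
                         "statistic": np.nan, "p_value": np.nan,
                         "significant": False, "note": str(exc)})
            continue
        rows.append({"scheme_a": s1, "scheme_b": s2, "metric": metric,
                     "statistic": statistic, "p_value": p,
                     "significant": bool(p < alpha), "note": ""})
    return pd.DataFrame(rows)
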