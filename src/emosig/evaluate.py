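"""Repeated hold-out evaluation and its summary statistics.

The protocol: optionally subsample the feature table, split it into
mutually exclusive train/test sets at a given fraction (stratified by class
by default), train the requested classifier arm, and score test accuracy on
the percent scale.  Repetitions redraw the subsample and split.  The
summary is the mean accuracy Acc* and the sample standard deviation

    Acc* = sum(Acc_i) / N
    sigma = sqrt( sum((Acc* - Acc_i)^2) / (N - 1) )

over the N repetitions, reported as "mean +/- std" in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classifiers import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    train_dt,
    train_elm,
    train_svm,
)
from .fusion import LABEL_COL, Scaler, single_channel_view, split_xy
from .team import ReferralConfig, classify_batch

__all__ = [
    "AccSummary",
    "acc_mean_std",
    "ExperimentConfig",
    "holdout_split",
    "run_experiment",
]


@dataclass(frozen=True)
class AccSummary:
    """Per-repetition accuracies (percent) with their mean and sample std."""

    accs: tuple
    mean: float
    std: float
    n: int


def acc_mean_std(accs) -> AccSummary:
    """Summarize repeated hold-out accuracies as mean and sample std.

    Accuracies are on the percent scale; the standard deviation uses the
    N - 1 denominator, so at least two repetitions are required.
    """
    accs = tuple(float(a) for a in accs)
    n = len(accs)
    if n < 2:
        raise ValueError(f"need >= 2 accuracies for a mean/std summary, got {n}")
    mean = sum(accs) / n
    std = math.sqrt(sum((mean - a) ** 2 for a in accs) / (n - 1))
    return AccSummary(accs=accs, mean=mean, std=std, n=n)


@dataclass(frozen=True)
class ExperimentConfig:
    """Hold-out protocol parameters.

    ``subsample_n`` draws that many rows uniformly without replacement
    before splitting (fresh each repetition); ``train_fraction`` of the
    (sub)sample is used for training.  ``group_by`` optionally keeps all
    rows sharing an id (e.g. segments of one recording) on the same side of
    the split, guarding against within-recording leakage.
    """

    train_fraction: float = 0.8
    repetitions: int = 10
    subsample_n: int | None = None
    seed: int = 0
    stratified: bool = True
    group_by: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")
        if self.repetitions < 1:
            raise ValueError(f"repetitions must be >= 1, got {self.repetitions}")


def _rep_seed(cfg: ExperimentConfig, rep_index: int) -> int:
    ss = np.random.SeedSequence([cfg.seed, rep_index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def holdout_split(
    table: pd.DataFrame, cfg: ExperimentConfig, rep_index: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one train/test partition, deterministic in (seed, rep_index)."""
    if len(table) == 0:
        raise ValueError("empty feature table")
    if cfg.subsample_n is not None and cfg.subsample_n > len(table):
        raise ValueError(
            f"subsample_n={cfg.subsample_n} exceeds table size {len(table)}"
        )
    seed = _rep_seed(cfg, rep_index)
    rng = np.random.default_rng(seed)
    if cfg.subsample_n is not None:
        idx = rng.choice(len(table), size=cfg.subsample_n, replace=False)
        table = table.iloc[np.sort(idx)]
    if cfg.group_by is not None:
        groups = table[cfg.group_by].unique()
        n_train_groups = int(round(cfg.train_fraction * len(groups)))
        train_groups = set(rng.choice(groups, size=n_train_groups, replace=False))
        mask = table[cfg.group_by].isin(train_groups)
        train, test = table[mask], table[~mask]
    else:
        strat = table[LABEL_COL] if cfg.stratified else None
        train, test = train_test_split(
            table,
            train_size=cfg.train_fraction,
            random_state=seed,
            stratify=strat,
        )
    if cfg.stratified and cfg.group_by is None:
        missing = set(table[LABEL_COL]) - set(train[LABEL_COL])
        if missing:
            raise ValueError(f"classes absent from training split: {missing}")
    return train, test


def _train_and_score(
    train: pd.DataFrame,
    test: pd.DataFrame,
    classifier: str,
    seed: int,
    c_grid,
    gamma_grid,
    referral: ReferralConfig,
    elm_hidden: int | None,
    scale: bool,
):
    """Accuracy (percent) of one arm on one split; also returns principle
    counts for the team arm."""
    if scale:
        scaler = Scaler().fit(train)
        train, test = scaler.transform(train), scaler.transform(test)
    Xtr, ytr, _ = split_xy(train)
    Xte, yte, _ = split_xy(test)
    principle_counts = None
    if classifier == "svm":
        model = train_svm(Xtr, ytr, c_grid, gamma_grid)
        pred = model.estimator.predict(Xte)
    elif classifier == "dt":
        pred = train_dt(Xtr, ytr).predict(Xte)
    elif classifier == "elm":
        M = elm_hidden or min(10 * Xtr.shape[1], len(ytr))
        pred = train_elm(Xtr, ytr, M=M, seed=seed).predict(Xte)
    elif classifier == "team":
        svm = train_svm(Xtr, ytr, c_grid, gamma_grid)
        dt = train_dt(Xtr, ytr)
        M = elm_hidden or min(10 * Xtr.shape[1], len(ytr))
        elm = train_elm(Xtr, ytr, M=M, seed=seed)
        verdicts = classify_batch(svm, dt, elm, Xte, referral)
        pred = np.array([v.label for v in verdicts])
        principle_counts = {p: 0 for p in ("I", "II", "III", "FALLBACK")}
        for v in verdicts:
            principle_counts[v.principle] += 1
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    acc = 100.0 * float(np.mean(pred == yte))
    return acc, principle_counts


def run_experiment(
    table: pd.DataFrame,
    cfg: ExperimentConfig,
    arms: list[dict],
    channels: list[str] | None = None,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    referral: ReferralConfig | None = None,
    elm_hidden: int | None = None,
    scale: bool = True,
) -> dict:
    """Run every arm over repeated hold-out splits and summarize.

    Each arm is a dict ``{"features": "fused" | <channel name>,
    "classifier": "svm" | "dt" | "elm" | "team"}``.  All arms share the same
    split in each repetition so comparisons are paired.  The report is a
    pure function of (table, config, arms).
    """
    if not arms:
        raise ValueError("no arms to run")
    referral = referral or ReferralConfig()
    results: dict[str, dict] = {}
    arm_names = []
    for arm in arms:
        name = f"{arm['features']}-{arm['classifier']}"
        arm_names.append(name)
        results[name] = {"accs": [], "principle_counts": []}
    for rep in range(cfg.repetitions):
        train, test = holdout_split(table, cfg, rep)
        for arm, name in zip(arms, arm_names):
            try:
                tr, te = train, test
                if arm["features"] != "fused":
                    tr = single_channel_view(tr, arm["features"])
                    te = single_channel_view(te, arm["features"])
                acc, pc = _train_and_score(
                    tr, te, arm["classifier"], _rep_seed(cfg, rep),
                    c_grid, gamma_grid, referral, elm_hidden, scale,
                )
            except Exception as exc:
                raise RuntimeError(f"arm {name!r}, repetition {rep}: {exc}") from exc
            results[name]["accs"].append(acc)
            if pc is not None:
                results[name]["principle_counts"].append(pc)
    report = {"config": asdict(cfg), "arms": {}}
    for name in arm_names:
        accs = results[name]["accs"]
        summary = (
            asdict(acc_mean_std(accs))
            if len(accs) >= 2
            else {"accs": tuple(accs), "mean": accs[0], "std": None, "n": 1}
        )
        if results[name]["principle_counts"]:
            summary["principle_counts"] = results[name]["principle_counts"]
        report["arms"][name] = summary
    return report
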