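"""Repeated-split evaluation of the full risk pipeline.

Each iteration draws a stratified subject-level 90/10 train/test split,
fits the balanced forest on the training epochs, selects the alert policy
(run length n̂ by maximal out-of-bag subject-level AUC over n = 1..10, then
the most sensitive threshold p̂t whose training false-positive rate stays
at or below the healthy-group Caesarean rate), freezes the policy, and
applies it to the held-out subjects. The policy therefore never sees test
data. Across iterations, curves are summarized by the sample median with a
distribution-free (order-statistic) 95% confidence interval, and per-group
recommendation rates are compared with the observed Caesarean rate by a
one-sample Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import GROUPS, PATHOLOGICAL_GROUPS, LaborRecord
from .features import FEATURE_NAMES, FeaturizeConfig, featurize_cohort
from .forest import ForestConfig, oob_probabilities, predict_p, train_forest
from .policy import (
    N_RANGE,
    DecisionPolicy,
    RocCurve,
    SubjectDecision,
    decide_subject,
    roc_for_n,
    select_n,
    select_pt,
)


@dataclass
class EvalConfig:
    """Knobs of one evaluation run (defaults mirror the study protocol)."""

    test_fraction: float = 0.1
    forest: ForestConfig = field(default_factory=ForestConfig)
    featurize: FeaturizeConfig = field(default_factory=FeaturizeConfig)
    n_grid: tuple[int, ...] = N_RANGE
    target_fpr: float | None = None  # None -> observed healthy Caesarean rate
    latch: bool = True


@dataclass
class IterationResult:
    """Everything one train/test split produced."""

    iteration: int
    seed: int
    n_hat: int
    pt_hat: float
    auc_by_n: dict[int, float]
    target_fpr: float
    train_fpr_at_pt: float
    test_curves: dict[str, np.ndarray]  # group -> rate per epoch index 0..max_k
    test_rates_at_delivery: dict[str, float]
    test_group_sizes: dict[str, int]
    oob_trajectory: pd.DataFrame  # training OOB median pHIE per group/epoch
    roc_at_n_hat: "RocCurve | None" = field(repr=False, default=None)
    decisions: dict[str, SubjectDecision] = field(repr=False, default_factory=dict)


@dataclass
class SummaryResult:
    """Median-with-CI summaries across iterations."""

    curve_summary: pd.DataFrame  # group, epoch_index, median, lo, hi
    auc_summary: pd.DataFrame  # n, median, lo, hi
    rate_comparisons: pd.DataFrame  # group, epoch, median rate, caesarean rate, p
    n_hat_by_iteration: list[int]
    pt_hat_by_iteration: list[float]


def split_cohort(
    records: list[LaborRecord], test_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Stratified subject-level split; every group keeps >= 1 test subject.

    Per-group test counts are round-half-up of size*fraction, floored at 1;
    groups with fewer than 2 subjects cannot be split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    by_group: dict[str, list[str]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec.subject_id)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for group, ids in by_group.items():
        if len(ids) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 subjects; cannot split")
        n_test = max(1, int(math.floor(len(ids) * test_fraction + 0.5)))
        n_test = min(n_test, len(ids) - 1)
        perm = rng.permutation(len(ids))
        ids_arr = np.asarray(ids)
        test_ids.extend(ids_arr[perm[:n_test]])
        train_ids.extend(ids_arr[perm[n_test:]])
    return sorted(train_ids), sorted(test_ids)


def observed_caesarean_rate(records: list[LaborRecord], group: str) -> float:
    members = [r for r in records if r.group == group]
    if not members:
        raise ValueError(f"no subjects in group {group!r}")
    return float(np.mean([r.caesarean for r in members]))


def phie_streams(
    feature_table: pd.DataFrame, phie: np.ndarray
) -> dict[str, np.ndarray]:
    """Chronological per-subject pHIE streams on the delivery-anchored grid.

    ``phie`` aligns with ``feature_table`` rows; invalid epochs (or NaN
    probabilities) become missing slots. Streams run from the earliest
    epoch (largest index) to delivery (index 0).
    """
    streams: dict[str, np.ndarray] = {}
    table = feature_table[["subject_id", "epoch_index"]].copy()
    table["phie"] = phie
    for sid, sub in table.groupby("subject_id", sort=False):
        n_epochs = int(sub["epoch_index"].max()) + 1
        grid = np.full(n_epochs, np.nan)
        grid[sub["epoch_index"].to_numpy(dtype=int)] = sub["phie"].to_numpy()
        streams[str(sid)] = grid[::-1]  # chronological: K-1 .. 0
    return streams


def recommendation_curve(
    decisions: dict[str, SubjectDecision], max_epoch: int
) -> np.ndarray:
    """Cumulative recommendation rate per epoch index 0..max_epoch.

    Entry k is the fraction of subjects whose first recommendation came at
    epoch index >= k, i.e. at or before that time; the denominator is all
    subjects supplied. Latching makes the curve non-decreasing toward
    delivery (decreasing k).
    """
    if not decisions:
        raise ValueError("no decisions supplied")
    firsts = [
        d.first_recommendation_epoch for d in decisions.values() if d.recommended
    ]
    curve = np.zeros(max_epoch + 1)
    for k in range(max_epoch + 1):
        curve[k] = sum(f >= k for f in firsts) / len(decisions)
    return curve


def median_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Sample median with a distribution-free order-statistic CI.

    The CI endpoints are the l-th and (n+1-l)-th order statistics, where l
    is the largest rank with Binom(n, 1/2) lower-tail mass at most
    (1-level)/2; needs n >= 8 at the 95% level.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError(f"median CI needs at least 8 values, got {n}")
    alpha2 = (1.0 - level) / 2.0
    l = int(stats.binom.ppf(alpha2, n, 0.5))
    while l > 0 and stats.binom.cdf(l - 1, n, 0.5) > alpha2:
        l -= 1
    while stats.binom.cdf(l, n, 0.5) <= alpha2:
        l += 1
    l = max(l, 0)
    lo = x[l] if l >= 1 else x[0]
    hi = x[n - 1 - l] if l >= 1 else x[-1]
    return float(np.median(x)), float(lo), float(hi)


def compare_to_caesarean(iteration_rates, caesarean_rate: float) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value vs a fixed rate."""
    rates = np.asarray(iteration_rates, dtype=float)
    if len(rates) < 8:
        raise ValueError(f"need at least 8 iteration rates, got {len(rates)}")
    diffs = rates - caesarean_rate
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)


def phie_trajectory(
    oob_table: pd.DataFrame, epoch_range: range | None = None, min_n_ci: int = 8
) -> pd.DataFrame:
    """Median OOB pHIE per group and epoch, pooled across subjects.

    ``oob_table`` needs columns group, epoch_index, phie. Cells with fewer
    than ``min_n_ci`` values get a median but no CI; empty cells are
    omitted (missing, not an error).
    """
    rows = []
    table = oob_table.dropna(subset=["phie"])
    if epoch_range is not None:
        table = table[table["epoch_index"].isin(list(epoch_range))]
    for (group, k), sub in table.groupby(["group", "epoch_index"]):
        vals = sub["phie"].to_numpy()
        if len(vals) >= min_n_ci:
            med, lo, hi = median_ci(vals)
        else:
            med, lo, hi = float(np.median(vals)), np.nan, np.nan
        rows.append(
            {"group": group, "epoch_index": int(k), "median": med, "lo": lo, "hi": hi,
             "n": len(vals)}
        )
    return pd.DataFrame(rows, columns=["group", "epoch_index", "median", "lo", "hi", "n"])


def run_iteration(
    records: list[LaborRecord],
    config: EvalConfig,
    seed: int,
    iteration: int = 0,
    feature_table: pd.DataFrame | None = None,
) -> IterationResult:
    """One complete train/calibrate/test pass.

    ``feature_table`` may be precomputed (featurization is split-
    independent); the policy (n̂, p̂t) is chosen from training OOB data only.
    """
    rng = np.random.default_rng(seed)
    if feature_table is None:
        feature_table = featurize_cohort(records, config.featurize)
    groups = {rec.subject_id: rec.group for rec in records}
    train_ids, test_ids = split_cohort(records, config.test_fraction, rng)
    train_set, test_set = set(train_ids), set(test_ids)

    is_train = feature_table["subject_id"].map(train_set.__contains__)
    train_table = feature_table[is_train]
    test_table = feature_table[~is_train.to_numpy()]
    train_valid = train_table[train_table["valid"]]
    y_train = (
        train_valid["group"].isin(PATHOLOGICAL_GROUPS).to_numpy(dtype=int)
    )
    model = train_forest(train_valid, y_train, config.forest, rng=rng)
    oob = oob_probabilities(model, train_valid, y_train)

    # assemble full-grid training streams (invalid epochs -> NaN)
    train_phie_rows = np.full(len(train_table), np.nan)
    train_phie_rows[train_table["valid"].to_numpy()] = oob
    train_streams = phie_streams(train_table, train_phie_rows)
    pathological = {sid: groups[sid] in PATHOLOGICAL_GROUPS for sid in train_streams}

    rocs = {
        n: roc_for_n(train_streams, pathological, n) for n in config.n_grid
    }
    auc_by_n = {n: roc.auc for n, roc in rocs.items()}
    n_hat = select_n(auc_by_n)
    target = (
        config.target_fpr
        if config.target_fpr is not None
        else observed_caesarean_rate(records, "healthy")
    )
    pt_hat = select_pt(rocs[n_hat], target)
    policy = DecisionPolicy(n=n_hat, pt=pt_hat, latch=config.latch)
    healthy_scores = rocs[n_hat].healthy_scores
    train_fpr = float(np.mean(healthy_scores > pt_hat))

    oob_df = pd.DataFrame(
        {
            "group": train_table["group"].to_numpy(),
            "epoch_index": train_table["epoch_index"].to_numpy(),
            "phie": train_phie_rows,
        }
    )
    trajectory = phie_trajectory(oob_df)

    # frozen policy on held-out subjects
    test_valid = test_table[test_table["valid"]]
    test_phie_rows = np.full(len(test_table), np.nan)
    if len(test_valid):
        test_phie_rows[test_table["valid"].to_numpy()] = predict_p(model, test_valid)
    test_streams = phie_streams(test_table, test_phie_rows)
    decisions = {
        sid: decide_subject(stream[:], policy, subject_id=sid)
        for sid, stream in test_streams.items()
    }

    max_epoch = int(feature_table["epoch_index"].max())
    curves: dict[str, np.ndarray] = {}
    rates_at_delivery: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for group in GROUPS:
        group_dec = {sid: d for sid, d in decisions.items() if groups[sid] == group}
        sizes[group] = len(group_dec)
        if group_dec:
            curves[group] = recommendation_curve(group_dec, max_epoch)
            rates_at_delivery[group] = float(curves[group][0])
    return IterationResult(
        iteration=iteration,
        seed=seed,
        n_hat=n_hat,
        pt_hat=pt_hat,
        auc_by_n=auc_by_n,
        target_fpr=float(target),
        train_fpr_at_pt=train_fpr,
        test_curves=curves,
        test_rates_at_delivery=rates_at_delivery,
        test_group_sizes=sizes,
        oob_trajectory=trajectory,
        roc_at_n_hat=rocs[n_hat],
        decisions=decisions,
    )


#: Table-1-style reporting epochs. Epoch indices are named by both the
#: window's start and end time before delivery (the 20-min epoch with
#: index 9 starts 3 h 20 min and ends 3 h before delivery).
REPORT_EPOCHS = {9: "start 3h20m / end 3h00m", 2: "start 1h00m / end 0h40m", 0: "start 0h20m / end delivery"}


def summarize(
    results: list[IterationResult], records: list[LaborRecord]
) -> SummaryResult:
    """Median-with-CI summaries of curves, AUCs and rate comparisons."""
    if len(results) < 8:
        raise ValueError("summaries need at least 8 iterations")
    curve_rows = []
    max_epoch = max(len(c) for r in results for c in r.test_curves.values()) - 1
    for group in GROUPS:
        for k in range(max_epoch + 1):
            vals = [
                r.test_curves[group][k]
                for r in results
                if group in r.test_curves and k < len(r.test_curves[group])
            ]
            if len(vals) >= 8:
                med, lo, hi = median_ci(vals)
                curve_rows.append(
                    {"group": group, "epoch_index": k, "median": med, "lo": lo, "hi": hi}
                )
    auc_rows = []
    for n in results[0].auc_by_n:
        med, lo, hi = median_ci([r.auc_by_n[n] for r in results])
        auc_rows.append({"n": n, "median": med, "lo": lo, "hi": hi})
    cmp_rows = []
    for group in GROUPS:
        caesarean = observed_caesarean_rate(records, group)
        for k, label in REPORT_EPOCHS.items():
            vals = [
                r.test_curves[group][k]
                for r in results
                if group in r.test_curves and k < len(r.test_curves[group])
            ]
            if len(vals) < 8:
                continue
            med, lo, hi = median_ci(vals)
            cmp_rows.append(
                {
                    "group": group,
                    "epoch_index": k,
                    "epoch_label": label,
                    "median_rate": med,
                    "lo": lo,
                    "hi": hi,
                    "caesarean_rate": caesarean,
                    "p_value": compare_to_caesarean(vals, caesarean),
                }
            )
    return SummaryResult(
        curve_summary=pd.DataFrame(curve_rows),
        auc_summary=pd.DataFrame(auc_rows),
        rate_comparisons=pd.DataFrame(cmp_rows),
        n_hat_by_iteration=[r.n_hat for r in results],
        pt_hat_by_iteration=[r.pt_hat for r in results],
    )


def run_evaluation(
    records: list[LaborRecord],
    config: EvalConfig | None = None,
    n_iterations: int = 100,
    seed: int = 0,
    feature_table: pd.DataFrame | None = None,
) -> tuple[list[IterationResult], SummaryResult | None]:
    """Run ``n_iterations`` independent splits from a root seed.

    Featurization happens once; each iteration gets a seed spawned from
    the root so results are reproducible and order-independent. The
    summary is None when fewer than 8 iterations were requested.
    """
    config = config or EvalConfig()
    if feature_table is None:
        feature_table = featurize_cohort(records, config.featurize)
    children = np.random.SeedSequence(seed).spawn(n_iterations)
    results = []
    for i, child in enumerate(children):
        iter_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        results.append(
            run_iteration(records, config, iter_seed, iteration=i, feature_table=feature_table)
        )
    summary = summarize(results, records) if len(results) >= 8 else None
    return results, summary
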