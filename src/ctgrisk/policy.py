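"""Consecutive-alert decision rule and (n, pt) policy selection.

An epoch alerts when its pHIE strictly exceeds a threshold ``pt``. The
system recommends intervention for a subject the first time the last ``n``
grid epochs are all alerting, tolerating up to ``floor(n/2)`` missing
epochs inside that window (invalid epochs or epochs with undefined OOB
probability); with more missing the system defers — it does not decide
until there are more observations. A window must also contain at least one
observed epoch, and the window cannot extend before monitoring onset: the
earliest possible recommendation therefore comes after ``n`` epochs
(100 min of monitoring for n = 5 and 20-min epochs). Recommendations
latch: once issued they persist, so subject-level detection curves are
cumulative.

Policy selection mirrors the training procedure: for each run length
``n`` in 1..10, build the subject-level ROC over thresholds from the
training out-of-bag probabilities; pick ``n̂`` maximizing AUC, then the
smallest (most sensitive) threshold whose training false-positive rate
does not exceed the healthy-group Caesarean rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ALERT = 1
NO_ALERT = 0
MISSING = -1

RECOMMEND = "recommend"
NO_RECOMMEND = "no-recommend"
DEFERRED = "deferred"

N_RANGE = tuple(range(1, 11))  # searched alert-run lengths


@dataclass(frozen=True)
class DecisionPolicy:
    """Alert-run length ``n``, threshold ``pt``, and the latch flag."""

    n: int
    pt: float
    latch: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 10:
            raise ValueError(f"n must be in 1..10, got {self.n}")
        if not 0.0 <= self.pt <= 1.0:
            raise ValueError(f"pt must be in [0, 1], got {self.pt}")

    @property
    def max_missing(self) -> int:
        """Missing epochs tolerated inside one decision window: floor(n/2)."""
        return self.n // 2


@dataclass
class SubjectDecision:
    """Outcome of the decision rule for one subject's epoch stream."""

    subject_id: str
    recommended: bool
    first_recommendation_epoch: int | None
    states: list[str] = field(default_factory=list)  # chronological, one per epoch


def alert_stream(phie_by_epoch: np.ndarray, pt: float) -> np.ndarray:
    """Per-epoch flags: ALERT iff pHIE > pt (strict); NaN propagates as MISSING."""
    phie = np.asarray(phie_by_epoch, dtype=float)
    finite = ~np.isnan(phie)
    if np.any((phie[finite] < 0) | (phie[finite] > 1)):
        raise ValueError("pHIE values must lie in [0, 1]")
    flags = np.full(phie.shape, MISSING, dtype=int)
    flags[finite & (phie > pt)] = ALERT
    flags[finite & (phie <= pt)] = NO_ALERT
    return flags


def recommend(
    alert_flags: np.ndarray,
    policy: DecisionPolicy,
    subject_id: str = "",
    epoch_indices: np.ndarray | None = None,
) -> SubjectDecision:
    """Run the n-consecutive-alert rule over a chronological flag stream.

    ``alert_flags`` is ordered chronologically, i.e. by decreasing epoch
    index; ``epoch_indices`` defaults to K-1..0 for a K-long stream. At
    each position the last ``n`` grid slots are examined: fewer than ``n``
    monitored slots, or more than ``floor(n/2)`` missing among them, or no
    observed slot at all, defers the decision; a window whose observed
    slots all alert recommends. Deferral never resets the run — the window
    test is simply re-applied at the next epoch.
    """
    flags = np.asarray(alert_flags, dtype=int)
    k = len(flags)
    if epoch_indices is None:
        epoch_indices = np.arange(k - 1, -1, -1)
    states: list[str] = []
    recommended = False
    first_epoch: int | None = None
    n, max_missing = policy.n, policy.max_missing
    for t in range(k):
        if recommended and policy.latch:
            states.append(RECOMMEND)
            continue
        if t < n - 1:  # window would extend before monitoring onset
            states.append(DEFERRED)
            continue
        window = flags[t - n + 1 : t + 1]
        n_missing = int(np.sum(window == MISSING))
        if n_missing > max_missing or n_missing == n:
            states.append(DEFERRED)
        elif np.all(window[window != MISSING] == ALERT):
            states.append(RECOMMEND)
            if not recommended:
                recommended = True
                first_epoch = int(epoch_indices[t])
        else:
            states.append(NO_RECOMMEND)
    return SubjectDecision(
        subject_id=subject_id,
        recommended=recommended,
        first_recommendation_epoch=first_epoch,
        states=states,
    )


def decide_subject(
    phie_by_epoch: np.ndarray,
    policy: DecisionPolicy,
    subject_id: str = "",
    epoch_indices: np.ndarray | None = None,
) -> SubjectDecision:
    """Convenience: threshold a pHIE stream and apply the decision rule."""
    return recommend(alert_stream(phie_by_epoch, policy.pt), policy, subject_id, epoch_indices)


# ---------------------------------------------------------------------------
# window-score reduction: drives ROC construction

def window_scores(phie_by_epoch: np.ndarray, n: int, max_missing: int | None = None) -> float:
    """Subject score s_n: max over admissible windows of the min observed pHIE.

    A window of the last ``n`` epochs is admissible when it lies fully in
    the monitored span, has at most ``floor(n/2)`` missing epochs, and at
    least one observed one. The subject is recommended at threshold ``pt``
    iff ``s_n > pt``: within an admissible window every observed pHIE
    exceeds ``pt`` exactly when their minimum does. Returns ``-inf`` when
    no admissible window exists (the subject can never be recommended).
    """
    phie = np.asarray(phie_by_epoch, dtype=float)
    n_epochs = len(phie)
    if n_epochs < n:
        return -np.inf
    if max_missing is None:
        max_missing = n // 2
    windows = np.lib.stride_tricks.sliding_window_view(phie, n)
    n_missing = np.isnan(windows).sum(axis=1)
    admissible = (n_missing <= max_missing) & (n_missing < n)
    if not admissible.any():
        return -np.inf
    return float(np.nanmin(windows[admissible], axis=1).max())


@dataclass
class RocCurve:
    """Subject-level ROC of the recommendation rule for one run length."""

    n: int
    thresholds: np.ndarray  # ascending
    fpr: np.ndarray  # non-increasing in threshold
    tpr: np.ndarray
    auc: float
    pathological_scores: np.ndarray = field(repr=False, default=None)
    healthy_scores: np.ndarray = field(repr=False, default=None)


def roc_for_n(
    phie_by_subject: dict[str, np.ndarray],
    pathological: dict[str, bool],
    n: int,
    threshold_grid: np.ndarray | None = None,
) -> RocCurve:
    """ROC of end-of-record recommendation status as ``pt`` varies.

    ``phie_by_subject`` maps subject -> chronological pHIE stream (NaN =
    missing). TPR/FPR at each threshold are the fractions of pathological/
    healthy subjects recommended by end of record; AUC is the trapezoidal
    area over the (FPR, TPR) points augmented with (0,0) and (1,1). The
    default grid is every distinct finite pHIE value plus {0, 1}.
    """
    scores = {sid: window_scores(phie, n) for sid, phie in phie_by_subject.items()}
    path_scores = np.array([s for sid, s in scores.items() if pathological[sid]])
    healthy_scores = np.array([s for sid, s in scores.items() if not pathological[sid]])
    if len(path_scores) == 0 or len(healthy_scores) == 0:
        raise ValueError("both healthy and pathological subjects are required")
    if threshold_grid is None:
        vals = np.concatenate([np.ravel(p) for p in phie_by_subject.values()])
        threshold_grid = np.unique(np.concatenate([vals[~np.isnan(vals)], [0.0, 1.0]]))
    grid = np.sort(np.asarray(threshold_grid, dtype=float))
    path_sorted = np.sort(path_scores)
    healthy_sorted = np.sort(healthy_scores)
    # count of scores strictly greater than each threshold
    tpr = 1.0 - np.searchsorted(path_sorted, grid, side="right") / len(path_sorted)
    fpr = 1.0 - np.searchsorted(healthy_sorted, grid, side="right") / len(healthy_sorted)
    fx = np.concatenate([[1.0], fpr, [0.0]])[::-1]
    ty = np.concatenate([[1.0], tpr, [0.0]])[::-1]
    auc = float(np.trapezoid(ty, fx))
    return RocCurve(
        n=n,
        thresholds=grid,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        pathological_scores=path_scores,
        healthy_scores=healthy_scores,
    )


def select_n(auc_by_n: dict[int, float]) -> int:
    """Run length with the highest AUC; ties break toward smaller n."""
    if not auc_by_n:
        raise ValueError("auc_by_n is empty")
    return min(auc_by_n, key=lambda n: (-auc_by_n[n], n))


def select_pt(roc: RocCurve, target_fpr: float) -> float:
    """Smallest threshold whose training FPR is at most ``target_fpr``.

    Smallest = most sensitive admissible operating point. If even the
    largest grid threshold violates the constraint, returns 1.0 with a
    warning (pHIE can never strictly exceed 1, so FPR(1.0) = 0).
    """
    if not 0.0 <= target_fpr <= 1.0:
        raise ValueError("target_fpr must be in [0, 1]")
    ok = roc.fpr <= target_fpr
    if not ok.any():
        warnings.warn(
            f"no grid threshold achieves FPR <= {target_fpr}; falling back to pt = 1.0",
            stacklevel=2,
        )
        return 1.0
    return float(roc.thresholds[np.argmax(ok)])  # fpr non-increasing => first True
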