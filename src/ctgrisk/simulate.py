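"""Synthetic cohorts of event-annotated labor records.

Each channel of a record is generated by an explicit semi-Markov process:
alternate between drawing a dwell time for the current event state
(log-normal) and sampling the next state from a transition row with zero
diagonal. Generation runs chronologically, from the start of the record
toward delivery; the time-to-delivery used for drift is the start of the
interval being generated, so the drift is causal.

Pathology is encoded in two group-dependent "drifts" that strengthen
linearly as delivery approaches within a drift horizon: (a) the probability
of entering a deceleration (BAS -> DEC) rises, and (b) the mean dwell of
decelerations lengthens. Decelerations are the physiologically expected
signature of progressive intrapartum hypoxia, so these two knobs give the
downstream classifier a risk signal that grows toward delivery, strongest
for the HIE group, intermediate for acidosis, mild for healthy.

Uninterpretable segments arrive as a Poisson process with exponential
durations; FHR events overlapping them are split at segment boundaries and
resulting fragments shorter than 5 s are dropped (UP events are untouched —
the noise model represents FHR signal loss).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .events import (
    FHR,
    FHR_LABELS,
    GROUPS,
    MAX_DURATION_S,
    UP,
    UP_LABELS,
    EventInterval,
    LaborRecord,
)

#: fragments of split FHR events shorter than this are discarded (seconds)
MIN_FRAGMENT_S = 5.0


@dataclass(frozen=True)
class DwellParams:
    """Log-normal dwell-time parameters for one event state.

    ``mean_log`` is the mean of log-duration (log-seconds), ``sd_log`` its
    standard deviation; ``sd_log = 0`` degenerates to a point mass at
    ``exp(mean_log)``.
    """

    mean_log: float
    sd_log: float

    def __post_init__(self) -> None:
        if self.sd_log < 0:
            raise ValueError("sd_log must be >= 0")


def _transition_dict_to_matrix(states: tuple[str, ...], rows: dict) -> np.ndarray:
    mat = np.zeros((len(states), len(states)))
    for i, s in enumerate(states):
        for j, t in enumerate(states):
            mat[i, j] = rows.get(s, {}).get(t, 0.0)
    return mat


@dataclass
class SemiMarkovParams:
    """Generative parameters for one group's two-channel event process.

    ``fhr_transition`` / ``up_transition`` are row-stochastic matrices over
    ``FHR_LABELS`` / ``UP_LABELS`` with zero diagonal (self-transitions are
    unobservable in an event stream). ``dec_entry_drift`` is added to the
    BAS->DEC probability (taken from the BAS->ACC mass) and
    ``dec_dwell_drift`` multiplies the DEC dwell mean, both scaled by
    ``max(0, 1 - t/drift_horizon_s)`` where ``t`` is time to delivery, so
    each drift is zero earlier than the horizon and maximal at delivery.
    """

    dwell: dict[str, DwellParams]
    fhr_transition: np.ndarray
    up_transition: np.ndarray
    dec_entry_drift: float = 0.0
    dec_dwell_drift: float = 0.0
    drift_horizon_s: float = 14_400.0
    invalid_rate_per_hour: float = 0.0
    invalid_mean_s: float = 120.0
    duration_range_s: tuple[float, float] = (14_400.0, 43_200.0)

    def __post_init__(self) -> None:
        self.fhr_transition = np.asarray(self.fhr_transition, dtype=float)
        self.up_transition = np.asarray(self.up_transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, mat, states in (
            ("fhr_transition", self.fhr_transition, FHR_LABELS),
            ("up_transition", self.up_transition, UP_LABELS),
        ):
            if mat.shape != (len(states), len(states)):
                raise ValueError(f"{name} must be {len(states)}x{len(states)}")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if np.any(np.diag(mat) != 0):
                raise ValueError(f"{name} diagonal must be 0")
            if np.any(mat < 0):
                raise ValueError(f"{name} entries must be >= 0")
        for state in FHR_LABELS + UP_LABELS:
            if state not in self.dwell:
                raise ValueError(f"missing dwell parameters for state {state}")
        i, j = FHR_LABELS.index("BAS"), FHR_LABELS.index("DEC")
        if not 0.0 <= self.fhr_transition[i, j] + max(self.dec_entry_drift, 0.0) <= 1.0:
            raise ValueError("dec_entry_drift pushes BAS->DEC outside [0, 1]")
        if self.dec_dwell_drift < -1.0:
            raise ValueError("dec_dwell_drift must keep the DEC dwell mean positive")
        lo, hi = self.duration_range_s
        if not 0 < lo <= hi <= MAX_DURATION_S:
            raise ValueError(f"duration_range_s must lie in (0, {MAX_DURATION_S}]")

    def drift_factor(self, time_to_delivery: float) -> float:
        """Linear ramp: 0 beyond the horizon, 1 at delivery."""
        return max(0.0, 1.0 - time_to_delivery / self.drift_horizon_s)

    def states(self, channel: str) -> tuple[str, ...]:
        return FHR_LABELS if channel == FHR else UP_LABELS

    def transition_row(self, state: str, channel: str, time_to_delivery: float) -> np.ndarray:
        """Transition probabilities out of ``state``, with drift applied.

        The BAS row moves ``dec_entry_drift * drift_factor`` of probability
        mass from ACC to DEC, clipped so the row stays a distribution.
        """
        states = self.states(channel)
        mat = self.fhr_transition if channel == FHR else self.up_transition
        i = states.index(state)
        row = mat[i].copy()
        if channel == FHR and state == "BAS" and self.dec_entry_drift != 0.0:
            j_dec = states.index("DEC")
            j_acc = states.index("ACC")
            shift = self.dec_entry_drift * self.drift_factor(time_to_delivery)
            shift = min(max(shift, -row[j_dec]), row[j_acc])
            row[j_dec] += shift
            row[j_acc] -= shift
        return row


def sample_dwell(
    state: str, time_to_delivery: float, params: SemiMarkovParams, rng: np.random.Generator
) -> float:
    """Draw one dwell time (seconds) for ``state`` at ``time_to_delivery``.

    DEC dwells have their mean multiplied by
    ``1 + dec_dwell_drift * drift_factor``; other states are undrifted.
    Degenerate ``sd_log = 0`` returns ``exp(mean_log)`` exactly.
    """
    if state not in params.dwell:
        raise ValueError(f"unknown state {state!r}")
    dp = params.dwell[state]
    mu = dp.mean_log
    if state == "DEC" and params.dec_dwell_drift != 0.0:
        mu += math.log1p(params.dec_dwell_drift * params.drift_factor(time_to_delivery))
    if dp.sd_log == 0.0:
        return math.exp(mu)
    return float(rng.lognormal(mean=mu, sigma=dp.sd_log))


def next_state(
    current_state: str,
    channel: str,
    time_to_delivery: float,
    params: SemiMarkovParams,
    rng: np.random.Generator,
) -> str:
    """Sample the successor state from the (drifted) transition row."""
    states = params.states(channel)
    if current_state not in states:
        raise ValueError(f"unknown state {current_state!r} on channel {channel}")
    row = params.transition_row(current_state, channel, time_to_delivery)
    u = rng.random() * row.sum()  # row sums to 1 up to clipping roundoff
    idx = int(np.searchsorted(np.cumsum(row), u, side="right"))
    return states[min(idx, len(states) - 1)]


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping (start, end) intervals; sorted by decreasing start."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: -iv[0])
    merged = [ivs[0]]
    for start, end in ivs[1:]:
        m_start, m_end = merged[-1]
        if start >= m_end:  # touches or overlaps the previous (chronologically)
            merged[-1] = (m_start, min(m_end, end))
        else:
            merged.append((start, end))
    return merged


def _subtract_invalid(
    ev: EventInterval, invalid: list[tuple[float, float]]
) -> list[EventInterval]:
    """Split an FHR event around invalid segments; drop short fragments."""
    pieces = [(ev.start, ev.end)]
    for inv_start, inv_end in invalid:
        nxt = []
        for p_start, p_end in pieces:
            if min(p_start, inv_start) <= max(p_end, inv_end):  # no overlap
                nxt.append((p_start, p_end))
                continue
            if p_start > inv_start:
                nxt.append((p_start, inv_start))
            if inv_end > p_end:
                nxt.append((inv_end, p_end))
        pieces = nxt
    return [
        replace(ev, start=s, end=e) for s, e in pieces if s - e >= MIN_FRAGMENT_S
    ]


def _simulate_channel(
    channel: str,
    duration: float,
    params: SemiMarkovParams,
    rng: np.random.Generator,
) -> list[EventInterval]:
    states = params.states(channel)
    state = "BAS" if channel == FHR else states[rng.integers(len(states))]
    events: list[EventInterval] = []
    t = duration
    while t > 0:
        dwell = sample_dwell(state, t, params, rng)
        end = max(t - dwell, 0.0)
        events.append(EventInterval(channel=channel, label=state, start=t, end=end))
        t = end
        if t <= 0:
            break
        state = next_state(state, channel, t, params, rng)
    return events


def simulate_record(
    subject_id: str,
    group: str,
    params: SemiMarkovParams,
    rng: np.random.Generator,
    caesarean: bool = False,
    duration: float | None = None,
) -> LaborRecord:
    """Simulate one labor record; the result always passes validation.

    The two channels are generated independently with the group's shared
    drift. Invalid segments are then superimposed (Poisson arrivals,
    exponential durations, merged if overlapping) and FHR events are split
    around them.
    """
    if duration is None:
        lo, hi = params.duration_range_s
        duration = min(float(rng.uniform(lo, hi)), MAX_DURATION_S)
    fhr_events = _simulate_channel(FHR, duration, params, rng)
    up_events = _simulate_channel(UP, duration, params, rng)

    invalid: list[tuple[float, float]] = []
    if params.invalid_rate_per_hour > 0:
        n_seg = rng.poisson(params.invalid_rate_per_hour * duration / 3600.0)
        for _ in range(n_seg):
            seg_start = float(rng.uniform(0.0, duration))
            seg_len = float(rng.exponential(params.invalid_mean_s))
            seg_end = max(seg_start - seg_len, 0.0)
            if seg_start > seg_end:
                invalid.append((seg_start, seg_end))
        invalid = _merge_intervals(invalid)
        fhr_events = [
            piece for ev in fhr_events for piece in _subtract_invalid(ev, invalid)
        ]
    return LaborRecord(
        subject_id=subject_id,
        group=group,
        duration=duration,
        caesarean=caesarean,
        events={FHR: fhr_events, UP: up_events},
        invalid_intervals=invalid,
    )


# ---------------------------------------------------------------------------
# cohort-level configuration


def _default_dwell() -> dict[str, DwellParams]:
    # medians (seconds): BAS 240, ACC 40, DEC 50, CON 70, RIN 120 — typical
    # active-labor event scales (contractions every ~3 min lasting ~70 s).
    return {
        "BAS": DwellParams(math.log(240.0), 0.6),
        "ACC": DwellParams(math.log(40.0), 0.4),
        "DEC": DwellParams(math.log(50.0), 0.4),
        "CON": DwellParams(math.log(70.0), 0.3),
        "RIN": DwellParams(math.log(120.0), 0.5),
    }


_UP_ALTERNATE = np.array([[0.0, 1.0], [1.0, 0.0]])


def _fhr_matrix(p_bas_dec: float) -> np.ndarray:
    # rows: BAS, ACC, DEC; baseline returns dominate after ACC/DEC
    return np.array(
        [
            [0.0, 1.0 - p_bas_dec, p_bas_dec],
            [0.9, 0.0, 0.1],
            [0.9, 0.1, 0.0],
        ]
    )


def default_group_params(group: str) -> SemiMarkovParams:
    """The configured study conditions for one group.

    All groups share dwell scales and the UP process; pathological groups
    have a higher baseline deceleration-entry probability and stronger
    near-delivery drift on both deceleration entry and deceleration dwell.
    """
    base = dict(
        dwell=_default_dwell(),
        up_transition=_UP_ALTERNATE,
        drift_horizon_s=14_400.0,
        invalid_rate_per_hour=1.0,
        invalid_mean_s=120.0,
        duration_range_s=(14_400.0, 43_200.0),
    )
    if group == "healthy":
        return SemiMarkovParams(
            fhr_transition=_fhr_matrix(0.30), dec_entry_drift=0.15, dec_dwell_drift=0.2, **base
        )
    if group == "acidosis":
        return SemiMarkovParams(
            fhr_transition=_fhr_matrix(0.40), dec_entry_drift=0.25, dec_dwell_drift=0.5, **base
        )
    if group == "HIE":
        return SemiMarkovParams(
            fhr_transition=_fhr_matrix(0.45), dec_entry_drift=0.35, dec_dwell_drift=0.8, **base
        )
    raise ValueError(f"unknown group {group!r}")


#: group proportions of the emulated cohort (healthy : acidosis : HIE),
#: normalized from 37,546 : 3,056 : 374
DEFAULT_PROPORTIONS = {
    "healthy": 37_546 / 40_976,
    "acidosis": 3_056 / 40_976,
    "HIE": 374 / 40_976,
}

#: observed Caesarean delivery rates per group
DEFAULT_CAESAREAN_RATES = {"healthy": 0.389, "acidosis": 0.376, "HIE": 0.549}


@dataclass
class CohortConfig:
    """Cohort size, composition, and per-group generative parameters."""

    size: int
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    caesarean_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAESAREAN_RATES)
    )
    params: dict[str, SemiMarkovParams] = field(
        default_factory=lambda: {g: default_group_params(g) for g in GROUPS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"group proportions must sum to 1, got {total}")
        for g, p in self.caesarean_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"caesarean rate for {g} outside [0, 1]: {p}")


def null_cohort_config(size: int, seed: int = 0) -> CohortConfig:
    """A cohort whose three groups share identical generative parameters.

    Group labels are then pure noise, so any downstream discrimination
    should collapse to chance — the negative control for the pipeline.
    """
    healthy = default_group_params("healthy")
    return CohortConfig(size=size, params={g: healthy for g in GROUPS}, seed=seed)


def largest_remainder_counts(size: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer group counts summing to ``size`` by largest-remainder rounding."""
    quotas = {g: size * p for g, p in proportions.items()}
    counts = {g: int(math.floor(q)) for g, q in quotas.items()}
    short = size - sum(counts.values())
    # ties broken by group order in the proportions dict
    by_remainder = sorted(quotas, key=lambda g: quotas[g] - counts[g], reverse=True)
    for g in by_remainder[:short]:
        counts[g] += 1
    return counts


def simulate_cohort(config: CohortConfig) -> list[LaborRecord]:
    """Simulate a full cohort, deterministic given ``config.seed``.

    A root seed sequence spawns one substream per record, so cohorts are
    reproducible independently of generation order.
    """
    counts = largest_remainder_counts(config.size, config.proportions)
    assignments = [g for g in config.proportions for _ in range(counts[g])]
    children = np.random.SeedSequence(config.seed).spawn(len(assignments))
    records = []
    for i, (group, child) in enumerate(zip(assignments, children)):
        rng = np.random.default_rng(child)
        caesarean = bool(rng.random() < config.caesarean_rates[group])
        records.append(
            simulate_record(f"S{i:05d}", group, config.params[group], rng, caesarean=caesarean)
        )
    return records


# ---------------------------------------------------------------------------
# YAML config round-trip (CLI surface)


def config_from_yaml(path) -> CohortConfig:
    """Load a CohortConfig from a YAML file.

    Recognized keys: size (required), seed, proportions, caesarean_rates,
    and an optional ``groups:`` mapping overriding per-group drift and
    noise settings on top of the built-in defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {"size": int(raw["size"]), "seed": int(raw.get("seed", 0))}
    if "proportions" in raw:
        kwargs["proportions"] = {g: float(p) for g, p in raw["proportions"].items()}
    if "caesarean_rates" in raw:
        kwargs["caesarean_rates"] = {g: float(p) for g, p in raw["caesarean_rates"].items()}
    params = {g: default_group_params(g) for g in GROUPS}
    for g, overrides in (raw.get("groups") or {}).items():
        params[g] = replace(params[g], **overrides)
    kwargs["params"] = params
    return CohortConfig(**kwargs)
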