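"""Synthetic afferent spike-train protocols.

All experiments are driven by Poisson input: a background of low-rate
irregular firing over all K input neurons, interrupted by 100-ms events
during which one input-neuron group fires at a high rate.  Occurrence
probabilities of the event patterns are the quantity the recurrent
network is supposed to internalize, so the generator is deliberately
simple and exactly reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatternSpec",
    "StimulusSchedule",
    "CoherenceSpec",
    "build_schedule",
    "build_conditioned_schedule",
    "schedule_to_rates",
    "coherence_rates",
    "coherence_rate_vector",
    "rates_to_spikes",
    "iter_spike_chunks",
    "merge_segments",
]


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of the probabilistic pattern protocol.

    Patterns are groups of ``group_size`` input neurons firing at
    ``pattern_rate`` Hz for ``duration_ms``; between events every input
    neuron fires at ``background_rate`` Hz.  With zero overlap the total
    input count is ``K = group_size * n_patterns``.  ``overlap_fraction``
    makes consecutive groups share that fraction of their members.
    """

    n_patterns: int
    group_size: int = 100
    overlap_fraction: float = 0.0
    pattern_rate: float = 50.0
    background_rate: float = 2.0
    duration_ms: float = 100.0
    interval_ms: float = 100.0
    probabilities: Optional[tuple[float, ...]] = None
    order: str = "random"

    def __post_init__(self) -> None:
        if self.n_patterns < 1:
            raise ValueError("need at least one pattern")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.order not in ("random", "fixed_sequence"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.probabilities is not None:
            prob = np.asarray(self.probabilities, dtype=float)
            if len(prob) != self.n_patterns or (prob < 0).any():
                raise ValueError("probabilities must be non-negative, one per pattern")
            if abs(prob.sum() - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")

    @property
    def prob_vector(self) -> np.ndarray:
        if self.probabilities is None:
            return np.full(self.n_patterns, 1.0 / self.n_patterns)
        return np.asarray(self.probabilities, dtype=float)

    def memberships(self) -> list[np.ndarray]:
        """Input-neuron index arrays, one per pattern."""
        shared = int(round(self.overlap_fraction * self.group_size))
        groups, start = [], 0
        for j in range(self.n_patterns):
            groups.append(np.arange(start, start + self.group_size))
            start += self.group_size - (shared if j < self.n_patterns - 1 else 0)
        return groups

    @property
    def K(self) -> int:
        return int(self.memberships()[-1][-1]) + 1


@dataclass
class StimulusSchedule:
    """Realized event list of a protocol.

    ``events`` are ``(pattern_id, onset_ms, offset_ms)`` triples, ordered
    and non-overlapping; ``groups`` maps each pattern id to its member
    input neurons within a K-wide input layer.
    """

    events: list[tuple[int, float, float]]
    groups: list[np.ndarray]
    K: int
    total_duration_ms: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        last = -np.inf
        for pid, on, off in self.events:
            if on < last:
                raise ValueError("events overlap")
            if off <= on:
                raise ValueError("event offset must exceed onset")
            last = off

    def event_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["pattern_id", "onset_ms", "offset_ms"])

    def to_csv(self, path) -> None:
        self.event_frame().to_csv(path, index=False)

    def groups_to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({str(i): g.tolist() for i, g in enumerate(self.groups)})
        )

    @classmethod
    def from_csv(cls, path, groups, K, total_duration_ms, seed=None) -> "StimulusSchedule":
        df = pd.read_csv(path)
        events = [
            (int(r.pattern_id), float(r.onset_ms), float(r.offset_ms))
            for r in df.itertuples()
        ]
        return cls(events, groups, K, total_duration_ms, seed)


@dataclass(frozen=True)
class CoherenceSpec:
    """Random-dot coherence input: two pools, R and L.

    ``coh`` in [-0.5, 0.5] sets the rate asymmetry: the R pool fires at
    ``(coh + 0.5) * r_max`` and the L pool at ``(-coh + 0.5) * r_max``.
    """

    coh: float
    r_max: float = 50.0
    n_R: int = 100
    n_L: int = 100

    def __post_init__(self) -> None:
        if abs(self.coh) > 0.5:
            raise ValueError("coherence must lie in [-0.5, 0.5]")


def coherence_rates(spec: CoherenceSpec) -> tuple[float, float]:
    """(R-pool rate, L-pool rate) in Hz."""
    return ((spec.coh + 0.5) * spec.r_max, (-spec.coh + 0.5) * spec.r_max)


def coherence_rate_vector(spec: CoherenceSpec) -> np.ndarray:
    """Per-input-neuron rates, R pool first."""
    r_R, r_L = coherence_rates(spec)
    return np.concatenate([np.full(spec.n_R, r_R), np.full(spec.n_L, r_L)])


# ---------------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------------

def build_schedule(
    spec: PatternSpec,
    total_duration_ms: float,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> StimulusSchedule:
    """Tile ``[0, total)`` with alternating intervals and pattern events.

    Pattern identities are drawn i.i.d. from the configured occurrence
    probabilities (``random`` order) or cycled (``fixed_sequence``).
    """
    cycle = spec.interval_ms + spec.duration_ms
    onsets = []
    t = spec.interval_ms
    while t + spec.duration_ms <= total_duration_ms:
        onsets.append(t)
        t += cycle
    n = len(onsets)
    if spec.order == "random":
        ids = rng.choice(spec.n_patterns, size=n, p=spec.prob_vector)
    else:
        ids = np.arange(n) % spec.n_patterns
    events = [(int(i), on, on + spec.duration_ms) for i, on in zip(ids, onsets)]
    return StimulusSchedule(events, spec.memberships(), spec.K, total_duration_ms, seed)


def build_conditioned_schedule(
    conditional_table: np.ndarray,
    spec: PatternSpec,
    total_duration_ms: float,
    rng: np.random.Generator,
) -> tuple[StimulusSchedule, StimulusSchedule]:
    """Paired schedules for the two-subnetwork conditioning protocol.

    The A-schedule presents S1/S2 with equal marginal probability; at the
    same instants the B-schedule presents S3/S4 drawn from the row of
    ``conditional_table`` selected by the A-event.  ``spec`` must have
    ``n_patterns = 4`` (groups ordered S1, S2, S3, S4).
    """
    table = np.asarray(conditional_table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or np.abs(table.sum(1) - 1).max() > 1e-9:
        raise ValueError("conditional table must be 2x2 with rows summing to 1")
    if spec.n_patterns != 4:
        raise ValueError("conditioned protocol needs four pattern groups")
    base = build_schedule(spec, total_duration_ms, rng)
    groups = spec.memberships()
    ev_A, ev_B = [], []
    for _, on, off in base.events:
        a = int(rng.random() < 0.5)
        b = int(rng.random() < table[a, 1])
        ev_A.append((a, on, off))
        ev_B.append((2 + b, on, off))
    sched_A = StimulusSchedule(ev_A, groups, spec.K, total_duration_ms)
    sched_B = StimulusSchedule(ev_B, groups, spec.K, total_duration_ms)
    return sched_A, sched_B


# ---------------------------------------------------------------------------
# rates and spikes
# ---------------------------------------------------------------------------

def schedule_to_rates(
    schedule: StimulusSchedule,
    spec: PatternSpec,
    event_rate_vectors: Optional[dict[int, np.ndarray]] = None,
) -> list[tuple[float, float, np.ndarray]]:
    """Piecewise-constant per-neuron rate program.

    Returns ``(t0_ms, t1_ms, rates)`` segments covering the schedule's
    duration.  During an event the active pattern's members fire at the
    pattern rate and everyone else at the background rate, unless an
    explicit K-wide rate vector is supplied for that pattern id (used by
    the coherence task, where the non-preferred pool is set by ``coh``).
    """
    K = schedule.K
    bg = np.full(K, spec.background_rate)
    segs: list[tuple[float, float, np.ndarray]] = []
    t = 0.0
    for pid, on, off in schedule.events:
        if on > t:
            segs.append((t, on, bg))
        if event_rate_vectors is not None and pid in event_rate_vectors:
            rates = np.asarray(event_rate_vectors[pid], dtype=float)
        else:
            rates = bg.copy()
            rates[schedule.groups[pid]] = spec.pattern_rate
        segs.append((on, off, rates))
        t = off
    if t < schedule.total_duration_ms:
        segs.append((t, schedule.total_duration_ms, bg))
    return segs


def merge_segments(
    seg_a: list[tuple[float, float, np.ndarray]],
    seg_b: list[tuple[float, float, np.ndarray]],
    background_rate: float,
) -> list[tuple[float, float, np.ndarray]]:
    """Merge two time-aligned rate programs over the same input layer.

    Where either program exceeds the background it wins; the paired
    conditioning schedules are exactly aligned so segment boundaries
    coincide.
    """
    if len(seg_a) != len(seg_b):
        raise ValueError("segment lists are not aligned")
    out = []
    for (a0, a1, ra), (b0, b1, rb) in zip(seg_a, seg_b):
        if (a0, a1) != (b0, b1):
            raise ValueError("segment boundaries differ")
        out.append((a0, a1, np.maximum(ra, rb)))
    return out


def rates_to_spikes(
    rates: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli thinning of a dense (n_steps, K) rate array into spikes."""
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    prob = rates * dt / 1000.0
    if prob.size and prob.max() > 1.0:
        raise ValueError("rate too high for this dt")
    return (rng.random(rates.shape) < prob).astype(np.uint8)


def iter_spike_chunks(
    segments: list[tuple[float, float, np.ndarray]],
    dt: float,
    rng: np.random.Generator,
):
    """Yield ``(start_step, spikes)`` chunks, one per rate segment.

    ``spikes`` has shape (n_steps_in_segment, K); segment boundaries are
    assumed to be integer multiples of ``dt``.
    """
    for t0, t1, rates in segments:
        s0 = int(round(t0 / dt))
        s1 = int(round(t1 / dt))
        if s1 <= s0:
            continue
        prob = rates * dt / 1000.0
        yield s0, (rng.random((s1 - s0, rates.shape[0])) < prob).astype(np.uint8)
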