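"""Config-driven experiment runner.

Every experiment follows the same arc: probabilistic stimulation with all
plasticity on (learning), removal of afferent input with plasticity off
while the homeostatic gain recovers (recovery), an input-free epoch whose
replay statistics are the result (spontaneous), and trial-averaged evoked
probes with plasticity off that define the cell assemblies.  Variations —
the decision task, the two-subnetwork conditioning protocol, the ablations
— are expressed as configuration, not code paths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ModelKind,
    NetworkState,
    NetworkWeights,
    NeuronParams,
    init_state,
    init_weights,
)
from .engine import PhaseRecording, run_phase
from .metrics import (
    AssemblyAssignment,
    MetricsReport,
    activity_ratio_AR,
    assign_assemblies,
    choices_to_right,
    summarize_assemblies,
)
from .plasticity import ALL_MATRICES
from .stimuli import (
    CoherenceSpec,
    PatternSpec,
    StimulusSchedule,
    build_conditioned_schedule,
    build_schedule,
    coherence_rate_vector,
    merge_segments,
    schedule_to_rates,
)

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "run_experiment",
    "run_probability_sweep",
    "run_decision_task",
    "run_conditioned_prior",
    "PRESETS",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulation experiment."""

    protocol: str = "patterns"  # patterns | decision | conditioned
    kind: str = "nDL"
    N: int = 100
    n_exc: Optional[int] = None
    seed: int = 0
    neuron: NeuronParams = field(default_factory=NeuronParams)
    init_width: str = "variance"

    # pattern protocol
    n_patterns: int = 2
    probabilities: Optional[tuple[float, ...]] = None
    group_size: int = 100
    overlap_fraction: float = 0.0
    pattern_rate: float = 50.0
    background_rate: float = 2.0
    duration_ms: float = 100.0
    interval_ms: float = 100.0
    order: str = "random"

    # decision protocol: P(rightward stimulus) during training
    p_right: float = 0.5

    # conditioned protocol: 2x2 table P(B-stim | A-stim)
    conditional_table: Optional[tuple[tuple[float, float], tuple[float, float]]] = None

    # phase durations (ms)
    learn_ms: float = 1_000_000.0
    recovery_ms: float = 20_000.0
    spontaneous_ms: float = 100_000.0
    probe_reps: int = 20
    probe_settle_ms: float = 0.0

    # plasticity gating during the spontaneous epoch (empty = frozen)
    spont_plastic: tuple[str, ...] = ()
    # keep the input neurons' 2-Hz background firing after the patterned
    # stimulation ends; replay ignition rides on these weak fluctuations
    spont_background: bool = True

    # ablations
    fixed_h: bool = False
    h_fixed_value: float = 0.5
    frozen_G_after_stimuli: bool = False
    remove_between_assembly_excitation: bool = False

    # analysis
    selectivity_threshold: float = 0.3
    bin_ms: float = 20.0
    record_spont_events: bool = False
    pred_err_window_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.protocol not in ("patterns", "decision", "conditioned"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for name in ("learn_ms", "recovery_ms", "spontaneous_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.neuron, dict):
            self.neuron = NeuronParams(**self.neuron)
        if self.protocol == "conditioned" and self.conditional_table is None:
            raise ValueError("conditioned protocol needs a conditional_table")

    # -- derived -----------------------------------------------------------
    def pattern_spec(self) -> PatternSpec:
        if self.protocol == "decision":
            return PatternSpec(
                n_patterns=2,
                group_size=self.group_size,
                pattern_rate=self.pattern_rate,
                background_rate=self.background_rate,
                duration_ms=self.duration_ms,
                interval_ms=self.interval_ms,
                probabilities=(self.p_right, 1.0 - self.p_right),
                order="random",
            )
        n = 4 if self.protocol == "conditioned" else self.n_patterns
        return PatternSpec(
            n_patterns=n,
            group_size=self.group_size,
            overlap_fraction=self.overlap_fraction,
            pattern_rate=self.pattern_rate,
            background_rate=self.background_rate,
            duration_ms=self.duration_ms,
            interval_ms=self.interval_ms,
            probabilities=self.probabilities if self.protocol == "patterns" else None,
            order=self.order,
        )

    def coherence_training_vectors(self) -> dict[int, np.ndarray]:
        """Per-pattern rate vectors for the decision task (R first)."""
        n = self.group_size
        right = CoherenceSpec(coh=+0.5, r_max=self.pattern_rate, n_R=n, n_L=n)
        left = CoherenceSpec(coh=-0.5, r_max=self.pattern_rate, n_R=n, n_L=n)
        return {0: coherence_rate_vector(right), 1: coherence_rate_vector(left)}

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["neuron"] = asdict(self.neuron)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "neuron" in d and isinstance(d["neuron"], dict):
            d["neuron"] = NeuronParams(**d["neuron"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("probabilities", "spont_plastic"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("conditional_table") is not None:
            d["conditional_table"] = tuple(tuple(row) for row in d["conditional_table"])
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class RunResult:
    """Artifacts of one complete experiment."""

    config: ExperimentConfig
    weights: NetworkWeights
    state: NetworkState
    schedule: StimulusSchedule
    assignment: AssemblyAssignment
    evoked_rates: np.ndarray  # (N, n_stimuli)
    report: MetricsReport
    recordings: dict[str, PhaseRecording]
    ar_spont: Optional[float] = None  # decision task only


def _phase_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("init", "schedule", "learn", "recovery", "spont", "probe", "extra")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _learning_segments(cfg: ExperimentConfig, rng) -> tuple[StimulusSchedule, list]:
    spec = cfg.pattern_spec()
    if cfg.protocol == "conditioned":
        table = np.asarray(cfg.conditional_table, dtype=float)
        sched_A, sched_B = build_conditioned_schedule(table, spec, cfg.learn_ms, rng)
        seg_A = schedule_to_rates(sched_A, spec)
        seg_B = schedule_to_rates(sched_B, spec)
        return sched_A, merge_segments(seg_A, seg_B, spec.background_rate)
    sched = build_schedule(spec, cfg.learn_ms, rng, seed=cfg.seed)
    if cfg.protocol == "decision":
        segs = schedule_to_rates(sched, spec, cfg.coherence_training_vectors())
    else:
        segs = schedule_to_rates(sched, spec)
    return sched, segs


def _probe_evoked_rates(
    cfg: ExperimentConfig,
    weights: NetworkWeights,
    state: NetworkState,
    p: NeuronParams,
    rng,
) -> np.ndarray:
    """Trial-averaged per-neuron rates for each stimulus, plasticity off."""
    spec = cfg.pattern_spec()
    n_stim = spec.n_patterns
    K = weights.K
    bg = np.full(K, spec.background_rate)
    vectors = cfg.coherence_training_vectors() if cfg.protocol == "decision" else None
    gap = int(round(spec.interval_ms))
    dur = int(round(spec.duration_ms))
    counts = np.zeros((weights.N, n_stim))
    h_frozen = cfg.fixed_h
    for _ in range(cfg.probe_reps):
        for pid in range(n_stim):
            run_phase(weights, state, p, rng, gap,
                      input_segments=[(0.0, gap, bg)], h_frozen=h_frozen)
            if vectors is not None:
                rv = vectors[pid]
            else:
                rv = bg.copy()
                rv[spec.memberships()[pid]] = spec.pattern_rate
            r = run_phase(weights, state, p, rng, dur,
                          input_segments=[(0.0, dur, rv)], h_frozen=h_frozen)
            counts[:, pid] += r.counts
    return counts / (cfg.probe_reps * dur / 1000.0)


def run_experiment(cfg: ExperimentConfig) -> RunResult:
    """Learning -> recovery -> spontaneous -> evoked probes, with metrics.

    Deterministic given ``cfg.seed``: initialization, stimulus schedule
    and every phase draw from independent child generators of the seed.
    """
    p = cfg.neuron
    kind = ModelKind(cfg.kind)
    rngs = _phase_rngs(cfg.seed)
    spec = cfg.pattern_spec()
    K = spec.K

    weights = init_weights(kind, cfg.N, K, rngs["init"],
                           n_exc=cfg.n_exc, init_width=cfg.init_width)
    if cfg.protocol == "conditioned":
        # groups 1-2 drive subnetwork A (first half), groups 3-4 subnetwork B
        mask = np.zeros((cfg.N, K))
        half = cfg.N // 2
        mem = spec.memberships()
        a_cols = np.concatenate([mem[0], mem[1]])
        b_cols = np.concatenate([mem[2], mem[3]])
        mask[np.ix_(np.arange(half), a_cols)] = 1.0
        mask[np.ix_(np.arange(half, cfg.N), b_cols)] = 1.0
        weights.W_mask = mask
        weights.W *= mask
    state = init_state(cfg.N, K, p)
    if cfg.fixed_h:
        state.h[:] = cfg.h_fixed_value

    recordings: dict[str, PhaseRecording] = {}

    # --- learning ---------------------------------------------------------
    schedule, segments = _learning_segments(cfg, rngs["schedule"])
    recordings["learning"] = run_phase(
        weights, state, p, rngs["learn"], int(round(cfg.learn_ms / p.dt)),
        input_segments=segments, plastic=ALL_MATRICES[kind],
        hbar_every_ms=1000.0, pred_err_window_ms=cfg.pred_err_window_ms,
        h_frozen=cfg.fixed_h,
    )

    # --- recovery: patterned input removed, all plasticity off ------------
    def _bg_segments(duration_ms: float):
        if not cfg.spont_background:
            return None
        return [(0.0, duration_ms, np.full(K, cfg.background_rate))]

    recordings["recovery"] = run_phase(
        weights, state, p, rngs["recovery"], int(round(cfg.recovery_ms / p.dt)),
        input_segments=_bg_segments(cfg.recovery_ms),
        hbar_every_ms=1000.0, h_frozen=cfg.fixed_h,
    )

    # --- optionally probe before the spontaneous epoch --------------------
    evoked_rates = None
    if cfg.remove_between_assembly_excitation:
        evoked_rates = _probe_evoked_rates(cfg, weights, state, p, rngs["probe"])
        assignment = assign_assemblies(evoked_rates, cfg.selectivity_threshold)
        labels = assignment.labels
        same = np.equal.outer(labels, labels)
        assigned = labels >= 0
        cross = (~same) & np.outer(assigned, assigned)
        weights.M[cross & (weights.M > 0)] = 0.0
        # let the evoked excitability transient die down before measuring
        run_phase(weights, state, p, rngs["extra"],
                  int(round(cfg.recovery_ms / p.dt)),
                  input_segments=_bg_segments(cfg.recovery_ms),
                  h_frozen=cfg.fixed_h)

    # --- spontaneous epoch ------------------------------------------------
    spont_plastic = frozenset(cfg.spont_plastic)
    if cfg.frozen_G_after_stimuli:
        spont_plastic = spont_plastic - {"G"}
    recordings["spontaneous"] = run_phase(
        weights, state, p, rngs["spont"], int(round(cfg.spontaneous_ms / p.dt)),
        input_segments=_bg_segments(cfg.spontaneous_ms),
        plastic=spont_plastic, bin_ms=cfg.bin_ms, hbar_every_ms=1000.0,
        pred_err_window_ms=cfg.pred_err_window_ms,
        record_events=cfg.record_spont_events, h_frozen=cfg.fixed_h,
    )

    # --- evoked probes and assembly assignment ----------------------------
    if evoked_rates is None:
        evoked_rates = _probe_evoked_rates(cfg, weights, state, p, rngs["probe"])
        assignment = assign_assemblies(evoked_rates, cfg.selectivity_threshold)

    spont_rates = recordings["spontaneous"].rates()
    report = summarize_assemblies(spont_rates, assignment, target_assembly=0)

    ar = None
    if cfg.protocol == "decision":
        r_R = report.pop_rates[0]
        r_L = report.pop_rates[1]
        if r_R + r_L > 0:
            ar = activity_ratio_AR(r_R, r_L)

    return RunResult(
        config=cfg, weights=weights, state=state, schedule=schedule,
        assignment=assignment, evoked_rates=evoked_rates, report=report,
        recordings=recordings, ar_spont=ar,
    )


def run_probability_sweep(
    base: ExperimentConfig,
    ratios: Sequence[float],
    n_trials: int = 5,
) -> pd.DataFrame:
    """Replay statistics vs the occurrence-probability ratio of stimulus 1.

    For each ratio ``r`` stimulus 1 is presented ``r`` times as often as
    each of the other patterns; ``n_trials`` independent seeds per ratio.
    Returns one row per (ratio, trial) plus the three ratio metrics.
    """
    if len(ratios) < 1:
        raise ValueError("need at least one ratio")
    rows = []
    for r in ratios:
        n = base.n_patterns
        p1 = r / (r + n - 1)
        probs = (p1,) + tuple((1.0 - p1) / (n - 1) for _ in range(n - 1))
        for trial in range(n_trials):
            cfg = dataclasses.replace(
                base, probabilities=probs, seed=base.seed + 1000 * trial + int(r * 7919)
            )
            res = run_experiment(cfg)
            rows.append(
                {
                    "ratio": r,
                    "trial": trial,
                    "seed": cfg.seed,
                    "firing_rate_ratio": res.report.firing_rate_ratio,
                    "assembly_size_ratio": res.report.assembly_size_ratio,
                    "assembly_activity_ratio": res.report.assembly_activity_ratio,
                }
            )
    return pd.DataFrame(rows)


def run_decision_task(
    cfg: ExperimentConfig,
    test_cohs: Sequence[float] = (-0.5, -0.25, -0.1, 0.0, 0.1, 0.25, 0.5),
    probe_reps: int = 20,
    probe_ms: float = 1000.0,
) -> tuple[RunResult, pd.DataFrame]:
    """Train under a coherence protocol, then measure the psychometric curve.

    Each test coherence is probed ``probe_reps`` times for ``probe_ms``
    with plasticity off; a probe's choices-to-right is the activity-ratio
    percentage of the R assembly during the stimulus.
    """
    if cfg.protocol != "decision":
        cfg = dataclasses.replace(cfg, protocol="decision")
    res = run_experiment(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 17).spawn(1)[0])
    p = cfg.neuron
    K = res.weights.K
    bg = np.full(K, cfg.background_rate)
    members_R = res.assignment.members(0)
    members_L = res.assignment.members(1)
    rows = []
    gap = int(round(cfg.interval_ms))
    for coh in test_cohs:
        spc = CoherenceSpec(coh=coh, r_max=cfg.pattern_rate,
                            n_R=cfg.group_size, n_L=cfg.group_size)
        rv = coherence_rate_vector(spc)
        ars = []
        for _ in range(probe_reps):
            run_phase(res.weights, res.state, p, rng, gap,
                      input_segments=[(0.0, gap, bg)], h_frozen=cfg.fixed_h)
            rec = run_phase(res.weights, res.state, p, rng, int(round(probe_ms)),
                            input_segments=[(0.0, probe_ms, rv)], h_frozen=cfg.fixed_h)
            rates = rec.rates()
            r_R, r_L = rates[members_R].sum(), rates[members_L].sum()
            if r_R + r_L > 0:
                ars.append(activity_ratio_AR(r_R, r_L))
        mean_ar = float(np.mean(ars)) if ars else np.nan
        rows.append(
            {
                "coh": coh,
                "choices_to_right_pct": choices_to_right(mean_ar) if ars else np.nan,
                "sd": float(100.0 * np.std(ars)) if ars else np.nan,
                "n_probes": len(ars),
            }
        )
    return res, pd.DataFrame(rows)


def run_conditioned_prior(
    cfg: ExperimentConfig,
    probe_ms: float = 100_000.0,
) -> tuple[RunResult, dict]:
    """Train the two-subnetwork model, then condition B on A's stimulus.

    After learning, only S1 (then only S2) is presented; subnetwork B
    receives no afferent input and its S3-/S4-assembly population rates
    are read out.  Reports the S4 fraction r_S4/(r_S3+r_S4) per context,
    which in a trained network matches the conditional probability
    P(S4 | A-stimulus).
    """
    if cfg.protocol != "conditioned":
        raise ValueError("config must use the conditioned protocol")
    res = run_experiment(cfg)
    p = cfg.neuron
    spec = cfg.pattern_spec()
    mem = spec.memberships()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 29).spawn(1)[0])
    bg = np.full(res.weights.K, cfg.background_rate)
    out = {}
    for a_stim in (0, 1):
        rv = bg.copy()
        rv[mem[a_stim]] = cfg.pattern_rate
        cyc = cfg.duration_ms + cfg.interval_ms
        segs = []
        t = 0.0
        while t + cyc <= probe_ms:
            segs.append((t, t + cfg.interval_ms, bg))
            segs.append((t + cfg.interval_ms, t + cyc, rv))
            t += cyc
        if t < probe_ms:
            segs.append((t, probe_ms, bg))
        rec = run_phase(res.weights, res.state, p, rng, int(round(probe_ms / p.dt)),
                        input_segments=segs, h_frozen=cfg.fixed_h)
        rates = rec.rates()
        r3 = rates[res.assignment.members(2)].sum()
        r4 = rates[res.assignment.members(3)].sum()
        out[f"S{a_stim + 1}"] = {
            "r_pop_S3": float(r3),
            "r_pop_S4": float(r4),
            "S4_fraction": float(r4 / (r3 + r4)) if (r3 + r4) > 0 else np.nan,
        }
    return res, out


# ---------------------------------------------------------------------------
# named presets (desk scale by default; pass full=True for paper scale)
# ---------------------------------------------------------------------------

def PRESETS(name: str, full: bool = False, seed: int = 0) -> ExperimentConfig:
    """Named experiment configurations.

    Desk-scale presets use N=100 and shorter analysis epochs so a run
    fits in minutes; ``full=True`` restores the published network size.
    """
    N = 500 if full else 100
    learn = 1_000_000.0
    spont = 100_000.0
    base = dict(N=N, seed=seed, learn_ms=learn, spontaneous_ms=spont)
    if name == "fig2":
        return ExperimentConfig(protocol="patterns", n_patterns=5 if full else 3, **base)
    if name == "fig3":
        n = 5 if full else 3
        r = 2.0
        p1 = r / (r + n - 1)
        probs = (p1,) + ((1 - p1) / (n - 1),) * (n - 1)
        return ExperimentConfig(protocol="patterns", n_patterns=n,
                                probabilities=probs, **base)
    if name == "fig4":
        return ExperimentConfig(protocol="patterns", n_patterns=2,
                                probabilities=(0.3, 0.7), **base)
    if name == "fig5":
        return ExperimentConfig(protocol="decision", p_right=0.5, **base)
    if name == "fig5-biased":
        return ExperimentConfig(protocol="decision", p_right=0.8, **base)
    if name == "fig6":
        return ExperimentConfig(protocol="patterns", kind="signed",
                                n_patterns=5 if full else 2, **base)
    if name == "fig7":
        return ExperimentConfig(protocol="patterns", kind="DL", n_patterns=3,
                                n_exc=N // 2, **base)
    if name == "conditioned":
        return ExperimentConfig(protocol="conditioned",
                                conditional_table=((1 / 3, 2 / 3), (2 / 3, 1 / 3)),
                                **base)
    raise ValueError(f"unknown preset {name!r}")
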