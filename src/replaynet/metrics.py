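"""Cell-assembly identification and replay statistics.

Assemblies are defined functionally: after learning, each neuron is
assigned to the stimulus that drives it most strongly in evoked probe
trials, provided the response is selective enough.  All replay measures
(firing-rate ratio, assembly-size ratio, assembly-activity ratio, the
decision-task activity ratio AR) compare the target assembly against the
average of the others; the assembly-activity ratio is the quantity that
tracks the stimulus occurrence probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "AssemblyAssignment",
    "MetricsReport",
    "assign_assemblies",
    "firing_rate_ratio",
    "assembly_size_ratio",
    "assembly_activity_ratio",
    "activity_ratio_AR",
    "choices_to_right",
    "normalized_excitatory_incoming_weights",
    "lateral_inhibition_matrix",
    "pairwise_correlations",
    "prediction_error_trace",
]

UNASSIGNED = -1


@dataclass
class AssemblyAssignment:
    """Neuron -> assembly map (assembly ids are stimulus ids).

    ``labels`` holds ``UNASSIGNED`` (-1) for neurons with no selective
    response; ``selectivity`` is ``(max - second_max)/(max + second_max)``
    of the evoked-rate profile.
    """

    labels: np.ndarray
    selectivity: np.ndarray
    n_assemblies: int

    def members(self, j: int) -> np.ndarray:
        return np.nonzero(self.labels == j)[0]

    def sizes(self) -> np.ndarray:
        return np.array(
            [int((self.labels == j).sum()) for j in range(self.n_assemblies)]
        )

    @property
    def n_assigned(self) -> int:
        return int((self.labels != UNASSIGNED).sum())


def assign_assemblies(evoked_rates: np.ndarray, threshold: float = 0.3) -> AssemblyAssignment:
    """Assign each neuron to its preferred stimulus.

    Parameters
    ----------
    evoked_rates : (N, n_stimuli) array
        Trial-averaged firing rate of each neuron during presentations of
        each stimulus.
    threshold : float
        Minimum selectivity index ``(max - second)/(max + second)``; less
        selective neurons are left unassigned.  Ties go to the lowest
        stimulus id via ``argmax``.
    """
    rates = np.asarray(evoked_rates, dtype=float)
    N, n_stim = rates.shape
    labels = np.full(N, UNASSIGNED, dtype=int)
    sel = np.zeros(N)
    if not rates.any():
        warnings.warn("all-zero evoked responses; every neuron left unassigned")
        return AssemblyAssignment(labels, sel, n_stim)
    order = np.sort(rates, axis=1)
    top = order[:, -1]
    second = order[:, -2] if n_stim > 1 else np.zeros(N)
    denom = top + second
    with np.errstate(invalid="ignore", divide="ignore"):
        sel = np.where(denom > 0, (top - second) / denom, 0.0)
    ok = (top > 0) & (sel >= threshold)
    labels[ok] = rates[ok].argmax(axis=1)
    return AssemblyAssignment(labels, sel, n_stim)


@dataclass
class MetricsReport:
    """Replay statistics of one spontaneous epoch."""

    assembly_sizes: np.ndarray  # N_j
    mean_rates: np.ndarray  # per-assembly mean single-neuron rate, Hz
    pop_rates: np.ndarray  # per-assembly population rate sum_i r_i, Hz
    firing_rate_ratio: Optional[float] = None
    assembly_size_ratio: Optional[float] = None
    assembly_activity_ratio: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "assembly_sizes": self.assembly_sizes.tolist(),
            "mean_rates": self.mean_rates.tolist(),
            "pop_rates": self.pop_rates.tolist(),
            "firing_rate_ratio": self.firing_rate_ratio,
            "assembly_size_ratio": self.assembly_size_ratio,
            "assembly_activity_ratio": self.assembly_activity_ratio,
        }


def summarize_assemblies(
    rates: np.ndarray, assignment: AssemblyAssignment, target_assembly: int = 0
) -> MetricsReport:
    """Per-assembly rate summaries plus the three ratio statistics.

    ``rates`` are per-neuron firing rates (Hz) over the analysis epoch;
    unassigned neurons are excluded from every numerator and denominator.
    """
    nj = assignment.sizes()
    mean_r = np.zeros(len(nj))
    pop_r = np.zeros(len(nj))
    for j in range(len(nj)):
        idx = assignment.members(j)
        if idx.size:
            mean_r[j] = rates[idx].mean()
            pop_r[j] = rates[idx].sum()
    rep = MetricsReport(assembly_sizes=nj, mean_rates=mean_r, pop_rates=pop_r)
    rep.firing_rate_ratio = firing_rate_ratio(rep, target_assembly)
    rep.assembly_size_ratio = assembly_size_ratio(rep, target_assembly)
    rep.assembly_activity_ratio = assembly_activity_ratio(rep, target_assembly)
    return rep


def _others_mean(values: np.ndarray, sizes: np.ndarray, target: int) -> Optional[float]:
    others = [v for j, v in enumerate(values) if j != target and sizes[j] > 0]
    if not others or sizes[target] == 0:
        return None
    return float(np.mean(others))


def firing_rate_ratio(report: MetricsReport, target_assembly: int = 0) -> Optional[float]:
    """Mean single-neuron rate of the target assembly over the average of
    the other assemblies' mean rates.  ``None`` if an assembly is empty."""
    denom = _others_mean(report.mean_rates, report.assembly_sizes, target_assembly)
    if denom is None or denom == 0:
        return None
    return float(report.mean_rates[target_assembly] / denom)


def assembly_size_ratio(report: MetricsReport, target_assembly: int = 0) -> Optional[float]:
    """Member count of the target assembly over the mean of the others."""
    sizes = report.assembly_sizes.astype(float)
    denom = _others_mean(sizes, report.assembly_sizes, target_assembly)
    if denom is None or denom == 0:
        return None
    return float(sizes[target_assembly] / denom)


def assembly_activity_ratio(report: MetricsReport, target_assembly: int = 0) -> Optional[float]:
    """Population rate of the target assembly over the mean of the others.

    This is the probability-readout statistic: in a well-trained network
    it matches the stimulus occurrence-probability ratio.
    """
    denom = _others_mean(report.pop_rates, report.assembly_sizes, target_assembly)
    if denom is None or denom == 0:
        return None
    return float(report.pop_rates[target_assembly] / denom)


def activity_ratio_AR(r_R_pop: float, r_L_pop: float) -> float:
    """Fraction of total population activity carried by the R assembly."""
    if r_R_pop < 0 or r_L_pop < 0:
        raise ValueError("population rates must be non-negative")
    total = r_R_pop + r_L_pop
    if total == 0:
        raise ValueError("AR undefined: both population rates are zero")
    return float(r_R_pop / total)


def choices_to_right(ar: float) -> float:
    """Model 'choices to right' in percent: AR x 100."""
    return 100.0 * ar


def normalized_excitatory_incoming_weights(
    M: np.ndarray, assignment: AssemblyAssignment
) -> np.ndarray:
    """Within-assembly positive recurrent weight mass, normalized.

    For each assembly, sums the positive entries of ``M`` whose pre- and
    postsynaptic neurons both belong to it, then normalizes across
    assemblies.  In a trained network these fractions approximate the
    stimulus occurrence probabilities.
    """
    pos = np.clip(M, 0.0, None)
    sums = np.zeros(assignment.n_assemblies)
    for j in range(assignment.n_assemblies):
        idx = assignment.members(j)
        if idx.size:
            sums[j] = pos[np.ix_(idx, idx)].sum()
    total = sums.sum()
    if total == 0:
        raise ValueError("no positive within-assembly weights")
    return sums / total


def lateral_inhibition_matrix(G_path: np.ndarray, M_IE: np.ndarray) -> np.ndarray:
    """Effective inhibition between excitatory neurons through one path.

    ``G_path`` maps inhibitory activity onto excitatory neurons and
    ``M_IE`` maps excitatory activity onto inhibitory neurons; their
    product is the disynaptic E->I->E inhibition."""
    if G_path.shape[1] != M_IE.shape[0]:
        raise ValueError("shape mismatch between inhibitory path and M_IE")
    return G_path @ M_IE


def within_between_summary(
    matrix: np.ndarray, assignment: AssemblyAssignment
) -> dict[str, float]:
    """Median and quartiles of within- vs between-assembly entries."""
    labels = assignment.labels
    ok = labels != UNASSIGNED
    same = np.equal.outer(labels, labels) & np.outer(ok, ok)
    off_diag = ~np.eye(len(labels), dtype=bool)
    within = matrix[same & off_diag]
    between = matrix[(~same) & np.outer(ok, ok)]
    out = {}
    for name, vals in (("within", within), ("between", between)):
        if vals.size == 0:
            out.update({f"{name}_median": np.nan, f"{name}_q1": np.nan, f"{name}_q3": np.nan, f"{name}_mean": np.nan})
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out.update({f"{name}_median": med, f"{name}_q1": q1, f"{name}_q3": q3, f"{name}_mean": float(vals.mean())})
    return out


def pairwise_correlations(binned_counts: np.ndarray) -> np.ndarray:
    """Pearson correlations of binned spike counts between neurons.

    ``binned_counts`` is (n_bins, N); needs at least 100 bins for a
    stable estimate.  Zero-variance neurons get correlation 0 (diagonal
    stays 1).
    """
    counts = np.asarray(binned_counts, dtype=float)
    if counts.shape[0] < 100:
        raise ValueError("need at least 100 bins for correlations")
    sd = counts.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} neurons with zero variance; correlations set to 0")
    centered = counts - counts.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centered.T @ centered / counts.shape[0]
        corr = cov / np.outer(sd, sd)
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def prediction_error_trace(pred_err: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-connection-class mean |f - phi(v)| time series.

    Thin accessor over the windows accumulated by the integrator; kept as
    a function so ablation comparisons read uniformly."""
    return {k: np.asarray(v, dtype=float) for k, v in pred_err.items()}
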