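"""Experiment drivers: condition sweeps and their summary statistics.

Three families of predictions are computed over trial ensembles:

* performance and error-type fractions as a function of the tonic 5-HT
  level or of receptor-specific activation (inverted-U performance that
  splits into monotone decaying-/emergent-bump branches),
* delay-length dependence of the fraction correct,
* distractor experiments (distraction matrices and the fraction of trials
  resisting a distant distractor), and cue- vs report-aligned delay tuning
  curves with Gaussian fits.

The cue is fixed at 0 degrees: the ring is statistically homogeneous, so
the cue location is immaterial (a symmetry test backs this reduction) and
fixing it removes one source of variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

from .decoding import (C_THRESH, OUTCOMES, TrialResult, circ_dist,
                       decode_batch)
from .model_core import NetworkSpec, make_fixture_network
from .serotonin import SerotoninSpec
from .simulator import StimulusSpec, TrialProtocol, run_trials

#: distractor distances probed, degrees (0 to 180 in steps of 11.25)
DISTRACTOR_DISTANCES = np.arange(0.0, 180.1, 11.25)

#: the "distant distractor" subset (>= 90 degrees, inclusive)
DISTANT_DISTANCES = DISTRACTOR_DISTANCES[DISTRACTOR_DISTANCES >= 90.0]


@dataclass(frozen=True)
class ConditionSpec:
    """One neuromodulatory condition of a sweep.

    Exactly one axis may be manipulated: the global 5-HT concentration
    multiplier, the 5-HT1A-specific multiplier, or the 5-HT2A-specific
    multiplier (the receptor-specific ones fix the other receptor at its
    physiological activation, mimicking agonists/antagonists).
    """

    name: str = "physiological"
    mult_5ht: float = 1.0
    mult_1A: float = 1.0
    mult_2A: float = 1.0
    n_trials: int = 50
    master_seed: int = 0
    protocol: TrialProtocol = field(default_factory=TrialProtocol.standard)
    theta_s: float = 0.0
    c_thresh: float = C_THRESH

    def __post_init__(self):
        manipulated = sum(m != 1.0 for m in
                          (self.mult_5ht, self.mult_1A, self.mult_2A))
        if manipulated > 1:
            raise ValueError("exactly one manipulated axis per condition")

    def serotonin(self) -> SerotoninSpec:
        from .calibration import default_serotonin
        return default_serotonin(mult_1A=self.mult_5ht * self.mult_1A,
                                 mult_2A=self.mult_5ht * self.mult_2A)


def run_condition(cond: ConditionSpec, network: NetworkSpec | None = None, *,
                  theta_d=None, dt: float = 0.02,
                  stimulus: StimulusSpec | None = None) -> list[TrialResult]:
    """Simulate and decode all trials of one condition.

    The stimulus defaults to the calibrated task intensity (see
    :mod:`ringmem.calibration`).
    """
    if network is None:
        network = NetworkSpec.reference()
    if stimulus is None:
        if cond.protocol.has_distractor:
            # cue and distractor share the balance-calibrated intensity
            from .calibration import default_stimulus
            stimulus = default_stimulus(theta_s=cond.theta_s)
        else:
            stimulus = StimulusSpec(theta_s=cond.theta_s)
    batch = run_trials(network, cond.serotonin(), cond.protocol,
                       cond.master_seed, cond.n_trials,
                       stimulus=stimulus, theta_d=theta_d, dt=dt)
    return decode_batch(batch, c_thresh=cond.c_thresh)


def wilson_interval(k: int, n: int, alpha: float = 0.05):
    """Wilson score interval for a binomial fraction."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def performance_summary(results: list[TrialResult], alpha: float = 0.05) -> dict:
    """Outcome fractions with Wilson binomial intervals.

    The three fractions partition the ensemble and sum to one.
    """
    if not results:
        raise ValueError("empty result list")
    n = len(results)
    out = {"n": n}
    for outcome in OUTCOMES:
        k = sum(r.outcome == outcome for r in results)
        lo, hi = wilson_interval(k, n, alpha)
        key = {"correct": "correct", "decaying_bump_error": "decaying",
               "emergent_bump_error": "emergent"}[outcome]
        out[key] = k / n
        out[f"{key}_ci"] = (lo, hi)
    return out


def performance_sweep(levels=(0.8, 0.9, 1.0, 1.1, 1.2), axis: str = "5ht",
                      n_trials: int = 50, master_seed: int = 0,
                      network: NetworkSpec | None = None,
                      protocol: TrialProtocol | None = None,
                      dt: float = 0.02) -> pd.DataFrame:
    """Outcome fractions across a concentration or receptor-activation sweep.

    ``axis`` is one of "5ht", "1A", "2A"; each level manipulates only that
    axis.  Seeds are decorrelated across conditions by offsetting the
    master seed per level.
    """
    key = {"5ht": "mult_5ht", "1A": "mult_1A", "2A": "mult_2A"}[axis]
    rows = []
    for j, level in enumerate(levels):
        cond = ConditionSpec(name=f"{axis}x{level}", n_trials=n_trials,
                             master_seed=master_seed + 1000 * j,
                             protocol=protocol or TrialProtocol.standard(),
                             **{key: level})
        summ = performance_summary(run_condition(cond, network, dt=dt))
        rows.append({"axis": axis, "level": level, **_flatten_summary(summ)})
    return pd.DataFrame(rows)


def _flatten_summary(summ: dict) -> dict:
    out = {"n": summ["n"]}
    for k in ("correct", "decaying", "emergent"):
        out[k] = summ[k]
        out[f"{k}_lo"], out[f"{k}_hi"] = summ[f"{k}_ci"]
    return out


def delay_sweep(levels=(0.8, 1.0, 1.2), delays_s=(1.0, 2.0, 3.0),
                n_trials: int = 50, master_seed: int = 0,
                network: NetworkSpec | None = None,
                dt: float = 0.02) -> pd.DataFrame:
    """Fraction correct per ([5-HT] level, delay length) cell.

    High 5-HT errors are decay-driven and accumulate with delay length;
    low-5-HT (emergent-bump) errors are largely delay-independent.
    """
    rows = []
    for j, level in enumerate(levels):
        for d in delays_s:
            cond = ConditionSpec(
                name=f"5htx{level}_delay{d}", mult_5ht=level,
                n_trials=n_trials, master_seed=master_seed + 1000 * j,
                protocol=TrialProtocol.standard(delay_ms=1000.0 * d))
            summ = performance_summary(run_condition(cond, network, dt=dt))
            rows.append({"level": level, "delay_s": d, "n": n_trials,
                         "correct": summ["correct"],
                         "lo": summ["correct_ci"][0],
                         "hi": summ["correct_ci"][1]})
    return pd.DataFrame(rows)


@dataclass
class DistractionMatrix:
    """Distribution of report displacements per distractor distance.

    ``fraction[i, j]`` is the fraction of trials at distractor distance
    ``distances[j]`` whose signed report displacement theta_R - theta_S
    (positive toward the distractor) falls in displacement bin ``i``;
    columns sum to one.
    """

    distances: np.ndarray
    bin_edges: np.ndarray
    fraction: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def distraction_experiment(mult_5ht: float = 1.0, mult_1A: float = 1.0,
                           mult_2A: float = 1.0,
                           distances=DISTRACTOR_DISTANCES,
                           n_per_distance: int = 100, master_seed: int = 0,
                           network: NetworkSpec | None = None,
                           bin_width: float = 11.25, dt: float = 0.02,
                           c_thresh: float = C_THRESH):
    """Distractor-task ensemble for one serotonin condition.

    Returns ``(DistractionMatrix, distant_correct_fraction, results)`` where
    the scalar is the fraction of trials with |theta_R - theta_S| < 22.5
    degrees among distractor distances >= 90 degrees.
    """
    if network is None:
        network = NetworkSpec.reference()
    cond = ConditionSpec(name="distraction", mult_5ht=mult_5ht,
                         mult_1A=mult_1A, mult_2A=mult_2A,
                         n_trials=n_per_distance * len(distances),
                         master_seed=master_seed,
                         protocol=TrialProtocol.distractor(),
                         c_thresh=c_thresh)
    distances = np.asarray(distances, dtype=float)
    theta_d = np.repeat(distances, n_per_distance)  # on the +side of the cue
    results = run_condition(cond, network, theta_d=theta_d, dt=dt)

    matrix = displacement_matrix(results, distances, bin_width)
    distant = [r for r in results if r.theta_D >= 90.0]
    n_corr = sum(r.correct for r in distant)
    distant_fraction = n_corr / len(distant) if distant else np.nan
    return matrix, distant_fraction, results


def displacement_matrix(results: list[TrialResult], distances,
                        bin_width: float = 11.25) -> DistractionMatrix:
    """Column-normalized histogram of report displacements per distance.

    Displacement is theta_R - theta_S wrapped to [-180, 180), signed
    positive toward the distractor side (distractors sit at +theta_D).
    """
    distances = np.asarray(distances, dtype=float)
    edges = np.arange(-180.0, 180.0 + 1e-9, bin_width)
    frac = np.zeros((len(edges) - 1, len(distances)))
    for j, d in enumerate(distances):
        rs = [r for r in results if r.theta_D == d]
        disp = np.array([((r.theta_R - r.theta_S + 180.0) % 360.0) - 180.0
                         for r in rs])
        h, _ = np.histogram(np.clip(disp, edges[0], edges[-1] - 1e-9), bins=edges)
        frac[:, j] = h / max(len(rs), 1)
    return DistractionMatrix(distances, edges, frac)


def distant_distractor_fraction(network: NetworkSpec, master_seed: int,
                                n_per_distance: int,
                                distances=DISTANT_DISTANCES, *,
                                mult_5ht: float = 1.0, mult_1A: float = 1.0,
                                mult_2A: float = 1.0, dt: float = 0.02):
    """Fraction of distant-distractor trials that resist distraction.

    The headline distractibility statistic: distractor distances are spread
    uniformly over ``distances`` (default 90..180 deg in 11.25-deg steps)
    and a trial counts as correct when the decoded report stays within 22.5
    deg of the cue.  Returns ``(fraction, n, results)``.
    """
    distances = np.asarray(distances, dtype=float)
    theta_d = np.tile(distances, n_per_distance)
    cond = ConditionSpec(name="distant_distraction", mult_5ht=mult_5ht,
                         mult_1A=mult_1A, mult_2A=mult_2A,
                         n_trials=len(theta_d), master_seed=master_seed,
                         protocol=TrialProtocol.distractor())
    results = run_condition(cond, network, theta_d=theta_d, dt=dt)
    frac = sum(r.correct for r in results) / len(results)
    return frac, len(results), results


@dataclass
class TuningCurve:
    """Delay-rate tuning around the cue or report location.

    ``curve`` is the trial-averaged rate at full ring resolution as a
    function of the (circular) distance from the alignment angle;
    ``bin_means`` are 45-degree-bin averages; the Gaussian fit is
    baseline + amplitude * exp(-theta^2 / (2 width^2)).
    """

    alignment: str
    offsets: np.ndarray
    curve: np.ndarray
    bin_centers: np.ndarray
    bin_means: np.ndarray
    baseline: float
    amplitude: float
    width: float
    n_trials: int

    @property
    def sharpness(self) -> float:
        """Amplitude-to-width ratio; larger = sharper tuning."""
        return self.amplitude / self.width


def tuning_curves(results: list[TrialResult], angles_e: np.ndarray,
                  alignment: str = "cue", trial_filter: str = "all",
                  bin_width: float = 45.0) -> TuningCurve:
    """Average delay firing rates aligned to cue or report, with Gaussian fit.

    Per trial, the per-neuron delay rate vector is rotated so that the
    alignment angle (theta_S for "cue", theta_R for "report") maps to zero
    (nearest ring grid step), then averaged over trials and binned.
    """
    if alignment not in ("cue", "report"):
        raise ValueError("alignment must be 'cue' or 'report'")
    if trial_filter not in ("all", "errors_only"):
        raise ValueError("trial_filter must be 'all' or 'errors_only'")
    if trial_filter == "errors_only":
        results = [r for r in results if not r.correct]
    if len(results) < 2:
        raise ValueError("need at least 2 trials after filtering")
    n = len(angles_e)
    step = 360.0 / n
    acc = np.zeros(n)
    for r in results:
        if r.delay_rates is None:
            raise ValueError("trial results carry no delay rates")
        ref = r.theta_S if alignment == "cue" else r.theta_R
        shift = int(round(ref / step))
        acc += np.roll(r.delay_rates, -shift)
    curve = acc / len(results)
    offsets = angles_e.copy()

    # bins *centered* on multiples of bin_width (one centered at zero), so
    # an aligned peak is not split across an edge
    n_bins = int(round(360.0 / bin_width))
    centers = np.arange(n_bins) * bin_width
    centers = ((centers + 180.0) % 360.0) - 180.0
    idx = np.round(offsets / bin_width).astype(int) % n_bins
    means = np.array([curve[idx == i].mean() for i in range(n_bins)])
    order = np.argsort(centers)
    centers, means = centers[order], means[order]

    def gauss(th, base, amp, w):
        return base + amp * np.exp(-th**2 / (2.0 * w**2))

    # minimum width of a quarter bin: narrower peaks are unresolvable and
    # would let the fit chase single-bin noise
    p0 = (float(means.min()), float(means.max() - means.min()), 30.0)
    try:
        popt, _ = curve_fit(gauss, centers, means, p0=p0,
                            bounds=([-np.inf, -np.inf, bin_width / 4.0],
                                    [np.inf, np.inf, 180.0]), maxfev=10000)
        base, amp, w = popt
    except RuntimeError:  # flat data: fall back to the initial guess shape
        base, amp, w = means.mean(), 0.0, 180.0
    return TuningCurve(alignment=alignment, offsets=offsets, curve=curve,
                       bin_centers=centers, bin_means=means,
                       baseline=float(base), amplitude=float(amp),
                       width=float(abs(w)), n_trials=len(results))
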