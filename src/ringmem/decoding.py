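"""Behavioral read-out: population-vector decoding and outcome taxonomy.

The report angle theta_R is the argument of the normalized population vector
P = (sum_i n_i e^{i theta_i}) / (sum_i n_i) computed from excitatory spike
counts in the 50 ms window closing the delay; its modulus C in [0, 1]
measures how coherent (bump-like) the late-delay activity is.

Trials are correct when the circular distance |theta_R - theta_S| is below
22.5 degrees.  Errors split by phenotype: a *decaying-bump* error has no
coherent end-of-delay signal (C below threshold; the report is effectively
random), while an *emergent-bump* error carries a confident but misaligned
bump (C above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

#: half-width of the correct-response window, degrees
RESPONSE_WINDOW = 22.5

#: default modulus threshold separating the two error phenotypes; calibrated
#: so fixation-period windows (no bump) fall below and correct end-of-delay
#: windows fall above (see the classifier calibration test).
C_THRESH = 0.3

#: Rayleigh-coherence floor, in units of N*C**2 (N = spikes in the decode
#: window).  The modulus of a window holding only a handful of spikes is
#: biased upward (E[C] ~ 1/sqrt(N) under uniformity), so a bare modulus
#: threshold would mislabel near-silent windows as coherent bumps; under the
#: uniform null N*C**2 is ~Exp(1), so a floor of 6 keeps the false-coherence
#: rate below 0.3% at any spike count.
Z_THRESH = 6.0

OUTCOMES = ("correct", "decaying_bump_error", "emergent_bump_error")


def circ_dist(a, b):
    """Absolute circular distance in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


class PopulationVector(NamedTuple):
    theta_R: float  # degrees; meaningless when flagged
    modulus: float  # in [0, 1]
    flagged: bool  # all-zero counts or exact cancellation
    n_spikes: float = 0.0  # total count in the window


def population_vector(counts, angles_deg) -> PopulationVector:
    """Decode (theta_R, C) from per-neuron spike counts on the ring.

    All-zero counts (or an exactly cancelling pattern) leave the angle
    undefined; such windows are returned flagged and resolved to a random
    report at the outcome layer.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return PopulationVector(np.nan, 0.0, True, 0.0)
    z = np.sum(counts * np.exp(1j * np.deg2rad(angles_deg))) / total
    C = float(np.abs(z))
    if C < 1e-12:
        return PopulationVector(np.nan, 0.0, True, float(total))
    return PopulationVector(float(np.rad2deg(np.angle(z))), C, False, float(total))


def is_coherent(pv: PopulationVector, c_thresh: float = C_THRESH,
                z_thresh: float = Z_THRESH) -> bool:
    """Whether a decode window holds a genuine bump.

    Requires both a large modulus and a Rayleigh statistic N*C**2 above the
    uniform-null floor, so sparse windows are not mistaken for bumps.
    """
    if pv.flagged:
        return False
    return (pv.modulus >= c_thresh
            and pv.n_spikes * pv.modulus**2 >= z_thresh)


def classify_outcome(pv: PopulationVector, theta_S: float,
                     c_thresh: float = C_THRESH,
                     rng: np.random.Generator | None = None,
                     z_thresh: float = Z_THRESH):
    """Label one trial and resolve flagged (signal-free) reports.

    Returns ``(outcome, theta_R)``.  A flagged window has no decodable
    signal: the report is drawn uniformly at random and — carrying no bump —
    the trial counts as a decaying-bump error unless the draw happens to
    fall inside the response window.
    """
    if pv.flagged:
        if rng is None:
            rng = np.random.default_rng(0)
        theta_R = float(rng.uniform(-180.0, 180.0))
    else:
        theta_R = pv.theta_R
    if circ_dist(theta_R, theta_S) < RESPONSE_WINDOW:
        return "correct", theta_R
    if is_coherent(pv, c_thresh, z_thresh):
        return "emergent_bump_error", theta_R
    return "decaying_bump_error", theta_R


def delay_rates(counts, window_ms: float) -> np.ndarray:
    """Per-neuron firing rate (Hz) from spike counts in a window."""
    if window_ms <= 0:
        raise ValueError("window must have positive duration")
    return np.asarray(counts, dtype=float) / (window_ms * 1e-3)


def delay_rates_from_raster(raster, t0: float, t1: float, n_neurons: int) -> np.ndarray:
    """Per-neuron excitatory rates (Hz) in the window (t0, t1]."""
    if t1 <= t0:
        raise ValueError("empty rate window")
    times, idx = raster.select("E", t0, t1)
    counts = np.bincount(idx, minlength=n_neurons)
    return delay_rates(counts, t1 - t0)


@dataclass
class TrialResult:
    """One decoded trial."""

    trial_index: int
    theta_S: float
    theta_D: float | None
    theta_R: float
    modulus_C: float
    precue_modulus: float
    outcome: str
    delay_rates: np.ndarray | None = None
    flagged: bool = False

    @property
    def correct(self) -> bool:
        return self.outcome == "correct"


def decode_batch(batch, c_thresh: float = C_THRESH,
                 keep_delay_rates: bool = True) -> list[TrialResult]:
    """Decode every trial of a simulated batch into TrialResult records.

    The uniform-report fallback for signal-free windows uses a stream
    derived from the trial's own seed, keeping the whole pipeline
    reproducible.
    """
    out = []
    for b, ti in enumerate(batch.trial_indices):
        pv = population_vector(batch.decode_counts[b], batch.angles_e)
        rng = np.random.default_rng(
            np.random.SeedSequence((batch.master_seed, int(ti), 7)))
        outcome, theta_R = classify_outcome(pv, batch.theta_s, c_thresh, rng)
        pre = population_vector(batch.precue_counts[b], batch.angles_e)
        rates = None
        if keep_delay_rates:
            rates = delay_rates(batch.delay_counts[b], batch.delay_duration)
        out.append(TrialResult(
            trial_index=int(ti), theta_S=batch.theta_s,
            theta_D=None if batch.theta_d is None else float(batch.theta_d[b]),
            theta_R=theta_R, modulus_C=pv.modulus,
            precue_modulus=0.0 if pre.flagged else pre.modulus,
            outcome=outcome, delay_rates=rates, flagged=pv.flagged))
    return out
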