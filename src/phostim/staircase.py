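"""Three-step phosphene-threshold staircase over a simulated observer.

The protocol estimates the lowest stimulation amplitude (µA) at which an
observer reliably reports phosphenes, on a 25 µA grid:

1. ascending search, 50 µA steps from 50 to 500 µA, first detection is the
   reference;
2. refinement at reference −25/+25/+50 µA, each presented twice; the lowest
   intensity detected on both presentations carries forward;
3. final bracket at refined −25/0/+25 µA, three 16 Hz presentations each in
   randomized order plus one 5 Hz catch burst per intensity (logged, never
   counted); the threshold is the lowest intensity detected in ≥ 2 of 3.

An observer is a psychometric model: true threshold θ (µA), spread s (µA,
0 = deterministic step function), lapse and false-positive rates, and a
frequency gate that multiplies detection probability at the 5 Hz control
frequency (0 by default: genuine phosphenes are frequency-tuned).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ObserverModel",
    "Trial",
    "ThresholdRecord",
    "respond",
    "step1_ascending",
    "step2_refine",
    "step3_final",
    "run_protocol",
    "PT_FLOOR_UA",
    "STEP1_INTENSITIES_UA",
]

STEP1_INTENSITIES_UA = tuple(range(50, 501, 50))
STEP_GRID_UA = 25
PT_FLOOR_UA = 50
STIM_FREQ_HZ = 16
CATCH_FREQ_HZ = 5


@dataclass
class ObserverModel:
    """Psychometric observer for one subject × montage condition."""

    threshold_uA: float
    slope_uA: float = 0.0
    lapse_rate: float = 0.0
    false_positive_rate: float = 0.0
    gate_5hz: float = 0.0

    def __post_init__(self):
        if not self.threshold_uA > 0:
            raise ValueError("threshold must be positive")
        if self.slope_uA < 0:
            raise ValueError("slope must be >= 0")
        for name in ("lapse_rate", "false_positive_rate", "gate_5hz"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def detection_probability(self, intensity_uA: float, frequency_hz: float) -> float:
        if self.slope_uA == 0:
            psi = 1.0 if intensity_uA >= self.threshold_uA else 0.0
        else:
            psi = float(ndtr((intensity_uA - self.threshold_uA) / self.slope_uA))
        p = (1.0 - self.lapse_rate) * psi + self.false_positive_rate * (1.0 - psi)
        gate = 1.0 if frequency_hz == STIM_FREQ_HZ else self.gate_5hz
        return gate * p


@dataclass
class Trial:
    intensity_uA: float
    frequency_hz: float
    step: int
    response: bool

    def __post_init__(self):
        if self.intensity_uA % STEP_GRID_UA != 0:
            raise ValueError("intensities lie on the 25 µA grid")
        if self.step == 1 and self.intensity_uA % 50 != 0:
            raise ValueError("step-1 intensities lie on the 50 µA grid")


@dataclass
class ThresholdRecord:
    subject: str
    montage: str
    pt_uA: float | None
    trials: list[Trial] = field(default_factory=list)
    valid: bool = True
    reason: str = ""


def respond(observer: ObserverModel, intensity_uA: float, frequency_hz: float,
            rng: np.random.Generator) -> bool:
    """One burst: Bernoulli draw from the observer's detection probability.

    The random draw is consumed even for degenerate probabilities so trial
    sequences stay aligned across observers sharing an RNG stream.
    """
    p = observer.detection_probability(intensity_uA, frequency_hz)
    return bool(rng.random() < p)


def step1_ascending(observer: ObserverModel, rng: np.random.Generator,
                    log: list[Trial] | None = None):
    """Ascend 50..500 µA in 50 µA steps; return the first detected intensity."""
    for intensity in STEP1_INTENSITIES_UA:
        det = respond(observer, intensity, STIM_FREQ_HZ, rng)
        if log is not None:
            log.append(Trial(intensity, STIM_FREQ_HZ, 1, det))
        if det:
            return intensity
    return None


def step2_refine(observer: ObserverModel, reference_uA: float,
                 rng: np.random.Generator, log: list[Trial] | None = None):
    """Test ref−25/+25/+50 twice each; lowest intensity detected both times.

    Falls back to the reference itself if nothing is detected twice (a branch
    the protocol description leaves open).
    """
    offsets = (-25, 25, 50)
    detected_twice = []
    for off in offsets:
        intensity = reference_uA + off
        if intensity < STEP_GRID_UA:
            continue
        hits = 0
        for _ in range(2):
            det = respond(observer, intensity, STIM_FREQ_HZ, rng)
            if log is not None:
                log.append(Trial(intensity, STIM_FREQ_HZ, 2, det))
            hits += det
        if hits == 2:
            detected_twice.append(intensity)
    if detected_twice:
        return min(detected_twice), True
    return reference_uA, False


def step3_final(observer: ObserverModel, refined_uA: float,
                rng: np.random.Generator, log: list[Trial] | None = None):
    """Randomized 3×3 bracket around the refined value, plus 5 Hz catches.

    Returns ``(pt_uA, qualified)``: the lowest intensity with ≥ 2/3
    detections at 16 Hz, or ``(refined + 25, False)`` if none qualifies.
    Catch bursts are logged but never counted toward the rule.
    """
    intensities = [refined_uA - 25, refined_uA, refined_uA + 25]
    intensities = [i for i in intensities if i >= STEP_GRID_UA]
    bursts = [(i, STIM_FREQ_HZ) for i in intensities for _ in range(3)]
    bursts += [(i, CATCH_FREQ_HZ) for i in intensities]
    order = rng.permutation(len(bursts))
    hits: dict[float, int] = {i: 0 for i in intensities}
    for k in order:
        intensity, freq = bursts[k]
        det = respond(observer, intensity, freq, rng)
        if log is not None:
            log.append(Trial(intensity, freq, 3, det))
        if freq == STIM_FREQ_HZ and det:
            hits[intensity] += 1
    qualifying = [i for i in intensities if hits[i] >= 2]
    if qualifying:
        return min(qualifying), True
    return refined_uA + 25, False


def run_protocol(observer: ObserverModel, rng: np.random.Generator,
                 subject: str = "s0", montage: str = "") -> ThresholdRecord:
    """Chain steps 1–3 with a full trial log."""
    log: list[Trial] = []
    ref = step1_ascending(observer, rng, log)
    if ref is None:
        return ThresholdRecord(
            subject, montage, None, log, valid=False,
            reason="no detection up to 500 µA in step 1",
        )
    refined, ok2 = step2_refine(observer, ref, rng, log)
    pt, ok3 = step3_final(observer, refined, rng, log)
    pt = max(pt, PT_FLOOR_UA)
    valid = ok3
    reason = "" if valid else "no intensity reached 2/3 detections in step 3"
    if not ok2:
        reason = (reason + "; " if reason else "") + "step 2 fell back to reference"
    return ThresholdRecord(subject, montage, float(pt), log, valid, reason)
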