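"""Synthetic observer cohorts and packaged reference tables.

Cohorts emulate the study population: per-subject phosphene thresholds on
the scale the threshold experiment reported (e.g. mean 95 µA, SD 33 µA for
the F7-F8 montage), measured through the 25 µA staircase grid.  Two modes:

* **direct** — per-montage thresholds drawn independently from stated
  Normal(mean, SD) distributions, truncated to [30, 450] µA so every true
  threshold is inside the protocol's dynamic range;
* **coupled** — one retinal current-density threshold per subject; the
  per-montage µA threshold is that density divided by the montage's
  simulated retinal coupling c_m (mA/m² per mA), so montages that deliver
  more current to the retina get lower thresholds by construction.

The packaged fixture tables transcribe the printed reference values
(threshold summaries and simulated current densities per montage) and are
checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .staircase import ObserverModel, ThresholdRecord, run_protocol

__all__ = [
    "CohortSpec",
    "FixtureTables",
    "TRUNCATION_UA",
    "generate_cohort",
    "simulate_study",
    "load_fixtures",
    "STANDARD_MONTAGE_ORDER",
]

TRUNCATION_UA = (30.0, 450.0)

STANDARD_MONTAGE_ORDER = (
    "Fp2-So", "F7-F8", "So-rS", "Cz-F8", "Fp2-rS", "Fp2-Cz", "Fp2-O2",
)

_FIXTURE_SHA256 = {
    "table1_pt_eye_density.csv":
        "b55bd27c6c6e8f09b3b15a4eb386423afb3b0a652b8f97e0251df45aa52ec982",
    "table2_visual_pathway.csv":
        "2055b94305ac3b8a10136a041503d123056feb859d303a17abec054d9e453d9c",
    "fig4_unilateral_densities.csv":
        "0b2a3da6141b3af28b2da7eb7ff5360125197c4a3017d374752fda73d57334e5",
}


@dataclass
class CohortSpec:
    """Study-condition parameters for a synthetic cohort."""

    n_subjects: int = 15
    montages: tuple[str, ...] = STANDARD_MONTAGE_ORDER
    mode: str = "direct"
    # direct mode: montage -> (mean, SD) in µA; defaults to the fixture table
    pt_distributions_uA: dict[str, tuple[float, float]] | None = None
    # coupled mode: density threshold distribution scale, relative to the
    # reference montage's µA distribution (see generate_cohort)
    reference_montage: str = "F7-F8"
    reference_mean_uA: float = 95.0
    reference_sd_uA: float = 33.0
    slope_uA: float = 0.0
    lapse_rate: float = 0.0
    false_positive_rate: float = 0.0
    truncation_uA: tuple[float, float] = TRUNCATION_UA
    eye_dominance_effect_uA: float = 0.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        lo, hi = self.truncation_uA
        if lo >= hi:
            raise ValueError("truncation bounds inverted")
        if self.mode not in ("direct", "coupled"):
            raise ValueError(f"unknown cohort mode {self.mode!r}")


@dataclass
class Cohort:
    spec: CohortSpec
    observers: dict[tuple[int, str], ObserverModel]
    eye_dominance: list[str] = field(default_factory=list)
    density_thresholds: np.ndarray | None = None  # coupled mode only


def _truncnorm(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec,
    rng: np.random.Generator,
    coupling: dict[str, float] | None = None,
) -> Cohort:
    """Draw per-subject, per-montage observers.

    In coupled mode ``coupling`` maps montage -> c_m (mean retinal |J| in
    mA/m² per mA injected).  The subject's retinal density threshold is
    drawn so that the reference montage's µA thresholds follow its stated
    Normal(mean, SD); other montages inherit θ = density / c_m, reversing
    the coupling order by construction.
    """
    lo, hi = spec.truncation_uA
    dominance = list(rng.choice(["right", "left"], size=spec.n_subjects))
    observers: dict[tuple[int, str], ObserverModel] = {}
    density = None

    def make(theta):
        return ObserverModel(
            threshold_uA=float(theta),
            slope_uA=spec.slope_uA,
            lapse_rate=spec.lapse_rate,
            false_positive_rate=spec.false_positive_rate,
        )

    if spec.mode == "direct":
        dists = spec.pt_distributions_uA
        if dists is None:
            t1 = load_fixtures().table1.set_index("montage")
            dists = {
                m: (float(t1.loc[m, "mean_pt_uA"]), float(t1.loc[m, "sd_pt_uA"]))
                for m in spec.montages
            }
        for m in spec.montages:
            mean, sd = dists[m]
            thetas = _truncnorm(mean, sd, lo, hi, spec.n_subjects, rng)
            for s, th in enumerate(thetas):
                th = th + _dominance_shift(spec, dominance[s])
                observers[(s, m)] = make(np.clip(th, lo, hi))
    else:
        if coupling is None:
            raise ValueError("coupled mode needs a montage -> c_m coupling table")
        missing = [m for m in spec.montages if m not in coupling]
        if missing:
            raise ValueError(f"coupling table lacks montages {missing}")
        if any(coupling[m] <= 0 for m in spec.montages):
            raise ValueError("couplings must be positive")
        c_ref = coupling[spec.reference_montage]
        density = _truncnorm(
            spec.reference_mean_uA * c_ref,
            spec.reference_sd_uA * c_ref,
            lo * c_ref,
            hi * c_ref,
            spec.n_subjects,
            rng,
        )
        for s in range(spec.n_subjects):
            for m in spec.montages:
                th = density[s] / coupling[m] + _dominance_shift(spec, dominance[s])
                observers[(s, m)] = make(max(th, 1.0))
    return Cohort(spec, observers, dominance, density)


def _dominance_shift(spec: CohortSpec, dominance: str) -> float:
    if spec.eye_dominance_effect_uA == 0.0:
        return 0.0
    sign = -0.5 if dominance == "right" else 0.5
    return sign * spec.eye_dominance_effect_uA


def simulate_study(cohort: Cohort, rng: np.random.Generator) -> pd.DataFrame:
    """Run the three-step protocol for every subject × montage.

    Montage order is permuted per subject (logged in the ``order`` column);
    each subject × montage gets its own RNG substream derived from the master
    generator, so the montage order cannot leak into step responses.
    """
    spec = cohort.spec
    rows = []
    for s in range(spec.n_subjects):
        order = rng.permutation(len(spec.montages))
        streams = {
            m: np.random.Generator(np.random.PCG64(int(rng.integers(2**31))))
            for m in spec.montages
        }
        for pos, mi in enumerate(order):
            m = spec.montages[mi]
            rec: ThresholdRecord = run_protocol(
                cohort.observers[(s, m)], streams[m],
                subject=f"s{s:03d}", montage=m,
            )
            rows.append(
                {
                    "subject": f"s{s:03d}",
                    "montage": m,
                    "order": pos,
                    "pt_uA": rec.pt_uA,
                    "valid": rec.valid,
                    "n_trials": len(rec.trials),
                    "eye_dominance": cohort.eye_dominance[s],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FixtureTables:
    """Transcribed reference tables (checksummed on load)."""

    table1: pd.DataFrame  # montage, median/mean/SD PT, eye densities per model
    table2: pd.DataFrame  # montage, median PT, LGN and OC densities
    fig4_densities: pd.DataFrame  # five unilateral eye-model densities

    def model_difference(self) -> pd.Series:
        """Eye-model minus brain-model right-eye density per montage (mA/m²)."""
        t = self.table1.set_index("montage")
        return (t["eye_density_eye_model"] - t["eye_density_brain_model"]).round(10)


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("phostim.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if digest != expected:
        raise ValueError(
            f"fixture {name!r} failed its checksum: expected {expected}, "
            f"got {digest}; the packaged transcription has been altered"
        )
    return pd.read_csv(io.BytesIO(raw), comment="#")


def load_fixtures() -> FixtureTables:
    return FixtureTables(
        table1=_read_fixture("table1_pt_eye_density.csv"),
        table2=_read_fixture("table2_visual_pathway.csv"),
        fig4_densities=_read_fixture("fig4_unilateral_densities.csv"),
    )
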