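"""Synthetic sparse pediatric TDM cohorts.

The generator emulates the statistical structure of a prospective
pediatric cetirizine cohort: ~63 children aged 0.5-14 y on age-banded
label regimens, a configurable fraction escalated to off-label doses
within a two-fold range, twice/once-daily dosing maintained beyond 144 h
(steady state), and 1-3 sparse concentration samples per child with
lognormal inter-individual variability and proportional residual error.

It is a stand-in for undeposited clinical data: real features it does not
emulate (adherence gaps, assay quantification limits, covariate
correlations beyond a weight-age rule of thumb) are listed in
docs/methods.md.  The true subject-level random effects are carried in the
dataset metadata so that estimation can be checked by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import Dataset, Observation, Subject
from .model import Covariates, DoseEvent, PopulationParameters
from .reference import LABEL_DOSE_BANDS, default_parameters

__all__ = ["CohortConfig", "generate_cohort", "truth_report"]


@dataclass
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults mirror the emulated study: 63 children, ages spanning the
    label bands, 24/63 on off-label doses within a two-fold range, at most
    three samples per child taken at steady state.
    """

    n_subjects: int = 63
    age_range: tuple[float, float] = (0.5, 14.0)
    female_fraction: float = 25 / 63
    weight_slope: float = 2.0  # kg per year
    weight_intercept: float = 8.0  # kg
    weight_cv: float = 0.15  # lognormal noise on weight
    dose_bands: tuple = LABEL_DOSE_BANDS
    #: relative occupancy of the age bands (emulated cohort: 10/22/33);
    #: ages are log-uniform within the selected band
    band_weights: tuple = (10, 22, 33)
    #: probability of an off-label (escalated) dose, per band (emulated
    #: cohort: 5/10, 17/22, 2/33) or a single float applied to every band
    offlabel_fraction: tuple | float = (5 / 10, 17 / 22, 2 / 33)
    dose_multiplier_range: tuple[float, float] = (1.0, 2.0)
    samples_per_subject: dict = field(default_factory=lambda: {1: 1 / 3, 2: 1 / 3, 3: 1 / 3})
    tad_window: tuple[float, float] = (1.0, 24.0)
    min_treatment_h: float = 144.0
    true_params: PopulationParameters | None = None  # None -> package defaults
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.dose_bands:
            raise ValueError("dose_bands must not be empty")
        if isinstance(self.offlabel_fraction, (int, float)):
            self.offlabel_fraction = (float(self.offlabel_fraction),) * len(self.dose_bands)
        if len(self.offlabel_fraction) != len(self.dose_bands):
            raise ValueError("offlabel_fraction must match the number of dose bands")
        if len(self.band_weights) != len(self.dose_bands):
            raise ValueError("band_weights must match the number of dose bands")
        fracs = (*self.offlabel_fraction, self.female_fraction)
        if not all(0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.dose_multiplier_range
        if not (1.0 <= lo <= hi):
            raise ValueError("dose multipliers must be >= 1 and ordered")


def generate_cohort(config: CohortConfig) -> Dataset:
    """Draw a synthetic cohort and simulate its sparse concentration data.

    An age band is drawn by occupancy weight, the age log-uniform within
    the band (clipped to the configured range); weight follows an
    affine-in-age rule with lognormal noise; the regimen is the age-band
    label dose, escalated by an off-label factor with the band's
    off-label probability; dosing runs to at least ``min_treatment_h``.
    Observations are drawn at 1-24 h after the final dose; concentrations
    include the true IIV draw and proportional/additive residual error.
    """
    from .estimation import subject_predictions  # local import avoids cycle at init

    pop = config.true_params if config.true_params is not None else default_parameters()
    rng = np.random.default_rng(config.seed)
    lo_a, hi_a = config.age_range

    # bands clipped to the age range, with their occupancy weights
    bands = []
    for (blo, bhi, dose, tau), w, f_off in zip(
        config.dose_bands, config.band_weights, config.offlabel_fraction
    ):
        clo, chi = max(blo, lo_a), min(bhi, hi_a)
        if clo < chi and w > 0:
            bands.append((clo, chi, dose, tau, float(w), f_off))
    if not bands:
        raise ValueError("no dose band overlaps the configured age range")
    weights = np.array([b[4] for b in bands])
    weights = weights / weights.sum()

    counts = sorted(config.samples_per_subject)
    probs = np.array([config.samples_per_subject[c] for c in counts], dtype=float)
    probs = probs / probs.sum()

    subjects = []
    truth_rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        b = bands[int(rng.choice(len(bands), p=weights))]
        blo, bhi, label_dose, tau, _, f_off = b
        age = float(np.exp(rng.uniform(math.log(blo), math.log(bhi))))
        sex = "female" if rng.random() < config.female_fraction else "male"
        weight = (config.weight_intercept + config.weight_slope * age) * float(
            rng.lognormal(0.0, config.weight_cv)
        )
        height = 75.0 + 6.0 * age  # descriptive only
        cov = Covariates(age=age, sex=sex, weight=weight, height=height)

        offlabel = rng.random() < f_off
        mult = float(rng.uniform(*config.dose_multiplier_range)) if offlabel else 1.0
        dose = label_dose * mult

        n_dose = int(math.ceil(config.min_treatment_h / tau)) + 1
        doses = [DoseEvent(j * tau, dose) for j in range(n_dose)]
        last_dose_t = doses[-1].time

        n_samp = int(rng.choice(counts, p=probs))
        tads = np.sort(rng.uniform(*config.tad_window, size=n_samp))

        eta_cl = float(rng.normal(0.0, math.sqrt(pop.omega2_cl)))
        eta_v = float(rng.normal(0.0, math.sqrt(pop.omega2_v)))

        stub = Subject(
            sid, cov, doses,
            [Observation(last_dose_t + tad, 0.0, tad) for tad in tads],
        )
        f = subject_predictions(pop, stub, np.array([eta_cl, eta_v]))
        eps1 = rng.normal(0.0, math.sqrt(pop.sigma2_prop), size=n_samp)
        eps2 = rng.normal(0.0, math.sqrt(pop.sigma2_add), size=n_samp) if pop.sigma2_add > 0 else 0.0
        dv = f * (1.0 + eps1) + eps2

        obs = [
            Observation(last_dose_t + tad, float(dvj), float(tad))
            for tad, dvj in zip(tads, dv)
        ]
        subjects.append(Subject(sid, cov, doses, obs))
        truth_rows.append(
            dict(
                id=sid, age=age, sex=sex, weight=weight, dose=dose, tau=tau,
                offlabel=offlabel, eta_cl=eta_cl, eta_v=eta_v,
                cl=pop.tvcl
                * (1 + pop.cl_age * (age - pop.age_ref))
                * (1 + (pop.cl_sex if sex == "female" else 0.0))
                * math.exp(eta_cl),
                v=pop.tvv * (1 + pop.v_age * (age - pop.age_ref)) * math.exp(eta_v),
            )
        )

    return Dataset(
        subjects=subjects,
        metadata={
            "synthetic": True,
            "seed": config.seed,
            "config": config,
            "true_params": pop,
            "truth": pd.DataFrame(truth_rows).set_index("id"),
        },
    )


def truth_report(dataset: Dataset) -> pd.DataFrame:
    """Per-subject true random effects and parameters of a synthetic cohort.

    Refuses on datasets without truth metadata (e.g. imported real data).
    """
    if not dataset.metadata.get("synthetic") or "truth" not in dataset.metadata:
        raise ValueError("no truth available: dataset is not a synthetic cohort")
    return dataset.metadata["truth"].copy()
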