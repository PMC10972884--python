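"""Worked clinical examples bundled with the package."""

from __future__ import annotations

from .estimation import Observation, Subject
from .model import Covariates, DoseEvent, Regimen

__all__ = ["overdose_case_subject"]


def overdose_case_subject() -> tuple[Subject, Regimen]:
    """The medication-error case: a 5-year-old boy on 5 mg bid.

    After the first 5 mg dose, a single 30 mg dose (1.5 mg/kg) was given
    in error 12 h later and the schedule stopped.  A TDM sample 2.5 h
    after the error dose measured 1725 ug/L.  Returns the subject (dosing
    history with the error dose flagged, plus the TDM observation) and the
    intended reference regimen.
    """
    cov = Covariates(age=5.0, sex="male", weight=20.0)
    doses = [
        DoseEvent(0.0, 5.0),
        DoseEvent(12.0, 30.0, is_error_dose=True),
    ]
    obs = [Observation(time=14.5, dv=1725.0, tad=2.5)]
    return Subject("overdose-case", cov, doses, obs), Regimen(dose=5.0, interval=12.0)
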