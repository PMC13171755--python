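"""Synthetic multi-study observation tables with known ground truth.

Digitized literature time courses are not redistributable, so the
calibration, profiling and heterogeneity machinery is exercised on
simulated studies that emulate the structure of the real calibration
sources: sparse sampling days concentrated in the first weeks after
immunization with late follow-up, four observed ASC tissues, a small number
of replicate animals per time point summarized as mean ± SE, multiplicative
(lognormal) measurement noise, and between-study heterogeneity carried by
the bone-marrow niche capacity ``Vmax``.

What the generator does **not** emulate: digitization error, per-study
sampling-schedule differences, and systematic assay biases.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .antigen import AntigenSchedule
from .model import simulate
from .observables import TISSUE_STATE
from .parameters import ParameterSet

__all__ = ["StudyDesign", "generate_observations", "generate_multistudy"]

#: Sampling days emulating the sparse schedules of the calibration sources.
DEFAULT_DAYS = (7.0, 14.0, 21.0, 28.0, 42.0, 60.0, 100.0, 200.0)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule and noise model of one synthetic study."""

    days: tuple = DEFAULT_DAYS
    tissues: tuple = ("spleen", "lymph_nodes", "bone_marrow", "blood")
    noise: str = "lognormal"  # or "additive"
    cv: float = 0.3  # noise magnitude (CV for lognormal, SD/mean additive)
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 <= d <= 350 for d in self.days):
            raise ValueError("sampling days must lie within [0, 350]")
        if self.cv <= 0:
            raise ValueError("noise magnitude must be positive")
        if self.noise not in ("lognormal", "additive"):
            raise ValueError("noise must be 'lognormal' or 'additive'")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per point")


def generate_observations(
    true_params: ParameterSet,
    schedule: AntigenSchedule,
    design: StudyDesign,
    study_id: str = "synthetic-1",
) -> tuple[pd.DataFrame, dict]:
    """Simulate one study and sample noisy observations.

    Per design day and tissue, ``n_replicates`` noisy animal-level values are
    drawn around the model prediction; the table reports their mean and
    standard error.  Returns (observation table, ground-truth record).
    """
    rng = np.random.default_rng(design.seed)
    days = np.asarray(sorted(design.days), dtype=float)
    t_eval = days if days[0] == 0 else np.concatenate([[0.0], days])
    traj = simulate(true_params, schedule, t_eval=t_eval)
    offset = len(t_eval) - len(days)

    if design.noise == "lognormal":
        # mean-1 lognormal multiplier with the requested CV
        sig2 = np.log(1.0 + design.cv**2)
        mu = -0.5 * sig2
    rows = []
    for tissue in design.tissues:
        y = traj[TISSUE_STATE[tissue]][offset:]
        for d, mean_pred in zip(days, y):
            if design.noise == "lognormal":
                reps = mean_pred * rng.lognormal(
                    mu, np.sqrt(sig2), size=design.n_replicates
                )
            else:
                reps = mean_pred + rng.normal(
                    0.0, design.cv * mean_pred, size=design.n_replicates
                )
                reps = np.maximum(reps, 0.0)
            value = float(np.mean(reps))
            se = (
                float(np.std(reps, ddof=1) / np.sqrt(design.n_replicates))
                if design.n_replicates > 1
                else np.nan
            )
            rows.append(
                {
                    "study": study_id,
                    "tissue": tissue,
                    "day": d,
                    "value": value,
                    "error": se,
                    "scaled": True,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "study": study_id,
        "parameters": true_params.as_dict(),
        "schedule": schedule.as_dict(),
        "design": asdict(design),
    }
    return table, truth


def generate_multistudy(
    vmax_values,
    shared_params: ParameterSet,
    schedule: AntigenSchedule,
    design: StudyDesign,
) -> tuple[list[pd.DataFrame], list[dict]]:
    """One synthetic study per Vmax value; everything else shared.

    Emulates between-study heterogeneity in bone-marrow niche capacity.
    Study seeds are derived from the design seed so studies are independent
    but jointly reproducible.
    """
    vmax_values = list(vmax_values)
    if any(v <= 0 for v in vmax_values):
        raise ValueError("all Vmax values must be positive")
    tables, truths = [], []
    for i, vmax in enumerate(vmax_values):
        params_i = shared_params.with_updates(Vmax=float(vmax))
        design_i = StudyDesign(
            days=design.days,
            tissues=design.tissues,
            noise=design.noise,
            cv=design.cv,
            n_replicates=design.n_replicates,
            seed=design.seed + i,
        )
        table, truth = generate_observations(
            params_i, schedule, design_i, study_id=f"synthetic-{i + 1}"
        )
        tables.append(table)
        truths.append(truth)
    return tables, truths
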