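"""Mapping model states to reported quantities, and goodness-of-fit metrics.

Experimental ASC counts are reported per tissue sample (two femurs, a single
lymph node); :func:`apply_tissue_scaling` converts them to whole-animal
counts using the standard anatomical factors (femur-derived marrow is 12.7%
of total marrow → ×7.9; a mouse has 22 lymph nodes → ×22).  IgG time courses
from different studies are made comparable by per-study max-normalization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Trajectory

__all__ = [
    "TISSUES",
    "TISSUE_STATE",
    "ScalingConventions",
    "apply_tissue_scaling",
    "invert_tissue_scaling",
    "peak_summary",
    "normalize_to_max",
    "gof_stats",
    "read_observations",
    "write_observations",
]

TISSUES = ("spleen", "lymph_nodes", "bone_marrow", "blood", "igg")

#: Model state observed in each tissue.
TISSUE_STATE = {
    "spleen": "ASCSpleen",
    "lymph_nodes": "ASCLN",
    "bone_marrow": "ASCBone",
    "blood": "ASCBlood",
    "igg": "IgGBlood",
}

_OBS_COLUMNS = ["study", "tissue", "day", "value", "error", "scaled"]


@dataclass(frozen=True)
class ScalingConventions:
    """Sample-to-whole-animal conversion factors."""

    femur_factor: float = 7.9  # two-femur marrow counts -> whole marrow
    ln_count: float = 22.0  # single lymph node -> all nodes

    def __post_init__(self) -> None:
        if self.femur_factor <= 0 or self.ln_count <= 0:
            raise ValueError("scaling factors must be positive")


def apply_tissue_scaling(
    raw, tissue: str, conventions: ScalingConventions | None = None
):
    """Convert a per-sample measurement to a whole-animal count."""
    conventions = conventions or ScalingConventions()
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw values must be non-negative")
    if tissue == "bone_marrow":
        out = raw * conventions.femur_factor
    elif tissue == "lymph_nodes":
        out = raw * conventions.ln_count
    else:
        out = raw * 1.0
    return out if out.ndim else float(out)


def invert_tissue_scaling(
    scaled, tissue: str, conventions: ScalingConventions | None = None
):
    """Inverse of :func:`apply_tissue_scaling` (whole animal → sample)."""
    conventions = conventions or ScalingConventions()
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    scaled = np.asarray(scaled, dtype=float)
    if tissue == "bone_marrow":
        out = scaled / conventions.femur_factor
    elif tissue == "lymph_nodes":
        out = scaled / conventions.ln_count
    else:
        out = scaled * 1.0
    return out if out.ndim else float(out)


def peak_summary(traj: Trajectory, state: str) -> tuple[float, float]:
    """(Cmax, Tmax) of one state; Tmax is the earliest grid time at the max."""
    y = traj[state]
    if len(y) == 0:
        raise ValueError("empty trajectory")
    i = int(np.argmax(y))  # argmax returns the first maximizer: earliest time
    return float(y[i]), float(traj.time[i])


def normalize_to_max(series) -> np.ndarray:
    """Divide a series by its maximum; output peaks at exactly 1."""
    y = np.asarray(series, dtype=float)
    m = y.max() if y.size else 0.0
    if not (m > 0):
        raise ValueError("series maximum must be positive to normalize")
    return y / m


def gof_stats(
    obs: pd.DataFrame, pred: np.ndarray, sigma: dict[str, float] | float
) -> dict:
    """RMSE, weighted residuals, and the fraction of |WRES| ≤ 2.

    ``obs`` and ``pred`` must be aligned one-to-one.  ``sigma`` is the
    per-variable residual standard deviation (same quantity profiled in the
    likelihood), either a single float or a tissue → σ mapping.
    """
    pred = np.asarray(pred, dtype=float)
    if len(obs) != len(pred):
        raise ValueError("observations and predictions must align 1:1")
    residuals = obs["value"].to_numpy(dtype=float) - pred
    if isinstance(sigma, dict):
        sig = obs["tissue"].map(sigma).to_numpy(dtype=float)
    else:
        sig = np.full(len(obs), float(sigma))
    if np.any((sig == 0) & (residuals != 0)):
        raise ValueError("zero sigma with nonzero residuals")
    with np.errstate(invalid="ignore"):
        wres = np.where(sig > 0, residuals / np.where(sig > 0, sig, 1.0), 0.0)
    return {
        "rmse": float(np.sqrt(np.mean(residuals**2))),
        "wres": wres,
        "frac_wres_within_2": float(np.mean(np.abs(wres) <= 2.0)),
    }


# -- observation-table I/O ---------------------------------------------------

def read_observations(path) -> pd.DataFrame:
    """Read an observation table (study,tissue,day,value,error,scaled) CSV."""
    df = pd.read_csv(path)
    missing = set(_OBS_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if "error" not in df.columns:
        df["error"] = np.nan
    if "scaled" not in df.columns:
        df["scaled"] = True
    bad = set(df["tissue"]) - set(TISSUES)
    if bad:
        raise ValueError(f"unknown tissue(s) in table: {sorted(bad)}")
    if (df["day"] < 0).any() or (df["value"] < 0).any():
        raise ValueError("days and values must be non-negative")
    return df[_OBS_COLUMNS]


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_OBS_COLUMNS)
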