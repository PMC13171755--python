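"""Model constants for the murine B cell / antibody-secreting cell (ASC) model.

The model carries 31 named constants: seven homeostatic steady-state cell
counts, fourteen trafficking rate constants (``k1`` … ``k14``), maturation and
elimination rates, IgG synthesis/clearance rates, and the saturable
bone-marrow niche parameters (``Vmax``, ``Khalf``).  Two closure modes are
supported:

``paper``
    The published reference values verbatim.  Spleen and blood naive-B-cell
    balances close, but the lymph-node naive balance does not (the printed
    ``k7`` balances the LN pool against the *spleen* naive count rather than
    the blood influx), so the unstimulated system is only approximately
    stationary.

``self_consistent``
    The seven derivable rates are recomputed from compartment balance so that
    every homeostatic compartment is exactly stationary.  Preferred for
    forward simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import yaml

__all__ = [
    "ParameterSet",
    "PAPER_VALUES",
    "PRECURSOR_FREQUENCY",
    "FITTED_NAMES",
    "DERIVED_NAMES",
    "build_parameters",
]

#: Fraction of naive B cells specific for the antigen (1 in 10^6).
PRECURSOR_FREQUENCY = 1e-6

#: The five calibrated immune-activation parameters.
FITTED_NAMES = ("k9", "k12", "k13", "kmat_3", "Vmax")

#: The seven rates obtainable analytically from steady-state closure.
DERIVED_NAMES = ("kmat_1", "k1", "k3", "kmat_2", "k5", "kdeg_spl", "k7")

#: Published reference values (cells, 1/day, cells/day, pg/cell/day).
PAPER_VALUES: dict[str, float] = {
    # homeostatic steady-state cell counts
    "ImmBone_ss": 1.97e6,
    "T1Bone_ss": 0.76e6,
    "T1Blood_ss": 0.004e6,
    "T1Spleen_ss": 4.40e6,
    "NaiveSpleen_ss": 24.30e6,
    "NaiveBlood_ss": 4.64e6,
    "NaiveLN_ss": 1.90e6,
    # naive/T1 trafficking
    "k1": 26.32,
    "k2": 1.01,
    "k3": 6111.0,
    "k4": 10.08,
    "k5": 73.53,
    "k6": 4.9,
    "k7": 62.62,
    # production, maturation, elimination
    "ksyn_imm": 20e6,
    "kmat_1": 10.15,
    "kmat_2": 4.55,
    "kdeg_spl": 4.78,
    "kdeg_ln": 0.05,
    # ASC trafficking
    "k8": 2.52,
    "k9": 8.53,
    "k10": 143.60,
    "k11": 2.72,
    "k12": 0.02,
    "k13": 16.26,
    "k14": 0.02,
    # IgG
    "ksin_igg": 22.00,
    "kdeg_igg": 0.12,
    # activation and niche
    "kmat_3": 294.19,
    "Vmax": 490.60,
    "Khalf": 0.10,
}

_UNITS = {
    **{n: "cell" for n in PAPER_VALUES if n.endswith("_ss")},
    **{n: "1/day" for n in PAPER_VALUES if n.startswith(("k", "kmat", "kdeg"))},
    "ksyn_imm": "cell/day",
    "ksin_igg": "pg/cell/day",
    "Vmax": "cell/day",
    "Khalf": "cell",
}


@dataclass(frozen=True)
class ParameterSet:
    """Immutable container for the 31 model constants.

    ``precursor_frequency`` is a fixed convention (1e-6) rather than a free
    parameter; ``mode`` records which closure produced the rates.
    """

    ImmBone_ss: float
    T1Bone_ss: float
    T1Blood_ss: float
    T1Spleen_ss: float
    NaiveSpleen_ss: float
    NaiveBlood_ss: float
    NaiveLN_ss: float
    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    ksyn_imm: float
    kmat_1: float
    kmat_2: float
    kdeg_spl: float
    kdeg_ln: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    ksin_igg: float
    kdeg_igg: float
    kmat_3: float
    Vmax: float
    Khalf: float
    precursor_frequency: float = PRECURSOR_FREQUENCY
    mode: str = "paper"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "mode":
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"{f.name} must be numeric, got {type(v)!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    # -- accessors ---------------------------------------------------------
    def as_dict(self) -> dict[str, float]:
        """All 31 constants plus the precursor frequency, by name."""
        return {
            f.name: getattr(self, f.name) for f in fields(self) if f.name != "mode"
        }

    def with_updates(self, **overrides: float) -> "ParameterSet":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return replace(self, **overrides)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": self.as_dict(), "mode": self.mode}, fh)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc["parameters"], mode=doc.get("mode", "paper"))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {
                "name": n,
                "value": v,
                "units": _UNITS.get(n, "dimensionless"),
                "source": "derived" if n in DERIVED_NAMES else "reference",
            }
            for n, v in self.as_dict().items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def build_parameters(
    overrides: Mapping[str, float] | None = None, mode: str = "paper"
) -> ParameterSet:
    """Construct a parameter set from the reference table.

    Parameters
    ----------
    overrides
        Name → value replacements, applied after closure.
    mode
        ``"paper"`` uses the published rate table verbatim (with ``k14``
        tied to ``k12``).  ``"self_consistent"`` recomputes the seven
        derivable rates so that every homeostatic compartment is exactly
        balanced.

    Notes
    -----
    In paper mode ``k14`` follows ``k12`` (the peripheral-organ efflux is
    assumed equal to bone-marrow efflux) unless either is overridden
    explicitly.
    """
    if mode not in ("paper", "self_consistent"):
        raise ValueError(f"mode must be 'paper' or 'self_consistent', got {mode!r}")
    overrides = dict(overrides or {})
    values = dict(PAPER_VALUES)

    if mode == "self_consistent":
        # deferred import: steady_state depends on this module's constants
        from .steady_state import derive_rates

        counts = {n: values[n] for n in values if n.endswith("_ss")}
        fixed = {n: values[n] for n in ("ksyn_imm", "k2", "k4", "k6", "kdeg_ln")}
        derived = derive_rates(counts, fixed, mode="self_consistent")
        for name in DERIVED_NAMES:
            values[name] = getattr(derived, name)

    unknown = set(overrides) - set(values) - {"precursor_frequency"}
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")

    # k14 := k12 convention unless the caller pins either one
    if "k12" in overrides and "k14" not in overrides:
        overrides["k14"] = overrides["k12"]
    values.update({k: v for k, v in overrides.items() if k != "precursor_frequency"})
    pf = overrides.get("precursor_frequency", PRECURSOR_FREQUENCY)
    return ParameterSet(**values, precursor_frequency=pf, mode=mode)
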