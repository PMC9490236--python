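"""PAMPA apparent-permeability computation and classification.

The parallel artificial membrane permeability assay measures compound
concentrations in a donor and an acceptor well after incubation across an
artificial lipid membrane. With the equilibrium concentration

    C_e = (C_D * V_D + C_A * V_A) / (V_D + V_A)

the apparent permeability is

    P_app = -ln(1 - C_A / C_e) / (A * (1/V_D + 1/V_A) * t)   [cm/s]

where t is the incubation time (s), C_A and C_D the acceptor/donor
concentrations at t, V_A and V_D the well volumes (cm^3) and A the filter
area (cm^2). The single denominator grouping follows from dimensional
analysis (the bracket has units cm^-2 * cm^3 ... s = s/cm, so P_app is
cm/s). No membrane-retention correction is applied.

Classification thresholds (cm/s): P_app >= 1e-7 detectable/permeable,
>= 1e-6 significant, >= 1e-5 high; boundaries inclusive upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PampaMeasurement", "PermeabilityResult", "equilibrium_conc", "papp",
    "classify", "process_table", "THRESHOLDS",
]

DEFAULT_V_D = 0.300   # donor volume, cm^3 (300 uL)
DEFAULT_V_A = 0.250   # acceptor volume, cm^3 (250 uL)

THRESHOLDS = (("high", 1e-5), ("significant", 1e-6), ("permeable", 1e-7))


@dataclass(frozen=True)
class PampaMeasurement:
    """One PAMPA well pair. Concentrations share any common unit."""

    c_a: float                 # acceptor concentration at time t
    c_d: float                 # donor concentration at time t
    area: float                # filter area, cm^2
    t: float                   # incubation time, s
    v_d: float = DEFAULT_V_D   # donor volume, cm^3
    v_a: float = DEFAULT_V_A   # acceptor volume, cm^3

    def __post_init__(self):
        if self.v_d <= 0 or self.v_a <= 0:
            raise ValueError("well volumes must be positive")
        if self.area <= 0:
            raise ValueError("filter area must be positive")
        if self.t <= 0:
            raise ValueError("incubation time must be positive")
        if self.c_a < 0 or self.c_d < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class PermeabilityResult:
    c_e: float
    p_app: float      # cm/s
    label: str


def equilibrium_conc(m: PampaMeasurement) -> float:
    """Mass-balance equilibrium concentration C_e."""
    return (m.c_d * m.v_d + m.c_a * m.v_a) / (m.v_d + m.v_a)


def papp(m: PampaMeasurement) -> PermeabilityResult:
    """Apparent permeability of one measurement, cm/s."""
    c_e = equilibrium_conc(m)
    if m.c_a >= c_e:
        raise ValueError(
            "acceptor concentration at/over equilibrium: P_app undefined")
    p = float(-np.log(1.0 - m.c_a / c_e) /
              (m.area * (1.0 / m.v_d + 1.0 / m.v_a) * m.t))
    return PermeabilityResult(c_e, p, classify(p))


def classify(p: float) -> str:
    """Permeability class of a P_app value (cm/s)."""
    if p < 0:
        raise ValueError("P_app must be non-negative")
    for label, cut in THRESHOLDS:
        if p >= cut:
            return label
    return "below_detection"


def process_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row P_app plus per-id replicate mean and standard deviation.

    Expects columns id, C_A, C_D, A, t and optionally V_D, V_A, replicate.
    """
    df = df.copy()
    if "V_D" not in df:
        df["V_D"] = DEFAULT_V_D
    if "V_A" not in df:
        df["V_A"] = DEFAULT_V_A
    out = []
    for _, row in df.iterrows():
        m = PampaMeasurement(float(row["C_A"]), float(row["C_D"]),
                             float(row["A"]), float(row["t"]),
                             float(row["V_D"]), float(row["V_A"]))
        r = papp(m)
        out.append({"id": row["id"], "C_e": r.c_e, "P_app": r.p_app,
                    "class": r.label})
    res = pd.DataFrame(out)
    stats = res.groupby("id")["P_app"].agg(["mean", "std", "count"])
    res = res.merge(stats.rename(columns={
        "mean": "P_app_mean", "std": "P_app_sd", "count": "n_replicates"}),
        on="id", how="left")
    return res
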