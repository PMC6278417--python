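"""Ellman-assay arithmetic: percentage inhibition and reactivation.

The Ellman cholinesterase assay reads thiocholine-DTNB absorbance at 412 nm.
With L0 the mean absorbance of the uninhibited (negative-control) wells,
Li that of the inhibited wells, and Lr that after adding a reactivator,

    %I = (L0 - Li) / L0 * 100
    %R = (Lr - Li) / (L0 - Li) * 100

Percentages outside [0, 100] are reported with a warning, never clamped:
Lr > L0 does occur experimentally and clamping would hide it from QC.
Background/blank correction is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DataDomainError, PlateMeasurement, SchemaError

__all__ = [
    "AssayGroup",
    "percent_inhibition",
    "percent_reactivation",
    "reduce_plate",
    "read_plate_table",
]

ROLES = ("L0_negative_control", "Li_inhibited", "Lr_reactivated")


@dataclass(frozen=True)
class AssayGroup:
    """Replicate absorbances of one (compound, concentration, time) group."""

    L0_values: tuple[float, ...]
    Li_values: tuple[float, ...]
    Lr_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for vals in (self.L0_values, self.Li_values, self.Lr_values):
            if any(v < 0 for v in vals):
                raise DataDomainError("absorbance must be >= 0")

    @property
    def L0(self) -> float:
        return float(np.mean(self.L0_values))

    @property
    def Li(self) -> float:
        return float(np.mean(self.Li_values))

    @property
    def Lr(self) -> float | None:
        return float(np.mean(self.Lr_values)) if self.Lr_values else None


def _warn_range(name: str, value: float) -> None:
    if not 0.0 <= value <= 100.0:
        warnings.warn(f"{name} = {value:.2f} outside [0, 100] "
                      "(reported unclamped)", stacklevel=3)


def percent_inhibition(L0: float, Li: float) -> float:
    """%I = (L0 - Li)/L0 * 100; L0 must be positive."""
    if L0 == 0:
        raise DataDomainError("L0 = 0: cannot compute percent inhibition")
    pct = (L0 - Li) / L0 * 100.0
    _warn_range("%I", pct)
    return pct


def percent_reactivation(L0: float, Li: float, Lr: float) -> float:
    """%R = (Lr - Li)/(L0 - Li) * 100; requires L0 != Li."""
    if L0 == Li:
        raise DataDomainError(
            "L0 == Li: controls show no inhibition window, %R undefined")
    pct = (Lr - Li) / (L0 - Li) * 100.0
    _warn_range("%R", pct)
    return pct


def read_plate_table(path) -> pd.DataFrame:
    """Read a long-format plate CSV.

    Columns: compound, concentration_uM, time_min, role, replicate,
    absorbance.  Roles must be one of ``L0_negative_control``,
    ``Li_inhibited``, ``Lr_reactivated``.
    """
    df = pd.read_csv(path)
    required = {"compound", "concentration_uM", "time_min", "role",
                "replicate", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"plate table missing column(s) {sorted(missing)}")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise SchemaError(f"unknown plate role(s) {sorted(bad)}")
    if (df["absorbance"] < 0).any():
        raise DataDomainError("absorbance must be >= 0")
    return df


def _measurements_to_frame(measurements) -> pd.DataFrame:
    rows = [{"compound": m.compound,
             "concentration_uM": m.concentration_uM,
             "time_min": m.time_min,
             "role": m.role,
             "replicate": m.replicate,
             "absorbance": m.absorbance} for m in measurements]
    return pd.DataFrame(rows)


def reduce_plate(measurements,
                 aggregation: str = "mean_then_formula") -> pd.DataFrame:
    """Reduce plate measurements to %I and %R per (compound, conc, time).

    Accepts a long-format DataFrame (see :func:`read_plate_table`) or a list
    of :class:`~poserank.core_io.PlateMeasurement`.  Every group needs L0 and
    Li wells; Lr is optional (then %R is NaN).

    ``aggregation`` chooses between applying the formulas to role means
    (``mean_then_formula``, default) or averaging replicate-level
    percentages (``formula_then_mean``, replicates paired by replicate id).
    The replicate-level percentages also provide n and the standard
    deviation columns; for %I the two aggregations agree identically when
    replicate-wise L0 values are equal, and for %R when both L0 and Li are.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements
    else:
        df = _measurements_to_frame(list(measurements))
    if aggregation not in ("mean_then_formula", "formula_then_mean"):
        raise DataDomainError(f"unknown aggregation {aggregation!r}")

    keys = ["compound", "concentration_uM", "time_min"]
    out = []
    for group_key, g in df.groupby(keys, sort=False, dropna=False):
        roles = set(g["role"])
        for needed in ("L0_negative_control", "Li_inhibited"):
            if needed not in roles:
                raise SchemaError(
                    f"group {dict(zip(keys, group_key))} lacks role {needed}")
        L0s = g.loc[g.role == "L0_negative_control"].set_index(
            "replicate")["absorbance"]
        Lis = g.loc[g.role == "Li_inhibited"].set_index(
            "replicate")["absorbance"]
        Lrs = g.loc[g.role == "Lr_reactivated"].set_index(
            "replicate")["absorbance"]
        L0, Li = L0s.mean(), Lis.mean()
        has_lr = len(Lrs) > 0

        # replicate-level percentages, paired by replicate id
        common_I = L0s.index.intersection(Lis.index)
        rep_I = [percent_inhibition(L0s[k], Lis[k]) for k in common_I
                 if L0s[k] != 0]
        rep_R = []
        if has_lr:
            common_R = common_I.intersection(Lrs.index)
            rep_R = [percent_reactivation(L0s[k], Lis[k], Lrs[k])
                     for k in common_R if L0s[k] != Lis[k]]

        if aggregation == "mean_then_formula":
            pct_I = percent_inhibition(L0, Li)
            pct_R = (percent_reactivation(L0, Li, Lrs.mean())
                     if has_lr else np.nan)
        else:
            pct_I = float(np.mean(rep_I)) if rep_I else np.nan
            pct_R = float(np.mean(rep_R)) if rep_R else np.nan

        row = dict(zip(keys, group_key))
        row.update({
            "percent_inhibition": pct_I,
            "percent_reactivation": pct_R,
            "n_I": len(rep_I),
            "n_R": len(rep_R),
            "sd_percent_inhibition": float(np.std(rep_I, ddof=1))
            if len(rep_I) > 1 else np.nan,
            "sd_percent_reactivation": float(np.std(rep_R, ddof=1))
            if len(rep_R) > 1 else np.nan,
        })
        out.append(row)
    return pd.DataFrame(out)
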