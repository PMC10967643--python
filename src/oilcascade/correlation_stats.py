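"""Pearson correlation matrix across the study variables.

One observation is one (treatment × processing-time) condition; all
treatments are pooled.  The variable set mirrors the study's correlation
figure: the Lioumbas parameters a and b, the Arrhenius parameters μ0 and
Ea, ECN, TPC, t_P itself, and viscosity evaluated at 60 °C and 100 °C.
Significance is the raw two-sided t-test p-value with n − 2 degrees of
freedom, flagged at 0.05 (*) and 0.01 (**); no multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_types_io import OilCascadeError, StudyDataset
from .composition import compute_ecn
from .viscosity_models import compare_models, predict_lioumbas


class ConstantVariableWarning(UserWarning):
    """A variable has zero variance; its correlations are undefined."""


#: Canonical variable order for study correlation tables.
STUDY_VARIABLES = ("a", "b", "mu0", "Ea", "ECN", "TPC", "t_P",
                   "viscosity_60C", "viscosity_100C")


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson r and p matrices over named variables.

    ``flags`` marks raw two-sided significance: "**" for p < 0.01,
    "*" for p < 0.05, "" otherwise (and for undefined cells).
    """

    variables: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    n: int

    @property
    def flags(self) -> np.ndarray:
        out = np.full(self.p.shape, "", dtype=object)
        with np.errstate(invalid="ignore"):
            out[self.p < 0.05] = "*"
            out[self.p < 0.01] = "**"
        np.fill_diagonal(out, "")
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """(r, p, flags) as labelled DataFrames."""
        idx = list(self.variables)
        return (
            pd.DataFrame(self.r, index=idx, columns=idx),
            pd.DataFrame(self.p, index=idx, columns=idx),
            pd.DataFrame(self.flags, index=idx, columns=idx),
        )


def pearson_matrix(table: Mapping[str, Sequence[float]]) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-distribution p-values.

    All vectors must be aligned (same length n ≥ 3, no missing values).
    A zero-variance variable gets NaN rows/columns and raises a
    :class:`ConstantVariableWarning` naming it — never a silent NaN.
    """
    names = tuple(table)
    if len(names) < 2:
        raise OilCascadeError("need at least two variables to correlate")
    arrays = {}
    n = None
    for name in names:
        arr = np.asarray(table[name], dtype=float)
        if arr.ndim != 1:
            raise OilCascadeError(f"variable {name!r} is not a vector")
        if np.isnan(arr).any():
            raise OilCascadeError(f"variable {name!r} contains missing values")
        if n is None:
            n = arr.size
        elif arr.size != n:
            raise OilCascadeError(
                f"variable {name!r} has length {arr.size}, expected {n}"
            )
        arrays[name] = arr
    assert n is not None
    if n < 3:
        raise OilCascadeError(f"need n >= 3 observations, got {n}")

    constant = {name for name, arr in arrays.items() if np.ptp(arr) == 0}
    for name in sorted(constant):
        warnings.warn(
            f"variable {name!r} is constant; its correlations are undefined",
            ConstantVariableWarning,
            stacklevel=2,
        )

    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if names[i] in constant or names[j] in constant:
                r[i, j] = r[j, i] = math.nan
                p[i, j] = p[j, i] = math.nan
                continue
            res = stats.pearsonr(arrays[names[i]], arrays[names[j]])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    for i in range(k):
        if names[i] in constant:
            r[i, i] = math.nan
            p[i, i] = math.nan
    return CorrelationResult(variables=names, r=r, p=p, n=n)


def study_variable_table(dataset: StudyDataset) -> pd.DataFrame:
    """Assemble the per-condition variable table from a full dataset.

    Each viscosity sweep is fit with both models; ECN comes from the FA
    profile and TPC from the TPC series of the same (treatment, t_P).
    Conditions missing any component are dropped (inner join).  Returns a
    DataFrame with columns :data:`STUDY_VARIABLES` plus the identifying
    ``treatment``.
    """
    ecn_map = {
        (prof.treatment, prof.t_P): compute_ecn(prof).ecn
        for prof in dataset.profiles
    }
    tpc_map = {
        (series.treatment, t): v
        for series in dataset.tpc for t, v in series.observations
    }
    rows = []
    for sweep in dataset.sweeps:
        key = (sweep.treatment, sweep.t_P)
        if key not in ecn_map or key not in tpc_map:
            continue
        cmp_res = compare_models(sweep)
        lio, arr = cmp_res.lioumbas, cmp_res.arrhenius
        rows.append({
            "treatment": sweep.treatment,
            "t_P": sweep.t_P,
            "a": lio.a,
            "b": lio.b,
            "mu0": arr.mu0,
            "Ea": arr.Ea,
            "ECN": ecn_map[key],
            "TPC": tpc_map[key],
            "viscosity_60C": predict_lioumbas(lio, 60.0),
            "viscosity_100C": predict_lioumbas(lio, 100.0),
        })
    if not rows:
        raise OilCascadeError(
            "no (treatment, t_P) condition has sweep, FA profile and TPC"
        )
    df = pd.DataFrame(rows)
    return df[["treatment"] + [v for v in STUDY_VARIABLES]]


def correlate_study(dataset: StudyDataset) -> CorrelationResult:
    """Pearson matrix over :data:`STUDY_VARIABLES` from a full dataset."""
    df = study_variable_table(dataset)
    return pearson_matrix({v: df[v].to_numpy() for v in STUDY_VARIABLES})
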