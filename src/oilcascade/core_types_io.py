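"""Domain types, CSV readers/writers, packaged fixtures and configuration.

The study design these types describe: rapeseed oil (RSO), with or without
antioxidant dosing (carnosic acid at 200/400/700 mg/kg, or TBHQ at 200 mg/kg),
is held at 180 °C and sampled every 8 hours up to 32 h.  At each sampling
point three kinds of measurement are taken:

* a **viscosity sweep** — dynamic viscosity μ (mPa·s) over a temperature ramp
  (60–110 °C) at a fixed shear rate, the oil being Newtonian;
* a **fatty-acid profile** — mass percent per FA species from GC-FID of the
  methyl esters;
* a **TPC reading** — total polar compounds, percent, the regulatory
  degradation marker (waste point 27 % in China).

Everything downstream (model fits, the degradation cascade, correlations)
consumes these three containers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("oilcascade")

#: Universal gas constant, J/(mol·K); used by the Arrhenius viscosity model.
GAS_CONSTANT = 8.314

#: Slack allowed on the total mass percent of a fatty-acid profile.  GC-FID
#: tables routinely sum to ~97 % rather than 100 % because minor species are
#: not reported; totals above 100 % beyond this tolerance are rejected.
PROFILE_SUM_TOLERANCE = 0.5


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OilCascadeError(Exception):
    """Base class for all package errors."""


class FormatError(OilCascadeError):
    """A file or field does not have the expected structure."""


class ValidationError(OilCascadeError):
    """Structurally well-formed data violates a domain invariant."""


class SingularDesignError(OilCascadeError):
    """A regression design matrix is rank deficient (e.g. constant x)."""


class InsufficientDataError(OilCascadeError):
    """Too few observations for the requested fit."""


class NoCrossingError(OilCascadeError):
    """A fitted trend never crosses the requested threshold."""


# ---------------------------------------------------------------------------
# Fatty-acid species
# ---------------------------------------------------------------------------

_FA_CODE_RE = re.compile(r"^C(\d+):(\d+)([A-Za-z][A-Za-z0-9]*)?$")


@dataclass(frozen=True)
class FattyAcidSpec:
    """One fatty-acid species identified by its shorthand code.

    The code follows lipid-chemistry shorthand ``C<carbons>:<double_bonds>``
    with an optional positional suffix (``C18:3n3`` is α-linolenic acid);
    the suffix is ignored when deriving the counts.
    """

    code: str
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValidationError(f"{self.code!r}: carbons must be >= 2")
        if not 0 <= self.double_bonds < self.carbons:
            raise ValidationError(
                f"{self.code!r}: double bonds must satisfy 0 <= db < carbons"
            )

    @classmethod
    def parse(cls, code: str) -> "FattyAcidSpec":
        m = _FA_CODE_RE.match(code.strip())
        if m is None:
            raise FormatError(
                f"cannot parse fatty-acid code {code!r}; expected "
                "'C<carbons>:<double_bonds>' with optional suffix like 'n3'"
            )
        return cls(code=code.strip(), carbons=int(m.group(1)),
                   double_bonds=int(m.group(2)))

    @property
    def effective_carbons(self) -> int:
        """Carbons minus double bonds — the species' ECN contribution weight."""
        return self.carbons - self.double_bonds


@dataclass
class FattyAcidProfile:
    """Fatty-acid composition of one sample at one processing time.

    ``percents`` maps FA code → mass percent.  Percents need not sum to 100:
    unreported minor species make totals of ~97 % normal.
    """

    sample_id: str
    treatment: str
    t_P: float
    percents: dict[str, float]

    def __post_init__(self) -> None:
        if self.t_P < 0:
            raise ValidationError(f"{self.sample_id}: t_P must be >= 0 h")
        for code, pct in self.percents.items():
            FattyAcidSpec.parse(code)
            if pct < 0:
                raise ValidationError(
                    f"{self.sample_id}: percent for {code} is negative ({pct})"
                )
        total = sum(self.percents.values())
        if total > 100 + PROFILE_SUM_TOLERANCE:
            raise ValidationError(
                f"{self.sample_id}: percents sum to {total:.2f} > 100"
            )

    @property
    def specs(self) -> dict[str, FattyAcidSpec]:
        return {code: FattyAcidSpec.parse(code) for code in self.percents}


# ---------------------------------------------------------------------------
# Viscosity sweeps
# ---------------------------------------------------------------------------

@dataclass
class ViscositySweep:
    """Viscosity versus temperature for one sample at one processing time.

    ``points`` is an ordered list of (temperature °C, viscosity mPa·s) pairs;
    points are sorted by temperature on construction.  ``shear_rate`` (s⁻¹)
    is carried as metadata only — the oil is Newtonian, so the sweep is
    shear-rate independent.
    """

    sample_id: str
    treatment: str
    t_P: float
    shear_rate: float
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValidationError(
                f"{self.sample_id}: need >= 3 (T, mu) points, got {len(self.points)}"
            )
        self.points = sorted(self.points, key=lambda p: p[0])
        for temp, mu in self.points:
            if temp <= 0:
                raise ValidationError(
                    f"{self.sample_id}: temperature must be > 0 degC, got {temp}"
                )
            if mu <= 0:
                raise ValidationError(
                    f"{self.sample_id}: viscosity must be > 0 mPa*s, got {mu}"
                )
        temps = [p[0] for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ValidationError(
                f"{self.sample_id}: duplicate temperature in sweep"
            )

    @property
    def temperatures(self) -> list[float]:
        return [p[0] for p in self.points]

    @property
    def viscosities(self) -> list[float]:
        return [p[1] for p in self.points]


# ---------------------------------------------------------------------------
# Model-fit records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LioumbasFit:
    """Parameters of ln μ = a + b·(ln T)², T in °C; r² on the ln μ scale."""

    a: float
    b: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1 + 1e-12:
            raise ValidationError(f"r2 out of [0, 1]: {self.r2}")
        if self.n_points < 3:
            raise ValidationError("fit requires >= 3 points")


@dataclass(frozen=True)
class ArrheniusFit:
    """Parameters of ln μ = ln μ0 + Ea / (R·T_K); Ea in J/mol, μ0 in mPa·s."""

    mu0: float
    Ea: float
    r2: float
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValidationError(f"mu0 must be > 0, got {self.mu0}")
        if not 0 <= self.r2 <= 1 + 1e-12:
            raise ValidationError(f"r2 out of [0, 1]: {self.r2}")


# ---------------------------------------------------------------------------
# TPC series and the assembled dataset
# ---------------------------------------------------------------------------

@dataclass
class TPCSeries:
    """Total polar compounds (percent) versus processing time for one treatment."""

    treatment: str
    observations: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.observations = sorted(self.observations, key=lambda o: o[0])
        times = [t for t, _ in self.observations]
        if len(set(times)) != len(times):
            raise ValidationError(
                f"{self.treatment}: duplicate t_P in TPC series"
            )
        for t, tpc in self.observations:
            if not 0 <= tpc <= 100:
                raise ValidationError(
                    f"{self.treatment}: TPC must lie in [0, 100] %, got {tpc}"
                )

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.observations]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.observations]


@dataclass
class StudyDataset:
    """All measurements of one thermal-degradation study."""

    sweeps: list[ViscositySweep] = field(default_factory=list)
    profiles: list[FattyAcidProfile] = field(default_factory=list)
    tpc: list[TPCSeries] = field(default_factory=list)
    provenance: str = "user"

    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sweeps:
            seen.setdefault(s.treatment)
        for p in self.profiles:
            seen.setdefault(p.treatment)
        for t in self.tpc:
            seen.setdefault(t.treatment)
        return list(seen)


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

_SWEEP_COLUMNS = ["sample_id", "treatment", "t_P_h", "shear_rate_per_s",
                  "temperature_C", "viscosity_mPa_s"]
_FA_COLUMNS = ["sample_id", "treatment", "t_P_h", "fa_code", "percent"]
_TPC_COLUMNS = ["treatment", "t_P_h", "tpc_percent"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        # round_trip parsing keeps write->read lossless to the last bit
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_viscosity_sweeps(path: str | Path) -> list[ViscositySweep]:
    """Read a long-format viscosity CSV into sweeps.

    Rows are grouped by (sample_id, t_P_h) and sorted by temperature inside
    each sweep, so the result is independent of input row order.  Row numbers
    in error messages count the header as line 1.
    """
    df = _read_csv(path, _SWEEP_COLUMNS)
    for idx, row in df.iterrows():
        line = int(idx) + 2
        if row["viscosity_mPa_s"] <= 0:
            raise ValidationError(
                f"{path}, row {line}: non-positive viscosity "
                f"{row['viscosity_mPa_s']}"
            )
        if row["temperature_C"] <= 0:
            raise ValidationError(
                f"{path}, row {line}: non-positive temperature "
                f"{row['temperature_C']}"
            )
    sweeps = []
    for (sample_id, t_p), grp in sorted(
        df.groupby(["sample_id", "t_P_h"], sort=False),
        key=lambda kv: (str(kv[0][0]), float(kv[0][1])),
    ):
        treatments = grp["treatment"].unique()
        if len(treatments) > 1:
            raise ValidationError(
                f"{path}: sample {sample_id!r} at t_P={t_p} maps to multiple "
                f"treatments {list(treatments)}"
            )
        shear_rates = grp["shear_rate_per_s"].unique()
        if len(shear_rates) > 1:
            raise ValidationError(
                f"{path}: sample {sample_id!r} at t_P={t_p} has mixed shear "
                f"rates {list(shear_rates)}"
            )
        sweeps.append(ViscositySweep(
            sample_id=str(sample_id),
            treatment=str(treatments[0]),
            t_P=float(t_p),
            shear_rate=float(shear_rates[0]),
            points=list(zip(grp["temperature_C"].astype(float),
                            grp["viscosity_mPa_s"].astype(float))),
        ))
    return sweeps


def read_fatty_acid_table(path: str | Path) -> list[FattyAcidProfile]:
    """Read a long-format FA composition CSV into one profile per (sample, t_P)."""
    df = _read_csv(path, _FA_COLUMNS)
    dup = df.duplicated(subset=["sample_id", "t_P_h", "fa_code"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate fatty-acid entry "
            f"({first['sample_id']}, t_P={first['t_P_h']}, {first['fa_code']})"
        )
    profiles = []
    for (sample_id, t_p), grp in sorted(
        df.groupby(["sample_id", "t_P_h"], sort=False),
        key=lambda kv: (str(kv[0][0]), float(kv[0][1])),
    ):
        treatments = grp["treatment"].unique()
        if len(treatments) > 1:
            raise ValidationError(
                f"{path}: sample {sample_id!r} at t_P={t_p} maps to multiple "
                f"treatments {list(treatments)}"
            )
        percents = {
            str(code): float(pct)
            for code, pct in zip(grp["fa_code"], grp["percent"])
        }
        for code in percents:
            FattyAcidSpec.parse(code)  # raises FormatError on bad codes
        profiles.append(FattyAcidProfile(
            sample_id=str(sample_id), treatment=str(treatments[0]),
            t_P=float(t_p), percents=percents,
        ))
    return profiles


def read_tpc_table(path: str | Path) -> list[TPCSeries]:
    """Read a TPC CSV into one series per treatment, sorted by t_P."""
    df = _read_csv(path, _TPC_COLUMNS)
    for idx, row in df.iterrows():
        if not 0 <= row["tpc_percent"] <= 100:
            raise ValidationError(
                f"{path}, row {int(idx) + 2}: TPC {row['tpc_percent']} "
                "outside [0, 100] %"
            )
    series = []
    for treatment, grp in sorted(df.groupby("treatment", sort=False),
                                 key=lambda kv: str(kv[0])):
        series.append(TPCSeries(
            treatment=str(treatment),
            observations=list(zip(grp["t_P_h"].astype(float),
                                  grp["tpc_percent"].astype(float))),
        ))
    return series


# ---------------------------------------------------------------------------
# CSV writers (inverse of the readers)
# ---------------------------------------------------------------------------

def _write_rows(path: str | Path, header: Sequence[str],
                rows: Iterable[Sequence]) -> None:
    # floats are written with repr so that reading the file back restores
    # every value bit-identically
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in rows:
            writer.writerow([
                repr(v) if isinstance(v, float) else v for v in row
            ])


def write_viscosity_sweeps(sweeps: Iterable[ViscositySweep],
                           path: str | Path) -> None:
    _write_rows(path, _SWEEP_COLUMNS, (
        (s.sample_id, s.treatment, s.t_P, s.shear_rate, temp, mu)
        for s in sweeps for temp, mu in s.points
    ))


def write_fatty_acid_table(profiles: Iterable[FattyAcidProfile],
                           path: str | Path) -> None:
    _write_rows(path, _FA_COLUMNS, (
        (p.sample_id, p.treatment, p.t_P, code, pct)
        for p in profiles for code, pct in p.percents.items()
    ))


def write_tpc_table(series: Iterable[TPCSeries], path: str | Path) -> None:
    _write_rows(path, _TPC_COLUMNS, (
        (s.treatment, t, v) for s in series for t, v in s.observations
    ))


_DATASET_FILES = {
    "sweeps": "viscosity_sweeps.csv",
    "profiles": "fatty_acids.csv",
    "tpc": "tpc.csv",
}


def write_study_dataset(dataset: StudyDataset, directory: str | Path) -> None:
    """Write a dataset as three CSVs (sweeps, FA profiles, TPC) in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_viscosity_sweeps(dataset.sweeps, directory / _DATASET_FILES["sweeps"])
    write_fatty_acid_table(dataset.profiles, directory / _DATASET_FILES["profiles"])
    write_tpc_table(dataset.tpc, directory / _DATASET_FILES["tpc"])


def read_study_dataset(directory: str | Path,
                       provenance: str = "user") -> StudyDataset:
    """Read a dataset directory written by :func:`write_study_dataset`.

    Any of the three files may be absent; the corresponding component is
    left empty.
    """
    directory = Path(directory)
    ds = StudyDataset(provenance=provenance)
    sweeps_path = directory / _DATASET_FILES["sweeps"]
    if sweeps_path.exists():
        ds.sweeps = read_viscosity_sweeps(sweeps_path)
    fa_path = directory / _DATASET_FILES["profiles"]
    if fa_path.exists():
        ds.profiles = read_fatty_acid_table(fa_path)
    tpc_path = directory / _DATASET_FILES["tpc"]
    if tpc_path.exists():
        ds.tpc = read_tpc_table(tpc_path)
    return ds


# ---------------------------------------------------------------------------
# Packaged fixtures (the published study tables)
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("oilcascade.fixtures").joinpath(name)


def load_fixture_fatty_acids() -> list[FattyAcidProfile]:
    """FA compositions of all 15 published (treatment × time) samples."""
    with resources.as_file(_fixture_path("study_fatty_acids.csv")) as p:
        return read_fatty_acid_table(p)


def load_fixture_tpc() -> list[TPCSeries]:
    """Published TPC (%) series, five treatments × five time points."""
    with resources.as_file(_fixture_path("study_tpc.csv")) as p:
        return read_tpc_table(p)


def load_fixture_class_totals() -> pd.DataFrame:
    """Published UFA/MUFA/PUFA class totals for the 15 FA samples."""
    with resources.as_file(_fixture_path("study_fa_class_totals.csv")) as p:
        return pd.read_csv(p)


def load_fixture_ecn() -> pd.DataFrame:
    """Published ECN values (dimensionless), five treatments × five times."""
    with resources.as_file(_fixture_path("study_ecn.csv")) as p:
        return pd.read_csv(p)


def load_fixture_viscosity_params() -> pd.DataFrame:
    """Published per-(treatment, time) viscosity-model parameters.

    Columns: treatment, t_P_h, a, b, r2_lioumbas, mu0, Ea, r2_arrhenius.
    The raw sweeps behind these fits were not published, so these rounded
    parameters are the only viscosity fixture.
    """
    with resources.as_file(_fixture_path("study_viscosity_params.csv")) as p:
        return pd.read_csv(p)


def load_fixture_study() -> StudyDataset:
    """The published measurements as one dataset (no raw sweeps exist)."""
    return StudyDataset(
        sweeps=[],
        profiles=load_fixture_fatty_acids(),
        tpc=load_fixture_tpc(),
        provenance="fixture",
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "temperature_grid": {"start_C": 60.0, "stop_C": 110.0, "step_C": 5.0},
    "rounding": {"ecn_decimals": 2, "trend_decimals": 4},
    "output": {"directory": "oilcascade-output"},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file, deep-merged over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def temperature_grid(cfg: Mapping) -> list[float]:
    """Expand the config's temperature grid into an inclusive list of °C."""
    g = cfg["temperature_grid"]
    start, stop, step = float(g["start_C"]), float(g["stop_C"]), float(g["step_C"])
    if step <= 0 or stop < start:
        raise ValidationError("temperature grid requires step > 0, stop >= start")
    n = int(round((stop - start) / step))
    return [start + i * step for i in range(n + 1)]
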