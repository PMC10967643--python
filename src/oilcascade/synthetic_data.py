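"""Synthetic study generator.

Emulates a complete thermal-degradation study of rapeseed oil so the whole
pipeline is testable without the (unpublished) raw measurements.  The
generator's defaults are calibrated to the published study: five treatments
whose cascade coefficients (b versus t_P, a versus b) and TPC lines are the
published regression equations, time points 0–32 h every 8 h, a 60–110 °C
temperature grid in 5 °C steps, and noise levels matching the printed
replicate dispersion.

Structure generated per treatment and time point:

* viscosity sweep — μ(T) = exp(a + b·(ln T)² + ε) with ε ~ N(0, σ²) on the
  log scale, where b = b_slope·t_P + b_intercept and a = a_slope·b +
  a_intercept.  Log-scale noise is multiplicative on μ, matches the scale
  the models are fit on and keeps μ positive;
* FA profile — each polyunsaturate decays first-order in time, faster with
  more double bonds (factor exp(−k·t_P·(db−1))), and the lost mass is
  redistributed over saturates and monounsaturates proportionally to their
  shares, conserving the total (the study's oxidation picture: linoleic and
  linolenic convert to palmitic/stearic/oleic).  ECN therefore rises
  monotonically;
* TPC — linear in t_P with additive Gaussian noise, clipped to [0, 100] %.

Randomness comes from one explicit seed; each (treatment, time point) gets
its own deterministic substream, so regenerating with the same config and
seed is bit-identical regardless of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_types_io import (
    FattyAcidProfile,
    StudyDataset,
    TPCSeries,
    ValidationError,
    ViscositySweep,
)

#: Baseline fresh-oil FA composition (mass %): the study's fresh rapeseed
#: oil, dominated by oleic acid with ~28 % PUFA.
DEFAULT_FA_BASELINE: dict[str, float] = {
    "C16:0": 4.51,
    "C16:1": 0.15,
    "C18:0": 1.49,
    "C18:1": 62.43,
    "C18:2": 20.36,
    "C20:0": 0.45,
    "C18:3n3": 7.46,
    "C22:0": 0.24,
}


@dataclass(frozen=True)
class TreatmentParams:
    """Generator truth for one antioxidant treatment.

    ``b_slope``/``b_intercept`` define b(t_P); ``a_slope``/``a_intercept``
    define a(b); ``tpc_slope``/``tpc_intercept`` define TPC(t_P) in %/h and %.
    """

    name: str
    b_slope: float
    b_intercept: float
    a_slope: float
    a_intercept: float
    tpc_slope: float
    tpc_intercept: float


#: The five published treatments with their published cascade and TPC lines.
DEFAULT_TREATMENTS: tuple[TreatmentParams, ...] = (
    TreatmentParams("C", -0.0006, -0.1964, -42.57, -2.04, 0.8625, 5.2),
    TreatmentParams("CA-2", -0.0007, -0.1958, -42.10, -2.00, 0.8438, 4.9),
    TreatmentParams("CA-4", -0.0006, -0.1960, -42.02, -1.55, 0.7313, 6.0),
    TreatmentParams("CA-7", -0.0007, -0.1950, -41.59, -1.89, 0.5875, 6.7),
    TreatmentParams("TB-2", -0.0006, -0.1960, -41.67, -1.88, 0.7625, 5.6),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults reproduce the published design: 5 treatments × 5 time points,
    11-point temperature grid, 1 % multiplicative viscosity noise, 1 % TPC
    noise, and a PUFA decay constant of 0.005 /h (≈18 % PUFA loss over
    32 h, the untreated-control value).
    """

    treatments: tuple[TreatmentParams, ...] = DEFAULT_TREATMENTS
    time_points: tuple[float, ...] = (0.0, 8.0, 16.0, 24.0, 32.0)
    temp_grid: tuple[float, ...] = tuple(60.0 + 5.0 * i for i in range(11))
    shear_rate: float = 50.0
    log_noise_sd: float = 0.01
    tpc_noise_sd: float = 1.0
    pufa_decay_rate: float = 0.005
    fa_baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FA_BASELINE))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.log_noise_sd, self.tpc_noise_sd,
               self.pufa_decay_rate) < 0:
            raise ValidationError("noise sds and decay rate must be >= 0")
        if len(set(self.time_points)) != len(self.time_points):
            raise ValidationError("time points must be distinct")
        if len(self.temp_grid) < 3:
            raise ValidationError("temperature grid needs >= 3 points")

    def noiseless(self) -> "SyntheticConfig":
        """Copy with all noise switched off (closed-loop testing)."""
        return replace(self, log_noise_sd=0.0, tpc_noise_sd=0.0)


def _substream(seed: int, treatment_idx: int, time_idx: int) -> np.random.Generator:
    # deterministic per-(treatment, time) stream, independent of loop order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(treatment_idx, time_idx))
    )


def generate_sweep(a: float, b: float, temp_grid, log_noise_sd: float,
                   rng: np.random.Generator, *, sample_id: str = "synthetic",
                   treatment: str = "synthetic", t_P: float = 0.0,
                   shear_rate: float = 50.0) -> ViscositySweep:
    """One viscosity sweep from the Lioumbas law with log-scale noise."""
    temps = np.asarray(temp_grid, dtype=float)
    eps = rng.normal(0.0, log_noise_sd, size=temps.size) if log_noise_sd > 0 \
        else np.zeros(temps.size)
    mu = np.exp(a + b * np.log(temps) ** 2 + eps)
    return ViscositySweep(
        sample_id=sample_id, treatment=treatment, t_P=t_P,
        shear_rate=shear_rate,
        points=list(zip(temps.tolist(), mu.tolist())),
    )


def _decay_profile(baseline: dict[str, float], rate: float,
                   t_P: float) -> dict[str, float]:
    """First-order PUFA decay with mass-conserving redistribution."""
    from .core_types_io import FattyAcidSpec

    specs = {code: FattyAcidSpec.parse(code) for code in baseline}
    decayed = {}
    lost = 0.0
    sink_total = 0.0
    for code, pct in baseline.items():
        db = specs[code].double_bonds
        if db >= 2:
            factor = float(np.exp(-rate * t_P * (db - 1)))
            decayed[code] = pct * factor
            lost += pct * (1.0 - factor)
        else:
            decayed[code] = pct
            sink_total += pct
    if sink_total > 0 and lost > 0:
        for code, pct in baseline.items():
            if specs[code].double_bonds <= 1:
                decayed[code] += lost * pct / sink_total
    return decayed


def generate_study(config: SyntheticConfig) -> StudyDataset:
    """Generate a full study-shaped dataset under the configured conditions."""
    sweeps: list[ViscositySweep] = []
    profiles: list[FattyAcidProfile] = []
    tpc_series: list[TPCSeries] = []
    for ti, treat in enumerate(config.treatments):
        observations = []
        for pi, t_p in enumerate(config.time_points):
            rng = _substream(config.seed, ti, pi)
            b = treat.b_slope * t_p + treat.b_intercept
            a = treat.a_slope * b + treat.a_intercept
            sample_id = f"{treat.name}-{t_p:g}"
            sweeps.append(generate_sweep(
                a, b, config.temp_grid, config.log_noise_sd, rng,
                sample_id=sample_id, treatment=treat.name, t_P=t_p,
                shear_rate=config.shear_rate,
            ))
            profiles.append(FattyAcidProfile(
                sample_id=sample_id, treatment=treat.name, t_P=t_p,
                percents=_decay_profile(config.fa_baseline,
                                        config.pufa_decay_rate, t_p),
            ))
            tpc = treat.tpc_slope * t_p + treat.tpc_intercept
            if config.tpc_noise_sd > 0:
                tpc += float(rng.normal(0.0, config.tpc_noise_sd))
            observations.append((t_p, float(np.clip(tpc, 0.0, 100.0))))
        tpc_series.append(TPCSeries(treatment=treat.name,
                                    observations=observations))
    return StudyDataset(sweeps=sweeps, profiles=profiles, tpc=tpc_series,
                        provenance="synthetic")
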