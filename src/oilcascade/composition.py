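"""Fatty-acid class aggregation, effective carbon number, degradation rates.

The effective carbon number (ECN) summarises a fatty-acid composition as

    ECN = Σ_i (P_i / 100) · (C_i − db_i)

where P_i is the reported mass percent of species i, C_i its carbon count
and db_i its number of double bonds.  Oxidation strips double bonds (PUFAs
degrade, saturates accumulate), so ECN rises monotonically as the oil
degrades — which makes it a compact chemical-composition covariate for the
viscosity cascade.

Percents enter as printed, divided by 100 but **not** renormalised to a
100 % total: GC-FID tables typically sum to ~97 % because minor species go
unreported, and the published ECN values are reproduced only under this
convention (renormalising reproduces none of them).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .core_types_io import FattyAcidProfile, ValidationError


@dataclass(frozen=True)
class ClassTotals:
    """Mass-percent sums by unsaturation class.

    sfa: no double bonds; mufa: exactly one; pufa: two or more;
    ufa = mufa + pufa.
    """

    sfa: float
    mufa: float
    pufa: float

    @property
    def ufa(self) -> float:
        return self.mufa + self.pufa


@dataclass(frozen=True)
class ECNValue:
    """An ECN with its 2-decimal presentation value (half-away-from-zero)."""

    ecn: float
    rounded: float


def _round_half_away(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_fa_classes(profile: FattyAcidProfile) -> ClassTotals:
    """Sum mass percents into SFA / MUFA / PUFA classes by double-bond count."""
    sfa = mufa = pufa = 0.0
    for code, pct in profile.percents.items():
        db = profile.specs[code].double_bonds
        if db == 0:
            sfa += pct
        elif db == 1:
            mufa += pct
        else:
            pufa += pct
    return ClassTotals(sfa=sfa, mufa=mufa, pufa=pufa)


def compute_ecn(profile: FattyAcidProfile) -> ECNValue:
    """Compute ECN = Σ (P_i/100)(C_i − db_i) over the reported species.

    Raises ``ValidationError`` on an empty profile.  Linear in the percent
    vector; no renormalisation of the (typically ~97 %) total.
    """
    if not profile.percents:
        raise ValidationError(
            f"{profile.sample_id}: cannot compute ECN of an empty profile"
        )
    specs = profile.specs
    ecn = sum(
        (pct / 100.0) * specs[code].effective_carbons
        for code, pct in profile.percents.items()
    )
    return ECNValue(ecn=ecn, rounded=_round_half_away(ecn, 2))


def degradation_rate(initial: float, final: float) -> float:
    """Percent loss from ``initial`` to ``final``: (initial − final)/initial × 100.

    Negative values mean growth (final above initial) and are returned as
    such.  ``initial`` must be positive.
    """
    if initial <= 0:
        raise ValidationError(
            f"degradation rate needs initial > 0, got {initial}"
        )
    if final < 0:
        raise ValidationError(f"final value must be >= 0, got {final}")
    return (initial - final) / initial * 100.0
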