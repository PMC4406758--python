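"""qPCR screening arithmetic: dilution-series classification and
primer-architecture CT shifts.

A sample's working dilution must amplify free of inhibition with
sufficient template.  Under perfect efficiency, each 10-fold dilution
delays the cycle threshold by log2(10) ~ 3.32 cycles; observed shifts
much smaller than that (or negative — dilution relieving suppression)
diagnose inhibition, while series whose usable points only cross the
threshold very late (or never) are low-template.  The architecture
comparison reports the mean CT penalty of fusion-tagged primer designs
against standard template-specific primers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

NO_AMPLIFICATION = math.inf


@dataclass(frozen=True)
class DilutionPoint:
    dilution_factor: float  # >= 1, relative to neat
    ct: float               # cycles, or math.inf for no amplification


@dataclass
class DilutionSeries:
    points: list[DilutionPoint]
    efficiency_assumed: float = 1.0

    def __post_init__(self) -> None:
        self.points = [
            p if isinstance(p, DilutionPoint) else DilutionPoint(*_coerce_point(p))
            for p in self.points
        ]
        factors = [p.dilution_factor for p in self.points]
        if any(f < 1 for f in factors):
            raise ValueError("dilution factors are relative to neat and must be >= 1")
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("dilution factors must be strictly increasing")
        if any(p.ct <= 0 for p in self.points if math.isfinite(p.ct)):
            raise ValueError("CT values must be positive")
        if not 0 < self.efficiency_assumed <= 1:
            raise ValueError("efficiency must be in (0, 1]")


def _coerce_point(p) -> tuple[float, float]:
    factor, ct = p
    if isinstance(ct, str):
        ct = NO_AMPLIFICATION if ct.strip().lower() in ("no-amplification", "na", "") else float(ct)
    return float(factor), float(ct)


@dataclass(frozen=True)
class ScreeningCall:
    verdict: str  # ok | inhibited | low_template
    working_dilution: float | None
    details: pd.DataFrame

    def __post_init__(self) -> None:
        if self.verdict == "ok" and self.working_dilution is None:
            raise ValueError("an ok verdict must name a working dilution")


def expected_delta_ct(dilution_ratio: float, efficiency: float = 1.0) -> float:
    """Cycles by which CT should increase across a fold-dilution.

    delta_CT = ln(ratio) / ln(1 + efficiency); at perfect efficiency a
    10-fold dilution costs log2(10) ~ 3.3219 cycles.  Additive in log
    dilution: delta(a*b) = delta(a) + delta(b).
    """
    if dilution_ratio < 1:
        raise ValueError("dilution_ratio must be >= 1")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    return math.log(dilution_ratio) / math.log(1.0 + efficiency)


def classify_series(
    series: DilutionSeries,
    ct_low_template: float = 35.0,
    tol: float = 1.0,
) -> ScreeningCall:
    """Classify a dilution series as ok, inhibited or low_template.

    Inhibited: any consecutive pair of dilutions where the observed CT
    shift falls more than ``tol`` cycles short of the expected shift —
    dilution relieving suppression makes diluted points amplify earlier
    than the model predicts (including negative shifts).  Low template:
    no point amplifies below ``ct_low_template``.  Otherwise ok, with the
    least-diluted sufficiently-early point as the working dilution.
    """
    pts = series.points
    rows = []
    inhibited = False
    for a, b in zip(pts, pts[1:]):
        expected = expected_delta_ct(
            b.dilution_factor / a.dilution_factor, series.efficiency_assumed
        )
        observed = b.ct - a.ct  # inf - inf -> nan; treated as uninformative
        flag = math.isfinite(observed) and observed < expected - tol
        inhibited = inhibited or flag
        rows.append(
            {
                "dilution_from": a.dilution_factor,
                "dilution_to": b.dilution_factor,
                "expected_delta_ct": expected,
                "observed_delta_ct": observed if math.isfinite(observed) else math.nan,
                "inhibition_flag": flag,
            }
        )
    details = pd.DataFrame(
        rows,
        columns=[
            "dilution_from", "dilution_to", "expected_delta_ct",
            "observed_delta_ct", "inhibition_flag",
        ],
    )
    if inhibited:
        return ScreeningCall("inhibited", None, details)
    usable = [p for p in pts if math.isfinite(p.ct) and p.ct < ct_low_template]
    if not usable:
        return ScreeningCall("low_template", None, details)
    working = min(usable, key=lambda p: p.dilution_factor)
    return ScreeningCall("ok", working.dilution_factor, details)


def architecture_ct_shift(
    ct_by_architecture: Mapping[str, Sequence[float]],
    baseline: str = "TSP_only",
) -> pd.DataFrame:
    """Mean CT shift of each primer architecture against the non-fusion baseline."""
    if baseline not in ct_by_architecture:
        raise ValueError(f"baseline architecture {baseline!r} missing")
    base = ct_by_architecture[baseline]
    base_mean = sum(base) / len(base)
    rows = []
    for arch, cts in ct_by_architecture.items():
        mean = sum(cts) / len(cts)
        n = len(cts)
        sd = (sum((c - mean) ** 2 for c in cts) / (n - 1)) ** 0.5 if n > 1 else 0.0
        rows.append(
            {
                "architecture": arch,
                "n": n,
                "mean_ct": mean,
                "delta_ct_vs_baseline": mean - base_mean,
                "sd": sd,
            }
        )
    return pd.DataFrame(rows, columns=["architecture", "n", "mean_ct", "delta_ct_vs_baseline", "sd"])
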