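"""Sample-quality diagnostics: ageing, concentration and adduct checks.

Codifies three empirical findings as automated QC:

* the LPC:PC ratio is a hydrolysis clock — a gain of >= 50% between two
  acquisitions of the same sample flags base-mediated PC hydrolysis;
* S/N is proportional to sample mass, so a unit-slope log-log fit
  extrapolates the minimum mass for S/N 3 (log10(3) = 0.477); 4-16 mg is
  attached as the recommended working window;
* systematic shift drift of LPA/PA/PI/PE against a stationary PC points
  to counter-ion adducts and inconsistent sample handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import EstimationError, ValidationError
from .quantify import QuantReport
from .shift_library import ShiftLibrary, assign_peak

#: Recommended sample-mass window (mg), attached as guidance metadata.
OPTIMAL_MASS_WINDOW = (4.0, 16.0)

#: Classes whose drift against PC indicates adduct perturbation.
ADDUCT_SENTINEL_CLASSES = ("LPA", "PA", "PI", "PE")

DEFAULT_HYDROLYSIS_GAIN = 0.5
DEFAULT_WARN_PPM = 0.03
DEFAULT_TARGET_SNR = 3.0


@dataclass
class HydrolysisResult:
    index_t0: float
    index_t1: float
    gain: float  # fractional increase; inf when index_t0 == 0 < index_t1
    hydrolysis_flag: bool


@dataclass
class DriftResult:
    shift_drift: dict[str, float]
    adduct_warning: bool


@dataclass
class MinMassResult:
    min_mass_mg: float
    target_snr: float
    log10_target: float  # reference line value, log10(target_snr)


@dataclass
class QCResult:
    """Aggregate QC record emitted by the CLI."""

    hydrolysis: HydrolysisResult | None = None
    drift: DriftResult | None = None
    min_mass: MinMassResult | None = None
    optimal_mass_window: tuple[float, float] = OPTIMAL_MASS_WINDOW

    def to_dict(self) -> dict:
        out: dict = {"optimal_mass_window_mg": list(self.optimal_mass_window)}
        if self.hydrolysis is not None:
            out["hydrolysis"] = {
                "index_t0": self.hydrolysis.index_t0,
                "index_t1": self.hydrolysis.index_t1,
                "gain": self.hydrolysis.gain,
                "flag": self.hydrolysis.hydrolysis_flag,
            }
        if self.drift is not None:
            out["drift_ppm"] = self.drift.shift_drift
            out["adduct_warning"] = self.drift.adduct_warning
        if self.min_mass is not None:
            out["min_mass_mg"] = self.min_mass.min_mass_mg
            out["log10_target_snr"] = self.min_mass.log10_target
        return out


def hydrolysis_index(report: QuantReport) -> float:
    """LPC area / PC area; 0 when LPC is absent.  Scale-invariant."""
    pc = report.row("PC")
    if pc is None or pc.area <= 0:
        raise ValidationError("report does not contain a PC row")
    lpc = report.row("LPC")
    return (lpc.area / pc.area) if lpc is not None else 0.0


def hydrolysis_check(
    report_t0: QuantReport,
    report_t1: QuantReport,
    threshold_gain: float = DEFAULT_HYDROLYSIS_GAIN,
) -> HydrolysisResult:
    """Flag hydrolysis when the LPC:PC ratio gain meets ``threshold_gain``.

    LPC appearing from nothing (index 0 at t0) counts as infinite gain.
    """
    i0 = hydrolysis_index(report_t0)
    i1 = hydrolysis_index(report_t1)
    if i0 == 0.0:
        gain = math.inf if i1 > 0 else 0.0
    else:
        gain = i1 / i0 - 1.0
    return HydrolysisResult(
        index_t0=i0,
        index_t1=i1,
        gain=gain,
        hydrolysis_flag=gain >= threshold_gain,
    )


def estimate_min_mass(
    snr_at_mass: list[tuple[float, float]],
    target_snr: float = DEFAULT_TARGET_SNR,
) -> MinMassResult:
    """Mass (mg) at which predicted S/N reaches ``target_snr``.

    Assumes S/N proportional to mass: a unit-slope line is fitted in
    log-log space by least squares (the intercept is the mean of
    log10(snr) - log10(mass)) and solved for the target.  Exact on data
    generated with perfect proportionality.
    """
    if target_snr <= 0:
        raise ValidationError("target_snr must be > 0")
    obs = [(m, s) for m, s in snr_at_mass if s > 0 and m > 0]
    if not obs:
        raise EstimationError("need at least one observation with snr > 0")
    intercept = sum(math.log10(s) - math.log10(m) for m, s in obs) / len(obs)
    log10_target = math.log10(target_snr)
    return MinMassResult(
        min_mass_mg=10.0 ** (log10_target - intercept),
        target_snr=target_snr,
        log10_target=log10_target,
    )


def drift_check(
    report: QuantReport,
    library: ShiftLibrary,
    warn_ppm: float = DEFAULT_WARN_PPM,
) -> DriftResult:
    """Per-class offset of fitted centres from library interval midpoints.

    Drift is measured against the midpoint of the nearest interval of the
    row's own class (the library is interval-valued; the midpoint is the
    declared reference point).  ``adduct_warning`` is raised when at least
    two of LPA/PA/PI/PE drift beyond ``warn_ppm`` while PC sits at 0.00.
    """
    if not report.rows:
        raise ValidationError("report is empty")
    drift: dict[str, float] = {}
    for row in report.rows:
        entries = library.entries_for(row.lipid_class)
        if not entries:
            continue
        nearest = min(entries, key=lambda e: abs(row.center - e.midpoint))
        drift[row.lipid_class] = row.center - nearest.midpoint
    pc_ok = abs(drift.get("PC", math.inf)) <= warn_ppm
    n_drifted = sum(
        1
        for cls in ADDUCT_SENTINEL_CLASSES
        if abs(drift.get(cls, 0.0)) > warn_ppm
    )
    return DriftResult(shift_drift=drift, adduct_warning=pc_ok and n_drifted >= 2)
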