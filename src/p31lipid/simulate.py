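"""Synthetic 31P FID generation.

The signal model is a sum of damped complex exponentials, one per
resonance, with amplitudes proportional to sample mass, class mol
fraction, phosphorus count per molecule (cardiolipin carries two) and the
resonance's share of its class's phosphorus.  On top of that, three
empirical effects observed on real lipid extracts are modelled:

* concentration-dependent shift drift relative to PC (PE moves downfield
  with mass, PA/LPA move upfield; LPC and PI do not move);
* sample-ageing hydrolysis transferring PC to LPC so the LPC:PC ratio at
  21 days exceeds the 48-hour ratio by ~55% (50-60% observed);
* adduct-dependent shift offsets (TEA+, Na+, guanidinium) that never move
  PC, the calibration reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError

#: Default time-domain noise standard deviation per channel.  Low enough
#: that a 1 mol% class at 8 mg keeps its fitted-area error well under 5%
#: (the recovery tolerance); mass-scan scenarios that want the realistic
#: "S/N ~ 3 for a 10 mol% class at 1 mg" regime should pass
#: :data:`MASS_SCAN_NOISE_SIGMA` explicitly.
DEFAULT_NOISE_SIGMA = 0.08

#: Noise level at which a 10 mol% single-resonance class at 1 mg comes out
#: at S/N ~ 3 under default processing (anchors the minimum-mass finding).
MASS_SCAN_NOISE_SIGMA = 0.65

#: Default natural linewidth (Hz) before apodization; narrow enough that
#: the 1.5 Hz exponential broadening is non-negligible.
DEFAULT_FWHM_HZ = 2.0

#: Phosphorus atoms per molecule; cardiolipin has two phosphodiesters.
PHOSPHORUS_PER_MOLECULE: dict[str, int] = {"CL": 2}


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata for a 1D 31P experiment.

    Defaults follow quantitative acquisition at 324 MHz 31P (800 MHz 1H
    field): 3882 complex points over a 14.98 ppm sweep.  ``recovery_delay``
    and ``temperature`` are metadata only; partial saturation is not
    modelled.
    """

    observe_freq: float = 324.0  # MHz
    sw: float = 14.98  # ppm
    n_complex: int = 3882
    carrier_ppm: float = 3.5  # window ~ -4 .. +11 ppm around PC at 0
    recovery_delay: float = 8.4  # s, metadata only
    temperature: float = 293.0  # K, metadata only

    def __post_init__(self) -> None:
        if self.observe_freq <= 0:
            raise ValidationError("observe_freq must be > 0")
        if self.sw <= 0:
            raise ValidationError("sw must be > 0")
        if self.n_complex < 2:
            raise ValidationError("n_complex must be >= 2")

    @property
    def sw_hz(self) -> float:
        """Spectral width in Hz (ppm * MHz)."""
        return self.sw * self.observe_freq

    def to_dict(self) -> dict:
        return {
            "observe_freq": self.observe_freq,
            "sw": self.sw,
            "n_complex": self.n_complex,
            "carrier_ppm": self.carrier_ppm,
            "recovery_delay": self.recovery_delay,
            "temperature": self.temperature,
        }


@dataclass
class LipidComposition:
    """Mol fractions per lipid class plus phosphorus counts per molecule."""

    fractions: dict[str, float]
    phosphorus_per_molecule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ppm_map = dict(PHOSPHORUS_PER_MOLECULE)
        ppm_map.update(self.phosphorus_per_molecule)
        self.phosphorus_per_molecule = {
            cls: ppm_map.get(cls, 1) for cls in self.fractions
        }
        if any(f < 0 for f in self.fractions.values()):
            raise ValidationError("mol fractions must be >= 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mol fractions must sum to 1, got {total!r}")

    def total_phosphorus(self) -> float:
        """Sum of fraction * phosphorus count over all classes."""
        return sum(
            f * self.phosphorus_per_molecule[c] for c, f in self.fractions.items()
        )

    def phosphorus_shares(self) -> dict[str, float]:
        """Per-class share of total phosphorus (what a 31P spectrum sees)."""
        tot = self.total_phosphorus()
        return {
            c: f * self.phosphorus_per_molecule[c] / tot
            for c, f in self.fractions.items()
        }


@dataclass(frozen=True)
class ResonanceSpec:
    """One resonance of a lipid class.

    ``relative_weight`` is the fraction of the class's phosphorus carried
    by this resonance; classes with several resonances (PE, PG) split
    their signal.
    """

    lipid_class: str
    center_ppm: float
    fwhm_hz: float = DEFAULT_FWHM_HZ
    relative_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm_hz <= 0:
            raise ValidationError("fwhm_hz must be > 0")
        if self.relative_weight <= 0:
            raise ValidationError("relative_weight must be > 0")


#: Default resonance positions (ppm) per class, taken at library interval
#: midpoints.  PS and CL have no library interval; their defaults sit in
#: otherwise empty regions and are simulator-only.
DEFAULT_RESONANCE_TABLE: dict[str, list[tuple[float, float]]] = {
    # class -> [(center_ppm, relative_weight), ...]
    "LPA": [(6.0, 1.0)],
    "PA": [(5.3, 1.0)],
    "LPI": [(1.6, 1.0)],
    "PG": [(1.24, 0.5), (1.05, 0.5)],
    "PI": [(1.0, 1.0)],
    "SM": [(0.825, 1.0)],
    "PE": [(0.585, 0.25), (0.56, 0.25), (0.53, 0.25), (0.49, 0.25)],
    "PS": [(0.47, 1.0)],
    "LPC": [(0.445, 1.0)],
    "CL": [(0.38, 1.0)],
    "UNK1": [(0.275, 1.0)],
    "UNK2": [(0.175, 1.0)],
    "PC": [(0.0, 1.0)],
}


def default_resonances(
    classes, fwhm_hz: float = DEFAULT_FWHM_HZ
) -> list[ResonanceSpec]:
    """Build :class:`ResonanceSpec` entries for *classes* from the default
    position table."""
    specs = []
    for cls in classes:
        if cls not in DEFAULT_RESONANCE_TABLE:
            raise ValidationError(f"no default resonances for class {cls!r}")
        for center, weight in DEFAULT_RESONANCE_TABLE[cls]:
            specs.append(
                ResonanceSpec(
                    lipid_class=cls,
                    center_ppm=center,
                    fwhm_hz=fwhm_hz,
                    relative_weight=weight,
                )
            )
    return specs


# ---------------------------------------------------------------------------
# FID synthesis
# ---------------------------------------------------------------------------

def synthesize_fid(
    composition: LipidComposition,
    resonances: list[ResonanceSpec],
    params: AcquisitionParams | None = None,
    mass_mg: float = 4.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
):
    """Synthesize a FID: sum of damped complex exponentials plus noise.

    s(t_j) = sum_k a_k exp(i 2 pi nu_k t_j - pi fwhm_k t_j) + eps_j with
    a_k = mass_mg * fraction(class) * phosphorus_per_molecule(class) *
    relative_weight, nu_k the ppm offset from the carrier in Hz, and eps_j
    complex white noise of standard deviation *noise_sigma* per channel.
    Deterministic for a fixed seed.
    """
    from .process import FID  # local import to avoid a cycle

    if params is None:
        params = AcquisitionParams()
    if mass_mg <= 0:
        raise ValidationError(f"mass_mg must be > 0, got {mass_mg}")
    if noise_sigma < 0:
        raise ValidationError(f"noise_sigma must be >= 0, got {noise_sigma}")

    by_class: dict[str, list[ResonanceSpec]] = {}
    for r in resonances:
        by_class.setdefault(r.lipid_class, []).append(r)
    for cls, frac in composition.fractions.items():
        if frac > 0 and cls not in by_class:
            raise ValidationError(f"class {cls!r} has no resonance spec")
    for cls, specs in by_class.items():
        wsum = sum(r.relative_weight for r in specs)
        if abs(wsum - 1.0) > 1e-6:
            raise ValidationError(
                f"relative weights for class {cls!r} sum to {wsum}, expected 1"
            )

    t = np.arange(params.n_complex) / params.sw_hz
    signal = np.zeros(params.n_complex, dtype=np.complex128)
    for r in resonances:
        frac = composition.fractions.get(r.lipid_class, 0.0)
        if frac == 0.0:
            continue
        amp = (
            mass_mg
            * frac
            * composition.phosphorus_per_molecule[r.lipid_class]
            * r.relative_weight
        )
        nu = (r.center_ppm - params.carrier_ppm) * params.observe_freq
        signal += amp * np.exp((2j * np.pi * nu - np.pi * r.fwhm_hz) * t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(params.n_complex) + 1j * rng.standard_normal(
            params.n_complex
        )
        signal = signal + noise_sigma * noise
    return FID(
        samples=signal,
        params=params,
        history=[
            f"synthesize_fid(mass_mg={mass_mg}, noise_sigma={noise_sigma}, "
            f"seed={seed})"
        ],
    )


# ---------------------------------------------------------------------------
# empirical effect models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationShiftModel:
    """Shift drift per doubling of sample mass, relative to PC.

    Signs follow observation: PE drifts downfield (+), PA and LPA drift
    upfield (-); LPC and PI do not drift.  Magnitudes are configurable;
    only the directions are empirically anchored.
    """

    slopes: Mapping[str, float] = field(
        default_factory=lambda: {"PE": 0.01, "PA": -0.01, "LPA": -0.01}
    )
    mass_ref: float = 4.0  # mg at which offsets vanish

    def __post_init__(self) -> None:
        if self.slopes.get("PC", 0.0) != 0.0:
            raise ValidationError("PC slope must be 0 (calibration reference)")
        if self.slopes.get("PE", 0.0) < 0:
            raise ValidationError("PE slope must be >= 0 (downfield with mass)")
        for cls in ("PA", "LPA"):
            if self.slopes.get(cls, 0.0) > 0:
                raise ValidationError(f"{cls} slope must be <= 0 (upfield)")
        for cls in ("LPC", "PI"):
            if self.slopes.get(cls, 0.0) != 0.0:
                raise ValidationError(f"{cls} must not be concentration-dependent")


def apply_concentration_shifts(
    resonances: list[ResonanceSpec],
    model: ConcentrationShiftModel,
    mass_mg: float,
) -> list[ResonanceSpec]:
    """Shift each centre by slope(class) * log2(mass / mass_ref); PC fixed."""
    if mass_mg <= 0:
        raise ValidationError(f"mass_mg must be > 0, got {mass_mg}")
    factor = math.log2(mass_mg / model.mass_ref)
    out = []
    for r in resonances:
        slope = 0.0 if r.lipid_class == "PC" else model.slopes.get(r.lipid_class, 0.0)
        out.append(replace(r, center_ppm=r.center_ppm + slope * factor))
    return out


@dataclass(frozen=True)
class AgeingModel:
    """Two-anchor linear PC -> LPC hydrolysis model.

    The LPC:PC ratio grows linearly in time, parameterized so that the
    ratio at ``t_late_days`` exceeds the ratio at ``t_ref_hours`` by
    exactly ``ratio_gain`` (fractional).  Linear interpolation is the
    weakest model consistent with a two-point observation; no exponential
    kinetics are claimed.
    """

    t_ref_hours: float = 48.0
    t_late_days: float = 21.0
    ratio_gain: float = 0.55

    def __post_init__(self) -> None:
        if self.ratio_gain < 0:
            raise ValidationError("ratio_gain must be >= 0")
        if not 0 < self.t_ref_hours < self.t_late_days * 24.0:
            raise ValidationError("need 0 < t_ref_hours < t_late_days (in hours)")

    def ratio_at(self, r0: float, age_hours: float) -> float:
        """LPC:PC ratio after *age_hours*, given the ratio r0 at time 0."""
        if self.ratio_gain == 0:
            return r0
        t_late_h = self.t_late_days * 24.0
        denom = t_late_h - (1.0 + self.ratio_gain) * self.t_ref_hours
        if denom <= 0:
            raise ValidationError(
                "ageing anchors inconsistent: late ratio cannot exceed the "
                "reference ratio by the requested gain with a linear model"
            )
        k = self.ratio_gain * r0 / denom
        return r0 + k * age_hours


def apply_ageing(
    composition: LipidComposition, model: AgeingModel, age_hours: float
) -> LipidComposition:
    """Transfer material from PC to LPC according to the ageing model.

    Total phosphorus (sum of fraction * phosphorus count) is conserved
    exactly; all classes other than PC/LPC are untouched.
    """
    if age_hours < 0:
        raise ValidationError("age_hours must be >= 0")
    pc = composition.fractions.get("PC", 0.0)
    if pc <= 0:
        raise ValidationError("composition must contain PC with fraction > 0")
    if age_hours == 0:
        return LipidComposition(
            fractions=dict(composition.fractions),
            phosphorus_per_molecule=dict(composition.phosphorus_per_molecule),
        )
    lpc = composition.fractions.get("LPC", 0.0)
    r0 = lpc / pc
    if r0 == 0 and model.ratio_gain > 0:
        raise ValidationError(
            "ageing with ratio_gain > 0 requires LPC > 0 at time zero "
            "(the ratio profile is multiplicative in the initial ratio)"
        )
    r_t = model.ratio_at(r0, age_hours)
    pool = pc + lpc  # PC and LPC both carry one phosphorus
    fractions = dict(composition.fractions)
    fractions["PC"] = pool / (1.0 + r_t)
    fractions["LPC"] = pool * r_t / (1.0 + r_t)
    return LipidComposition(
        fractions=fractions,
        phosphorus_per_molecule=dict(composition.phosphorus_per_molecule),
    )


@dataclass(frozen=True)
class AdductModel:
    """Per-class ppm offsets for counter-ion adducts.

    PC never moves (it is the calibration reference).  Guanidinium offsets
    scale linearly with the added mass relative to ``scaled_ref_mg``; the
    fixed-dose adducts (TEA+, Na+) apply their offsets as given.  Offset
    magnitudes are illustrative; the empirical anchor is that LPA, PA, PI
    and PE all move relative to PC and not always in the same direction.
    """

    offsets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "TEA+": {"PE": 0.035, "PA": -0.04, "LPA": -0.04, "PI": 0.035},
            "Na+": {"PE": 0.04, "PA": 0.05, "LPA": 0.05, "PI": -0.04},
            "guanidinium": {
                "PE": -0.035, "PA": 0.04, "LPA": 0.05, "PI": 0.035, "PG": -0.03,
            },
        }
    )
    scaled_adducts: frozenset[str] = frozenset({"guanidinium"})
    scaled_ref_mg: float = 10.0

    def __post_init__(self) -> None:
        for adduct, table in self.offsets.items():
            if table.get("PC", 0.0) != 0.0:
                raise ValidationError(
                    f"PC offset for {adduct!r} must be 0 (calibration reference)"
                )


def apply_adducts(
    resonances: list[ResonanceSpec],
    model: AdductModel,
    adduct: str,
    amount_mg: float = 10.0,
) -> list[ResonanceSpec]:
    """Apply per-class adduct shift offsets; PC is pinned at its centre."""
    if adduct not in model.offsets:
        raise ValidationError(f"unknown adduct {adduct!r}")
    if amount_mg < 0:
        raise ValidationError("amount_mg must be >= 0")
    scale = 1.0
    if adduct in model.scaled_adducts:
        scale = amount_mg / model.scaled_ref_mg
    table = model.offsets[adduct]
    out = []
    for r in resonances:
        off = 0.0 if r.lipid_class == "PC" else table.get(r.lipid_class, 0.0)
        out.append(replace(r, center_ppm=r.center_ppm + off * scale))
    return out
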