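"""Class-level quantification: fitted areas to mol% with reporting rules.

Rules applied, in order:

1. each fitted peak is assigned to a lipid class via the shift library;
2. multi-resonance classes (PE, PG) are summed into one row;
3. on a ``per_molecule`` basis, class areas are divided by the phosphorus
   count per molecule (cardiolipin: 2) before mol% computation;
4. rows below 0.01% of the total integral are excluded (noise threshold);
5. rows with S/N below 3 are excluded by default ("genuine signal" rule);
6. mol% is renormalized over the surviving rows to sum to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .deconvolve import FitResult, PeakModel
from .errors import EmptyReportError, ValidationError
from .shift_library import DEFAULT_TOLERANCE, ShiftLibrary, assign_peak
from .simulate import PHOSPHORUS_PER_MOLECULE

DEFAULT_MIN_FRAC_PCT = 0.01  # % of total integral
DEFAULT_MIN_SNR = 3.0

UNASSIGNED = "UNASSIGNED"

REPORT_COLUMNS = [
    "lipid_class", "center_ppm", "area", "mol_pct", "snr", "flags",
    "basis", "library_version",
]


def compute_snr(peak: PeakModel, sigma: float) -> float:
    """Signal-to-noise ratio of a fitted peak: height / sigma."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    return peak.height / sigma


@dataclass
class QuantRow:
    lipid_class: str
    center: float  # area-weighted mean centre of the constituent peaks, ppm
    area: float
    mol_pct: float
    snr: float
    flags: set[str] = field(default_factory=set)
    peaks: list[PeakModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mol_pct < 0:
            raise ValidationError("mol_pct must be >= 0")


@dataclass
class QuantReport:
    rows: list[QuantRow]
    basis: str
    total_area: float  # pre-filter total (per-phosphorus scale)
    noise_sigma: float
    excluded_rows: list[QuantRow] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rows:
            total = sum(r.mol_pct for r in self.rows)
            if abs(total - 100.0) > 1e-6:
                raise ValidationError(
                    f"mol_pct over reported rows sums to {total!r}, expected 100"
                )

    def row(self, lipid_class: str) -> QuantRow | None:
        for r in self.rows:
            if r.lipid_class == lipid_class:
                return r
        return None

    def mol_pct(self, lipid_class: str) -> float:
        r = self.row(lipid_class)
        return r.mol_pct if r else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        recs = [
            {
                "lipid_class": r.lipid_class,
                "center_ppm": r.center,
                "area": r.area,
                "mol_pct": r.mol_pct,
                "snr": r.snr,
                "flags": ";".join(sorted(r.flags)),
                "basis": self.basis,
                "library_version": self.provenance.get("library_version", ""),
            }
            for r in self.rows
        ]
        return pd.DataFrame(recs, columns=REPORT_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "basis": self.basis,
            "total_area": self.total_area,
            "noise_sigma": self.noise_sigma,
            "provenance": self.provenance,
            "rows": self.to_dataframe().to_dict(orient="records"),
            "excluded": [
                {
                    "lipid_class": r.lipid_class,
                    "center_ppm": r.center,
                    "area": r.area,
                    "snr": r.snr,
                    "flags": ";".join(sorted(r.flags)),
                }
                for r in self.excluded_rows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def apply_reporting_filters(
    rows: list[QuantRow],
    min_frac_pct: float = DEFAULT_MIN_FRAC_PCT,
    min_snr: float = DEFAULT_MIN_SNR,
    keep_low_snr: bool = False,
) -> tuple[list[QuantRow], list[QuantRow]]:
    """Split rows into (reported, excluded) and renormalize mol%.

    A row survives the integral filter when its area is at least
    ``min_frac_pct`` percent of the total over all rows, and the presence
    filter when its S/N is at least ``min_snr`` (unless ``keep_low_snr``
    retains it with a ``low_snr`` flag).  mol% is renormalized over the
    survivors.
    """
    if not rows:
        raise EmptyReportError("no rows to filter")
    total = sum(r.area for r in rows)
    if total <= 0:
        raise ValidationError("total area must be > 0")
    kept, excluded = [], []
    for r in rows:
        frac_pct = 100.0 * r.area / total
        out = False
        if frac_pct < min_frac_pct:
            r.flags.add("below_threshold")
            out = True
        if r.snr < min_snr:
            r.flags.add("low_snr")
            if not keep_low_snr:
                out = True
        (excluded if out else kept).append(r)
    if not kept:
        raise EmptyReportError(
            "all rows excluded by the reporting filters "
            f"(min_frac_pct={min_frac_pct}, min_snr={min_snr})"
        )
    surv_total = sum(r.area for r in kept)
    for r in kept:
        r.mol_pct = 100.0 * r.area / surv_total
    for r in excluded:
        r.mol_pct = 0.0
    return kept, excluded


def build_report(
    fit: FitResult,
    library: ShiftLibrary,
    sigma: float,
    basis: str = "per_phosphorus",
    tolerance: float = DEFAULT_TOLERANCE,
    min_frac_pct: float = DEFAULT_MIN_FRAC_PCT,
    min_snr: float = DEFAULT_MIN_SNR,
    keep_low_snr: bool = False,
    allow_unconverged: bool = False,
    provenance: dict | None = None,
) -> QuantReport:
    """Assign fitted peaks, aggregate per class and apply reporting rules.

    ``basis='per_phosphorus'`` reports shares of total phosphorus (what
    the spectrum measures); ``basis='per_molecule'`` divides class areas
    by the phosphorus count per molecule first, so cardiolipin's two 31P
    nuclei count as one molecule.
    """
    if basis not in ("per_phosphorus", "per_molecule"):
        raise ValidationError(f"unknown basis {basis!r}")
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    if not fit.converged and not allow_unconverged:
        raise ValidationError(
            "fit did not converge; pass allow_unconverged=True to override"
        )

    groups: dict[str, list[tuple[PeakModel, bool]]] = {}
    unassigned: list[PeakModel] = []
    for peak in fit.peaks:
        candidates = assign_peak(peak.center, library, tolerance)
        if not candidates:
            unassigned.append(peak)
            continue
        best = candidates[0]
        groups.setdefault(best.lipid_class, []).append((peak, best.ambiguous))

    rows: list[QuantRow] = []
    for cls, members in groups.items():
        peaks = [p for p, _ in members]
        area = sum(p.area for p in peaks)
        if basis == "per_molecule":
            area /= PHOSPHORUS_PER_MOLECULE.get(cls, 1)
        center = sum(p.center * p.area for p in peaks) / sum(p.area for p in peaks)
        snr = max(compute_snr(p, sigma) for p in peaks)
        flags: set[str] = set()
        if any(amb for _, amb in members):
            flags.add("ambiguous_region")
        if any("degenerate" in p.flags for p in peaks):
            flags.add("degenerate_fit")
        rows.append(
            QuantRow(
                lipid_class=cls, center=center, area=area, mol_pct=0.0,
                snr=snr, flags=flags, peaks=peaks,
            )
        )
    for peak in unassigned:
        rows.append(
            QuantRow(
                lipid_class=UNASSIGNED,
                center=peak.center,
                area=peak.area,
                mol_pct=0.0,
                snr=compute_snr(peak, sigma),
                flags={"unassigned"}
                | ({"degenerate_fit"} if "degenerate" in peak.flags else set()),
                peaks=[peak],
            )
        )
    if not rows:
        raise EmptyReportError("fit produced no peaks to report")

    kept, excluded = apply_reporting_filters(
        rows, min_frac_pct=min_frac_pct, min_snr=min_snr, keep_low_snr=keep_low_snr
    )
    kept.sort(key=lambda r: -r.center)
    prov = dict(provenance or {})
    prov.setdefault("library_version", library.version)
    return QuantReport(
        rows=kept,
        basis=basis,
        total_area=sum(r.area for r in rows),
        noise_sigma=sigma,
        excluded_rows=excluded,
        provenance=prov,
    )
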