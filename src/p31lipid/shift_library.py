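"""Chemical-shift library and peak-to-lipid-class assignment.

The packaged library maps ppm intervals (324 MHz 31P, CUBO solvent,
phosphatidylcholine referenced to 0.00 ppm) to phospholipid head-group
classes.  Assignment of a fitted peak centre is interval containment with a
symmetric tolerance; candidates are ranked by distance from the interval
midpoint, with ties broken toward narrower then more upfield intervals.

Intervals overlapping the crowded 0.45-0.60 ppm region carry an ambiguity
flag because PE-plasmalogen, PE, PS and LPC all resonate there.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, ValidationError

#: Crowded region in which several head groups overlap (ppm).
BUSY_REGION: tuple[float, float] = (0.45, 0.60)

#: Default assignment tolerance (ppm); of the order of the achievable
#: separation of close 31P resonances (~0.025 ppm).
DEFAULT_TOLERANCE = 0.02

#: Controlled vocabulary of lipid-class labels.
KNOWN_CLASSES = frozenset(
    {
        "PC", "LPC", "PE", "PE-plasmalogen", "PS", "PA", "LPA",
        "PI", "LPI", "PG", "SM", "CL", "UNK1", "UNK2",
    }
)


@dataclass(frozen=True)
class ShiftEntry:
    """One ppm interval attributed to a lipid class."""

    lipid_class: str
    ppm_low: float
    ppm_high: float
    provenance: str = ""
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.lipid_class:
            raise ValidationError("lipid_class must be non-empty")
        if self.ppm_low > self.ppm_high:
            raise ValidationError(
                f"ppm_low ({self.ppm_low}) > ppm_high ({self.ppm_high})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.ppm_low + self.ppm_high)

    @property
    def width(self) -> float:
        return self.ppm_high - self.ppm_low

    def contains(self, ppm: float, tolerance: float = 0.0) -> bool:
        """True when *ppm* lies inside the interval expanded by *tolerance*."""
        return (self.ppm_low - tolerance) <= ppm <= (self.ppm_high + tolerance)

    def overlaps_busy_region(self) -> bool:
        lo, hi = BUSY_REGION
        return self.ppm_high >= lo and self.ppm_low <= hi


@dataclass
class ShiftLibrary:
    """Ordered set of :class:`ShiftEntry`, sorted downfield-first.

    Exactly one zero-width entry pins the reference class (PC) to 0.00 ppm.
    """

    entries: list[ShiftEntry]
    reference_class: str = "PC"
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries, key=lambda e: (-e.midpoint, e.width, e.lipid_class)
        )
        refs = [
            e
            for e in self.entries
            if e.ppm_low == 0.0 and e.ppm_high == 0.0
            and e.lipid_class == self.reference_class
        ]
        if len(refs) != 1:
            raise ValidationError(
                "library must contain exactly one zero-width entry pinning "
                f"{self.reference_class} to 0.00 ppm (found {len(refs)})"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def classes(self) -> set[str]:
        return {e.lipid_class for e in self.entries}

    def entries_for(self, lipid_class: str) -> list[ShiftEntry]:
        return [e for e in self.entries if e.lipid_class == lipid_class]

    def has_interval(self, ppm_low: float, ppm_high: float, lipid_class: str) -> bool:
        return any(
            e.lipid_class == lipid_class
            and abs(e.ppm_low - ppm_low) < 1e-9
            and abs(e.ppm_high - ppm_high) < 1e-9
            for e in self.entries
        )

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShiftLibrary":
        """Read a library from a TSV file.

        Required columns: lipid_class, ppm_low, ppm_high, provenance,
        ambiguous.  Lines starting with ``#`` are comments; a comment
        containing ``version <v>`` sets the library version.
        """
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"shift library file not found: {path}")
        version = "unversioned"
        rows: list[str] = []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                if "version" in line:
                    version = line.split("version", 1)[1].strip().rstrip(".")
                continue
            if line.strip():
                rows.append(line)
        if not rows:
            raise ConfigurationError(f"shift library file is empty: {path}")
        reader = csv.DictReader(rows, delimiter="\t")
        required = {"lipid_class", "ppm_low", "ppm_high", "provenance", "ambiguous"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConfigurationError(
                f"shift library header must contain {sorted(required)}"
            )
        entries = []
        try:
            for rec in reader:
                entries.append(
                    ShiftEntry(
                        lipid_class=rec["lipid_class"].strip(),
                        ppm_low=float(rec["ppm_low"]),
                        ppm_high=float(rec["ppm_high"]),
                        provenance=rec["provenance"].strip(),
                        ambiguous=rec["ambiguous"].strip().lower()
                        in {"true", "1", "yes"},
                    )
                )
        except (ValueError, KeyError) as exc:
            raise ConfigurationError(f"corrupt shift library {path}: {exc}") from exc
        try:
            return cls(entries=entries, version=version)
        except ValidationError as exc:
            raise ConfigurationError(f"invalid shift library {path}: {exc}") from exc

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# p31lipid 31P chemical-shift library, version {self.version}"]
        lines.append("lipid_class\tppm_low\tppm_high\tprovenance\tambiguous")
        for e in self.entries:
            lines.append(
                f"{e.lipid_class}\t{e.ppm_low!r}\t{e.ppm_high!r}\t"
                f"{e.provenance}\t{'true' if e.ambiguous else 'false'}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Assignment:
    """One candidate class for a peak centre.

    ``quality`` is 1 at the interval midpoint and decays linearly to 0 at
    the edge of the tolerance-expanded interval; ranking by descending
    quality equals ranking by ascending distance from the midpoint.
    """

    lipid_class: str
    quality: float
    ambiguous: bool
    distance_ppm: float
    entry: ShiftEntry = field(compare=False)

    @property
    def alternates(self) -> list[str]:
        """Alternate class labels recorded in the matched entry's provenance."""
        tag = "alternate"
        for part in self.entry.provenance.split(";"):
            part = part.strip()
            if part.startswith(tag) and "=" in part:
                return [a.strip() for a in part.split("=", 1)[1].split(",")]
        return []


def load_default_library() -> ShiftLibrary:
    """Load the packaged shift library (TSV under ``p31lipid/data``)."""
    try:
        ref = importlib.resources.files("p31lipid").joinpath(
            "data/shift_library.tsv"
        )
        with importlib.resources.as_file(ref) as path:
            return ShiftLibrary.from_tsv(path)
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError(
            f"packaged shift library missing or unreadable: {exc}"
        ) from exc


def assign_peak(
    center: float,
    library: ShiftLibrary,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[Assignment]:
    """Rank the library intervals matching a peak centre.

    A peak matches an interval when its centre lies inside the interval
    expanded by *tolerance* on each side.  Matches are ranked by distance
    from the interval midpoint (ascending); ties are broken toward the
    narrower interval and then toward the more upfield (smaller-ppm)
    interval.  The ambiguity flag is set when the matched interval overlaps
    the busy region or when more than one distinct class matches.

    An empty list is a valid no-match result.
    """
    if tolerance < 0:
        raise ValidationError(f"tolerance must be >= 0, got {tolerance}")
    matched = [e for e in library.entries if e.contains(center, tolerance)]
    matched.sort(key=lambda e: (abs(center - e.midpoint), e.width, e.midpoint))
    multi_class = len({e.lipid_class for e in matched}) > 1
    out = []
    for e in matched:
        dist = abs(center - e.midpoint)
        half = 0.5 * e.width + tolerance
        quality = 1.0 if half == 0 else max(0.0, 1.0 - dist / half)
        out.append(
            Assignment(
                lipid_class=e.lipid_class,
                quality=quality,
                ambiguous=e.ambiguous or e.overlaps_busy_region() or multi_class,
                distance_ppm=dist,
                entry=e,
            )
        )
    return out
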