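"""Band definitions and the default heart band library.

The default library holds the resonance Raman bands observed in
532 nm spectra of perfused heart tissue: reduced c-type cytochrome
bands (604, 750, 1310, 1582 cm⁻¹ dominated), reduced b-type bands
(1127, 1300, 1337 cm⁻¹), the myoglobin ν4 oxygenation markers
(1377 cm⁻¹ oMb, 1358 cm⁻¹ dMb) plus the oMb/dMb methine-bridge pairs
(1587/1556 and 1640/1606 cm⁻¹), and the amide-I protein band at
1658 cm⁻¹.  Four bands are species-unique markers: 604 (reduced
c-type), 1337 (reduced b-type), 1377 (oMb ν4) and 1358 (dMb ν4).

In intact tissue the c-type methine band sits at 1310 cm⁻¹ (downshifted
from 1313 cm⁻¹ in purified cytochrome c by overlap with the b-type band
at 1300 cm⁻¹); ``purified_cytochrome_c_library`` uses 1313.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

from .errors import ValidationError

SPECIES = ("cyt_c_red", "cyt_b_red", "cyt_c_ox", "oMb", "dMb", "metMb", "amide_I")

#: centers allowed to carry the species-unique flag
UNIQUE_MARKERS = frozenset({604.0, 1337.0, 1377.0, 1358.0})


@dataclass(frozen=True)
class Band:
    """One Raman band: a named Lorentzian at a fixed center.

    ``window`` is the half-width (cm⁻¹) of the search interval used by
    height-mode quantification; ``fwhm`` the nominal Lorentzian full
    width at half maximum used by fit-mode quantification.
    """

    name: str
    center: float
    window: float = 8.0
    fwhm: float = 14.0
    species: str = "oMb"
    unique: bool = False

    def __post_init__(self) -> None:
        if not (520.0 <= self.center <= 1750.0):
            raise ValidationError(f"band {self.name}: center {self.center} outside [520, 1750]")
        if self.window <= 0:
            raise ValidationError(f"band {self.name}: window must be > 0")
        if self.fwhm <= 0:
            raise ValidationError(f"band {self.name}: fwhm must be > 0")
        if self.species not in SPECIES:
            raise ValidationError(
                f"band {self.name}: species {self.species!r} not one of {SPECIES}"
            )
        if self.unique and self.center not in UNIQUE_MARKERS:
            raise ValidationError(
                f"band {self.name}: unique flag allowed only at "
                f"{sorted(UNIQUE_MARKERS)} cm⁻¹"
            )


class BandLibrary:
    """An ordered, name- and center-unique collection of bands."""

    def __init__(self, bands) -> None:
        bands = tuple(bands)
        names = [b.name for b in bands]
        centers = [b.center for b in bands]
        if len(set(names)) != len(names):
            raise ValidationError("band names must be unique")
        if len(set(centers)) != len(centers):
            raise ValidationError("band centers must be unique")
        self.bands = tuple(sorted(bands, key=lambda b: b.center))
        self._by_name = {b.name: b for b in self.bands}
        self._by_center = {b.center: b for b in self.bands}

    def __iter__(self) -> Iterator[Band]:
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __getitem__(self, key) -> Band:
        if isinstance(key, str):
            return self._by_name[key]
        return self._by_center[float(key)]

    def __contains__(self, key) -> bool:
        if isinstance(key, str):
            return key in self._by_name
        return float(key) in self._by_center

    @property
    def centers(self) -> tuple[float, ...]:
        return tuple(b.center for b in self.bands)

    def in_region(self, lo: float, hi: float) -> "BandLibrary":
        """Bands whose centers fall in the closed interval [lo, hi]."""
        return BandLibrary(b for b in self.bands if lo <= b.center <= hi)

    def clusters(self, max_gap: float = 40.0) -> list["BandLibrary"]:
        """Partition into groups of mutually overlapping bands.

        Consecutive bands closer than ``max_gap`` cm⁻¹ are grouped so
        that blended regions (1300–1377 and 1556–1658 cm⁻¹) are
        decomposed jointly while isolated bands stay alone.
        """
        groups: list[list[Band]] = [[self.bands[0]]]
        for band in self.bands[1:]:
            if band.center - groups[-1][-1].center <= max_gap:
                groups[-1].append(band)
            else:
                groups.append([band])
        return [BandLibrary(g) for g in groups]

    @classmethod
    def from_csv(cls, path) -> "BandLibrary":
        """Load a library from CSV columns name,center,window,fwhm,species,unique."""
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise ValidationError(f"{path}: empty band library")
        bands = [
            Band(
                name=r["name"],
                center=float(r["center"]),
                window=float(r["window"]),
                fwhm=float(r["fwhm"]),
                species=r["species"],
                unique=str(r["unique"]).strip() in ("1", "true", "True"),
            )
            for r in rows
        ]
        return cls(bands)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "center", "window", "fwhm", "species", "unique"])
            for b in self.bands:
                writer.writerow(
                    [b.name, f"{b.center:g}", f"{b.window:g}", f"{b.fwhm:g}",
                     b.species, int(b.unique)]
                )


def default_library() -> BandLibrary:
    """The heart band library shipped with the package (14 bands)."""
    src = resources.files("cardioraman").joinpath("data/band_library.csv")
    with resources.as_file(src) as path:
        return BandLibrary.from_csv(Path(path))


def purified_cytochrome_c_library() -> BandLibrary:
    """Default library with the c-type methine band at 1313 cm⁻¹.

    For spectra of purified cytochrome c, where no b-type band at
    1300 cm⁻¹ overlaps and the peak sits at its intrinsic position.
    """
    lib = default_library()
    bands = [
        replace(b, center=1313.0) if b.center == 1310.0 else b for b in lib
    ]
    return BandLibrary(bands)
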