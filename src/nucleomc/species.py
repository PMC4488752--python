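"""Hard-sphere species and the pairwise exclusion table.

The model contains two kinds of DNA bead sharing each plectoneme-rod vertex:
a small *red* bead that carries DNA-DNA excluded volume, and a larger co-located
*gray* bead that is invisible to other DNA beads but excludes ribosomal
particles (it stands in for the volume of the plectoneme seen by a ribosome).
Ribosomal species (70S, and the dissociated 30S/50S subunits) exclude each
other and the gray beads.  There are no attractive interactions anywhere in
the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical species order; integer codes index the exclusion matrix.
SPECIES_NAMES = ("dna_red", "dna_gray", "r70S", "r30S", "r50S", "rnap", "tracer")
SPECIES_CODE = {name: i for i, name in enumerate(SPECIES_NAMES)}

#: Default hard radii in nm.  The 70S radius reproduces the ~0.03 um^3 total
#: volume of 7,500 ribosomes; the subunit radii are chosen so that
#: V(30S) + V(50S) matches V(70S) to better than 1%; the RNAP radius
#: reproduces the ~0.003 um^3 total volume of 5,000 copies.  The DNA bead
#: radii and rod length are plectoneme-scale conventions, exposed in config.
DEFAULT_RADII = {
    "dna_red": 12.0,
    "dna_gray": 25.0,
    "r70S": 10.0,
    "r30S": 7.0,
    "r50S": 8.7,
    "rnap": 5.2,
    "tracer": 5.0,
}

#: Default plectoneme rod length in nm (distance between bonded DNA beads).
DEFAULT_ROD_LENGTH = 86.0

#: Default polysome joint length in nm (bonded 70S beads in contact).
DEFAULT_JOINT_LENGTH = 20.0


@dataclass(frozen=True)
class Species:
    """A hard-sphere species: name, radius (nm) and exclusion class."""

    name: str
    radius: float
    exclusion_class: str

    def __post_init__(self) -> None:
        if self.name not in SPECIES_CODE:
            raise ValueError(f"unknown species {self.name!r}")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    def volume_nm3(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius**3


_EXCLUSION_CLASS = {
    "dna_red": "dna",
    "dna_gray": "plectoneme_envelope",
    "r70S": "ribosome",
    "r30S": "ribosome",
    "r50S": "ribosome",
    "rnap": "ribosome",
    "tracer": "phantom",
}


def make_species_table(radii: dict | None = None) -> dict[str, Species]:
    """Species registry with (optionally overridden) radii.

    Overrides must keep ``dna_gray`` at least as large as ``dna_red``.
    """
    r = dict(DEFAULT_RADII)
    if radii:
        unknown = set(radii) - set(r)
        if unknown:
            raise ValueError(f"unknown species in radii override: {sorted(unknown)}")
        r.update(radii)
    if r["dna_gray"] < r["dna_red"]:
        raise ValueError(
            f"dna_gray radius ({r['dna_gray']}) must be >= dna_red radius "
            f"({r['dna_red']})"
        )
    return {n: Species(n, r[n], _EXCLUSION_CLASS[n]) for n in SPECIES_NAMES}


class ExclusionMatrix:
    """Symmetric boolean table: does a given species pair exclude?

    The default pattern:

    * red-red: yes (DNA-DNA excluded volume);
    * gray vs red or gray: no (gray beads are invisible to DNA);
    * gray vs any ribosomal species (70S/30S/50S/rnap): yes;
    * ribosomal vs ribosomal: yes;
    * tracer: excludes nothing (phantom test particle, wall-confined only).
    """

    def __init__(self, table: np.ndarray | None = None):
        if table is None:
            table = self._default_table()
        table = np.asarray(table, dtype=bool)
        n = len(SPECIES_NAMES)
        if table.shape != (n, n):
            raise ValueError(f"exclusion table must be {n}x{n}")
        if not np.array_equal(table, table.T):
            raise ValueError("exclusion table must be symmetric")
        self.table = table

    @staticmethod
    def _default_table() -> np.ndarray:
        n = len(SPECIES_NAMES)
        t = np.zeros((n, n), dtype=bool)
        ribo = [SPECIES_CODE[s] for s in ("r70S", "r30S", "r50S", "rnap")]
        red = SPECIES_CODE["dna_red"]
        gray = SPECIES_CODE["dna_gray"]
        t[red, red] = True
        for a in ribo:
            t[gray, a] = t[a, gray] = True
            for b in ribo:
                t[a, b] = True
        return t

    def excludes(self, a: str | int, b: str | int) -> bool:
        ia = SPECIES_CODE[a] if isinstance(a, str) else a
        ib = SPECIES_CODE[b] if isinstance(b, str) else b
        return bool(self.table[ia, ib])

    def validate_default_pattern(self) -> None:
        """Assert the canonical exclusion pattern (used at build time)."""
        assert self.excludes("dna_red", "dna_red")
        assert not self.excludes("dna_gray", "dna_red")
        assert not self.excludes("dna_gray", "dna_gray")
        for r in ("r70S", "r30S", "r50S"):
            assert self.excludes("dna_gray", r)
            for r2 in ("r70S", "r30S", "r50S"):
                assert self.excludes(r, r2)
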