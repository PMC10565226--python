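"""Study design: stimulus catalogue, presentation orders, screen geometry and AOIs.

The experiment shows pairs of photographs of the same snake specimen — one in a
threatening posture, one relaxed — side by side on a 1366x768 screen.  Every
species exists in two horizontally mirrored slide versions (threat on the left /
on the right) so that lateral gaze bias cancels when the pair is averaged.
Three rectangular areas of interest (AOIs) partition the informative screen
regions: a left and a right stimulus area (37% of the screen each) and a small
central area (1%) around the fixation-cross location.

Coordinate convention: origin at the top-left corner, x rightward, y downward,
pixel units.  Gaze coordinates are continuous; the horizontal mirror of a
continuous coordinate is ``width - x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stimulus",
    "ScreenGeometry",
    "Rect",
    "AoiSet",
    "PresentationOrder",
    "DEFAULT_CATALOGUE",
    "build_stimulus_set",
    "build_presentation_orders",
    "make_aoi_set",
    "assign_point",
    "mirror_x",
]

MORPHOTYPES = ("cobra", "viper", "other")

#: family -> morphotype used in the statistical models
_FAMILY_TO_MORPHOTYPE = {
    "cobra": "cobra",
    "viper": "viper",
    "python": "other",
    "colubrid": "other",
}

#: Default catalogue: 20 species as (species_id, family).
#: 8 cobra-morphotype elapids, 8 vipers, 2 pythons and 2 colubrids.
DEFAULT_CATALOGUE: tuple[tuple[str, str], ...] = (
    ("naja_haje", "cobra"),
    ("naja_nubiae", "cobra"),
    ("naja_pallida", "cobra"),
    ("naja_annulifera", "cobra"),
    ("naja_melanoleuca", "cobra"),
    ("naja_mossambica", "cobra"),
    ("hemachatus_haemachatus", "cobra"),
    ("dendroaspis_polylepis", "cobra"),
    ("bitis_arietans", "viper"),
    ("echis_pyramidum", "viper"),
    ("cerastes_cerastes", "viper"),
    ("bitis_gabonica", "viper"),
    ("daboia_palaestinae", "viper"),
    ("pseudocerastes_fieldi", "viper"),
    ("montivipera_xanthina", "viper"),
    ("macrovipera_lebetina", "viper"),
    ("python_sebae", "python"),
    ("python_regius", "python"),
    ("dispholidus_typus", "colubrid"),
    ("telescopus_dhara", "colubrid"),
)

_EXPECTED_FAMILY_COUNTS = {"cobra": 8, "viper": 8, "python": 2, "colubrid": 2}


@dataclass(frozen=True)
class Stimulus:
    """One slide version: a species with the threatening posture on one side."""

    species_id: str
    family: str          # cobra | viper | python | colubrid
    side_of_threat: str  # "left" | "right"
    is_practise: bool = False

    @property
    def morphotype(self) -> str:
        return _FAMILY_TO_MORPHOTYPE.get(self.family, "other")

    @property
    def version_id(self) -> str:
        suffix = "L" if self.side_of_threat == "left" else "R"
        return f"{self.species_id}_{suffix}"

    def mirrored(self) -> "Stimulus":
        """The horizontally flipped slide version (threat side swapped)."""
        other = "right" if self.side_of_threat == "left" else "left"
        return Stimulus(self.species_id, self.family, other, self.is_practise)


@dataclass(frozen=True)
class ScreenGeometry:
    width_px: int = 1366
    height_px: int = 768
    viewing_distance_cm: float = 60.0
    dispersion_radius_px: float = 23.0  # 0.5 degrees of visual angle

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.dispersion_radius_px <= 0:
            raise ValueError("dispersion radius must be positive")


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [x0, x1) x [y0, y1) in pixels."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("rectangle must have positive extent")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass(frozen=True)
class AoiSet:
    """The three disjoint interest areas: left stimulus, right stimulus, centre."""

    left: Rect
    right: Rect
    central: Rect
    screen: ScreenGeometry

    def __post_init__(self) -> None:
        rects = {"left": self.left, "right": self.right, "central": self.central}
        names = list(rects)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if rects[a].intersects(rects[b]):
                    raise ValueError(f"AOIs {a!r} and {b!r} overlap")

    def assign(self, x: float, y: float) -> str:
        return assign_point(self, x, y)

    def assign_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised AOI labelling; returns an array of {left,right,central,none}."""
        labels = np.full(np.shape(x), "none", dtype="<U7")
        for name, r in (("left", self.left), ("right", self.right),
                        ("central", self.central)):
            inside = (x >= r.x0) & (x < r.x1) & (y >= r.y0) & (y < r.y1)
            labels[inside] = name
        return labels


def assign_point(aois: AoiSet, x: float, y: float) -> str:
    """Label a gaze point with the unique AOI containing it, or ``"none"``.

    Out-of-screen and non-finite points map to ``"none"``.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        return "none"
    if aois.left.contains(x, y):
        return "left"
    if aois.right.contains(x, y):
        return "right"
    if aois.central.contains(x, y):
        return "central"
    return "none"


def mirror_x(screen: ScreenGeometry, x):
    """Horizontal mirror of a continuous gaze coordinate about the screen midline."""
    return screen.width_px - np.asarray(x, dtype=float)


def make_aoi_set(
    screen: ScreenGeometry,
    lateral_fraction: float = 0.37,
    central_fraction: float = 0.01,
) -> AoiSet:
    """Construct the three AOIs from a screen geometry.

    The left AOI is a full-height rectangle at the left edge with width
    ``round(lateral_fraction * width)``; the right AOI is its mirror at the
    right edge; the central AOI is a square of area ``central_fraction`` of
    the screen, centred on the screen centre (the fixation-cross location).
    """
    w, h = screen.width_px, screen.height_px
    lat_w = int(round(lateral_fraction * w))
    side = int(round(math.sqrt(central_fraction * w * h)))
    if side < 1 or lat_w < 1:
        raise ValueError("screen too small for the requested AOI areas")
    cx0 = (w - side) // 2
    cy0 = (h - side) // 2
    left = Rect(0, 0, lat_w, h)
    right = Rect(w - lat_w, 0, w, h)
    central = Rect(cx0, cy0, cx0 + side, cy0 + side)
    if left.intersects(central) or right.intersects(central) or left.intersects(right):
        raise ValueError("screen too small: AOIs at the requested areas overlap")
    return AoiSet(left=left, right=right, central=central, screen=screen)


def build_stimulus_set(
    catalogue=None,
    allow_nonstandard_counts: bool = False,
) -> list[Stimulus]:
    """Build the full stimulus set: both mirror versions of every species plus
    one practise slide.

    Parameters
    ----------
    catalogue
        Iterable of ``(species_id, family)`` pairs; defaults to the 20-species
        study catalogue (8 cobras, 8 vipers, 2 pythons, 2 colubrids).
    allow_nonstandard_counts
        Permit scaled-down catalogues (used by the simulator); otherwise the
        family counts must match the study design exactly.
    """
    if catalogue is None:
        catalogue = DEFAULT_CATALOGUE
    catalogue = list(catalogue)
    ids = [sid for sid, _ in catalogue]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species_id in catalogue")
    for sid, fam in catalogue:
        if fam not in _FAMILY_TO_MORPHOTYPE:
            raise ValueError(f"unknown family {fam!r} for species {sid!r}")
    counts = {f: sum(1 for _, fam in catalogue if fam == f)
              for f in _FAMILY_TO_MORPHOTYPE}
    if counts != _EXPECTED_FAMILY_COUNTS and not allow_nonstandard_counts:
        raise ValueError(
            f"catalogue family counts {counts} differ from the study design "
            f"{_EXPECTED_FAMILY_COUNTS}; pass allow_nonstandard_counts=True "
            "to scale down"
        )
    stimuli: list[Stimulus] = []
    for sid, fam in catalogue:
        stimuli.append(Stimulus(sid, fam, "left"))
        stimuli.append(Stimulus(sid, fam, "right"))
    stimuli.append(Stimulus("practise", "colubrid", "left", is_practise=True))
    return stimuli


def stimuli_frame(stimuli: list[Stimulus]):
    """Tabular view of a stimulus set (one row per slide version)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "stimulus_version_id": [s.version_id for s in stimuli],
            "species_id": [s.species_id for s in stimuli],
            "family": [s.family for s in stimuli],
            "morphotype": [s.morphotype for s in stimuli],
            "side_of_threat": [s.side_of_threat for s in stimuli],
            "is_practise": [s.is_practise for s in stimuli],
        }
    )


@dataclass(frozen=True)
class PresentationOrder:
    order_id: int
    slide_sequence: tuple[str, ...] = field(default_factory=tuple)  # version ids


def _split_halves(species_by_family: dict[str, list[str]], rng: np.random.Generator):
    """Split each family's species across the two 20-slide halves.

    At the study's counts the first half holds 4 cobras, 4 vipers, 1 python
    and 1 colubrid (both versions of each), the second half the rest.
    """
    first: list[str] = []
    second: list[str] = []
    for fam in sorted(species_by_family):
        sp = sorted(species_by_family[fam])
        k = len(sp) // 2
        chosen = rng.permutation(len(sp))
        first.extend(sp[i] for i in sorted(chosen[:k]))
        second.extend(sp[i] for i in sorted(chosen[k:]))
    return first, second


def build_presentation_orders(
    stimuli: list[Stimulus], seed: int
) -> list[PresentationOrder]:
    """Construct the four presentation orders.

    Order 1 is a seeded semi-random sequence in which half of the species (both
    versions of each) appear before the other half; order 2 is order 1 reversed;
    orders 3 and 4 are orders 1 and 2 with every slide replaced by its mirror
    version.
    """
    experimental = [s for s in stimuli if not s.is_practise]
    by_id = {s.version_id: s for s in experimental}
    species_by_family: dict[str, list[str]] = {}
    for s in experimental:
        species_by_family.setdefault(s.family, [])
        if s.species_id not in species_by_family[s.family]:
            species_by_family[s.family].append(s.species_id)
    n_species = sum(len(v) for v in species_by_family.values())
    if n_species < 4:
        raise ValueError("need at least 2 species per presentation half")

    rng = np.random.default_rng(seed)
    first_sp, second_sp = _split_halves(species_by_family, rng)

    def half_sequence(species: list[str]) -> list[str]:
        versions = [f"{sid}_{side}" for sid in species for side in ("L", "R")]
        order = rng.permutation(len(versions))
        return [versions[i] for i in order]

    order1 = half_sequence(first_sp) + half_sequence(second_sp)
    order2 = list(reversed(order1))

    def mirror_seq(seq: list[str]) -> list[str]:
        return [by_id[v].mirrored().version_id for v in seq]

    orders = [order1, order2, mirror_seq(order1), mirror_seq(order2)]
    return [
        PresentationOrder(order_id=i + 1, slide_sequence=tuple(seq))
        for i, seq in enumerate(orders)
    ]
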