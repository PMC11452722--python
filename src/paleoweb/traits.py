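"""Closed trait vocabularies and the per-guild trait profile.

The ecospace follows the classic motility / tiering / feeding scheme used
for marine fossil communities, extended with a categorical body-size class
and an optional calcification level.  All vocabularies are closed: any
string not in them (after normalisation) is rejected at the boundary, so
everything downstream can assume clean categories.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Optional

MOTILITY = ("fast", "slow", "facultative", "non-motile")
TIERING = (
    "pelagic",
    "erect",
    "surficial",
    "semi-infaunal",
    "shallow-infaunal",
    "deep-infaunal",
)
FEEDING = ("predator", "suspension-feeder", "deposit-feeder", "mining", "grazer")
SIZE_CLASSES = ("tiny", "small", "medium", "large", "very-large", "gigantic")
CALCIFICATION = ("light", "moderate", "heavy")
COARSE_TIERING = ("pelagic", "epifaunal", "infaunal")
INTERVALS = ("pre", "post", "early_recovery", "late_recovery")

#: fine tiering -> coarse tiering (pelagic / epifaunal / infaunal)
COARSE_TIERING_MAP = {
    "pelagic": "pelagic",
    "erect": "epifaunal",
    "surficial": "epifaunal",
    "semi-infaunal": "infaunal",
    "shallow-infaunal": "infaunal",
    "deep-infaunal": "infaunal",
}

#: motility speed rank, fastest first (used by rules and scenario orderings)
MOTILITY_RANK = {"fast": 3, "slow": 2, "facultative": 1, "non-motile": 0}

#: upper bounds (mm, longest axis) of each size class; gigantic is open-ended
SIZE_CLASS_BOUNDS_MM = {
    "tiny": (0.0, 10.0),
    "small": (10.0, 50.0),
    "medium": (50.0, 100.0),
    "large": (100.0, 300.0),
    "very-large": (300.0, 500.0),
    "gigantic": (500.0, float("inf")),
}

_ALIASES = {
    "nonmotile": "non-motile",
    "non-motile": "non-motile",
    "suspension": "suspension-feeder",
    "suspension-feeding": "suspension-feeder",
    "deposit": "deposit-feeder",
    "deposit-feeding": "deposit-feeder",
    "miner": "mining",
    "verylarge": "very-large",
    "semiinfaunal": "semi-infaunal",
    "shallowinfaunal": "shallow-infaunal",
    "deepinfaunal": "deep-infaunal",
}

_VOCABULARIES = {
    "motility": MOTILITY,
    "tiering": TIERING,
    "feeding": FEEDING,
    "size_class": SIZE_CLASSES,
    "calcification": CALCIFICATION,
}


class VocabularyError(ValueError):
    """A trait string is not in its closed vocabulary."""


def normalize_token(value: str) -> str:
    """Lower-case, strip diacritics and unify separators to hyphens."""
    s = unicodedata.normalize("NFKD", str(value))
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.strip().casefold()
    for sep in (" ", "_", "/"):
        s = s.replace(sep, "-")
    while "--" in s:
        s = s.replace("--", "-")
    return _ALIASES.get(s, s)


def validate_trait(field: str, value: str) -> str:
    """Normalise ``value`` and check it against ``field``'s vocabulary."""
    token = normalize_token(value)
    vocab = _VOCABULARIES[field]
    if token not in vocab:
        raise VocabularyError(
            f"unknown {field} value {value!r} (normalised {token!r}); "
            f"expected one of {vocab}"
        )
    return token


def size_class_from_mm(length_mm: float) -> str:
    """Categorical size class for a longest-axis measurement in mm.

    Boundaries: tiny <=10, small >10-50, medium >50-100, large >100-300,
    very-large >300-500, gigantic >500.
    """
    if length_mm < 0:
        raise ValueError("length must be non-negative")
    for cls in SIZE_CLASSES:
        if length_mm <= SIZE_CLASS_BOUNDS_MM[cls][1]:
            return cls
    return "gigantic"  # unreachable; gigantic bound is +inf


@dataclass(frozen=True)
class TraitProfile:
    """Immutable trait combination defining one trophic guild.

    ``calcification`` is optional: trace fossils and fish commonly lack a
    defensible calcification level.
    """

    motility: str
    tiering: str
    feeding: str
    size_class: str
    calcification: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "motility", validate_trait("motility", self.motility))
        object.__setattr__(self, "tiering", validate_trait("tiering", self.tiering))
        object.__setattr__(self, "feeding", validate_trait("feeding", self.feeding))
        object.__setattr__(
            self, "size_class", validate_trait("size_class", self.size_class)
        )
        if self.calcification is not None and str(self.calcification).strip() != "":
            object.__setattr__(
                self,
                "calcification",
                validate_trait("calcification", self.calcification),
            )
        else:
            object.__setattr__(self, "calcification", None)

    @property
    def coarse_tiering(self) -> str:
        return COARSE_TIERING_MAP[self.tiering]

    @property
    def coarse_motility(self) -> str:
        # same four levels as motility; kept as an explicit accessor because
        # extinction scenarios address the coarse axis by name
        return self.motility

    @property
    def size_index(self) -> int:
        return SIZE_CLASSES.index(self.size_class)

    @property
    def motility_rank(self) -> int:
        return MOTILITY_RANK[self.motility]

    @property
    def calcification_index(self) -> Optional[int]:
        if self.calcification is None:
            return None
        return CALCIFICATION.index(self.calcification)

    def key(self) -> tuple:
        return (
            self.motility,
            self.tiering,
            self.feeding,
            self.size_class,
            self.calcification or "",
        )

    def guild_id(self) -> str:
        """Deterministic readable identifier; equal traits -> equal id."""
        calc = self.calcification or "none"
        return ".".join(
            (self.motility, self.tiering, self.feeding, self.size_class, calc)
        )

    def as_dict(self) -> dict:
        return {
            "motility": self.motility,
            "tiering": self.tiering,
            "feeding": self.feeding,
            "size_class": self.size_class,
            "calcification": self.calcification,
        }
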