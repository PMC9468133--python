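"""FDI tooth identifiers and the landmark naming protocol.

The data model follows standard dental notation: two-digit FDI codes where
the first digit is the quadrant (1 = upper right, 2 = upper left, 3 = lower
left, 4 = lower right) and the second the position from the midline.  Only
positions 1-7 are used (second molars inclusive, no wisdom teeth), giving 28
teeth, 14 per jaw.

Each tooth carries a fixed set of labeled landmarks:

* crown landmarks, placed on cusps, incisal edges and central fissures of a
  surface scan -- their number depends on tooth class;
* exactly five root landmarks LM-1..LM-5 taken from CBCT: LM-1 at the
  cemento-enamel junction line (CEJL) in the root-canal center, LM-2..LM-4
  each 2 mm further apically along the canal, LM-5 at the root apex.
  Multi-rooted teeth are treated as having one merged root.

The default protocol allocates 130 crown landmarks over the 28 teeth and
5 x 28 = 140 root landmarks, i.e. 270 labels per fully dentate individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

__all__ = [
    "Jaw",
    "ToothClass",
    "LandmarkKind",
    "ToothId",
    "LandmarkLabel",
    "LandmarkProtocol",
    "make_default_protocol",
    "ALL_FDI_CODES",
    "ROOT_LANDMARKS_PER_TOOTH",
]

ROOT_LANDMARKS_PER_TOOTH = 5


class Jaw(str, Enum):
    UPPER = "upper"
    LOWER = "lower"


class ToothClass(str, Enum):
    INCISOR = "incisor"
    CANINE = "canine"
    PREMOLAR = "premolar"
    MOLAR = "molar"


class LandmarkKind(str, Enum):
    CROWN = "crown"
    ROOT = "root"


#: All 28 valid FDI codes (positions 1-7 in quadrants 1-4), midline outward.
ALL_FDI_CODES: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 8)
)

_POSITION_CLASS = {
    1: ToothClass.INCISOR,
    2: ToothClass.INCISOR,
    3: ToothClass.CANINE,
    4: ToothClass.PREMOLAR,
    5: ToothClass.PREMOLAR,
    6: ToothClass.MOLAR,
    7: ToothClass.MOLAR,
}


@dataclass(frozen=True, order=True)
class ToothId:
    """A single tooth in two-digit FDI notation (positions 1-7 only)."""

    fdi_code: int

    def __post_init__(self) -> None:
        if self.fdi_code not in ALL_FDI_CODES:
            raise ValueError(
                f"invalid FDI code {self.fdi_code}: expected quadrant 1-4, "
                "position 1-7 (wisdom teeth are excluded)"
            )

    @property
    def quadrant(self) -> int:
        return self.fdi_code // 10

    @property
    def position(self) -> int:
        return self.fdi_code % 10

    @property
    def jaw(self) -> Jaw:
        return Jaw.UPPER if self.quadrant in (1, 2) else Jaw.LOWER

    @property
    def tooth_class(self) -> ToothClass:
        return _POSITION_CLASS[self.position]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return str(self.fdi_code)


@dataclass(frozen=True, order=True)
class LandmarkLabel:
    """One labeled landmark: (tooth, crown|root, 1-based index).

    Root index k corresponds to the landmark LM-k of that tooth.
    The dataclass ordering (fdi, kind, index) is *not* the canonical
    vectorization order; use :attr:`LandmarkProtocol.label_order`.
    """

    tooth: ToothId
    kind: LandmarkKind
    index: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"landmark index must be >= 1, got {self.index}")
        if self.kind is LandmarkKind.ROOT and self.index > ROOT_LANDMARKS_PER_TOOTH:
            raise ValueError(
                f"root landmark index must be 1..{ROOT_LANDMARKS_PER_TOOTH}, "
                f"got {self.index}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.tooth.fdi_code}_{self.kind.value}_{self.index}"


def _default_crown_counts() -> dict[ToothId, int]:
    # Upper jaw: molars 6, premolars 5, canines 3, incisors 3  (62 total).
    # Lower jaw: molars 7 (extra distobuccal cusp on first molars taken as
    # the class norm), premolars 5, canines 3, central incisors 4, lateral
    # incisors 3  (68 total).  Sums to 130 crown landmarks.
    counts: dict[ToothId, int] = {}
    for code in ALL_FDI_CODES:
        tooth = ToothId(code)
        cls = tooth.tooth_class
        if tooth.jaw is Jaw.UPPER:
            n = {ToothClass.MOLAR: 6, ToothClass.PREMOLAR: 5,
                 ToothClass.CANINE: 3, ToothClass.INCISOR: 3}[cls]
        else:
            if cls is ToothClass.INCISOR:
                n = 4 if tooth.position == 1 else 3
            else:
                n = {ToothClass.MOLAR: 7, ToothClass.PREMOLAR: 5,
                     ToothClass.CANINE: 3}[cls]
        counts[tooth] = n
    return counts


@dataclass(frozen=True)
class LandmarkProtocol:
    """Per-tooth landmark allocation and the canonical label order.

    ``label_order`` is deterministic: teeth sorted by FDI code, crown
    landmarks before root landmarks, indices ascending.  All vectorized
    representations of a dentition use this order.
    """

    crown_counts: Mapping[ToothId, int]
    root_count_per_tooth: int = ROOT_LANDMARKS_PER_TOOTH
    _order: tuple[LandmarkLabel, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for tooth, n in self.crown_counts.items():
            if n < 1:
                raise ValueError(f"crown count for tooth {tooth} must be >= 1")
        order = []
        for tooth in sorted(self.crown_counts):
            for i in range(1, self.crown_counts[tooth] + 1):
                order.append(LandmarkLabel(tooth, LandmarkKind.CROWN, i))
            for i in range(1, self.root_count_per_tooth + 1):
                order.append(LandmarkLabel(tooth, LandmarkKind.ROOT, i))
        object.__setattr__(self, "_order", tuple(order))

    # -- protocol queries -------------------------------------------------

    @property
    def teeth(self) -> tuple[ToothId, ...]:
        return tuple(sorted(self.crown_counts))

    def teeth_of_jaw(self, jaw: Jaw) -> tuple[ToothId, ...]:
        return tuple(t for t in self.teeth if t.jaw is jaw)

    @property
    def label_order(self) -> tuple[LandmarkLabel, ...]:
        return self._order

    def labels_of_jaw(self, jaw: Jaw) -> tuple[LandmarkLabel, ...]:
        return tuple(l for l in self._order if l.tooth.jaw is jaw)

    def labels_of_tooth(self, tooth: ToothId) -> tuple[LandmarkLabel, ...]:
        if tooth not in self.crown_counts:
            raise KeyError(f"tooth {tooth} not in protocol")
        return tuple(l for l in self._order if l.tooth == tooth)

    def crown_labels(self) -> tuple[LandmarkLabel, ...]:
        return tuple(l for l in self._order if l.kind is LandmarkKind.CROWN)

    def root_labels(self) -> tuple[LandmarkLabel, ...]:
        return tuple(l for l in self._order if l.kind is LandmarkKind.ROOT)

    @property
    def n_crown(self) -> int:
        return sum(self.crown_counts.values())

    @property
    def n_root(self) -> int:
        return self.root_count_per_tooth * len(self.crown_counts)

    @property
    def n_labels(self) -> int:
        return len(self._order)

    def __contains__(self, label: LandmarkLabel) -> bool:
        if label.tooth not in self.crown_counts:
            return False
        if label.kind is LandmarkKind.CROWN:
            return 1 <= label.index <= self.crown_counts[label.tooth]
        return 1 <= label.index <= self.root_count_per_tooth

    def __iter__(self) -> Iterator[LandmarkLabel]:
        return iter(self._order)

    def content_hash(self) -> str:
        """Stable hash of the full label order, for model-file provenance."""
        import hashlib

        payload = ";".join(str(l) for l in self._order).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def make_default_protocol() -> LandmarkProtocol:
    """The default 270-label protocol: 130 crown + 140 root landmarks."""
    return LandmarkProtocol(crown_counts=_default_crown_counts())
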