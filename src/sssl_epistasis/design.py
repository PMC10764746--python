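"""Core domain types for a single-segment substitution line (SSSL) pyramiding study.

An SSSL carries one donor chromosome segment (one QTL) in an otherwise
uniform recipient background.  A *material* is either the recipient itself,
a single SSSL (heterozygous or homozygous for its donor segment), or a
pyramid combining several segments.  Every downstream stage — simulation,
mixed-model fitting, effect decomposition, network inference — is keyed by
these types.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple

RECIPIENT_ID = "HJX74"


class LocusState(Enum):
    """Substitution state of one locus in a material.

    ABSENT is the recipient allele; HET and HOM are the heterozygous and
    homozygous donor substitutions, conventionally written ``QTL-1`` and
    ``QTL-2``.
    """

    ABSENT = 0
    HET = 1
    HOM = 2

    @property
    def suffix(self) -> str:
        if self is LocusState.HET:
            return "1"
        if self is LocusState.HOM:
            return "2"
        raise ValueError("recipient state has no token suffix")

    @classmethod
    def from_code(cls, code: int) -> "LocusState":
        return cls(int(code))


@dataclass(frozen=True)
class Locus:
    """A substituted QTL region: name plus optional catalog metadata."""

    name: str
    chromosome: Optional[int] = None
    marker_interval: Optional[Tuple[str, str]] = None
    donor: Optional[str] = None


#: Catalog order used for canonical material names.  Heading-date study
#: defaults: Ehd1, OsMADS50, Hd3a, Hd1 (with donor varieties of each line).
DEFAULT_LOCI: Tuple[Locus, ...] = (
    Locus("Ehd1", chromosome=10, donor="IAPAR9"),
    Locus("OsMADS50", chromosome=3, donor="Lemont"),
    Locus("Hd3a", chromosome=6, donor="BG367"),
    Locus("Hd1", chromosome=6, donor="IR64"),
)


def state_token(locus: str, state: LocusState) -> str:
    """Canonical token for one substituted locus, e.g. ``Hd3a-2``."""
    return f"{locus}-{state.suffix}"


@dataclass(frozen=True)
class MaterialGenotype:
    """Per-locus substitution states identifying one material.

    ``states`` holds only the non-ABSENT loci, in catalog order.  Two
    materials with the same state mapping are the same material.
    """

    states: Tuple[Tuple[str, LocusState], ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for locus, state in self.states:
            if locus in seen:
                raise ValueError(f"duplicate locus {locus!r} in material")
            if state is LocusState.ABSENT:
                raise ValueError("states must list substituted loci only")
            seen.add(locus)

    @property
    def material_id(self) -> str:
        if not self.states:
            return RECIPIENT_ID
        return "/".join(state_token(l, s) for l, s in self.states)

    @property
    def order(self) -> int:
        return len(self.states)

    def state_of(self, locus: str) -> LocusState:
        for name, state in self.states:
            if name == locus:
                return state
        return LocusState.ABSENT

    def subsets(self, k: int) -> Iterable["MaterialGenotype"]:
        """All order-``k`` sub-materials (used to accumulate epistatic terms)."""
        for combo in itertools.combinations(self.states, k):
            yield MaterialGenotype(states=combo)

    @classmethod
    def from_mapping(
        cls, states: Mapping[str, LocusState], locus_order: Sequence[str]
    ) -> "MaterialGenotype":
        ordered = tuple(
            (name, states[name])
            for name in locus_order
            if name in states and states[name] is not LocusState.ABSENT
        )
        extra = set(states) - {n for n, _ in ordered} - {
            n for n, s in states.items() if s is LocusState.ABSENT
        }
        if extra:
            raise ValueError(f"loci {sorted(extra)} missing from locus order")
        return cls(states=ordered)


RECIPIENT = MaterialGenotype()


@dataclass(frozen=True)
class PlotRecord:
    """One field plot: (environment, block, material) and its mean heading date."""

    environment: str
    block: str
    material: str
    hd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.hd) and self.hd > 0):
            raise ValueError(
                f"heading date must be finite and positive, got {self.hd!r}"
            )


def enumerate_materials(
    loci: Sequence[Locus], max_order: int
) -> list[MaterialGenotype]:
    """Enumerate the recipient and every pyramid up to ``max_order`` loci.

    Materials are emitted in a deterministic canonical order: by substitution
    order, then by locus combination in catalog order, then HET before HOM at
    each locus.  With four loci and ``max_order=3`` this yields the classic
    65-material design (1 recipient + 8 singles + 24 duals + 32 triples).
    """
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        raise ValueError("duplicate locus names in catalog")
    if not 1 <= max_order <= len(loci):
        raise ValueError("max_order must be between 1 and the number of loci")

    materials: list[MaterialGenotype] = [RECIPIENT]
    for k in range(1, max_order + 1):
        for combo in itertools.combinations(names, k):
            for states in itertools.product(
                (LocusState.HET, LocusState.HOM), repeat=k
            ):
                materials.append(
                    MaterialGenotype(states=tuple(zip(combo, states)))
                )
    return materials


def material_order(m: MaterialGenotype) -> int:
    """Number of substituted (non-recipient) loci carried by a material."""
    return m.order


def parse_material_id(
    material_id: str, locus_names: Sequence[str]
) -> MaterialGenotype:
    """Parse a canonical id like ``Ehd1-1/Hd3a-2`` back into a genotype."""
    if material_id == RECIPIENT_ID:
        return RECIPIENT
    states = {}
    for token in material_id.split("/"):
        locus, sep, code = token.rpartition("-")
        if not sep or code not in ("1", "2"):
            raise ValueError(f"malformed material token {token!r}")
        if locus not in locus_names:
            raise ValueError(f"unknown locus {locus!r} in {material_id!r}")
        states[locus] = LocusState.HET if code == "1" else LocusState.HOM
    return MaterialGenotype.from_mapping(states, locus_names)


def component_class(m: MaterialGenotype) -> str:
    """Which of additive/dominance each locus contributes, e.g. ``d-a``.

    A homozygous segment enters through its additive effect (``a``), a
    heterozygous one through its dominance effect (``d``).
    """
    return "-".join(
        "a" if s is LocusState.HOM else "d" for _, s in m.states
    )
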