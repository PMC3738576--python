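"""Five-region decomposition of BZF/RING-H2 proteins and architecture profiles.

A canonical family member is segmented into five modules anchored on its two
zinc fingers: (I) N-terminus up to the BZF, (II) the BZF itself, (III) the
inter-finger region, (IV) the RING-H2, and (V) the RING-H2 to the C-terminus.
Motif occurrences are then mapped onto regions by their midpoints and each
protein is summarised as an ordered architecture string; proteins with equal
strings share an architecture class.
"""
from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .zf_grammar import ZnMatch

REGION_LABELS = ("I", "II", "III", "IV", "V")


class NotFamilyMemberError(ValueError):
    """Raised when a sequence lacks the RING-H2 anchor required for
    decomposition (a protein without it is not a family member)."""


@dataclass(frozen=True)
class RegionDecomposition:
    """The I-V segmentation of one protein (1-based inclusive bounds).

    ``regions[label]`` is a ``(start, end)`` pair or ``None`` for an empty
    region.  Non-empty regions are ordered and tile ``[1, length]`` without
    overlap.  When no BZF is present, regions I and II are undefined and the
    whole pre-RING segment is carried as an upstream, region-III-like
    interval (``has_bzf`` is False).
    """

    sequence_id: str
    length: int
    regions: dict[str, tuple[int, int] | None]
    has_bzf: bool = True

    def __post_init__(self) -> None:
        prev_end = 0
        for label in REGION_LABELS:
            bounds = self.regions.get(label)
            if bounds is None:
                continue
            start, end = bounds
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"{self.sequence_id}: region {label} bounds {bounds} outside "
                    f"[1, {self.length}]"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.sequence_id}: region {label} overlaps or is out of order"
                )
            prev_end = end

    def region_of(self, position: int) -> str:
        """Region label containing a 1-based position."""
        if not (1 <= position <= self.length):
            raise ValueError(
                f"{self.sequence_id}: position {position} outside [1, {self.length}]"
            )
        for label in REGION_LABELS:
            bounds = self.regions.get(label)
            if bounds is not None and bounds[0] <= position <= bounds[1]:
                return label
        raise ValueError(
            f"{self.sequence_id}: position {position} not covered by any region"
        )

    def nonempty(self) -> list[tuple[str, tuple[int, int]]]:
        return [
            (label, bounds)
            for label in REGION_LABELS
            if (bounds := self.regions.get(label)) is not None
        ]


def _interval(start: int, end: int) -> tuple[int, int] | None:
    return (start, end) if start <= end else None


def decompose(
    sequence_id: str,
    length: int,
    bzf: ZnMatch | None,
    ring: ZnMatch | None,
) -> RegionDecomposition:
    """Segment a protein of ``length`` residues using its finger spans.

    I = [1, bzf.start-1], II = bzf span, III = [bzf.end+1, ring.start-1],
    IV = ring span, V = [ring.end+1, length].  Empty intervals are marked
    empty.  A missing RING-H2 is a hard error; a missing BZF leaves I/II
    undefined and labels the pre-RING segment as III.
    """
    if ring is None:
        raise NotFamilyMemberError(
            f"{sequence_id}: no RING-H2 domain; not a family member"
        )
    if ring.end > length:
        raise ValueError(f"{sequence_id}: RING-H2 span {ring.span} beyond length {length}")
    if bzf is not None:
        if bzf.end >= ring.start:
            raise ValueError(
                f"{sequence_id}: BZF span {bzf.span} overlaps or follows "
                f"RING-H2 span {ring.span}"
            )
        regions = {
            "I": _interval(1, bzf.start - 1),
            "II": (bzf.start, bzf.end),
            "III": _interval(bzf.end + 1, ring.start - 1),
            "IV": (ring.start, ring.end),
            "V": _interval(ring.end + 1, length),
        }
        return RegionDecomposition(sequence_id, length, regions, has_bzf=True)
    regions = {
        "I": None,
        "II": None,
        "III": _interval(1, ring.start - 1),
        "IV": (ring.start, ring.end),
        "V": _interval(ring.end + 1, length),
    }
    return RegionDecomposition(sequence_id, length, regions, has_bzf=False)


@dataclass(frozen=True)
class ArchitectureProfile:
    """Ordered (region, motif) occurrences of one protein plus the canonical
    serialization, e.g. ``"I:- II:BZF III:m2,m6 IV:RING V:m10"``."""

    sequence_id: str
    occurrences: tuple[tuple[str, str, int], ...]  # (region_label, motif_id, start)
    architecture: str


def _serialize(has_bzf: bool, by_region: dict[str, list[str]]) -> str:
    parts = []
    for label in REGION_LABELS:
        if label == "II":
            body = "BZF" if has_bzf else "-"
        elif label == "IV":
            body = "RING"
        else:
            body = ",".join(by_region[label]) if by_region[label] else "-"
        parts.append(f"{label}:{body}")
    return " ".join(parts)


def build_profiles(
    decompositions: Iterable[RegionDecomposition],
    occurrences: Iterable,
) -> list[ArchitectureProfile]:
    """Assign motif occurrences to regions by midpoint and serialize.

    ``occurrences`` are objects with ``sequence_id``, ``motif_id``, ``start``
    and ``width`` attributes (see :class:`zfp.motifs.MotifOccurrence`).
    Every occurrence's sequence must have a decomposition; occurrences
    outside ``[1, length]`` are hard errors.  The serialization is injective
    on occurrence lists: motif ids are listed per region in start order.
    """
    decomp_by_id = {d.sequence_id: d for d in decompositions}
    occ_by_id: dict[str, list] = defaultdict(list)
    for occ in occurrences:
        if occ.sequence_id not in decomp_by_id:
            raise KeyError(f"no decomposition for sequence {occ.sequence_id!r}")
        occ_by_id[occ.sequence_id].append(occ)

    profiles = []
    for seq_id in decomp_by_id:
        decomp = decomp_by_id[seq_id]
        entries: list[tuple[str, str, int]] = []
        by_region: dict[str, list[str]] = {label: [] for label in REGION_LABELS}
        for occ in sorted(occ_by_id.get(seq_id, ()), key=lambda o: (o.start, o.motif_id)):
            end = occ.start + occ.width - 1
            if occ.start < 1 or end > decomp.length:
                raise ValueError(
                    f"{seq_id}: occurrence of {occ.motif_id} at [{occ.start}, {end}] "
                    f"outside [1, {decomp.length}]"
                )
            midpoint = (occ.start + end) // 2
            label = decomp.region_of(midpoint)
            entries.append((label, occ.motif_id, occ.start))
            by_region[label].append(occ.motif_id)
        profiles.append(
            ArchitectureProfile(
                sequence_id=seq_id,
                occurrences=tuple(entries),
                architecture=_serialize(decomp.has_bzf, by_region),
            )
        )
    return profiles


def architecture_classes(profiles: Iterable[ArchitectureProfile]) -> dict[str, list[str]]:
    """Group sequence ids by identical architecture strings."""
    classes: dict[str, list[str]] = defaultdict(list)
    for prof in profiles:
        classes[prof.architecture].append(prof.sequence_id)
    return dict(classes)
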