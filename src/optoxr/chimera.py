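"""Domain-swap chimera assembly.

An opto-XR chimera keeps the light-sensing backbone's N-terminus, all seven
transmembrane helices and the extracellular loops, and replaces a chosen set
of intracellular parts (IL1–3 and/or the C-terminus) with the corresponding
parts of the target GPCR. Splice junctions fall exactly at the backbone's TM
boundaries: a swapped loop replaces the backbone loop between the backbone's
TM end and the next TM start, whatever the target loop's length — the
backbone helices carry the light-sensing function and must remain intact, so
unequal loop lengths simply change the chimera's length (no padding, no
trimming).

An optional per-junction offset lets a user retain backbone "anchor" residues
at a splice edge (positive offset = that many backbone loop residues kept on
that side); the default of 0 splices whole loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import AssemblyError, TopologyError
from .seqio import ProteinSequence
from .topology import INTRACELLULAR_LABELS, TM_LABELS, Segment, TopologyMap

logger = logging.getLogger(__name__)

SWAPPABLE_LABELS = frozenset({"IL1", "IL2", "IL3", "Ct"})
DEFAULT_SWAP = frozenset({"IL1", "IL2", "IL3", "Ct"})


@dataclass(frozen=True)
class SwapSpec:
    """Which intracellular parts to take from the target.

    Defaults to the full set {IL1, IL2, IL3, Ct} — the construction that
    grafts the entire intracellular signaling surface of the target GPCR onto
    the backbone.
    """

    labels: frozenset[str] = DEFAULT_SWAP

    def __post_init__(self):
        labels = frozenset(self.labels)
        if not labels:
            raise AssemblyError("SwapSpec must name at least one segment")
        bad = labels - SWAPPABLE_LABELS
        if bad:
            raise AssemblyError(
                f"only intracellular labels {sorted(SWAPPABLE_LABELS)} may be "
                f"swapped; got {sorted(bad)}"
            )
        object.__setattr__(self, "labels", labels)

    @classmethod
    def parse(cls, text: str) -> "SwapSpec":
        return cls(frozenset(t.strip() for t in text.split(",") if t.strip()))


@dataclass(frozen=True)
class ChimeraPart:
    label: str
    source: str  # "backbone" | "target"
    sequence: str
    origin: tuple[int, int]  # coordinates in the source protein

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ChimeraDesign:
    """Provenance-tagged part list plus the assembled protein."""

    backbone_id: str
    target_id: str
    parts: tuple[ChimeraPart, ...]
    protein: ProteinSequence
    orientation: str = "extracellular"

    def __post_init__(self):
        assembled = "".join(p.sequence for p in self.parts)
        if assembled != self.protein.residues:
            raise AssemblyError("assembled protein must equal part concatenation")

    def topology_map(self) -> TopologyMap:
        """Segment map of the assembled chimera in its own coordinates."""
        segs = []
        pos = 0
        for part in self.parts:
            segs.append(Segment(part.label, pos, pos + len(part)))
            pos += len(part)
        return TopologyMap(self.protein.id, pos, tuple(segs), self.orientation)

    def junctions(self) -> list[tuple[str, int]]:
        """Chimera positions where provenance changes, as (label, position).

        The position is the first residue of the named part; only parts whose
        source differs from the previous part's source are reported.
        """
        out = []
        pos = 0
        prev = None
        for part in self.parts:
            if prev is not None and part.source != prev:
                out.append((part.label, pos))
            prev = part.source
            pos += len(part)
        return out

    def provenance_table(self) -> list[tuple[str, str, int, int]]:
        """(label, source, start, end) rows in chimera coordinates."""
        rows = []
        pos = 0
        for part in self.parts:
            rows.append((part.label, part.source, pos, pos + len(part)))
            pos += len(part)
        return rows


def _segment_str(protein: ProteinSequence, seg: Segment) -> str:
    return protein.residues[seg.start : seg.end]


def assemble_chimera(
    backbone: ProteinSequence,
    backbone_map: TopologyMap,
    target: ProteinSequence,
    target_map: TopologyMap,
    swap: Optional[SwapSpec] = None,
    junction_offsets: Optional[Mapping[str, tuple[int, int]]] = None,
) -> ChimeraDesign:
    """Splice target intracellular parts into the backbone.

    ``junction_offsets`` maps a swapped label to (five_prime, three_prime)
    counts of backbone loop residues to retain at the corresponding splice
    edge (default 0, 0: whole-loop swap).
    """
    if swap is None:
        swap = SwapSpec()
    backbone_map.validate()
    target_map.validate()
    if backbone_map.orientation != target_map.orientation:
        raise TopologyError("backbone and target orientations differ")
    if len(backbone) != backbone_map.length:
        raise TopologyError("backbone map length does not match protein")
    if len(target) != target_map.length:
        raise TopologyError("target map length does not match protein")
    offsets = dict(junction_offsets or {})
    for lbl in offsets:
        if lbl not in swap.labels:
            raise AssemblyError(f"offset given for non-swapped segment {lbl}")
        if lbl in TM_LABELS:
            logger.warning("junction offset touches a TM segment (%s)", lbl)

    parts = []
    for seg in backbone_map.segments:
        if seg.label in swap.labels:
            tseg = target_map.segment(seg.label)
            if tseg.end - tseg.start == 0:
                raise AssemblyError(
                    f"target segment {seg.label} is empty; cannot swap"
                )
            off5, off3 = offsets.get(seg.label, (0, 0))
            if off5 or off3:
                if off5 + off3 > len(seg):
                    raise AssemblyError(
                        f"junction offsets for {seg.label} exceed the backbone "
                        "loop length"
                    )
                if off5:
                    parts.append(
                        ChimeraPart(seg.label, "backbone",
                                    _segment_str(backbone, seg)[:off5],
                                    (seg.start, seg.start + off5))
                    )
                parts.append(
                    ChimeraPart(seg.label, "target", _segment_str(target, tseg),
                                (tseg.start, tseg.end))
                )
                if off3:
                    parts.append(
                        ChimeraPart(seg.label, "backbone",
                                    _segment_str(backbone, seg)[len(seg) - off3 :],
                                    (seg.end - off3, seg.end))
                    )
            else:
                parts.append(
                    ChimeraPart(seg.label, "target", _segment_str(target, tseg),
                                (tseg.start, tseg.end))
                )
        else:
            parts.append(
                ChimeraPart(seg.label, "backbone", _segment_str(backbone, seg),
                            (seg.start, seg.end))
            )
    assembled = "".join(p.sequence for p in parts)
    chimera_id = f"{backbone.id}|{target.id}|chimera"
    protein = ProteinSequence(
        chimera_id, assembled,
        f"opto-XR chimera: {backbone.id} backbone, {target.id} "
        f"{'+'.join(sorted(swap.labels))}",
    )
    return ChimeraDesign(
        backbone_id=backbone.id,
        target_id=target.id,
        parts=tuple(parts),
        protein=protein,
        orientation=backbone_map.orientation,
    )


@dataclass(frozen=True)
class DiffReport:
    """Per-residue provenance track of a chimera design.

    Symbols: ``B`` backbone-derived, ``T`` target-derived, ``=``
    target-derived but identical to the backbone's own segment (so the residue
    could be attributed to either source). ``identical`` is True when no
    position is distinguishably target-derived.
    """

    track: str
    counts: dict[str, int]
    identical: bool


def diff_report(
    design: ChimeraDesign,
    backbone: Optional[ProteinSequence] = None,
    backbone_map: Optional[TopologyMap] = None,
) -> DiffReport:
    """Two-color text schematic of a design (per-position provenance).

    When the backbone protein and map are supplied, target-derived parts whose
    sequence equals the backbone's own segment are marked ``=`` instead of
    ``T`` (a self-swap is reported as identical).
    """
    symbols = []
    for part in design.parts:
        if part.source == "backbone":
            symbols.append("B" * len(part))
        else:
            sym = "T"
            if backbone is not None and backbone_map is not None:
                try:
                    bseg = backbone_map.segment(part.label)
                except KeyError:
                    bseg = None
                if bseg is not None and _segment_str(backbone, bseg) == part.sequence:
                    sym = "="
            symbols.append(sym * len(part))
    track = "".join(symbols)
    counts = {s: track.count(s) for s in "BT=" if track.count(s)}
    return DiffReport(track=track, counts=counts, identical="T" not in track)
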