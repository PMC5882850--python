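"""7TM topology calling from hydropathy, with family-consensus refinement.

A seven-transmembrane protein is partitioned into the canonical 15 segments
Nt, TM1, IL1, TM2, EL1, TM3, IL2, TM4, EL2, TM5, IL3, TM6, EL3, TM7, Ct
(with an extracellular N-terminus; both channelrhodopsins and GPCRs satisfy
this). Transmembrane helices are detected as maximal runs of the windowed
Kyte–Doolittle hydropathy profile above a threshold; loop labels alternate
intracellular/extracellular starting from the declared N-terminal side.

Boundary calls can be refined by consensus over an aligned homolog family:
every homolog's boundary is projected into reference coordinates through a
star multiple alignment and each reference boundary is replaced by the median
vote. The median (not the mean) keeps boundaries integral and robust to a
single divergent homolog.

Defaults: window 9, threshold 0.2, TM length 15–30, minimum loop 4. A short
centered window is required to resolve the shortest GPCR loops (~8 residues):
a window wider than about twice the loop length can never dip below threshold
inside the loop, which would fuse adjacent helices. The threshold sits near
the midpoint of the hydropathy contrast between membrane-spanning and loop
residues, where the windowed profile crosses at the true helix edge; a
threshold deep inside the hydrophobic range would bias every boundary inward
by several residues. The classical long-window settings (19/1.6) remain
available for exploratory scans of long-loop proteins.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import MultipleAlignment, map_position
from .errors import ParameterError, TopologyError
from .seqio import ProteinSequence

logger = logging.getLogger(__name__)

# Kyte–Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SEGMENT_ORDER_EXTRACELLULAR = (
    "Nt", "TM1", "IL1", "TM2", "EL1", "TM3", "IL2", "TM4",
    "EL2", "TM5", "IL3", "TM6", "EL3", "TM7", "Ct",
)
SEGMENT_ORDER_INTRACELLULAR = (
    "Nt", "TM1", "EL1", "TM2", "IL1", "TM3", "EL2", "TM4",
    "IL2", "TM5", "EL3", "TM6", "IL3", "TM7", "Ct",
)

DEFAULT_WINDOW = 9
DEFAULT_THRESHOLD = 0.2
DEFAULT_MIN_TM_LEN = 15
DEFAULT_MAX_TM_LEN = 30
DEFAULT_MIN_LOOP_LEN = 4

INTRACELLULAR_LABELS = frozenset({"IL1", "IL2", "IL3", "Ct"})
TM_LABELS = frozenset({f"TM{i}" for i in range(1, 8)})


@dataclass(frozen=True)
class HydropathyProfile:
    values: tuple[float, ...]
    window: int
    scale: str = "Kyte-Doolittle"

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Segment:
    label: str
    start: int  # 0-based, half-open
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TopologyMap:
    """Ordered 15-segment partition of a 7TM protein.

    ``orientation`` is the membrane side of the N-terminus; it fixes the
    loop-label alternation.
    """

    sequence_id: str
    length: int
    segments: tuple[Segment, ...]
    orientation: str = "extracellular"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        order = (
            SEGMENT_ORDER_EXTRACELLULAR
            if self.orientation == "extracellular"
            else SEGMENT_ORDER_INTRACELLULAR
        )
        labels = tuple(s.label for s in self.segments)
        if labels != order:
            raise TopologyError(
                f"segments must appear in canonical order {order}, got {labels}"
            )
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.end < seg.start:
                raise TopologyError(
                    f"segments must be contiguous and non-overlapping; "
                    f"{seg.label} spans [{seg.start}, {seg.end}) at offset {pos}"
                )
            pos = seg.end
        if pos != self.length:
            raise TopologyError(
                f"segments cover [0, {pos}) but protein length is {self.length}"
            )

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    def boundaries(self) -> list[int]:
        """The 14 internal segment-start positions (segments 1..14)."""
        return [seg.start for seg in self.segments[1:]]

    def tm_intervals(self) -> list[tuple[int, int]]:
        return [(s.start, s.end) for s in self.segments if s.label in TM_LABELS]

    # -- BED-like text exchange (0-based half-open) --

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for seg in self.segments:
                fh.write(f"{self.sequence_id}\t{seg.start}\t{seg.end}\t{seg.label}\n")

    @classmethod
    def from_bed(cls, path, orientation: str = "extracellular") -> "TopologyMap":
        segs = []
        sid = None
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                sid_, start, end, label = line.split("\t")
                sid = sid_
                segs.append(Segment(label.strip(), int(start), int(end)))
        if not segs:
            raise TopologyError(f"{path}: no segments")
        return cls(sid, segs[-1].end, tuple(segs), orientation)


def hydropathy_profile(p: ProteinSequence, window: int = DEFAULT_WINDOW) -> HydropathyProfile:
    """Windowed-mean Kyte–Doolittle profile.

    Windows are truncated at the sequence ends and averaged over the residues
    actually available — no padding, so no fabricated hydropathy at termini.
    """
    if window % 2 == 0 or not (5 <= window <= 31):
        raise ParameterError(f"window must be odd and within [5, 31], got {window}")
    if window > len(p):
        raise ParameterError(
            f"window {window} exceeds protein length {len(p)}"
        )
    vals = np.array([KYTE_DOOLITTLE[r] for r in p.residues], dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    h = window // 2
    n = len(vals)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    means = (csum[hi] - csum[lo]) / (hi - lo)
    return HydropathyProfile(tuple(float(x) for x in means), window)


def call_tm_segments(
    profile: HydropathyProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_tm_len: int = DEFAULT_MIN_TM_LEN,
    max_tm_len: int = DEFAULT_MAX_TM_LEN,
    min_loop_len: int = DEFAULT_MIN_LOOP_LEN,
) -> list[tuple[int, int]]:
    """Candidate TM intervals: maximal above-threshold runs of the profile.

    Runs separated by fewer than ``min_loop_len`` positions are merged, runs
    shorter than ``min_tm_len`` are dropped, and runs longer than
    ``max_tm_len`` are split at their interior profile minimum.
    """
    vals = profile.values
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(vals):
        if v >= threshold and start is None:
            start = i
        elif v < threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(vals)))

    # merge runs separated by short gaps
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_loop_len:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    # split over-long runs at the interior minimum
    def split(run: tuple[int, int]) -> list[tuple[int, int]]:
        s, e = run
        if e - s <= max_tm_len:
            return [run]
        interior = range(s + 1, e - 1)
        m = min(interior, key=lambda i: vals[i])
        return split((s, m)) + split((m + 1, e))

    out: list[tuple[int, int]] = []
    for run in merged:
        out.extend(split(run))
    out = [r for r in out if r[1] - r[0] >= min_tm_len]
    return sorted(out)


def partition_7tm(
    p: ProteinSequence,
    tm_intervals: Sequence[tuple[int, int]],
    orientation: str = "extracellular",
) -> TopologyMap:
    """Label the 15-segment architecture around exactly 7 TM intervals.

    With an extracellular N-terminus the loop after TM1 is intracellular
    (IL1) and labels alternate from there; a declared intracellular
    N-terminus flips the alternation. Fails loudly (carrying the candidate
    list) when the candidate count is not 7 — chimera correctness depends on
    segment identity, so no silent "best 7" selection is attempted.
    """
    if orientation not in ("extracellular", "intracellular"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    intervals = sorted(tm_intervals)
    if len(intervals) != 7:
        raise TopologyError(
            f"expected exactly 7 TM intervals, got {len(intervals)}; "
            "adjust the calling threshold",
            candidates=list(intervals),
        )
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if e1 > s2:
            raise TopologyError("TM intervals overlap", candidates=list(intervals))
    order = (
        SEGMENT_ORDER_EXTRACELLULAR
        if orientation == "extracellular"
        else SEGMENT_ORDER_INTRACELLULAR
    )
    bounds: list[tuple[int, int]] = []
    pos = 0
    for k, (s, e) in enumerate(intervals):
        bounds.append((pos, s))  # preceding loop / Nt
        bounds.append((s, e))  # TM
        pos = e
    bounds.append((pos, len(p)))  # Ct
    segments = tuple(Segment(lbl, s, e) for lbl, (s, e) in zip(order, bounds))
    return TopologyMap(p.id, len(p), segments, orientation)


def call_topology(
    p: ProteinSequence,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_tm_len: int = DEFAULT_MIN_TM_LEN,
    max_tm_len: int = DEFAULT_MAX_TM_LEN,
    min_loop_len: int = DEFAULT_MIN_LOOP_LEN,
    orientation: str = "extracellular",
) -> TopologyMap:
    """Profile -> candidate TMs -> 15-segment map, in one call."""
    prof = hydropathy_profile(p, window)
    tms = call_tm_segments(prof, threshold, min_tm_len, max_tm_len, min_loop_len)
    return partition_7tm(p, tms, orientation)


def consensus_topology(
    reference_map: TopologyMap,
    family_maps: Sequence[TopologyMap],
    msa: MultipleAlignment,
    min_tm_len: int = DEFAULT_MIN_TM_LEN,
) -> TopologyMap:
    """Median-vote refinement of the reference boundaries over a family.

    ``msa`` must be the star alignment whose row 0 is the reference and whose
    rows 1..n correspond, in order, to ``family_maps``. Each of the 14
    internal boundaries is replaced by the rounded median of the homolog
    boundaries projected into reference coordinates, the reference's own call
    included. Homolog votes that land on a reference gap are skipped with a
    logged notice. The result is clipped to keep segments ordered, TMs at
    least ``min_tm_len`` long, and loops/termini non-negative.
    """
    if len(family_maps) != len(msa.rows) - 1:
        raise ParameterError(
            "family_maps must match the non-reference rows of the alignment"
        )
    ref_bounds = reference_map.boundaries()
    votes: list[list[int]] = [[b] for b in ref_bounds]
    for r, fmap in enumerate(family_maps, start=1):
        for k, b in enumerate(fmap.boundaries()):
            if b >= fmap.length:
                continue
            mapped = map_position(msa, r, b)
            if mapped is None:
                logger.info(
                    "consensus: homolog %s boundary %d falls in a reference "
                    "gap; vote skipped", fmap.sequence_id, b,
                )
                continue
            votes[k].append(mapped)
    # true median, rounded to the nearest integer (half toward the
    # reference's own call) — keeps boundaries integral without the downward
    # bias a lower-median would add on even vote counts
    consensus = []
    for ref_b, v in zip(ref_bounds, votes):
        med = statistics.median(v)
        if med == int(med):
            consensus.append(int(med))
        else:
            lo, hi = int(med), int(med) + 1
            consensus.append(lo if abs(lo - ref_b) <= abs(hi - ref_b) else hi)

    # clip to preserve order and minimum segment lengths
    order = [seg.label for seg in reference_map.segments]
    min_len = [min_tm_len if lbl in TM_LABELS else 0 for lbl in order]
    starts = [0] + consensus + [reference_map.length]
    for k in range(1, len(starts) - 1):
        lo = starts[k - 1] + min_len[k - 1]
        starts[k] = max(starts[k], lo)
    for k in range(len(starts) - 2, 0, -1):
        hi = starts[k + 1] - min_len[k]
        starts[k] = min(starts[k], hi)
    for k in range(1, len(starts)):
        if starts[k] < starts[k - 1]:
            raise TopologyError("consensus clipping failed to preserve order")
    segments = tuple(
        Segment(lbl, starts[k], starts[k + 1]) for k, lbl in enumerate(order)
    )
    return TopologyMap(
        reference_map.sequence_id, reference_map.length, segments,
        reference_map.orientation,
    )
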