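"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its arguments (seed included), so a
scenario is byte-reproducible from one integer. Synthetic 7TM proteins are
built segment by segment: transmembrane stretches draw only from a
hydrophobic alphabet, loops and termini only from a hydrophilic one, with
sampling weights chosen so the windowed Kyte–Doolittle profile over a true
TM clears the default calling threshold with a wide, asserted margin (strongly
hydrophobic residues dominate helices; tryptophan and cysteine are rare, as
in real membrane helices). Homolog families apply i.i.d. point substitutions
only — no indels — which keeps homolog-to-reference coordinate transfer exact
and isolates the consensus logic from alignment quality.

These fixtures emulate the hydropathy contrast and family structure of real
7TM receptors, not their composition statistics: real loops contain
hydrophobic residues, real helices polar ones, and real families have indels.

Derived seeds for sub-generators come from a documented splitting rule:
``numpy.random.SeedSequence(seed).generate_state(k)`` masked to 31 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chimera import ChimeraDesign, SwapSpec, assemble_chimera
from .construct import CodonUsageTable, back_translate
from .errors import ParameterError
from .primers import QpcrMeasurement
from .seqio import NucleotideSequence, ProteinSequence
from .topology import (
    SEGMENT_ORDER_EXTRACELLULAR,
    Segment,
    TopologyMap,
)

HYDROPHOBIC_ALPHABET = "AILVFMWC"
HYDROPHILIC_ALPHABET = "DEKRSTNQGPHY"

# helix-like composition: strongly hydrophobic residues dominate
_TM_WEIGHTS = {
    "I": 0.24, "L": 0.24, "V": 0.20, "F": 0.15, "A": 0.10,
    "M": 0.04, "C": 0.02, "W": 0.01,
}
# loop-like composition: charged/polar residues dominate
_LOOP_WEIGHTS = {
    "D": 0.14, "E": 0.14, "K": 0.14, "R": 0.14, "N": 0.10, "Q": 0.10,
    "S": 0.05, "T": 0.05, "G": 0.04, "P": 0.04, "H": 0.04, "Y": 0.02,
}


def derive_seeds(seed: int, k: int) -> list[int]:
    """Split one top-level seed into ``k`` reproducible child seeds."""
    state = np.random.SeedSequence(seed).generate_state(k)
    return [int(s) & 0x7FFFFFFF for s in state]


def _draw(rng: np.random.Generator, weights: dict[str, float], n: int) -> str:
    letters = list(weights)
    p = np.array([weights[l] for l in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


@dataclass(frozen=True)
class SyntheticTopologyTruth:
    """A generated 7TM protein plus its ground-truth topology."""

    protein: ProteinSequence
    topology: TopologyMap
    params: dict


def make_7tm(
    seed: int,
    tm_len_range: tuple[int, int] = (18, 25),
    loop_len_range: tuple[int, int] = (8, 40),
    nt_len: int = 30,
    ct_len: int = 60,
) -> SyntheticTopologyTruth:
    """Generate a synthetic 7TM protein with known segment boundaries."""
    if tm_len_range[0] < 15 or tm_len_range[1] > 30 or tm_len_range[0] > tm_len_range[1]:
        raise ParameterError(
            f"tm_len_range must lie within [15, 30], got {tm_len_range}"
        )
    if loop_len_range[0] < 1 or loop_len_range[0] > loop_len_range[1]:
        raise ParameterError(f"invalid loop_len_range {loop_len_range}")
    if nt_len < 1 or ct_len < 1:
        raise ParameterError("nt_len and ct_len must be positive")
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    segments: list[Segment] = []
    pos = 0
    for label in SEGMENT_ORDER_EXTRACELLULAR:
        if label == "Nt":
            n = nt_len
            chunk = _draw(rng, _LOOP_WEIGHTS, n)
        elif label == "Ct":
            n = ct_len
            chunk = _draw(rng, _LOOP_WEIGHTS, n)
        elif label.startswith("TM"):
            n = int(rng.integers(tm_len_range[0], tm_len_range[1] + 1))
            chunk = _draw(rng, _TM_WEIGHTS, n)
        else:
            n = int(rng.integers(loop_len_range[0], loop_len_range[1] + 1))
            chunk = _draw(rng, _LOOP_WEIGHTS, n)
        pieces.append(chunk)
        segments.append(Segment(label, pos, pos + n))
        pos += n
    protein = ProteinSequence(
        f"syn7tm_{seed}", "".join(pieces), "synthetic 7TM protein"
    )
    topo = TopologyMap(protein.id, len(protein), tuple(segments), "extracellular")
    return SyntheticTopologyTruth(
        protein=protein,
        topology=topo,
        params={
            "seed": seed, "tm_len_range": tm_len_range,
            "loop_len_range": loop_len_range, "nt_len": nt_len, "ct_len": ct_len,
        },
    )


def make_family(
    truth: SyntheticTopologyTruth,
    n: int,
    sub_rate: float,
    seed: int,
    class_preserving: bool = True,
) -> list[ProteinSequence]:
    """Point-substituted homologs of a synthetic protein (no indels).

    With ``class_preserving`` substitutions stay within the hydrophobic or
    hydrophilic alphabet of the site's true segment, so every homolog keeps
    the hydropathy contrast a topology caller needs.
    """
    if not (0.0 <= sub_rate <= 0.2):
        raise ParameterError(f"sub_rate must be in [0, 0.2], got {sub_rate}")
    if n < 1:
        raise ParameterError("family size must be >= 1")
    rng = np.random.default_rng(seed)
    residues = truth.protein.residues
    seg_class = []
    for seg in truth.topology.segments:
        alpha = HYDROPHOBIC_ALPHABET if seg.label.startswith("TM") else HYDROPHILIC_ALPHABET
        seg_class.extend([alpha] * (seg.end - seg.start))
    out = []
    for h in range(n):
        chars = list(residues)
        mask = rng.random(len(chars)) < sub_rate
        for i in np.flatnonzero(mask):
            if class_preserving:
                options = [c for c in seg_class[i] if c != chars[i]]
            else:
                options = [
                    c for c in "ACDEFGHIKLMNPQRSTVWY" if c != chars[i]
                ]
            chars[i] = options[int(rng.integers(len(options)))]
        out.append(
            ProteinSequence(
                f"{truth.protein.id}_hom{h}", "".join(chars),
                f"synthetic homolog (sub_rate={sub_rate})",
            )
        )
    return out


@dataclass(frozen=True)
class ParentChimeraSet:
    """Backbone + target truths, their chimera, and all three CDSs."""

    backbone: SyntheticTopologyTruth
    target: SyntheticTopologyTruth
    design: ChimeraDesign
    backbone_cds: NucleotideSequence
    target_cds: NucleotideSequence
    chimera_cds: NucleotideSequence


def make_parent_chimera_set(seed: int) -> ParentChimeraSet:
    """End-to-end scaffold: two synthetic parents, the full intracellular
    swap {IL1, IL2, IL3, Ct}, and deterministic codon-optimized CDSs."""
    s_backbone, s_target = derive_seeds(seed, 2)
    backbone = make_7tm(s_backbone)
    target = make_7tm(s_target)
    design = assemble_chimera(
        backbone.protein, backbone.topology, target.protein, target.topology,
        SwapSpec(),
    )
    table = CodonUsageTable.mouse()
    return ParentChimeraSet(
        backbone=backbone,
        target=target,
        design=design,
        backbone_cds=back_translate(backbone.protein, table),
        target_cds=back_translate(target.protein, table),
        chimera_cds=back_translate(design.protein, table),
    )


def make_reporter(seed: int, length: int = 80) -> NucleotideSequence:
    """Synthetic fluorescent-reporter CDS (stand-in; begins ATG, ends TAA).

    The reporter used in real constructs (mCherry) is not bundled; this
    synthetic CDS has the same shape: an initiator codon, an open frame, one
    terminal stop.
    """
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLNPQRSTVWY"  # no Met inside, keeps the initiator unique
    protein = ProteinSequence(
        f"synreporter_{seed}",
        "M" + "".join(rng.choice(list(aas), size=length - 1)),
        "synthetic reporter protein",
    )
    cds = back_translate(protein, CodonUsageTable.mouse())
    return NucleotideSequence(protein.id, cds.bases + "TAA", protein.description)


def make_qpcr_table(
    seed: int,
    n_samples: int,
    true_fold_changes: Sequence[float],
    ct_noise_sd: float,
    n_replicates: int = 3,
    reference_ct: float = 18.0,
    calibrator_target_ct: float = 25.0,
) -> tuple[QpcrMeasurement, list[tuple[QpcrMeasurement, float]]]:
    """Simulated Ct replicate tables with known fold changes.

    Returns ``(calibrator, samples)`` where each sample is paired with its
    true fold change. Reference-gene Ct is constant plus noise; target Ct is
    the calibrator's target Ct minus log2(fold) plus noise, so a noise-free
    table inverts exactly under the 2^(-ΔΔCt) calculation.
    """
    if any(f <= 0 for f in true_fold_changes):
        raise ParameterError("fold changes must be positive")
    if ct_noise_sd < 0:
        raise ParameterError("noise sd must be >= 0")
    if n_samples < 1 or n_replicates < 1:
        raise ParameterError("need at least one sample and one replicate")
    rng = np.random.default_rng(seed)

    def noisy(base: float) -> tuple[float, ...]:
        return tuple(float(base + rng.normal(0.0, ct_noise_sd)) for _ in range(n_replicates))

    calibrator = QpcrMeasurement(
        "calibrator", noisy(calibrator_target_ct), noisy(reference_ct)
    )
    samples = []
    for k in range(n_samples):
        fold = float(true_fold_changes[k % len(true_fold_changes)])
        target_base = calibrator_target_ct - math.log2(fold)
        m = QpcrMeasurement(f"sample{k}", noisy(target_base), noisy(reference_ct))
        samples.append((m, fold))
    return calibrator, samples
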