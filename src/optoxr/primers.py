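"""Junction-spanning qPCR primer design, in-silico PCR, and ΔΔCt analysis.

A chimera-specific qPCR assay must amplify the fusion transcript but neither
parental transcript. The designer therefore places the forward primer across
a splice junction (with a minimum anchor on each side, so neither parent
alone can template it) and verifies every candidate pair by in-silico PCR
against the chimera and both parents before emitting it.

Relative expression follows the standard 2^(-ΔΔCt) calculation: per sample,
ΔCt = mean(target Ct) - mean(reference Ct); ΔΔCt subtracts the calibrator's
ΔCt; the fold change is 2^(-ΔΔCt). Replicates are aggregated by the
arithmetic mean of Ct and no amplification-efficiency correction is applied.

Melting temperatures use the Wallace rule for short oligos and the simple
GC formula otherwise — adequate for ranking candidates against each other;
nearest-neighbor thermodynamics is a listed extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import DesignFailureError, InputError
from .seqio import NucleotideSequence, revcomp

DEFAULT_MAX_MISMATCH = 2
DEFAULT_THREE_PRIME_EXACT = 5
DEFAULT_MAX_PRODUCT = 2000


@dataclass(frozen=True)
class PrimerProperties:
    length: int
    gc_fraction: float
    tm: float


def primer_properties(oligo) -> PrimerProperties:
    """Length, GC fraction, and melting temperature of one oligo.

    Tm: Wallace rule 2(A+T) + 4(G+C) below 14 nt, otherwise
    64.9 + 41*(G+C-16.4)/length.
    """
    seq = oligo.bases if isinstance(oligo, NucleotideSequence) else NucleotideSequence("oligo", oligo).bases
    n = len(seq)
    gc = seq.count("G") + seq.count("C")
    at = n - gc
    if n < 14:
        tm = 2.0 * at + 4.0 * gc
    else:
        tm = 64.9 + 41.0 * (gc - 16.4) / n
    return PrimerProperties(length=n, gc_fraction=gc / n, tm=tm)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair (both written 5'→3')."""

    name: str
    forward: NucleotideSequence
    reverse: NucleotideSequence
    amplicon: Optional[tuple[int, int]] = None  # intended interval on template
    specificity: str = "unscreened"

    @property
    def forward_properties(self) -> PrimerProperties:
        return primer_properties(self.forward)

    @property
    def reverse_properties(self) -> PrimerProperties:
        return primer_properties(self.reverse)


@dataclass(frozen=True)
class AmpliconHit:
    """A convergent primer-pair match on one template."""

    template_id: str
    start: int  # 0-based half-open, top strand
    end: int
    forward_strand: str  # strand the pair's forward primer matched
    reverse_strand: str
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def product_length(self) -> int:
        return self.end - self.start


def _matches(template: str, probe: str, max_mm: int, exact_suffix: bool,
             k_exact: int) -> list[tuple[int, int]]:
    """(start, mismatches) of every ≤max_mm match of ``probe`` in ``template``.

    ``exact_suffix`` selects which probe end carries the exact-match
    requirement of ``k_exact`` bases (suffix for a top-strand forward match,
    prefix for the reverse-complemented reverse match, where the primer's 3'
    end faces left).
    """
    n, m = len(template), len(probe)
    out = []
    if exact_suffix:
        exact_range = range(m - k_exact, m)
    else:
        exact_range = range(0, k_exact)
    exact_set = set(exact_range)
    for s in range(n - m + 1):
        mm = 0
        ok = True
        for i in range(m):
            if template[s + i] != probe[i]:
                if i in exact_set:
                    ok = False
                    break
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            out.append((s, mm))
    return out


def in_silico_pcr(
    template: NucleotideSequence,
    pair: PrimerPair,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[AmpliconHit]:
    """All products the pair would form on the template (either strand).

    A product requires one primer matching the top strand and the other the
    bottom strand, 3' ends converging, within ``max_product``. Each primer
    may carry at most ``max_mismatch`` mismatches but its 3'-terminal
    ``three_prime_exact`` bases must match exactly.
    """
    seq = template.bases
    k = three_prime_exact
    fwd, rev = pair.forward.bases, pair.reverse.bases
    hits = []
    configs = [
        (fwd, rev, "+", "-"),  # forward primer on top strand
        (rev, fwd, "-", "+"),  # pair acting on the bottom strand
    ]
    seen = set()
    for top_primer, bottom_primer, fstrand, rstrand in configs:
        tops = _matches(seq, top_primer, max_mismatch, True, k)
        bottoms = _matches(seq, revcomp(bottom_primer), max_mismatch, False, k)
        for ts, tmm in tops:
            for bs, bmm in bottoms:
                start = ts
                end = bs + len(bottom_primer)
                if bs < ts + len(top_primer):
                    continue  # not convergent / overlapping
                if end - start > max_product:
                    continue
                key = (start, end, fstrand)
                if key in seen:
                    continue
                seen.add(key)
                if fstrand == "+":
                    fm, rm = tmm, bmm
                else:
                    fm, rm = bmm, tmm
                hits.append(
                    AmpliconHit(
                        template_id=template.id, start=start, end=end,
                        forward_strand=fstrand, reverse_strand=rstrand,
                        forward_mismatches=fm, reverse_mismatches=rm,
                    )
                )
    return sorted(hits, key=lambda h: (h.start, h.end))


@dataclass(frozen=True)
class PrimerDesignParams:
    primer_len_min: int = 18
    primer_len_max: int = 25
    amplicon_min: int = 80
    amplicon_max: int = 300
    junction_anchor: int = 6
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT
    max_product: int = DEFAULT_MAX_PRODUCT
    max_screens: int = 400


def design_junction_primers(
    template: NucleotideSequence,
    junction: int,
    parents: Sequence[NucleotideSequence],
    params: Optional[PrimerDesignParams] = None,
    name: str = "junction",
) -> PrimerPair:
    """Design a pair whose forward primer spans the splice junction.

    The forward primer must cover at least ``junction_anchor`` bases on each
    side of the junction; the reverse primer sits downstream so the amplicon
    contains the junction strictly in its interior. Candidates are ranked by
    |Tm_fwd − Tm_rev|, then by combined GC distance from 50%, and screened in
    rank order by in-silico PCR: the first pair with ≥1 product on the
    template and 0 products on every parent is returned. With no parents the
    best-ranked candidate is returned flagged ``unscreened``.
    """
    if params is None:
        params = PrimerDesignParams()
    seq = template.bases
    a = params.junction_anchor
    if junction < a or junction > len(seq) - a:
        raise InputError(
            f"junction {junction} leaves no {a}-base anchor on both sides "
            f"(template length {len(seq)})"
        )

    candidates = []
    for flen in range(params.primer_len_min, params.primer_len_max + 1):
        # forward windows covering [junction - a, junction + a)
        lo = max(junction + a - flen, 0)
        hi = min(junction - a, len(seq) - flen)
        for fs in range(lo, hi + 1):
            fwd = seq[fs : fs + flen]
            fp = primer_properties(NucleotideSequence("f", fwd))
            rlen = 20
            for amp in range(params.amplicon_min, params.amplicon_max + 1, 7):
                re_end = fs + amp
                rs = re_end - rlen
                if rs < fs + flen or re_end > len(seq):
                    continue
                rev = revcomp(seq[rs:re_end])
                rp = primer_properties(NucleotideSequence("r", rev))
                rank = (
                    abs(fp.tm - rp.tm),
                    abs(fp.gc_fraction - 0.5) + abs(rp.gc_fraction - 0.5),
                )
                candidates.append((rank, fs, fwd, rev, (fs, re_end)))
    if not candidates:
        raise DesignFailureError(
            "no primer windows satisfy the length/anchor/amplicon constraints"
        )
    candidates.sort(key=lambda c: (c[0], c[1]))

    if not parents:
        _, _, fwd, rev, interval = candidates[0]
        return PrimerPair(
            name, NucleotideSequence(f"{name}_F", fwd),
            NucleotideSequence(f"{name}_R", rev),
            amplicon=interval, specificity="unscreened",
        )

    rejected = []
    for rank, _, fwd, rev, interval in candidates[: params.max_screens]:
        pair = PrimerPair(
            name, NucleotideSequence(f"{name}_F", fwd),
            NucleotideSequence(f"{name}_R", rev), amplicon=interval,
        )
        on_template = in_silico_pcr(
            template, pair, params.max_mismatch, params.three_prime_exact,
            params.max_product,
        )
        covering = [h for h in on_template if h.start < junction < h.end]
        if not covering:
            rejected.append((pair, "no junction-covering product on template"))
            continue
        parent_hits = 0
        for parent in parents:
            parent_hits += len(
                in_silico_pcr(parent, pair, params.max_mismatch,
                              params.three_prime_exact, params.max_product)
            )
            if parent_hits:
                break
        if parent_hits:
            rejected.append((pair, "amplifies a parent under the screen"))
            continue
        return PrimerPair(
            name, pair.forward, pair.reverse, amplicon=interval,
            specificity="chimera-specific",
        )
    raise DesignFailureError(
        f"no candidate pair passed the specificity screen "
        f"({len(rejected)} screened)",
        diagnostics=[(p.forward.bases, p.reverse.bases, why) for p, why in rejected[:10]],
    )


# ---------------------------------------------------------------------------
# Relative quantification (2^-ΔΔCt)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct replicates for one sample: target gene and reference gene."""

    sample: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self):
        if not self.target_ct or not self.reference_ct:
            raise InputError(f"sample {self.sample}: empty Ct replicate list")
        if any(c <= 0 for c in self.target_ct + self.reference_ct):
            raise InputError(f"sample {self.sample}: Ct values must be positive")
        object.__setattr__(self, "target_ct", tuple(float(c) for c in self.target_ct))
        object.__setattr__(
            self, "reference_ct", tuple(float(c) for c in self.reference_ct)
        )

    @property
    def delta_ct(self) -> float:
        return (sum(self.target_ct) / len(self.target_ct)
                - sum(self.reference_ct) / len(self.reference_ct))


def ddct(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Fold change of the sample relative to the calibrator, 2^(-ΔΔCt)."""
    return 2.0 ** -(sample.delta_ct - calibrator.delta_ct)


def measurements_from_table(
    table: pd.DataFrame, target_gene: str, reference_gene: str,
) -> dict[str, QpcrMeasurement]:
    """Group a tidy Ct table (columns: sample, gene, ct) into measurements."""
    required = {"sample", "gene", "ct"}
    if not required.issubset(table.columns):
        raise InputError(f"Ct table must have columns {sorted(required)}")
    out = {}
    for sample, grp in table.groupby("sample"):
        tct = grp.loc[grp["gene"] == target_gene, "ct"].tolist()
        rct = grp.loc[grp["gene"] == reference_gene, "ct"].tolist()
        if not tct or not rct:
            raise InputError(
                f"sample {sample}: missing Ct values for {target_gene} or "
                f"{reference_gene}"
            )
        out[str(sample)] = QpcrMeasurement(str(sample), tuple(tct), tuple(rct))
    return out


def fold_changes(
    table: pd.DataFrame, target_gene: str, reference_gene: str, calibrator: str,
) -> pd.DataFrame:
    """Per-sample 2^(-ΔΔCt) fold changes against a calibrator sample."""
    meas = measurements_from_table(table, target_gene, reference_gene)
    if calibrator not in meas:
        raise InputError(f"calibrator sample {calibrator!r} not in table")
    cal = meas[calibrator]
    rows = [
        {"sample": s, "delta_ct": m.delta_ct, "fold_change": ddct(m, cal)}
        for s, m in sorted(meas.items())
    ]
    return pd.DataFrame(rows)
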