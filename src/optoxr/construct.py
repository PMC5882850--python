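"""Codon optimization, restriction-site auditing, and cassette assembly.

The chimera protein is compiled into an expression cassette: back-translated
with host-preferred codons, cleared of internal cloning sites by synonymous
substitution, fused to a fluorescent reporter either directly (through a
short in-frame linker, the reporter's initiator codon deleted) or
bicistronically (through a self-cleaving 2A peptide, the reporter's initiator
retained), and flanked by cloning sites (KpnI/BamHI by default).

The default codon-usage host is Mus musculus — the expression animal for
AAV-delivered opto-XR constructs. The table is ordinary relative-usage data
(fractions per amino acid) and can be replaced from a two-column text file.
The 9-nt linker GCGGCCGCC (Ala-Ala-Ala) deliberately contains a NotI core
usable for cloning, so it is protected from site removal by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import (
    CassetteError,
    FrameError,
    InputError,
    TableError,
    UnresolvableSiteError,
)
from .seqio import (
    STANDARD_CODE,
    NucleotideSequence,
    ProteinSequence,
    revcomp,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_LINKER = "GCGGCCGCC"  # encodes Ala-Ala-Ala; contains a NotI core
DEFAULT_STOP = "TAA"

# Relative synonymous-codon usage fractions for Mus musculus
# (rounded Kazusa-style values; normalized per amino acid at load time).
_MOUSE_USAGE = {
    "A": [("GCC", 0.38), ("GCT", 0.29), ("GCA", 0.23), ("GCG", 0.10)],
    "R": [("AGA", 0.22), ("AGG", 0.22), ("CGG", 0.19), ("CGC", 0.17),
          ("CGA", 0.12), ("CGT", 0.08)],
    "N": [("AAC", 0.57), ("AAT", 0.43)],
    "D": [("GAC", 0.56), ("GAT", 0.44)],
    "C": [("TGC", 0.52), ("TGT", 0.48)],
    "Q": [("CAG", 0.75), ("CAA", 0.25)],
    "E": [("GAG", 0.60), ("GAA", 0.40)],
    "G": [("GGC", 0.33), ("GGA", 0.26), ("GGG", 0.23), ("GGT", 0.18)],
    "H": [("CAC", 0.60), ("CAT", 0.40)],
    "I": [("ATC", 0.50), ("ATT", 0.34), ("ATA", 0.16)],
    "L": [("CTG", 0.39), ("CTC", 0.20), ("CTT", 0.13), ("TTG", 0.13),
          ("CTA", 0.08), ("TTA", 0.07)],
    "K": [("AAG", 0.61), ("AAA", 0.39)],
    "M": [("ATG", 1.00)],
    "F": [("TTC", 0.57), ("TTT", 0.43)],
    "P": [("CCC", 0.31), ("CCT", 0.31), ("CCA", 0.28), ("CCG", 0.10)],
    "S": [("AGC", 0.24), ("TCC", 0.22), ("TCT", 0.19), ("AGT", 0.15),
          ("TCA", 0.14), ("TCG", 0.06)],
    "T": [("ACC", 0.35), ("ACA", 0.29), ("ACT", 0.25), ("ACG", 0.11)],
    "W": [("TGG", 1.00)],
    "Y": [("TAC", 0.57), ("TAT", 0.43)],
    "V": [("GTG", 0.46), ("GTC", 0.25), ("GTT", 0.17), ("GTA", 0.12)],
}


class CodonUsageTable:
    """Per-amino-acid synonymous-codon relative frequencies for one host."""

    def __init__(self, host: str, usage: dict[str, list[tuple[str, float]]]):
        self.host = host
        self.usage: dict[str, list[tuple[str, float]]] = {}
        for aa, entries in usage.items():
            if not entries:
                raise TableError(f"amino acid {aa} has no codons")
            total = sum(f for _, f in entries)
            if total <= 0:
                raise TableError(f"amino acid {aa}: non-positive frequencies")
            norm = [(c.upper(), f / total) for c, f in entries]
            for codon, _ in norm:
                if STANDARD_CODE.amino_acid(codon) != aa:
                    raise TableError(
                        f"codon {codon} does not encode {aa} under the "
                        "standard code"
                    )
            # highest frequency first; ties broken alphabetically
            norm.sort(key=lambda cf: (-cf[1], cf[0]))
            self.usage[aa] = norm
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.usage)
        if missing:
            raise TableError(f"table lacks amino acids: {sorted(missing)}")

    def codons(self, aa: str) -> list[tuple[str, float]]:
        try:
            return list(self.usage[aa])
        except KeyError:
            raise TableError(f"amino acid {aa!r} missing from table") from None

    def preferred(self, aa: str) -> str:
        return self.codons(aa)[0][0]

    def synonyms_by_rank(self, aa: str) -> list[str]:
        return [c for c, _ in self.codons(aa)]

    @classmethod
    def mouse(cls) -> "CodonUsageTable":
        return cls("Mus musculus", _MOUSE_USAGE)

    @classmethod
    def from_file(cls, path, host: Optional[str] = None) -> "CodonUsageTable":
        """Two-column text: ``codon frequency`` per line, grouped by amino
        acid (grouping is implied by the genetic code; blank lines and ``#``
        comments ignored)."""
        path = Path(path)
        usage: dict[str, list[tuple[str, float]]] = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, freq = line.split()[:2]
            aa = STANDARD_CODE.amino_acid(codon.upper())
            if aa is None:
                continue  # stop codons are not part of usage tables
            usage.setdefault(aa, []).append((codon.upper(), float(freq)))
        return cls(host or path.stem, usage)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# codon usage, host: {self.host}\n")
            for aa in sorted(self.usage):
                for codon, freq in self.usage[aa]:
                    fh.write(f"{codon}\t{freq:.6f}\n")


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    site: str

    def __post_init__(self):
        site = self.site.upper()
        if len(site) < 4 or set(site) - set("ACGT"):
            raise InputError(
                f"enzyme {self.name}: recognition site must be >= 4 nt over "
                f"A/C/G/T, got {self.site!r}"
            )
        object.__setattr__(self, "site", site)

    @property
    def palindromic(self) -> bool:
        return revcomp(self.site) == self.site


ENZYMES = {
    "KpnI": RestrictionEnzyme("KpnI", "GGTACC"),
    "BamHI": RestrictionEnzyme("BamHI", "GGATCC"),
    "NotI": RestrictionEnzyme("NotI", "GCGGCCGC"),
    "EcoRI": RestrictionEnzyme("EcoRI", "GAATTC"),
    "XhoI": RestrictionEnzyme("XhoI", "CTCGAG"),
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT"),
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return ENZYMES[name]
    except KeyError:
        raise InputError(
            f"unknown enzyme {name!r}; known: {sorted(ENZYMES)}"
        ) from None


def back_translate(
    p: ProteinSequence,
    table: Optional[CodonUsageTable] = None,
    mode: str = "deterministic",
    seed: int = 0,
) -> NucleotideSequence:
    """Reverse-translate with host-preferred codons.

    ``deterministic`` picks each residue's highest-frequency codon (ties
    alphabetical); ``sampled`` draws codons proportionally to usage under the
    seed. Either way ``translate(result) == p``.
    """
    if table is None:
        table = CodonUsageTable.mouse()
    if mode == "deterministic":
        codons = [table.preferred(aa) for aa in p.residues]
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        codons = []
        for aa in p.residues:
            opts = table.codons(aa)
            probs = np.array([f for _, f in opts])
            probs = probs / probs.sum()
            codons.append(opts[rng.choice(len(opts), p=probs)][0])
    else:
        raise InputError(f"unknown mode {mode!r}")
    return NucleotideSequence(p.id, "".join(codons), p.description)


def scan_sites(
    nt: NucleotideSequence, enzymes: Sequence[RestrictionEnzyme]
) -> list[tuple[RestrictionEnzyme, int]]:
    """All recognition-site occurrences on both strands.

    Positions are 0-based starts on the given (top) strand; a reverse-strand
    occurrence is reported at the top-strand start of its reverse complement.
    Palindromic sites are deduplicated.
    """
    seq = nt.bases
    hits: set[tuple[str, int]] = set()
    by_name = {}
    for enz in enzymes:
        by_name[enz.name] = enz
        patterns = {enz.site}
        if not enz.palindromic:
            patterns.add(revcomp(enz.site))
        for pat in patterns:
            start = seq.find(pat)
            while start != -1:
                hits.add((enz.name, start))
                start = seq.find(pat, start + 1)
    return sorted(
        ((by_name[name], pos) for name, pos in hits),
        key=lambda h: (h[1], h[0].name),
    )


def remove_sites(
    nt: NucleotideSequence,
    frame_start: int,
    enzymes: Sequence[RestrictionEnzyme],
    table: Optional[CodonUsageTable] = None,
    protected: Sequence[tuple[int, int]] = (),
    max_iter: int = 100,
) -> NucleotideSequence:
    """Eliminate internal recognition sites by synonymous codon substitution.

    Works leftmost-hit first: one codon overlapping the site is replaced by
    its next-most-frequent synonym so that the site disappears; translation
    is unchanged by construction. Hits overlapping a ``protected`` interval
    (e.g. a linker whose NotI core is wanted) are exempt. Raises
    :class:`UnresolvableSiteError` when no synonymous escape exists, or after
    ``max_iter`` rounds.
    """
    if table is None:
        table = CodonUsageTable.mouse()
    seq = nt.bases
    orf_len = len(seq) - frame_start
    orf_codons = orf_len // 3

    def is_protected(pos: int, length: int) -> bool:
        return any(pos < pe and pos + length > ps for ps, pe in protected)

    original_aa = translate(
        NucleotideSequence(nt.id, seq[frame_start : frame_start + orf_codons * 3]),
    ).protein.residues

    for _ in range(max_iter):
        hits = [
            (enz, pos)
            for enz, pos in scan_sites(NucleotideSequence(nt.id, seq), enzymes)
            if not is_protected(pos, len(enz.site))
        ]
        if not hits:
            out = NucleotideSequence(nt.id, seq, nt.description)
            check = translate(
                NucleotideSequence(
                    nt.id, seq[frame_start : frame_start + orf_codons * 3]
                )
            ).protein.residues
            assert check == original_aa, "site removal altered the translation"
            return out
        enz, pos = hits[0]
        site_end = pos + len(enz.site)
        first_codon = max((pos - frame_start) // 3, 0)
        last_codon = min((site_end - 1 - frame_start) // 3, orf_codons - 1)
        fixed = False
        for ci in range(first_codon, last_codon + 1):
            if ci < 0:
                continue
            cstart = frame_start + 3 * ci
            current = seq[cstart : cstart + 3]
            aa = STANDARD_CODE.amino_acid(current)
            if aa is None:
                continue
            for alt in table.synonyms_by_rank(aa):
                if alt == current:
                    continue
                candidate = seq[:cstart] + alt + seq[cstart + 3 :]
                window = candidate[max(pos - 1, 0) : site_end + 1]
                still = enz.site in window or revcomp(enz.site) in window
                # re-scan the exact position to confirm the hit is gone
                if candidate[pos:site_end] not in (enz.site, revcomp(enz.site)) and not still:
                    seq = candidate
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            raise UnresolvableSiteError(
                f"no synonymous substitution removes the {enz.name} site at "
                f"position {pos} (forced Met/Trp codons?)",
                position=pos,
            )
    raise UnresolvableSiteError(
        f"site removal did not converge within {max_iter} iterations"
    )


# ---------------------------------------------------------------------------
# Cassette assembly
# ---------------------------------------------------------------------------

ELEMENT_ROLES = (
    "promoter", "kozak", "orf", "linker", "t2a", "reporter", "stop",
    "cloning_site",
)

_FEATURE_TYPE = {
    "orf": "CDS",
    "reporter": "CDS",
    "promoter": "regulatory",
    "kozak": "regulatory",
    "linker": "misc_feature",
    "t2a": "misc_feature",
    "stop": "misc_feature",
    "cloning_site": "misc_feature",
}


@dataclass(frozen=True)
class CassetteElement:
    role: str
    sequence: str
    note: str = ""

    def __post_init__(self):
        if self.role not in ELEMENT_ROLES:
            raise CassetteError(f"unknown element role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExpressionCassette:
    """Annotated nucleotide construct (element list + full sequence)."""

    name: str
    style: str  # "direct_fusion" | "t2a_bicistronic"
    elements: tuple[CassetteElement, ...]
    promoter: str = ""
    host: str = ""

    @property
    def sequence(self) -> str:
        return "".join(e.sequence for e in self.elements)

    def nucleotide(self) -> NucleotideSequence:
        return NucleotideSequence(self.name, self.sequence)

    def coding_region(self) -> tuple[int, int]:
        """Top-strand interval of the uninterrupted reading frame."""
        coding_roles = {"orf", "linker", "t2a", "reporter", "stop", "kozak"}
        start = end = None
        pos = 0
        for el in self.elements:
            if el.role in coding_roles and el.role != "kozak":
                if start is None:
                    start = pos
                end = pos + len(el)
            pos += len(el)
        if start is None:
            raise CassetteError("cassette has no coding elements")
        return start, end

    def validate(self) -> None:
        """Check the reading-frame invariants of the declared style."""
        start, end = self.coding_region()
        cds = self.sequence[start:end]
        if len(cds) % 3:
            raise CassetteError("coding region length is not a multiple of 3")
        res = translate(NucleotideSequence(self.name, cds))
        n_codons = len(cds) // 3
        if res.stop_codon_index is None:
            raise CassetteError("coding region lacks a terminal stop codon")
        if res.stop_codon_index != n_codons - 1:
            raise CassetteError(
                f"internal stop at codon {res.stop_codon_index} of the "
                "coding region"
            )
        # direct_fusion: reporter-initiator deletion is enforced at fusion
        # time (a leading ATG could legitimately reappear from a Met codon).

    def to_seqrecord(self) -> SeqRecord:
        record = SeqRecord(
            Seq(self.sequence),
            id=self.name[:16] or "cassette",
            name=(self.name[:16] or "cassette").replace(" ", "_"),
            description=f"{self.style} expression cassette",
        )
        record.annotations["molecule_type"] = "DNA"
        record.annotations["date"] = "01-JAN-1980"
        if self.promoter:
            record.annotations["comment"] = f"promoter={self.promoter}; host={self.host}; style={self.style}"
        pos = 0
        for el in self.elements:
            feature = SeqFeature(
                FeatureLocation(pos, pos + len(el)),
                type=_FEATURE_TYPE[el.role],
                qualifiers={"label": [el.role], "note": [el.note or el.role]},
            )
            record.features.append(feature)
            pos += len(el)
        return record

    @classmethod
    def from_seqrecord(cls, record: SeqRecord) -> "ExpressionCassette":
        elements = []
        style = "direct_fusion"
        promoter = host = ""
        comment = record.annotations.get("comment", "")
        if isinstance(comment, (list, tuple)):
            comment = " ".join(comment)
        for tokens in comment.replace("\n", " ").split(";"):
            tokens = tokens.strip()
            if tokens.startswith("promoter="):
                promoter = tokens.split("=", 1)[1]
            elif tokens.startswith("host="):
                host = tokens.split("=", 1)[1]
            elif tokens.startswith("style="):
                style = tokens.split("=", 1)[1]
        for feat in sorted(record.features, key=lambda f: int(f.location.start)):
            role = feat.qualifiers.get("label", ["misc_feature"])[0]
            note = feat.qualifiers.get("note", [""])[0]
            sub = str(record.seq[int(feat.location.start) : int(feat.location.end)])
            elements.append(CassetteElement(role, sub, note))
        return cls(
            name=record.id, style=style, elements=tuple(elements),
            promoter=promoter, host=host,
        )


def fuse_reporter(
    orf: NucleotideSequence,
    reporter: NucleotideSequence,
    linker: str = DEFAULT_LINKER,
    style: str = "direct_fusion",
    t2a: Optional[str] = None,
    stop_codon: str = DEFAULT_STOP,
    name: Optional[str] = None,
) -> ExpressionCassette:
    """Fuse a reporter to the receptor ORF.

    ``direct_fusion``: ORF + in-frame linker + reporter with its initiator
    codon deleted + one terminal stop, a single uninterrupted reading frame.
    ``t2a_bicistronic``: ORF + 2A peptide + reporter with its initiator
    retained (the AAV vector layout); the 2A sequence must be supplied.
    A terminal stop on the incoming ORF is stripped with a logged notice.
    """
    if stop_codon not in STANDARD_CODE.stops:
        raise InputError(f"{stop_codon!r} is not a stop codon")
    orf_seq = orf.bases
    if len(orf_seq) % 3:
        raise FrameError(f"ORF length {len(orf_seq)} is not a multiple of 3")
    if orf_seq[-3:] in STANDARD_CODE.stops:
        logger.info("ORF %s: terminal stop codon stripped before fusion", orf.id)
        orf_seq = orf_seq[:-3]
    res = translate(NucleotideSequence(orf.id, orf_seq))
    if res.stopped:
        raise CassetteError(
            f"ORF {orf.id} contains an internal stop at codon "
            f"{res.stop_codon_index}"
        )
    rep_seq = reporter.bases
    if rep_seq[-3:] in STANDARD_CODE.stops:
        rep_seq = rep_seq[:-3]

    if style == "direct_fusion":
        if len(linker) % 3:
            raise FrameError(
                f"direct-fusion linker length {len(linker)} is not a multiple "
                "of 3; the reading frame would shift"
            )
        if not rep_seq.startswith("ATG"):
            raise InputError(
                f"reporter {reporter.id} lacks an initial ATG; cannot delete "
                "its start codon"
            )
        elements = (
            CassetteElement("orf", orf_seq, f"receptor ORF ({orf.id})"),
            CassetteElement("linker", linker.upper(), "in-frame linker"),
            CassetteElement(
                "reporter", rep_seq[3:],
                f"{reporter.id} (start codon deleted)",
            ),
            CassetteElement("stop", stop_codon, "terminal stop"),
        )
    elif style == "t2a_bicistronic":
        if not t2a:
            raise InputError(
                "t2a_bicistronic style requires an explicit 2A peptide "
                "sequence"
            )
        if len(t2a) % 3:
            raise FrameError(f"2A sequence length {len(t2a)} is not a multiple of 3")
        elements = (
            CassetteElement("orf", orf_seq, f"receptor ORF ({orf.id})"),
            CassetteElement("t2a", t2a.upper(), "self-cleaving 2A peptide"),
            CassetteElement("reporter", rep_seq, f"{reporter.id} (initiator retained)"),
            CassetteElement("stop", stop_codon, "terminal stop"),
        )
    else:
        raise InputError(f"unknown fusion style {style!r}")
    cassette = ExpressionCassette(
        name=name or f"{orf.id}-{reporter.id}", style=style, elements=elements,
    )
    cassette.validate()
    return cassette


def build_cassette(
    promoter: str,
    insert: ExpressionCassette,
    upstream_site: RestrictionEnzyme,
    downstream_site: RestrictionEnzyme,
    table: Optional[CodonUsageTable] = None,
    auto_remove: bool = True,
    host: str = "Mus musculus",
) -> ExpressionCassette:
    """Flank the fused insert with cloning sites under a named promoter.

    The insert must be internally free of both cloning sites; when
    ``auto_remove`` is set (default) internal hits inside the reading frame
    are first cleared by synonymous substitution with the linker/2A exempt,
    otherwise (or if hits remain) a :class:`CassetteError` lists the
    positions.
    """
    elements = list(insert.elements)
    seq = "".join(e.sequence for e in elements)
    cloning = [upstream_site, downstream_site]

    def internal_hits(s: str):
        return scan_sites(NucleotideSequence("insert", s), cloning)

    protected = []
    pos = 0
    for el in elements:
        if el.role in ("linker", "t2a"):
            protected.append((pos, pos + len(el)))
        pos += len(el)

    hits = [
        (e, p) for e, p in internal_hits(seq)
        if not any(p < pe and p + len(e.site) > ps for ps, pe in protected)
    ]
    if hits and auto_remove:
        start, _ = insert.coding_region()
        cleaned = remove_sites(
            NucleotideSequence(insert.name, seq),
            frame_start=start,
            enzymes=cloning,
            table=table,
            protected=protected,
        )
        # redistribute the cleaned sequence back onto the element boundaries
        new_elements = []
        pos = 0
        for el in elements:
            new_elements.append(
                CassetteElement(el.role, cleaned.bases[pos : pos + len(el)], el.note)
            )
            pos += len(el)
        elements = new_elements
        seq = cleaned.bases
        hits = [
            (e, p) for e, p in internal_hits(seq)
            if not any(p < pe and p + len(e.site) > ps for ps, pe in protected)
        ]
    if hits:
        raise CassetteError(
            "insert contains internal cloning site(s): "
            + ", ".join(f"{e.name}@{p}" for e, p in hits),
            positions=[p for _, p in hits],
        )
    full = (
        [CassetteElement("cloning_site", upstream_site.site, upstream_site.name)]
        + elements
        + [CassetteElement("cloning_site", downstream_site.site, downstream_site.name)]
    )
    cassette = ExpressionCassette(
        name=insert.name, style=insert.style, elements=tuple(full),
        promoter=promoter, host=host,
    )
    cassette.validate()
    return cassette
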