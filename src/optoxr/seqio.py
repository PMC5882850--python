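"""Core sequence types, the genetic code, and FASTA/GenBank input/output.

Sequences are validated at construction: nucleotide sequences are normalized
to uppercase DNA over {A, C, G, T} (RNA ``U`` is accepted and mapped to ``T``
with a logged notice), protein sequences to the 20 standard one-letter codes.
Internal coordinates are 0-based, half-open everywhere in this package;
human-facing reports are 1-based, closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, LengthError, ParseError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence with an identifier.

    Lowercase input is uppercased and ``U`` is converted to ``T``; any other
    symbol (including ambiguity codes such as ``N``) raises
    :class:`~optoxr.errors.AlphabetError`. This workflow designs sequences
    and must never emit ambiguity.
    """

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        raw = self.bases.upper()
        if "U" in raw:
            logger.info("sequence %s: RNA symbol U converted to T", self.id)
            raw = raw.replace("U", "T")
        bad = set(raw) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r}: invalid nucleotide symbol(s) "
                f"{sorted(bad)!r} (alphabet is A/C/G/T)"
            )
        object.__setattr__(self, "bases", raw)

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int, sid: Optional[str] = None) -> "NucleotideSequence":
        return NucleotideSequence(sid or self.id, self.bases[start:end], self.description)


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20 standard residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        raw = self.residues.upper()
        bad = set(raw) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r}: invalid residue symbol(s) {sorted(bad)!r} "
                "(20 standard amino-acid letters only; no internal stop)"
            )
        object.__setattr__(self, "residues", raw)

    def __len__(self) -> int:
        return len(self.residues)


class GeneticCode:
    """Codon -> amino-acid mapping (64 entries) plus the stop-codon set.

    The code table is data: alternate tables can be constructed from any
    mapping, but only the standard code ships enabled.
    """

    def __init__(self, forward: dict[str, str], stops: set[str], name: str = "custom"):
        if len(forward) + len(stops) != 64:
            raise ValueError("genetic code must map exactly 64 codons")
        self.forward = dict(forward)
        self.stops = frozenset(stops)
        self.name = name
        by_aa: dict[str, list[str]] = {}
        for codon, aa in self.forward.items():
            by_aa.setdefault(aa, []).append(codon)
        self._by_aa = {aa: sorted(cs) for aa, cs in by_aa.items()}

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        return cls(dict(table.forward_table), set(table.stop_codons), name="standard")

    def amino_acid(self, codon: str) -> Optional[str]:
        """Translate one codon; ``None`` means stop."""
        if codon in self.stops:
            return None
        try:
            return self.forward[codon]
        except KeyError:
            raise AlphabetError(f"invalid codon {codon!r}") from None

    def codons_for(self, aa: str) -> list[str]:
        try:
            return list(self._by_aa[aa])
        except KeyError:
            raise AlphabetError(f"no codons for symbol {aa!r}") from None


STANDARD_CODE = GeneticCode.standard()
# sanity: standard stop set
assert STANDARD_CODE.stops == frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class TranslationResult:
    """Protein product of a translation plus where (if) a stop was hit.

    ``stop_codon_index`` is the 0-based codon index of the first stop codon
    encountered, or ``None`` if translation ran to the end of the sequence.
    """

    protein: ProteinSequence
    stop_codon_index: Optional[int]

    @property
    def stopped(self) -> bool:
        return self.stop_codon_index is not None


def translate(nt: NucleotideSequence, frame: int = 0) -> TranslationResult:
    """Translate successive codons from ``frame`` until the end or first stop.

    The trailing partial codon is ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if len(nt) - frame < 3:
        raise LengthError(
            f"sequence {nt.id!r}: need at least one full codon after frame "
            f"{frame} (length {len(nt)})"
        )
    residues = []
    stop_index: Optional[int] = None
    seq = nt.bases
    for ci, pos in enumerate(range(frame, len(seq) - 2, 3)):
        aa = STANDARD_CODE.amino_acid(seq[pos : pos + 3])
        if aa is None:
            stop_index = ci
            break
        residues.append(aa)
    prot = ProteinSequence(nt.id, "".join(residues), nt.description)
    return TranslationResult(prot, stop_index)


def reverse_complement(nt: NucleotideSequence) -> NucleotideSequence:
    """Reverse-complement; an involution on valid DNA."""
    return NucleotideSequence(
        nt.id, nt.bases.translate(_COMPLEMENT)[::-1], nt.description
    )


def revcomp(bases: str) -> str:
    """Reverse-complement a raw base string (validated)."""
    bad = set(bases.upper()) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid nucleotide symbol(s) {sorted(bad)!r}")
    return bases.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / GenBank I/O
# ---------------------------------------------------------------------------


def _check_fasta_shape(path: Path) -> None:
    """Raise ParseError naming the line number for obviously malformed FASTA."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected a '>' header before "
                    "sequence data"
                )
            return
    raise ParseError(f"{path}: empty file, no FASTA records")


def _dedupe_ids(records: list) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            new_id = f"{rec.id}.{seen[rec.id]}"
            logger.warning("duplicate id %s renamed to %s", rec.id, new_id)
            rec.id = new_id
        else:
            seen[rec.id] = 0


def read_fasta(path, kind: str = "nucleotide"):
    """Read a multi-record FASTA into validated sequence objects.

    ``kind`` selects the target type: ``"nucleotide"`` or ``"protein"``.
    Duplicate ids are disambiguated with a numeric suffix and a warning.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    _dedupe_ids(records)
    out = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        if kind == "nucleotide":
            out.append(NucleotideSequence(rec.id, str(rec.seq), desc))
        elif kind == "protein":
            out.append(ProteinSequence(rec.id, str(rec.seq), desc))
        else:
            raise ValueError(f"unknown kind {kind!r}")
    return out


def write_fasta(seqs: Iterable, path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = []
    for s in seqs:
        letters = s.bases if isinstance(s, NucleotideSequence) else s.residues
        records.append(SeqRecord(Seq(letters), id=s.id, description=s.description))
    SeqIO.write(records, str(path), "fasta")


def read_genbank(path) -> SeqRecord:
    """Read one annotated GenBank record."""
    try:
        return SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genbank(record: SeqRecord, path) -> None:
    """Write an annotated record as a GenBank flat file.

    The LOCUS date is pinned so identical records serialize byte-identically.
    """
    record.annotations.setdefault("molecule_type", "DNA")
    record.annotations.setdefault("date", "01-JAN-1980")
    SeqIO.write(record, str(path), "genbank")
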