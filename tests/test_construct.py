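"""Codon optimization, restriction auditing, reporter fusion, cassettes."""

import numpy as np
import pytest

from optoxr.construct import (
    DEFAULT_LINKER,
    CodonUsageTable,
    ExpressionCassette,
    RestrictionEnzyme,
    back_translate,
    build_cassette,
    fuse_reporter,
    get_enzyme,
    remove_sites,
    scan_sites,
)
from optoxr.errors import (
    CassetteError,
    FrameError,
    InputError,
    TableError,
    UnresolvableSiteError,
)
from optoxr.seqio import NucleotideSequence, ProteinSequence, read_genbank, translate, write_genbank

KPNI = get_enzyme("KpnI")
BAMHI = get_enzyme("BamHI")
NOTI = get_enzyme("NotI")

LETTERS = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(seed: int, length: int) -> ProteinSequence:
    rng = np.random.default_rng(seed)
    return ProteinSequence(f"p{seed}", "".join(rng.choice(LETTERS, size=length)))


class TestCodonUsageTable:
    def test_frequencies_normalized(self, mouse_table):
        for aa, entries in mouse_table.usage.items():
            assert sum(f for _, f in entries) == pytest.approx(1.0, abs=1e-9)
            for codon, _ in entries:
                assert translate(NucleotideSequence("c", codon)).protein.residues == aa

    def test_file_round_trip(self, mouse_table, tmp_path):
        path = tmp_path / "mouse.txt"
        mouse_table.to_file(path)
        back = CodonUsageTable.from_file(path, host="Mus musculus")
        assert {aa: back.preferred(aa) for aa in back.usage} == {
            aa: mouse_table.preferred(aa) for aa in mouse_table.usage
        }

    def test_wrong_codon_rejected(self):
        with pytest.raises(TableError):
            CodonUsageTable("x", {**{aa: [(c, 1.0)] for aa, c in
                                     zip("ACDEFGHIKLMNPQRSTVWY",
                                         ["GCC", "TGC", "GAC", "GAG", "TTC", "GGC",
                                          "CAC", "ATC", "AAG", "CTG", "ATG", "AAC",
                                          "CCC", "CAG", "AGA", "AGC", "ACC", "GTG",
                                          "TGG", "TAC"])},
                                 "A": [("TTT", 1.0)]})


class TestBackTranslate:
    @pytest.mark.parametrize("mode", ["deterministic", "sampled"])
    def test_single_codon_residues(self, mouse_table, mode):
        assert back_translate(ProteinSequence("m", "M"), mouse_table, mode, seed=1).bases == "ATG"
        assert back_translate(ProteinSequence("w", "W"), mouse_table, mode, seed=1).bases == "TGG"

    @pytest.mark.parametrize("mode", ["deterministic", "sampled"])
    def test_round_trip(self, mouse_table, mode):
        p = random_protein(2, 120)
        nt = back_translate(p, mouse_table, mode, seed=2)
        assert translate(nt).protein.residues == p.residues

    def test_sampled_is_seed_deterministic(self, mouse_table):
        p = random_protein(9, 200)
        a = back_translate(p, mouse_table, "sampled", seed=5)
        b = back_translate(p, mouse_table, "sampled", seed=5)
        assert a.bases == b.bases


class TestScanSites:
    def test_kpni_single_hit(self):
        hits = scan_sites(NucleotideSequence("x", "AAGGTACCAA"), [KPNI])
        assert [(e.name, p) for e, p in hits] == [("KpnI", 2)]

    def test_linker_contains_noti_core(self):
        hits = scan_sites(NucleotideSequence("x", DEFAULT_LINKER), [NOTI])
        assert [(e.name, p) for e, p in hits] == [("NotI", 0)]

    def test_reverse_strand_hit_of_asymmetric_site(self):
        bsai = RestrictionEnzyme("BsaI", "GGTCTC")
        # revcomp(GGTCTC) = GAGACC present on the top strand
        hits = scan_sites(NucleotideSequence("x", "TTGAGACCTT"), [bsai])
        assert [(e.name, p) for e, p in hits] == [("BsaI", 2)]

    def test_site_free_sequence_is_empty(self):
        rng = np.random.default_rng(4)
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=300))
            if "GGTACC" not in seq and "GGATCC" not in seq:
                break
        assert scan_sites(NucleotideSequence("x", seq), [KPNI, BAMHI]) == []


class TestRemoveSites:
    def test_spanning_codon_site_removed(self, mouse_table):
        orf = NucleotideSequence("x", "ATGGGTACCTAA")
        out = remove_sites(orf, 0, [KPNI], mouse_table)
        assert scan_sites(out, [KPNI]) == []
        assert translate(out).protein.residues == "MGT"

    def test_fixed_point_when_clean(self, mouse_table):
        orf = NucleotideSequence("x", "ATGGCCAAATAA")
        out = remove_sites(orf, 0, [KPNI, BAMHI], mouse_table)
        assert out.bases == orf.bases

    def test_protected_region_exempt(self, mouse_table):
        # linker NotI core flagged protected stays untouched
        orf = NucleotideSequence("x", "ATG" + DEFAULT_LINKER + "TAA")
        out = remove_sites(orf, 0, [NOTI], mouse_table, protected=[(3, 12)])
        assert out.bases == orf.bases
        assert len(scan_sites(out, [NOTI])) == 1

    def test_unresolvable_raises_with_position(self, mouse_table):
        # TGGATGGATG..: BamHI-like site over forced Trp/Met codons
        orf = NucleotideSequence("x", "TGGATGTGGATG")  # W M W M
        enz = RestrictionEnzyme("fake", "GGATGTGGATG"[:6])  # GGATGT
        with pytest.raises(UnresolvableSiteError):
            remove_sites(orf, 0, [enz], mouse_table)


def make_reporter_nt(seed=0, length=60) -> NucleotideSequence:
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLNPQRSTVWY"
    p = ProteinSequence("rep", "M" + "".join(rng.choice(list(aas), size=length)))
    return NucleotideSequence("rep", back_translate(p).bases)


class TestFuseReporter:
    def test_direct_fusion_junction_and_initiator_deletion(self):
        orf = NucleotideSequence("orf", "ATGAAA")
        reporter = NucleotideSequence("rep", "ATGGTGAAACAC")
        cassette = fuse_reporter(orf, reporter, DEFAULT_LINKER, "direct_fusion")
        seq = cassette.sequence
        assert "AAA" + DEFAULT_LINKER + "GTG" in seq  # reporter ATG deleted
        roles = [e.role for e in cassette.elements]
        assert roles == ["orf", "linker", "reporter", "stop"]

    def test_direct_fusion_translation(self):
        chim = random_protein(6, 40)
        orf = back_translate(chim)
        reporter = make_reporter_nt(1, 30)
        cassette = fuse_reporter(orf, reporter, DEFAULT_LINKER, "direct_fusion")
        res = translate(NucleotideSequence("c", cassette.sequence))
        rep_protein = translate(reporter).protein.residues
        assert res.protein.residues == chim.residues + "AAA" + rep_protein[1:]
        assert res.stop_codon_index == len(res.protein.residues)

    def test_terminal_stop_stripped_with_notice(self, caplog):
        orf = NucleotideSequence("orf", "ATGAAATAA")
        reporter = NucleotideSequence("rep", "ATGGTGAAACAC")
        cassette = fuse_reporter(orf, reporter, DEFAULT_LINKER, "direct_fusion")
        assert cassette.elements[0].sequence == "ATGAAA"

    def test_bad_linker_frame(self):
        with pytest.raises(FrameError):
            fuse_reporter(
                NucleotideSequence("o", "ATGAAA"),
                NucleotideSequence("r", "ATGGTGAAA"),
                "GCGG", "direct_fusion",
            )

    def test_reporter_without_atg_rejected(self):
        with pytest.raises(InputError):
            fuse_reporter(
                NucleotideSequence("o", "ATGAAA"),
                NucleotideSequence("r", "GTGGTGAAA"),
                DEFAULT_LINKER, "direct_fusion",
            )

    def test_t2a_bicistronic_keeps_reporter_initiator(self):
        orf = NucleotideSequence("orf", "ATGAAA")
        reporter = NucleotideSequence("rep", "ATGGTGAAACAC")
        t2a = "GGA" * 18  # placeholder 2A, 54 nt
        cassette = fuse_reporter(orf, reporter, style="t2a_bicistronic", t2a=t2a)
        roles = [e.role for e in cassette.elements]
        assert roles == ["orf", "t2a", "reporter", "stop"]
        rep = next(e for e in cassette.elements if e.role == "reporter")
        assert rep.sequence.startswith("ATG")

    def test_t2a_requires_sequence(self):
        with pytest.raises(InputError):
            fuse_reporter(
                NucleotideSequence("o", "ATGAAA"),
                NucleotideSequence("r", "ATGGTGAAA"),
                style="t2a_bicistronic",
            )


class TestBuildCassette:
    def _fragment(self, seed=8):
        chim = random_protein(seed, 50)
        return fuse_reporter(back_translate(chim), make_reporter_nt(seed, 30),
                             DEFAULT_LINKER, "direct_fusion")

    def test_flanked_by_cloning_sites(self):
        cassette = build_cassette("hSyn", self._fragment(), KPNI, BAMHI)
        assert cassette.sequence.startswith("GGTACC")
        assert cassette.sequence.endswith("GGATCC")
        assert cassette.elements[0].role == "cloning_site"
        assert cassette.elements[-1].role == "cloning_site"

    def test_internal_site_error_without_auto_remove(self):
        frag = self._fragment()
        # plant a KpnI site inside the ORF element, in frame
        orf = frag.elements[0]
        planted = orf.sequence[:30] + "GGTACC" + orf.sequence[30:]
        from optoxr.construct import CassetteElement

        elements = (CassetteElement("orf", planted, orf.note),) + frag.elements[1:]
        frag2 = ExpressionCassette(frag.name, frag.style, elements)
        with pytest.raises(CassetteError) as exc:
            build_cassette("hSyn", frag2, KPNI, BAMHI, auto_remove=False)
        assert 30 in exc.value.positions

    def test_auto_remove_clears_internal_sites(self):
        frag = self._fragment()
        orf = frag.elements[0]
        planted = orf.sequence[:30] + "GGTACC" + orf.sequence[30:]
        from optoxr.construct import CassetteElement

        elements = (CassetteElement("orf", planted, orf.note),) + frag.elements[1:]
        frag2 = ExpressionCassette(frag.name, frag.style, elements)
        cassette = build_cassette("hSyn", frag2, KPNI, BAMHI, auto_remove=True)
        internal = cassette.sequence[6:-6]
        assert "GGTACC" not in internal and "GGATCC" not in internal

    def test_genbank_round_trip_preserves_element_table(self, tmp_path):
        cassette = build_cassette("hSyn", self._fragment(), KPNI, BAMHI)
        path = tmp_path / "cassette.gb"
        write_genbank(cassette.to_seqrecord(), path)
        back = ExpressionCassette.from_seqrecord(read_genbank(path))
        assert [(e.role, e.sequence) for e in back.elements] == [
            (e.role, e.sequence) for e in cassette.elements
        ]
        assert back.promoter == "hSyn"
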