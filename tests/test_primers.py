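"""Primer properties, in-silico PCR, junction design, ΔΔCt quantification."""

import numpy as np
import pandas as pd
import pytest

from optoxr.errors import InputError
from optoxr.fixtures import make_parent_chimera_set
from optoxr.primers import (
    PrimerPair,
    QpcrMeasurement,
    ddct,
    design_junction_primers,
    fold_changes,
    in_silico_pcr,
    primer_properties,
)
from optoxr.seqio import NucleotideSequence, revcomp

# qPCR oligos of a chimera-specific opto-GPR37 assay. The reverse oligo is
# stored with an internal typesetting space removed; the intended contiguous
# sequence is assumed, so no claim about its genomic context is encoded here.
OPTO_FWD = "TGACAACGAGTACACCACGG"
OPTO_REV = "GCTTCGTCGCAATGAGTTCC"


class TestPrimerProperties:
    def test_wallace_short_at(self):
        p = primer_properties("AAAA")
        assert (p.length, p.gc_fraction, p.tm) == (4, 0.0, 8.0)

    def test_wallace_short_gc(self):
        p = primer_properties("GGGG")
        assert (p.length, p.gc_fraction, p.tm) == (4, 1.0, 16.0)

    def test_assay_forward_primer(self):
        # direct tally: 5 G + 6 C over 20 nt
        p = primer_properties(OPTO_FWD)
        assert p.length == 20
        assert p.gc_fraction == pytest.approx(11 / 20)
        assert p.tm == pytest.approx(64.9 + 41 * (11 - 16.4) / 20)


def synthetic_template(seed=9, spacer=160):
    rng = np.random.default_rng(seed)
    flank1 = "".join(rng.choice(list("ACGT"), size=100))
    middle = "".join(rng.choice(list("ACGT"), size=spacer))
    flank2 = "".join(rng.choice(list("ACGT"), size=100))
    seq = flank1 + OPTO_FWD + middle + revcomp(OPTO_REV) + flank2
    return NucleotideSequence("tmpl", seq)


@pytest.fixture
def pair():
    return PrimerPair(
        "opto", NucleotideSequence("F", OPTO_FWD), NucleotideSequence("R", OPTO_REV)
    )


class TestInSilicoPcr:
    def test_constructed_template_single_product(self, pair):
        tmpl = synthetic_template()
        hits = in_silico_pcr(tmpl, pair)
        assert len(hits) == 1
        assert hits[0].product_length == len(OPTO_FWD) + 160 + len(OPTO_REV)
        assert hits[0].start == 100

    def test_missing_reverse_site_yields_nothing(self):
        rng = np.random.default_rng(9)
        flank1 = "".join(rng.choice(list("ACGT"), size=100))
        middle = "".join(rng.choice(list("ACGT"), size=160))
        tmpl = NucleotideSequence("tmpl", flank1 + OPTO_FWD + middle)
        p = PrimerPair(
            "opto", NucleotideSequence("F", OPTO_FWD), NucleotideSequence("R", OPTO_REV)
        )
        assert in_silico_pcr(tmpl, p) == []

    def test_strand_symmetry(self, pair):
        tmpl = synthetic_template()
        flipped = NucleotideSequence("flip", revcomp(tmpl.bases))
        fwd_hits = in_silico_pcr(tmpl, pair)
        rev_hits = in_silico_pcr(flipped, pair)
        assert len(rev_hits) == 1
        L = len(tmpl)
        h, f = fwd_hits[0], rev_hits[0]
        assert (L - f.end, L - f.start) == (h.start, h.end)

    def test_mismatch_tolerance_respects_three_prime_exact(self, pair):
        tmpl = synthetic_template()
        # mutate one base in the 5' half of the forward site: still amplifies
        seq = list(tmpl.bases)
        seq[102] = "A" if seq[102] != "A" else "C"
        assert len(in_silico_pcr(NucleotideSequence("m", "".join(seq)), pair)) == 1
        # mutate the forward primer's 3'-terminal base: no product
        seq = list(tmpl.bases)
        pos = 100 + len(OPTO_FWD) - 1
        seq[pos] = "A" if seq[pos] != "A" else "C"
        assert in_silico_pcr(NucleotideSequence("m", "".join(seq)), pair) == []

    def test_zero_mismatch_agrees_with_naive_scan(self):
        """Independent quadratic oracle for exact matching."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            n = int(rng.integers(300, 1200))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            fwd = seq[50:70]
            rev = revcomp(seq[200:220])
            p = PrimerPair("t", NucleotideSequence("F", fwd), NucleotideSequence("R", rev))
            got = {
                (h.start, h.end)
                for h in in_silico_pcr(NucleotideSequence("t", seq), p, max_mismatch=0)
            }
            naive = set()
            for probe_f, probe_r in ((fwd, rev), (rev, fwd)):
                rsite = revcomp(probe_r)
                for i in range(n - len(probe_f) + 1):
                    if seq[i : i + len(probe_f)] != probe_f:
                        continue
                    for j in range(i + len(probe_f), n - len(rsite) + 1):
                        if seq[j : j + len(rsite)] != rsite:
                            continue
                        if j + len(rsite) - i <= 2000:
                            naive.add((i, j + len(rsite)))
            assert got == naive


class TestDesignJunctionPrimers:
    def test_fixture_design_is_chimera_specific(self, bundle):
        label, aa_pos = next(
            (l, p) for l, p in bundle.design.junctions() if l == "IL3"
        )
        pair = design_junction_primers(
            bundle.chimera_cds, 3 * aa_pos,
            [bundle.backbone_cds, bundle.target_cds],
        )
        assert pair.specificity == "chimera-specific"
        assert in_silico_pcr(bundle.backbone_cds, pair) == []
        assert in_silico_pcr(bundle.target_cds, pair) == []
        hits = in_silico_pcr(bundle.chimera_cds, pair)
        assert len(hits) >= 1
        # junction strictly interior to the amplicon
        assert hits[0].start < 3 * aa_pos < hits[0].end

    def test_junction_at_origin_rejected(self, bundle):
        with pytest.raises(InputError):
            design_junction_primers(bundle.chimera_cds, 0, [])

    def test_no_parents_returns_unscreened(self, bundle):
        _, aa_pos = bundle.design.junctions()[0]
        pair = design_junction_primers(bundle.chimera_cds, 3 * aa_pos, [])
        assert pair.specificity == "unscreened"


class TestDdct:
    def test_identical_sample_is_unit_fold(self):
        m = QpcrMeasurement("a", (25.0, 25.2), (18.0, 18.1))
        assert ddct(m, m) == pytest.approx(1.0)

    def test_lower_target_ct_means_higher_fold(self):
        cal = QpcrMeasurement("cal", (25.0,), (18.0,))
        sample = QpcrMeasurement("s", (23.0,), (18.0,))  # ddCt = -2
        assert ddct(sample, cal) == pytest.approx(4.0)

    def test_higher_target_ct_means_lower_fold(self):
        cal = QpcrMeasurement("cal", (25.0,), (18.0,))
        sample = QpcrMeasurement("s", (26.0,), (18.0,))  # ddCt = +1
        assert ddct(sample, cal) == pytest.approx(0.5)

    def test_monotone_decreasing_in_target_ct(self):
        cal = QpcrMeasurement("cal", (25.0,), (18.0,))
        folds = [
            ddct(QpcrMeasurement("s", (ct,), (18.0,)), cal)
            for ct in np.linspace(20, 30, 11)
        ]
        assert all(a > b for a, b in zip(folds, folds[1:]))

    def test_empty_replicates_rejected(self):
        with pytest.raises(InputError):
            QpcrMeasurement("a", (), (18.0,))

    def test_tidy_table_fold_changes(self):
        rows = []
        for s, tct in (("control", 25.0), ("treated", 23.0)):
            rows += [
                {"sample": s, "gene": "target", "ct": tct},
                {"sample": s, "gene": "GAPDH", "ct": 18.0},
            ]
        out = fold_changes(pd.DataFrame(rows), "target", "GAPDH", "control")
        by = dict(zip(out["sample"], out["fold_change"]))
        assert by["control"] == pytest.approx(1.0)
        assert by["treated"] == pytest.approx(4.0)
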