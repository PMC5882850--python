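# optoxr

A design toolkit for **opto-XRs** — light-activatable chimeric receptors made
by grafting a G protein-coupled receptor's intracellular signaling surfaces
onto a light-sensing seven-transmembrane (7TM) backbone such as
channelrhodopsin-2 (ChR2). The canonical use case: an orphan GPCR (e.g.
GPR37) whose endogenous ligand is unknown cannot be probed pharmacologically;
an opto-GPCR chimera makes its downstream signaling optically addressable in
cells and in vivo.

The toolkit covers the full dry-lab design path:

1. **Topology calling** — partition a 7TM protein into the canonical 15
   segments (Nt, TM1–7, IL1–3, EL1–3, Ct) from windowed Kyte–Doolittle
   hydropathy, optionally refined by median consensus over an aligned
   homolog family (star multiple alignment around the reference, affine-gap
   Needleman–Wunsch pairwise cores).
2. **Chimera assembly** — replace the backbone's intracellular loops and/or
   C-terminus with the target GPCR's, splicing exactly at the backbone's TM
   boundaries, with per-part provenance tracking.
3. **Cassette compilation** — back-translate with host-preferred codons
   (Mus musculus default), clear internal cloning sites (KpnI `GGTACC`,
   BamHI `GGATCC`) by synonymous substitution, fuse a fluorescent reporter
   either in-frame through a 9-nt Ala-Ala-Ala linker (`GCGGCCGCC`, reporter
   initiator deleted) or bicistronically through a 2A peptide, and emit an
   annotated GenBank record flanked by the cloning sites.
4. **qPCR assay design** — junction-spanning primer pairs verified by
   in-silico PCR to amplify the chimera and neither parent, plus relative
   quantification by the standard 2^(−ΔΔCt) method:
   ΔCt = mean Ct(target) − mean Ct(reference);
   ΔΔCt = ΔCt(sample) − ΔCt(calibrator); fold change = 2^(−ΔΔCt).

A seeded synthetic-data module generates 7TM proteins with known ground-truth
topology, homolog families, parent/chimera scaffolds, and qPCR tables, so the
whole workflow is testable without any downloads.

## Worked example

```python
from optoxr.fixtures import make_parent_chimera_set
from optoxr.primers import design_junction_primers, in_silico_pcr

bundle = make_parent_chimera_set(3)          # backbone, target, chimera, CDSs
print(len(bundle.backbone.protein), len(bundle.target.protein),
      len(bundle.design.protein))            # 381 369 397

label, aa = next((l, p) for l, p in bundle.design.junctions() if l == "IL3")
pair = design_junction_primers(
    bundle.chimera_cds, 3 * aa,
    parents=[bundle.backbone_cds, bundle.target_cds],
)
print(pair.forward.bases, pair.reverse.bases, pair.specificity)
```

prints

```
forward: TCATGATGGACAACCAGAGC  (Tm 51.8 C, GC 0.50)
reverse: CACCATCTTGTCCTTTCTGC  (Tm 51.8 C, GC 0.50)
specificity: chimera-specific
```

The chimera is 397 residues: the backbone's 381 minus its intracellular
loops and C-terminus, plus the target's (which here are 16 residues longer
in total — loop lengths need not match, the splice points sit at the
backbone's TM boundaries). The designed pair's forward primer straddles the
IL3 splice junction (at least 6 bases on each side), so in-silico PCR finds
one 80-bp amplicon on the chimera CDS and zero products on either parent CDS
under the default screen (≤2 mismatches per primer, 3'-terminal 5 bases
exact, products ≤2 kb).

The same workflow is available from the shell:

```bash
optoxr simulate --seed 3 --out scenario/
optoxr pipeline run --scenario scenario/ --seed 3 --out design/
optoxr primers qpcr --table scenario/qpcr.csv \
    --target target --reference reference --calibrator calibrator
```

`pipeline run` executes topology → chimera → construct → primers and writes
a manifest (input checksums, fully resolved configuration with provenance,
seed); rerunning from the same manifest inputs reproduces every output file
byte for byte.

## Layout

- `src/optoxr/seqio.py` — validated sequence types, genetic code, FASTA/GenBank I/O
- `src/optoxr/align.py` — affine-gap global alignment, star MSA, coordinate maps
- `src/optoxr/topology.py` — hydropathy profiles, TM calling, 15-segment maps, consensus
- `src/optoxr/chimera.py` — swap specs, chimera assembly, provenance reports
- `src/optoxr/construct.py` — codon tables, back-translation, site removal, cassettes
- `src/optoxr/primers.py` — primer properties, in-silico PCR, junction design, ΔΔCt
- `src/optoxr/fixtures.py` — seeded synthetic generators with ground truth
- `src/optoxr/config.py`, `pipeline.py`, `cli.py` — layered config, end-to-end runs, CLI

See `docs/methods.md` for the models, parameter choices, and limitations.
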