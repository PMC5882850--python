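"""Scenario simulation and the end-to-end design pipeline.

``simulate_scenario`` writes a self-contained directory (parent proteins,
homolog family, ground-truth topology, coding sequences, reporter, qPCR
table, manifest) from one seed. ``run_pipeline`` executes the four design
stages — topology calling, chimera assembly, cassette compilation, junction
primer design — on such a directory and writes every output plus a manifest
recording input checksums, the fully resolved configuration with provenance,
the seed, and the stage list. All outputs are deterministic: two runs from
the same manifest inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .chimera import SwapSpec, assemble_chimera
from .config import RunConfig, resolve_config
from .construct import (
    CodonUsageTable,
    back_translate,
    build_cassette,
    fuse_reporter,
    get_enzyme,
)
from .errors import StageError
from .fixtures import (
    derive_seeds,
    make_family,
    make_parent_chimera_set,
    make_qpcr_table,
    make_reporter,
)
from .primers import PrimerDesignParams, design_junction_primers
from .seqio import read_fasta, write_fasta, write_genbank
from .topology import TopologyMap, call_topology

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_scenario(seed: int, out_dir, config: Optional[RunConfig] = None) -> Path:
    """Write a synthetic design scenario (all plain-text files) under a seed."""
    cfg = config or resolve_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_parent_chimera_set(seed)
    s_family, s_reporter, s_qpcr = derive_seeds(seed + 1, 3)

    write_fasta([bundle.backbone.protein, bundle.target.protein], out / "proteins.fasta")
    family = make_family(
        bundle.target, n=cfg["simulate.n_homologs"],
        sub_rate=cfg["simulate.sub_rate"], seed=s_family,
    )
    write_fasta(family, out / "family.fasta")
    with open(out / "truth.bed", "w") as fh:
        for topo in (bundle.backbone.topology, bundle.target.topology):
            for seg in topo.segments:
                fh.write(f"{topo.sequence_id}\t{seg.start}\t{seg.end}\t{seg.label}\n")
    write_fasta(
        [bundle.backbone_cds, bundle.target_cds, bundle.chimera_cds],
        out / "cds.fasta",
    )
    write_fasta([make_reporter(s_reporter)], out / "reporter.fasta")

    folds = [float(f) for f in str(cfg["simulate.qpcr_folds"]).split(",")]
    calibrator, samples = make_qpcr_table(
        s_qpcr, cfg["simulate.n_samples"], folds, cfg["simulate.qpcr_noise_sd"],
        n_replicates=cfg["simulate.n_replicates"],
    )
    rows = []
    for meas in [calibrator] + [m for m, _ in samples]:
        for ct in meas.target_ct:
            rows.append({"sample": meas.sample, "gene": "target", "ct": round(ct, 6)})
        for ct in meas.reference_ct:
            rows.append({"sample": meas.sample, "gene": "reference", "ct": round(ct, 6)})
    pd.DataFrame(rows).to_csv(out / "qpcr.csv", index=False)

    manifest = {
        "kind": "optoxr-scenario",
        "seed": seed,
        "version": __version__,
        "config": cfg.as_manifest(),
        "files": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def run_pipeline(
    scenario_dir,
    out_dir,
    config: Optional[RunConfig] = None,
    seed: int = 0,
) -> Path:
    """Topology -> chimera -> construct -> primers on a scenario directory."""
    cfg = config or resolve_config()
    scenario = Path(scenario_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done: list[str] = []
    failed_marker = out / "FAILED"

    def fail(stage: str, exc: Exception):
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise StageError(stage, str(exc)) from exc

    inputs = {
        name: scenario / name
        for name in ("proteins.fasta", "cds.fasta", "reporter.fasta")
    }
    for name, path in inputs.items():
        if not path.exists():
            fail("topology", FileNotFoundError(f"missing input {path}"))

    tcfg = cfg.section("topology")
    # stage 1: topology
    try:
        proteins = read_fasta(inputs["proteins.fasta"], kind="protein")
        if len(proteins) < 2:
            raise ValueError("proteins.fasta must contain backbone and target")
        backbone_p, target_p = proteins[0], proteins[1]
        maps = {}
        for p in (backbone_p, target_p):
            maps[p.id] = call_topology(
                p, window=tcfg["window"], threshold=tcfg["threshold"],
                min_tm_len=tcfg["min_tm_len"], max_tm_len=tcfg["max_tm_len"],
                min_loop_len=tcfg["min_loop_len"],
                orientation=tcfg["orientation"],
            )
        topo_dir = out / "topology"
        topo_dir.mkdir(exist_ok=True)
        maps[backbone_p.id].to_bed(topo_dir / "backbone.bed")
        maps[target_p.id].to_bed(topo_dir / "target.bed")
        stages_done.append("topology")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("topology", exc)

    # stage 2: chimera
    try:
        swap = SwapSpec.parse(cfg["chimera.swap"])
        design = assemble_chimera(
            backbone_p, maps[backbone_p.id], target_p, maps[target_p.id], swap
        )
        chim_dir = out / "chimera"
        chim_dir.mkdir(exist_ok=True)
        write_fasta([design.protein], chim_dir / "chimera.fasta")
        with open(chim_dir / "provenance.tsv", "w") as fh:
            fh.write("label\tsource\tstart\tend\n")
            for label, source, start, end in design.provenance_table():
                fh.write(f"{label}\t{source}\t{start}\t{end}\n")
        stages_done.append("chimera")
    except Exception as exc:  # noqa: BLE001
        fail("chimera", exc)

    # stage 3: construct
    try:
        table = CodonUsageTable.mouse()
        chimera_cds = back_translate(design.protein, table)
        reporter = read_fasta(inputs["reporter.fasta"], kind="nucleotide")[0]
        fragment = fuse_reporter(
            chimera_cds, reporter, linker=cfg["construct.linker"],
            style=cfg["construct.style"],
            stop_codon=cfg["construct.stop_codon"],
        )
        cassette = build_cassette(
            cfg["construct.promoter"], fragment,
            get_enzyme(cfg["construct.upstream_site"]),
            get_enzyme(cfg["construct.downstream_site"]),
            table=table, host=cfg["construct.host"],
        )
        cons_dir = out / "construct"
        cons_dir.mkdir(exist_ok=True)
        write_genbank(cassette.to_seqrecord(), cons_dir / "cassette.gb")
        stages_done.append("construct")
    except Exception as exc:  # noqa: BLE001
        fail("construct", exc)

    # stage 4: primers
    try:
        parents = read_fasta(inputs["cds.fasta"], kind="nucleotide")[:2]
        junctions = design.junctions()
        if not junctions:
            raise ValueError("design has no provenance junction")
        label, aa_pos = junctions[0]
        nt_junction = 3 * aa_pos
        pcfg = cfg.section("primers")
        params = PrimerDesignParams(
            primer_len_min=pcfg["primer_len_min"],
            primer_len_max=pcfg["primer_len_max"],
            amplicon_min=pcfg["amplicon_min"],
            amplicon_max=pcfg["amplicon_max"],
            junction_anchor=pcfg["junction_anchor"],
            max_mismatch=pcfg["max_mismatch"],
            three_prime_exact=pcfg["three_prime_exact"],
            max_product=pcfg["max_product"],
        )
        pair = design_junction_primers(
            chimera_cds, nt_junction, parents, params, name=f"{label}_junction"
        )
        prim_dir = out / "primers"
        prim_dir.mkdir(exist_ok=True)
        with open(prim_dir / "primers.tsv", "w") as fh:
            fh.write("name\tforward\treverse\tamplicon_start\tamplicon_end\tspecificity\n")
            fh.write(
                f"{pair.name}\t{pair.forward.bases}\t{pair.reverse.bases}\t"
                f"{pair.amplicon[0]}\t{pair.amplicon[1]}\t{pair.specificity}\n"
            )
        stages_done.append("primers")
    except Exception as exc:  # noqa: BLE001
        fail("primers", exc)

    manifest = {
        "kind": "optoxr-run",
        "seed": seed,
        "version": __version__,
        "config": cfg.as_manifest(),
        "inputs": {name: _sha256(path) for name, path in sorted(inputs.items())},
        "stages": stages_done,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
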