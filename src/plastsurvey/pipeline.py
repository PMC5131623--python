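"""End-to-end orchestration: structure -> markers -> schemes -> trees -> rank.

`run_all` executes the whole survey on a list of annotated genomes (real or
simulated), writing region/class tables, the six concatenated scheme
alignments with partition files, per-marker trees and the ranked marker
table, plus a JSON manifest recording configuration, seeds and per-stage
outputs and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alnstats import SchemeSet, build_schemes, write_partition_file
from .errors import PipelineError
from .io import write_fasta_alignment
from .markers import extract_cds, survey_markers
from .model import CircularGenome, MarkerAlignment
from .ranking import survey_alignments
from .structure import class_stats, detect_inverted_repeats, region_stats, summarize_cohort
from .trees import PhyloTree, nj_from_alignment, write_newick

log = logging.getLogger(__name__)


def remove_ir_copy(genome: CircularGenome, min_ir: int = 10_000) -> CircularGenome:
    """Genome with the second inverted-repeat copy (IRb) removed.

    The circle is cut at the LSC start and IRb dropped, leaving
    LSC + IRa + SSC.  Features fully inside the retained span are shifted;
    features straddling a removed boundary are dropped (logged).  Used
    before scheme concatenation so IR loci are not represented twice.
    """
    p = detect_inverted_repeats(genome, min_ir=min_ir)
    n = genome.length
    ls = p.lsc[0] % n
    keep = n - p.ir_length
    seq = genome.fetch(ls, ls + keep)
    feats = []
    for f in genome.features:
        new_parts = []
        ok = True
        for s, e, st in f.parts:
            ns = (s - ls) % n
            if ns + (e - s) > keep:
                ok = False
                break
            new_parts.append((ns, ns + (e - s), st))
        if ok:
            feats.append(
                type(f)(name=f.name, ftype=f.ftype, parts=tuple(new_parts), pseudo=f.pseudo)
            )
        else:
            log.info("%s: feature %s dropped with IR copy", genome.id, f.name)
    return CircularGenome(id=genome.id, seq=seq, features=feats)


def marker_sets_to_alignments(
    sets: dict[str, dict[str, str]], mclass: str = "other"
) -> dict[str, MarkerAlignment]:
    """Collated per-taxon sequence sets -> alignments (pad if ragged).

    Simulator output is gap-free and column-homologous, so sequences of one
    marker already align; real unaligned data of unequal lengths is padded
    with trailing gaps and a warning — run a proper aligner upstream
    instead for real sequences.
    """
    out = {}
    for name in sorted(sets):
        seqs = sets[name]
        labels = sorted(seqs)
        width = max(len(seqs[t]) for t in labels)
        if any(len(seqs[t]) != width for t in labels):
            log.warning("marker %s: ragged sequence set padded with gaps", name)
        rows = [seqs[t].ljust(width, "-") for t in labels]
        out[name] = MarkerAlignment(name, labels, rows, mclass)
    return out


def build_scheme_set(
    genomes: list[CircularGenome],
    min_ir: int = 10_000,
    min_taxa: int = 4,
    window: int = 5,
    max_gap_frac: float = 0.5,
) -> SchemeSet:
    """The six analysis schemes from IR-reduced genomes."""
    reduced = [remove_ir_copy(g, min_ir=min_ir) for g in genomes]
    ncs_sets = survey_markers(reduced, min_len=1, max_len=10**9, min_taxa=min_taxa)
    cds_sets: dict[str, dict[str, str]] = {}
    for g in reduced:
        for mdef, seq in extract_cds(g):
            cds_sets.setdefault(mdef.name, {})[g.id] = seq
    cds_sets = {k: v for k, v in cds_sets.items() if len(v) >= min_taxa}
    ncs = marker_sets_to_alignments(ncs_sets)
    cds = marker_sets_to_alignments(cds_sets, mclass="cds")
    return build_schemes(ncs, cds, window=window, max_gap_frac=max_gap_frac)


@dataclass
class RunManifest:
    """What a pipeline run did: config, seeds, inputs, outputs, timings."""

    version: str
    config: dict
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(
    genomes: list[CircularGenome],
    outdir: str | Path,
    reference: PhyloTree | None = None,
    min_ir: int = 10_000,
    min_len: int = 400,
    max_len: int = 1_600,
    replicates: int = 100,
    seed: int = 0,
) -> RunManifest:
    """Run every stage of the survey and write all tables and trees.

    Outputs under ``outdir``: ``regions.tsv`` / ``classes.tsv`` and their
    cohort summaries, six scheme FASTAs with partition files, the
    full-scheme NJ tree (the default RF reference), the ranked marker
    table ``markers.tsv`` and ``manifest.json``.  Deterministic for a
    fixed input set and seed.  Any stage failure raises
    :class:`PipelineError` naming the stage, after writing a partial
    manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config={
            "min_ir": min_ir, "min_len": min_len, "max_len": max_len,
            "replicates": replicates, "n_genomes": len(genomes),
        },
        seed=seed,
    )

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest.warnings.append(f"stage {name} failed: {exc}")
            manifest.write(outdir / "manifest.json")
            raise PipelineError(name, exc) from exc
        manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
        return result

    def _structure():
        rows_r, rows_c = [], []
        for g in genomes:
            p = detect_inverted_repeats(g, min_ir=min_ir)
            rows_r.append(region_stats(g, p).as_row())
            rows_c.append(class_stats(g).as_row())
        regions = pd.DataFrame(rows_r).set_index("genome")
        classes = pd.DataFrame(rows_c).set_index("genome")
        regions.to_csv(outdir / "regions.tsv", sep="\t")
        classes.to_csv(outdir / "classes.tsv", sep="\t")
        summarize_cohort(regions).to_csv(outdir / "regions_summary.tsv", sep="\t")
        summarize_cohort(classes).to_csv(outdir / "classes_summary.tsv", sep="\t")
        manifest.outputs.update(
            regions="regions.tsv", classes="classes.tsv",
            regions_summary="regions_summary.tsv", classes_summary="classes_summary.tsv",
        )

    stage("structure", _structure)

    def _schemes():
        ss = build_scheme_set(genomes, min_ir=min_ir)
        for name, aln in ss.schemes.items():
            write_fasta_alignment(aln, outdir / f"scheme_{name}.fasta")
            write_partition_file(ss.partitions.get(name, []), outdir / f"scheme_{name}.partitions")
            manifest.outputs[f"scheme_{name}"] = f"scheme_{name}.fasta"
        return ss

    schemes = stage("schemes", _schemes)

    def _reference():
        if reference is not None:
            return reference
        tree = nj_from_alignment(schemes.schemes["full"])
        write_newick(tree, outdir / "full_scheme.nwk")
        manifest.outputs["reference_tree"] = "full_scheme.nwk"
        return tree

    ref = stage("reference_tree", _reference)

    def _rank():
        from .markers import survey_markers as _sm

        sets = _sm(genomes, min_len=min_len, max_len=max_len)
        alns = marker_sets_to_alignments(sets)
        table = survey_alignments(alns, ref, replicates=replicates, seed=seed)
        table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        manifest.outputs["markers"] = "markers.tsv"
        return table

    stage("rank", _rank)

    for key, rel in manifest.outputs.items():
        manifest.checksums[key] = _checksum(outdir / rel)
    manifest.write(outdir / "manifest.json")
    return manifest
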