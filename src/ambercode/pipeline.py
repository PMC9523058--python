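"""Pipeline orchestration: stage functions, configuration and reports.

Each stage reads its inputs from files in the run directory and writes
its outputs there, so the composed :func:`run_pipeline` and the per-stage
CLI subcommands produce identical results.  A run manifest (JSON) records
the configuration, its hash and the files produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import code_assign as ca
from . import evidence as ev
from . import proteodb as pdb
from . import synthdata as sd
from .seqcore import (
    Contig,
    load_code_table,
    predict_orfs,
    read_fasta,
    read_gff3,
    read_protein_fasta,
    select_nonoverlapping,
    write_fasta,
    write_gff3,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the validated defaults:
    10/5-point density thresholds, 30-residue upstream extensions,
    3 missed cleavages, 1% FDR, ALC >50, residue confidence >90,
    6 shared residues."""

    contigs: str | None = None
    auxiliary: str | None = None
    contaminants: str | None = None
    psms: str | None = None
    tags: str | None = None
    outdir: str = "ambercode_run"
    seed: int = 1

    min_protein_len: int = 30
    assign_mode: str = "absolute"
    skew_window: int = 1000
    skew_step: int = 10
    max_ext: int = 30
    max_missed: int = 3
    digest_specificity: str = "semi"
    digest_min_len: int = 6
    digest_max_len: int = 50
    fdr: float = 0.01
    min_shared: int = 6
    min_alc: float = 50.0
    min_residue_conf: float = 90.0
    flank: int = 2
    equate_il: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_contigs(config: PipelineConfig) -> dict[str, Contig]:
    if not config.contigs:
        raise ValueError("no contig FASTA configured")
    return {c.contig_id: c for c in read_fasta(config.contigs)}


def stage_predict(config: PipelineConfig) -> None:
    """Six-frame ORF prediction under codes 11 and 15 -> GFF3 files."""
    out = _outdir(config)
    contigs = _load_contigs(config)
    for code in (11, 15):
        table = load_code_table(code)
        genes = select_nonoverlapping(
            [
                g
                for c in sorted(contigs.values(), key=lambda c: c.contig_id)
                for g in predict_orfs(c, table, config.min_protein_len)
            ]
        )
        write_gff3(genes, out / f"genes_code{code}.gff3")


def stage_assign(config: PipelineConfig) -> None:
    """Coding-density code assignment and GC-skew profiles -> TSV."""
    out = _outdir(config)
    contigs = _load_contigs(config)
    g11 = read_gff3(out / "genes_code11.gff3", contigs)
    g15 = read_gff3(out / "genes_code15.gff3", contigs)
    rows = []
    skew_rows = []
    for cid in sorted(contigs):
        c = contigs[cid]
        a = ca.assign_code(
            c,
            [g for g in g11 if g.contig_id == cid],
            [g for g in g15 if g.contig_id == cid],
            mode=config.assign_mode,
        )
        rows.append(dataclasses.asdict(a))
        if len(c) >= config.skew_window:
            prof = ca.gc_skew(c, config.skew_window, config.skew_step)
            for p, s, cum in zip(prof.positions, prof.skew, prof.cumulative):
                skew_rows.append(
                    {
                        "contig_id": cid,
                        "position": int(p),
                        "skew": round(float(s), 6),
                        "cumulative": round(float(cum), 6),
                        "origin_pos": prof.origin_pos,
                        "terminus_pos": prof.terminus_pos,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(skew_rows).to_csv(out / "skew.tsv", sep="\t", index=False)


def stage_build_db(config: PipelineConfig) -> None:
    """Layered dual-code proteome database with decoys -> FASTA."""
    out = _outdir(config)
    contigs = _load_contigs(config)
    g11 = read_gff3(out / "genes_code11.gff3", contigs)
    g15 = read_gff3(out / "genes_code15.gff3", contigs)
    aux = read_protein_fasta(config.auxiliary) if config.auxiliary else None
    cont = read_protein_fasta(config.contaminants) if config.contaminants else None
    db = pdb.build_database(
        g11, g15, contigs, auxiliary=aux, contaminants=cont, max_ext=config.max_ext
    )
    pdb.write_database_fasta(db, out / "database.fasta")


def stage_fdr(config: PipelineConfig) -> None:
    """Peptide-level target-decoy FDR -> accepted_peptides.tsv."""
    out = _outdir(config)
    if not config.psms:
        raise ValueError("no PSM table configured")
    psms = ev.read_psm_table(config.psms)
    accepted = ev.fdr_filter(psms, threshold=config.fdr)
    pd.DataFrame(
        [
            {
                "peptide": p.peptide,
                "score": p.score,
                "q_value": p.q_value,
                "parents": ";".join(p.parent_ids),
            }
            for p in accepted
        ],
        columns=["peptide", "score", "q_value", "parents"],
    ).to_csv(out / "accepted_peptides.tsv", sep="\t", index=False)


def stage_map_evidence(config: PipelineConfig) -> None:
    """Codon-level mapping, classification, corroboration and summaries."""
    out = _outdir(config)
    contigs = _load_contigs(config)
    g11 = read_gff3(out / "genes_code11.gff3", contigs)
    g15 = read_gff3(out / "genes_code15.gff3", contigs)
    db = pdb.records_from_fasta(out / "database.fasta")
    by_id = {r.record_id: r for r in db}
    genes = {g.gene_id: g for g in g11 + g15}
    acc_df = pd.read_csv(out / "accepted_peptides.tsv", sep="\t", dtype=str)
    accepted = [
        ev.PSM(r.peptide, float(r.score), str(r.parents).split(";"), q_value=float(r.q_value))
        for r in acc_df.itertuples(index=False)
    ]
    tags = ev.read_tag_table(config.tags) if config.tags else []

    alignments: dict[str, list[ev.PeptideGenomeAlignment]] = {}
    classes: dict[str, frozenset[str]] = {}
    for p in accepted:
        alns: list[ev.PeptideGenomeAlignment] = []
        for pid in p.parent_ids:
            rec = by_id.get(pid)
            if rec is None or rec.is_decoy or rec.gene_id not in genes:
                continue
            try:
                alns.extend(ev.map_peptide(p.peptide, rec, genes[rec.gene_id], contigs[genes[rec.gene_id].contig_id]))
            except ev.MappingError as exc:
                logger.warning("skipping unmappable PSM: %s", exc)
        if alns:
            # deduplicate identical codon mappings from redundant parents
            uniq = {tuple(a.codon_spans): a for a in alns}
            alignments[p.peptide] = list(uniq.values())
            cls: set[str] = set()
            for a in alignments[p.peptide]:
                cls |= ev.classify_peptide(a, db, g11, equate_il=config.equate_il)
            classes[p.peptide] = frozenset(cls)

    events = ev.collect_recoding_events(
        accepted,
        alignments,
        contigs,
        db,
        g11,
        tags=tags,
        min_shared=config.min_shared,
        min_alc=config.min_alc,
        min_residue_conf=config.min_residue_conf,
        flank=config.flank,
    )
    pd.DataFrame(
        [
            {
                "contig_id": e.contig_id,
                "codon_start": e.span[0],
                "codon_end": e.span[1],
                "observed_residue": e.observed_residue,
                "n_peptides": len(e.supporting_peptides),
                "peptides": ";".join(e.supporting_peptides),
                "classes": ";".join(sorted(set().union(*e.evidence_classes.values()))),
                "denovo_corroborated": e.denovo_corroborated,
            }
            for e in events
        ],
        columns=[
            "contig_id",
            "codon_start",
            "codon_end",
            "observed_residue",
            "n_peptides",
            "peptides",
            "classes",
            "denovo_corroborated",
        ],
    ).to_csv(out / "events.tsv", sep="\t", index=False)

    summary, coverage = ev.summarize_genes(events, alignments, accepted, g15, classes)
    summary.to_csv(out / "gene_summary.tsv", sep="\t", index=False)
    coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)


def stage_report(config: PipelineConfig) -> None:
    """Human-readable run report from the stage TSVs."""
    out = _outdir(config)
    lines = ["# ambercode run report", ""]
    assignments = pd.read_csv(out / "assignments.tsv", sep="\t")
    lines.append("## Code assignment")
    for r in assignments.itertuples(index=False):
        lines.append(
            f"{r.contig_id}\tlen={r.contig_len}\tdensity11={r.density_11:.3f}\t"
            f"density15={r.density_15:.3f}\tgain={r.gain_points:.1f}pts\t"
            f"assigned=code {r.assigned_code}\trule={r.rule}"
        )
    ev_path = out / "events.tsv"
    if ev_path.exists():
        events = pd.read_csv(ev_path, sep="\t")
        lines += ["", f"## Recoding events ({len(events)})"]
        for r in events.itertuples(index=False):
            lines.append(
                f"{r.contig_id}:{r.codon_start}-{r.codon_end}\tTAG->Q\t"
                f"peptides={r.n_peptides}\tclasses={r.classes}\t"
                f"corroborated={r.denovo_corroborated}"
            )
        summary = pd.read_csv(out / "gene_summary.tsv", sep="\t")
        det = summary[summary.detected]
        lines += ["", f"## Detected genes ({len(det)}/{len(summary)})"]
        for r in det.itertuples(index=False):
            lines.append(
                f"{r.gene_id}\tpeptides={r.n_peptides}\tunique={r.n_unique_peptides}\t"
                f"exclusive={r.n_code15_exclusive}\tevents={r.n_recoding_events}\t"
                f"coverage={r.coverage:.2f}"
            )
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def write_manifest(config: PipelineConfig) -> None:
    out = _outdir(config)
    try:
        ver = _pkg_version("ambercode")
    except Exception:
        ver = "unknown"
    manifest = {
        "package": "ambercode",
        "version": ver,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and write the manifest; returns the outdir."""
    stage_predict(config)
    stage_assign(config)
    stage_build_db(config)
    if config.psms:
        stage_fdr(config)
        stage_map_evidence(config)
    stage_report(config)
    write_manifest(config)
    return _outdir(config)


def write_simulation(config: PipelineConfig, sim: sd.SimConfig | None = None) -> Path:
    """Generate the synthetic bundle (contig FASTA, PSM/tag TSVs, truth JSON)
    into the run directory and point the config at it."""
    out = _outdir(config)
    sim = sim or sd.SimConfig(seed=config.seed)
    contig, truth = sd.simulate_genome(sim)
    write_fasta([contig], out / "sim_contig.fasta")
    t11, t15 = load_code_table(11), load_code_table(15)
    g11 = select_nonoverlapping(predict_orfs(contig, t11, config.min_protein_len))
    g15 = select_nonoverlapping(predict_orfs(contig, t15, config.min_protein_len))
    db = pdb.build_database(g11, g15, contig, max_ext=config.max_ext)
    psm_df, tag_df, labels = sd.simulate_psms(db, truth, sim)
    psm_df.to_csv(out / "sim_psms.tsv", sep="\t", index=False)
    tag_df.to_csv(out / "sim_tags.tsv", sep="\t", index=False)
    labels.to_csv(out / "sim_labels.tsv", sep="\t", index=False)
    truth_json = {
        "sim_config": dataclasses.asdict(sim),
        "origin_pos": truth.origin_pos,
        "terminus_pos": truth.terminus_pos,
        "tag_positions": [[p, g] for p, g in truth.tag_positions],
        "genes": [
            {
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "code_id": g.code_id,
            }
            for g in truth.genes
        ],
    }
    (out / "sim_truth.json").write_text(json.dumps(truth_json, indent=1) + "\n")
    config.contigs = str(out / "sim_contig.fasta")
    config.psms = str(out / "sim_psms.tsv")
    config.tags = str(out / "sim_tags.tsv")
    return out
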