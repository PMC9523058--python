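"""Peptide evidence for stop-codon reassignment.

This module takes search-engine output (peptide-spectrum matches and
de novo sequence tags), applies classical target-decoy FDR at the peptide
level, maps accepted peptides codon-by-codon back onto the genome, and
classifies each one:

* ``code15-exclusive`` — the peptide exists in no code-11 (or auxiliary /
  contaminant) target protein, only in the code-15 proteome;
* ``stop-readthrough`` — a residue of the peptide sits on a genomic TAG
  codon with at least one residue on each side, i.e. translation read
  through a standard-code stop;
* ``start-readthrough`` — the peptide's genomic span covers a code-11
  start codon with residues upstream of it, i.e. translation started
  upstream of where the standard code says it could;
* ``shared`` — also explained by a standard-code protein.

A recoding event is a TAG codon observed as glutamine in one or more
accepted peptides; de novo tags corroborate an event when a long-enough
stretch matches the peptide and the recoded Q plus its flanking residues
all carry high per-residue confidence.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .proteodb import DECOY_PREFIX, ProteinRecord
from .seqcore import Contig, GeneModel, load_code_table, reverse_complement, translate

logger = logging.getLogger(__name__)

_MOD_RE = re.compile(r"\(([^()]*)\)")

_TABLE15 = load_code_table(15)


class SchemaError(ValueError):
    pass


class MappingError(ValueError):
    pass


@dataclass
class PSM:
    """A peptide-spectrum match, modifications stripped to ``mods``."""

    peptide: str
    score: float
    parent_ids: list[str]
    is_decoy: bool = False
    mixed_parents: bool = False
    mods: list[tuple[int, str]] = field(default_factory=list)
    q_value: float | None = None


@dataclass
class DeNovoTag:
    sequence: str
    alc: float  # average local confidence, percent
    residue_conf: list[float]  # per-residue confidence, percent

    def __post_init__(self):
        if len(self.residue_conf) != len(self.sequence):
            raise ValueError("residue_conf length != sequence length")
        if abs(self.alc - float(np.mean(self.residue_conf))) > 0.5:
            raise ValueError("ALC inconsistent with residue confidences")


@dataclass
class PeptideGenomeAlignment:
    peptide: str
    gene_id: str
    contig_id: str
    strand: str
    codon_spans: list[tuple[int, int]]  # one 3-nt forward-axis span per residue
    residues_at_TAG: list[int]  # peptide positions whose genomic codon is TAG


@dataclass
class RecodingEvent:
    contig_id: str
    span: tuple[int, int]  # forward-axis span of the TAG codon
    observed_residue: str
    supporting_peptides: list[str]
    evidence_classes: dict[str, frozenset[str]]  # peptide -> classes
    denovo_corroborated: bool = False


@dataclass
class CorroborationVerdict:
    corroborated: bool  # >= min_shared contiguous residues matched by a tag
    shared_len: int
    recoded_ok: dict[int, bool]  # peptide TAG position -> confidence check


def strip_modifications(peptide: str) -> tuple[str, list[tuple[int, str]]]:
    """Remove parenthesised modification annotations, e.g. ``M(+15.99)``.

    Returns the plain sequence and ``(residue_index, annotation)`` pairs
    where the index points at the residue preceding the annotation.
    """
    mods: list[tuple[int, str]] = []
    out: list[str] = []
    i = 0
    for token in _MOD_RE.split(peptide):
        if _is_mod_annotation(token, peptide):
            mods.append((len(out) - 1, token))
        else:
            out.extend(token)
    return "".join(out), mods


def _is_mod_annotation(token: str, raw: str) -> bool:
    return bool(token) and f"({token})" in raw


def read_psm_table(path) -> list[PSM]:
    """Read a PSM TSV with columns ``peptide``, ``score``, ``parents``
    (``;``-delimited record ids).  Decoy status derives from the parents:
    all-decoy parents make a decoy, any target parent makes a (possibly
    flagged) target."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("peptide", "score", "parents"):
        if col not in df.columns:
            raise SchemaError(f"PSM table missing required column {col!r}")
    psms: list[PSM] = []
    for row in df.itertuples(index=False):
        seq, mods = strip_modifications(str(row.peptide))
        parents = [p for p in str(row.parents).split(";") if p]
        decoy_flags = [p.startswith(DECOY_PREFIX) for p in parents]
        psms.append(
            PSM(
                peptide=seq,
                score=float(row.score),
                parent_ids=parents,
                is_decoy=all(decoy_flags) if parents else False,
                mixed_parents=any(decoy_flags) and not all(decoy_flags),
                mods=mods,
            )
        )
    return psms


def read_tag_table(path) -> list[DeNovoTag]:
    """Read de novo tags (columns ``tag``, ``alc``, ``residue_conf`` as a
    comma-delimited list).  Rows violating the per-residue invariants are
    dropped with a warning rather than aborting the run."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tag", "alc", "residue_conf"):
        if col not in df.columns:
            raise SchemaError(f"tag table missing required column {col!r}")
    tags: list[DeNovoTag] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            conf = [float(x) for x in str(row.residue_conf).split(",")]
            tags.append(DeNovoTag(str(row.tag), float(row.alc), conf))
        except ValueError as exc:
            logger.warning("tag table row %d rejected: %s", i, exc)
    return tags


# ---------------------------------------------------------------------------
# Target-decoy FDR


def fdr_filter(psms: list[PSM], threshold: float = 0.01) -> list[PSM]:
    """Peptide-level classical target-decoy FDR.

    PSMs are collapsed to the best-scoring entry per peptide sequence
    (a sequence matching both target and decoy parents counts as target).
    With entries sorted by decreasing score, FDR at rank k is
    ``decoys(<=k) / targets(<=k)``; q-values are the running minimum from
    the bottom; targets with q <= ``threshold`` are accepted.
    """
    best: dict[str, PSM] = {}
    for p in psms:
        cur = best.get(p.peptide)
        if cur is None or p.score > cur.score or (p.score == cur.score and cur.is_decoy and not p.is_decoy):
            best[p.peptide] = p
    ranked = sorted(best.values(), key=lambda p: (-p.score, p.is_decoy, p.peptide))
    if not any(p.is_decoy for p in ranked):
        logger.warning("no decoy PSMs present; all q-values are 0")
    n_decoy = 0
    n_target = 0
    fdrs = np.empty(len(ranked))
    for i, p in enumerate(ranked):
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs[i] = n_decoy / max(n_target, 1)
    qvals = np.minimum.accumulate(fdrs[::-1])[::-1] if len(ranked) else fdrs
    for p, q in zip(ranked, qvals):
        p.q_value = float(min(q, 1.0))
    return [p for p in ranked if not p.is_decoy and p.q_value <= threshold]


# ---------------------------------------------------------------------------
# Codon-level genome mapping


def map_peptide(
    peptide: str,
    record: ProteinRecord,
    gene: GeneModel,
    contig: Contig,
) -> list[PeptideGenomeAlignment]:
    """Map each residue of ``peptide`` to its 3-nt genomic codon span.

    One alignment per occurrence of the peptide in the parent record;
    upstream-extension records shift coordinates by ``extension_len`` so
    residues ahead of the annotated start map upstream of ``gene.start``.
    ``residues_at_TAG`` records the peptide positions whose literal genomic
    codon is TAG.
    """
    occurrences = [m.start() for m in re.finditer(f"(?={re.escape(peptide)})", record.sequence)]
    if not occurrences:
        raise MappingError(f"peptide {peptide!r} not found in record {record.record_id}")
    alignments = []
    for off in occurrences:
        spans: list[tuple[int, int]] = []
        at_tag: list[int] = []
        for r in range(len(peptide)):
            q = off - record.extension_len + r  # codon index relative to annotated start
            if gene.strand == "+":
                a = gene.start + 3 * q
            else:
                a = gene.end - 3 * (q + 1)
            if a < 0 or a + 3 > len(contig):
                raise MappingError(
                    f"residue {r} of {peptide!r} maps outside contig {contig.contig_id}"
                )
            spans.append((a, a + 3))
            codon = contig.sequence[a : a + 3]
            if gene.strand == "-":
                codon = reverse_complement(codon)
            if codon == "TAG":
                at_tag.append(r)
            expected = translate(codon, _TABLE15, stop_policy="readthrough")
            if expected not in ("X", peptide[r]):
                raise MappingError(
                    f"residue {r} of {peptide!r} ({peptide[r]}) does not match "
                    f"genomic codon {codon} at {a} on {contig.contig_id}"
                )
        alignments.append(
            PeptideGenomeAlignment(
                peptide=peptide,
                gene_id=gene.gene_id,
                contig_id=contig.contig_id,
                strand=gene.strand,
                codon_spans=spans,
                residues_at_TAG=at_tag,
            )
        )
    return alignments


def classify_peptide(
    alignment: PeptideGenomeAlignment,
    db: list[ProteinRecord],
    genes_11: list[GeneModel],
    equate_il: bool = False,
) -> frozenset[str]:
    """Evidence classes for one mapped peptide (order-independent in ``db``).

    Exactly one of ``code15-exclusive`` / ``shared`` is assigned, plus
    ``stop-readthrough`` and/or ``start-readthrough`` when the geometry
    applies.
    """
    classes: set[str] = set()
    pep = alignment.peptide
    key = pep.replace("I", "L") if equate_il else pep

    def contains(rec: ProteinRecord) -> bool:
        seq = rec.sequence.replace("I", "L") if equate_il else rec.sequence
        return key in seq

    standard_sources = {"phage-code11", "auxiliary", "contaminant"}
    in_standard = any(
        contains(r) for r in db if not r.is_decoy and r.source in standard_sources
    )
    classes.add("shared" if in_standard else "code15-exclusive")

    n = len(pep)
    if any(0 < r < n - 1 for r in alignment.residues_at_TAG):
        classes.add("stop-readthrough")

    pmin = min(a for a, _ in alignment.codon_spans)
    pmax = max(b for _, b in alignment.codon_spans)
    for g11 in genes_11:
        if g11.contig_id != alignment.contig_id or g11.strand != alignment.strand:
            continue
        if alignment.strand == "+":
            start_pos = g11.start
            in_frame = (start_pos - alignment.codon_spans[0][0]) % 3 == 0
            # >=1 residue upstream of the start codon and >=1 beyond it
            covers = pmin <= start_pos - 3 and pmax >= start_pos + 6
        else:
            start_pos = g11.end  # start codon occupies [end-3, end)
            in_frame = (start_pos - alignment.codon_spans[0][1]) % 3 == 0
            covers = pmax >= start_pos + 3 and pmin <= start_pos - 6
        if in_frame and covers:
            classes.add("start-readthrough")
            break
    return frozenset(classes)


# ---------------------------------------------------------------------------
# De novo corroboration


def _longest_common_stretch(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_in_a, start_in_b) of the longest common contiguous
    stretch, with I and L treated as equivalent (de novo tags cannot
    distinguish the isobaric pair)."""
    a_ = a.replace("I", "L")
    b_ = b.replace("I", "L")
    best = (0, 0, 0)
    prev = [0] * (len(b_) + 1)
    for i in range(1, len(a_) + 1):
        cur = [0] * (len(b_) + 1)
        for j in range(1, len(b_) + 1):
            if a_[i - 1] == b_[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best


def corroborate(
    peptide: str,
    tags: list[DeNovoTag],
    alignment: PeptideGenomeAlignment | None = None,
    min_shared: int = 6,
    min_alc: float = 50.0,
    min_residue_conf: float = 90.0,
    flank: int = 2,
) -> CorroborationVerdict:
    """Check whether any de novo tag corroborates the peptide.

    A tag must pass ALC > ``min_alc`` and share a contiguous stretch of at
    least ``min_shared`` residues with the peptide.  For each recoded
    position of the alignment, the recoded Q and up to ``flank`` neighbours
    on each side (clipped at the tag ends) must additionally each exceed
    ``min_residue_conf``.
    """
    recoded = list(alignment.residues_at_TAG) if alignment else []
    best = CorroborationVerdict(False, 0, {r: False for r in recoded})
    for tag in tags:
        if tag.alc <= min_alc:
            continue
        length, a0, b0 = _longest_common_stretch(peptide, tag.sequence)
        if length < min_shared:
            continue
        verdict = CorroborationVerdict(True, length, {})
        for r in recoded:
            if not (a0 <= r < a0 + length):
                verdict.recoded_ok[r] = False
                continue
            t = b0 + (r - a0)  # recoded Q position in tag coordinates
            lo = max(0, t - flank)
            hi = min(len(tag.sequence) - 1, t + flank)
            verdict.recoded_ok[r] = all(
                tag.residue_conf[k] > min_residue_conf for k in range(lo, hi + 1)
            )
        better = verdict.shared_len > best.shared_len or (
            sum(verdict.recoded_ok.values()) > sum(best.recoded_ok.values())
        )
        if not best.corroborated or better:
            best = verdict
    return best


# ---------------------------------------------------------------------------
# Event collection and gene summaries


def collect_recoding_events(
    accepted: list[PSM],
    alignments: dict[str, list[PeptideGenomeAlignment]],
    contigs: dict[str, Contig],
    db: list[ProteinRecord],
    genes_11: list[GeneModel],
    tags: list[DeNovoTag] | None = None,
    **corro_kwargs,
) -> list[RecodingEvent]:
    """Group TAG-codon observations into per-codon recoding events.

    Hard invariant: an event is only ever emitted at a literal TAG codon
    observed as Q.
    """
    tags = tags or []
    by_span: dict[tuple[str, int, int], RecodingEvent] = {}
    accepted_seqs = {p.peptide for p in accepted}
    for pep in sorted(accepted_seqs):
        for aln in alignments.get(pep, []):
            contig = contigs[aln.contig_id]
            classes = classify_peptide(aln, db, genes_11)
            verdict = corroborate(pep, tags, aln, **corro_kwargs)
            for r in aln.residues_at_TAG:
                a, b = aln.codon_spans[r]
                codon = contig.sequence[a:b]
                if aln.strand == "-":
                    codon = reverse_complement(codon)
                assert codon == "TAG", f"recoding event at non-TAG codon {codon}"
                assert pep[r] == "Q", f"TAG observed as {pep[r]}, expected Q"
                ev = by_span.setdefault(
                    (aln.contig_id, a, b),
                    RecodingEvent(aln.contig_id, (a, b), "Q", [], {}),
                )
                if pep not in ev.supporting_peptides:
                    ev.supporting_peptides.append(pep)
                ev.evidence_classes[pep] = classes
                if verdict.recoded_ok.get(r, False):
                    ev.denovo_corroborated = True
    return sorted(by_span.values(), key=lambda e: (e.contig_id, e.span))


def summarize_genes(
    events: list[RecodingEvent],
    alignments: dict[str, list[PeptideGenomeAlignment]],
    accepted: list[PSM],
    genes: list[GeneModel],
    peptide_classes: dict[str, frozenset[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene evidence table and per-residue coverage map.

    Returns ``(summary, coverage)``: the summary has peptide counts,
    exclusivity counts, recoding-event counts and a detected flag; the
    coverage map has one row per (gene, residue) with coverage flags.
    """
    accepted_seqs = {p.peptide for p in accepted}
    gene_by_id = {g.gene_id: g for g in genes}
    peps_by_gene: dict[str, set[str]] = defaultdict(set)
    genes_by_pep: dict[str, set[str]] = defaultdict(set)
    for pep, alns in alignments.items():
        if pep not in accepted_seqs:
            continue
        for aln in alns:
            if aln.gene_id in gene_by_id:
                peps_by_gene[aln.gene_id].add(pep)
                genes_by_pep[pep].add(aln.gene_id)

    ev_by_gene: dict[str, list[RecodingEvent]] = defaultdict(list)
    for ev in events:
        touching = {
            aln.gene_id
            for pep in ev.supporting_peptides
            for aln in alignments.get(pep, [])
            if any(span == (ev.span[0], ev.span[1]) for span in aln.codon_spans)
        }
        for gid in touching:
            if gid in gene_by_id:
                ev_by_gene[gid].append(ev)

    peptide_classes = peptide_classes or {}
    rows = []
    cov_rows = []
    for g in genes:
        peps = peps_by_gene.get(g.gene_id, set())
        unique = {p for p in peps if genes_by_pep[p] == {g.gene_id}}
        exclusive = sum(
            1 for p in peps if "code15-exclusive" in peptide_classes.get(p, frozenset())
        )
        covered = np.zeros(len(g.protein), dtype=bool)
        for pep in peps:
            # residue coverage via occurrence offsets in the gene protein
            for m in re.finditer(f"(?={re.escape(pep)})", g.protein):
                covered[m.start() : m.start() + len(pep)] = True
        gene_events = ev_by_gene.get(g.gene_id, [])
        rows.append(
            {
                "gene_id": g.gene_id,
                "contig_id": g.contig_id,
                "n_peptides": len(peps),
                "n_unique_peptides": len(unique),
                "n_code15_exclusive": exclusive,
                "n_recoding_events": len(gene_events),
                "n_corroborated_events": sum(ev.denovo_corroborated for ev in gene_events),
                "detected": len(unique) >= 1,
                "coverage": float(covered.mean()) if len(covered) else 0.0,
            }
        )
        for i, flag in enumerate(covered):
            cov_rows.append(
                {"gene_id": g.gene_id, "residue_index": i, "covered_by_peptide": bool(flag)}
            )
    return pd.DataFrame(rows), pd.DataFrame(cov_rows)
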