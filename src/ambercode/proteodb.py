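"""Layered proteome search database and in-silico tryptic digestion.

The search database mirrors a proteogenomic validation setup: the phage
proteome predicted under code 11, the same genome predicted under code 15,
upstream start-extension variants of the code-15 genes (to test whether
translation initiates upstream of the annotated ATG), auxiliary proteomes
(e.g. host), common contaminants, and one reversed decoy per target.

Upstream extensions append at most 30 residues of in-frame sequence
upstream of the annotated start, stopping at the nearest upstream TAA or
TGA; TAG is *not* a boundary under code 15 and reads through as Q.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mass as _ptmass

from .seqcore import Contig, GeneModel, GeneticCodeTable, load_code_table, reverse_complement, translate

DECOY_PREFIX = "DECOY_"
WATER_MONO = _ptmass.calculate_mass(formula="H2O")
CARBAMIDOMETHYL = 57.02146  # fixed Cys modification, Da
MET_OXIDATION = 15.994915  # variable Met modification, Da

#: boundary codons for upstream extensions (stops under *both* codes)
EXTENSION_BOUNDARY = frozenset({"TAA", "TGA"})

SOURCES = (
    "phage-code11",
    "phage-code15",
    "phage-code15-extended",
    "auxiliary",
    "contaminant",
)


@dataclass
class ProteinRecord:
    record_id: str
    sequence: str
    source: str
    gene_id: str | None = None
    extension_len: int = 0
    is_decoy: bool = False

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.extension_len > 30:
            raise ValueError("extension_len exceeds the 30-residue cap")


@dataclass
class PeptideRecord:
    sequence: str
    parent_ids: list[str]
    start_in_protein: list[int]  # one 0-based offset per parent
    missed_cleavages: int
    specificity: str  # full | semi-N | semi-C
    mono_mass: float


class IdCollisionError(ValueError):
    pass


def upstream_extension(
    gene: GeneModel,
    contig: Contig,
    table: GeneticCodeTable | None = None,
    max_ext: int = 30,
) -> str:
    """Residues of the in-frame codons strictly between the nearest upstream
    TAA/TGA (or the ``max_ext`` cap, or the contig edge) and the start codon,
    translated under code 15 so an upstream TAG reads as Q.

    Returned N-terminal-first, ready to prepend to the annotated protein.
    """
    if table is None:
        table = load_code_table(15)
    residues: list[str] = []
    seq = contig.sequence
    for k in range(1, max_ext + 1):
        if gene.strand == "+":
            pos = gene.start - 3 * k
            if pos < 0:
                break
            codon = seq[pos : pos + 3]
        else:
            pos = gene.end + 3 * (k - 1)
            if pos + 3 > len(seq):
                break
            codon = reverse_complement(seq[pos : pos + 3])
        if codon in EXTENSION_BOUNDARY:
            break
        residues.append(translate(codon, table, stop_policy="readthrough"))
    return "".join(reversed(residues))


def build_database(
    genes_11: list[GeneModel],
    genes_15: list[GeneModel],
    contigs: Contig | dict[str, Contig],
    auxiliary: list[tuple[str, str]] | None = None,
    contaminants: list[tuple[str, str]] | None = None,
    with_decoys: bool = True,
    max_ext: int = 30,
) -> list[ProteinRecord]:
    """Assemble the layered target database, optionally with reversed decoys.

    One record per code-11 gene, per code-15 gene and per code-15 gene with
    a non-empty upstream extension; auxiliary/contaminant entries are
    (id, sequence) pairs.  Decoys are whole-protein reversals, id-prefixed
    with ``DECOY_``.
    """
    if isinstance(contigs, Contig):
        contigs = {contigs.contig_id: contigs}
    table15 = load_code_table(15)
    records: list[ProteinRecord] = []
    for g in genes_11:
        records.append(
            ProteinRecord(f"phage-code11|{g.gene_id}", g.protein, "phage-code11", g.gene_id)
        )
    for g in genes_15:
        records.append(
            ProteinRecord(f"phage-code15|{g.gene_id}", g.protein, "phage-code15", g.gene_id)
        )
        ext = upstream_extension(g, contigs[g.contig_id], table15, max_ext=max_ext)
        if ext:
            records.append(
                ProteinRecord(
                    f"phage-code15-extended|{g.gene_id}|ext{len(ext)}",
                    ext + g.protein,
                    "phage-code15-extended",
                    g.gene_id,
                    extension_len=len(ext),
                )
            )
    for rid, seq in auxiliary or []:
        records.append(ProteinRecord(f"auxiliary|{rid}", seq.upper(), "auxiliary"))
    for rid, seq in contaminants or []:
        records.append(ProteinRecord(f"contaminant|{rid}", seq.upper(), "contaminant"))

    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise IdCollisionError(f"duplicate record id {r.record_id!r}")
        seen.add(r.record_id)

    if with_decoys:
        decoys = [
            ProteinRecord(
                DECOY_PREFIX + r.record_id,
                r.sequence[::-1],
                r.source,
                r.gene_id,
                extension_len=r.extension_len,
                is_decoy=True,
            )
            for r in records
        ]
        records.extend(decoys)
    return records


def records_from_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a database FASTA written by :func:`write_database_fasta`,
    reconstructing provenance from the ``|``-delimited record ids."""
    records: list[ProteinRecord] = []
    rid = None
    seq: list[str] = []

    def flush():
        if rid is None:
            return
        raw = rid
        is_decoy = raw.startswith(DECOY_PREFIX)
        core = raw[len(DECOY_PREFIX) :] if is_decoy else raw
        parts = core.split("|")
        source = parts[0]
        gene_id = None
        ext = 0
        if source in ("phage-code11", "phage-code15", "phage-code15-extended"):
            gene_id = "|".join(parts[1:-1] if source.endswith("extended") else parts[1:])
            if source.endswith("extended"):
                ext = int(parts[-1].removeprefix("ext"))
        records.append(
            ProteinRecord(raw, "".join(seq), source, gene_id, extension_len=ext, is_decoy=is_decoy)
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rid = line[1:].split()[0]
                seq = []
            else:
                seq.append(line)
        flush()
    return records


def write_database_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Protein FASTA with ``|``-delimited provenance in the header."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.record_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Digestion


def cleavage_sites(sequence: str) -> list[int]:
    """Trypsin cut positions: after K or R, suppressed before P.

    A site ``p`` means a cut between ``sequence[p-1]`` and ``sequence[p]``;
    the protein termini (0 and len) are not listed but always count as
    tryptic termini.
    """
    return [
        p
        for p in range(1, len(sequence))
        if sequence[p - 1] in "KR" and sequence[p] != "P"
    ]


def digest(
    protein: ProteinRecord | str,
    max_missed: int = 3,
    specificity: str = "full",
    min_len: int = 6,
    max_len: int = 50,
) -> list[PeptideRecord]:
    """In-silico tryptic digestion with missed cleavages.

    ``specificity="full"`` requires both peptide termini to be tryptic
    (a cleavage site or a protein terminus); ``"semi"`` additionally emits
    every peptide with exactly one tryptic terminus.  Missed cleavages are
    cleavage sites strictly inside the peptide.
    """
    if isinstance(protein, str):
        record = ProteinRecord("adhoc|protein", protein.upper(), "auxiliary")
    else:
        record = protein
    if specificity not in ("full", "semi"):
        raise ValueError(f"unknown specificity {specificity!r}")
    seq = record.sequence
    if not seq:
        raise ValueError("empty protein sequence")
    n = len(seq)
    sites = cleavage_sites(seq)
    tryptic = set(sites) | {0, n}
    out: list[PeptideRecord] = []
    max_len = max_len or n
    for s in range(n):
        n_tryptic_start = s in tryptic
        lo = max(s + min_len, s + 1)
        for e in range(lo, min(n, s + max_len) + 1):
            c_tryptic = e in tryptic
            if specificity == "full":
                if not (n_tryptic_start and c_tryptic):
                    continue
            else:
                if not (n_tryptic_start or c_tryptic):
                    continue
            missed = bisect_left(sites, e) - bisect_right(sites, s)
            if missed > max_missed:
                continue
            if n_tryptic_start and c_tryptic:
                spec = "full"
            elif n_tryptic_start:
                spec = "semi-N"  # tryptic at the N-terminus only
            else:
                spec = "semi-C"  # tryptic at the C-terminus only
            pep = seq[s:e]
            out.append(
                PeptideRecord(
                    sequence=pep,
                    parent_ids=[record.record_id],
                    start_in_protein=[s],
                    missed_cleavages=missed,
                    specificity=spec,
                    mono_mass=peptide_mass(pep, variable_mods=[])[0][0],
                )
            )
    return out


def peptide_mass(
    sequence: str,
    fixed_cys_mod: float = CARBAMIDOMETHYL,
    variable_mods: list[tuple[str, float]] | None = None,
    max_var: int = 3,
) -> list[tuple[float, tuple[tuple[int, float], ...]]]:
    """Monoisotopic masses of a peptide under fixed and variable modifications.

    Returns ``(mass, sites)`` pairs, one per distinct mass: the unmodified
    form (fixed carbamidomethyl applied to every C) plus every combination of
    up to ``max_var`` variable modifications; ``sites`` is a representative
    ``(position, delta)`` assignment for that mass.
    """
    if variable_mods is None:
        variable_mods = [("M", MET_OXIDATION)]
    try:
        base = sum(_ptmass.std_aa_mass[aa] for aa in sequence) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"unknown residue in {sequence!r}: {exc}") from exc
    base += sequence.count("C") * fixed_cys_mod
    var_sites = [
        (i, delta)
        for res, delta in variable_mods
        for i, aa in enumerate(sequence)
        if aa == res
    ]
    results: dict[float, tuple[tuple[int, float], ...]] = {}
    for k in range(0, min(max_var, len(var_sites)) + 1):
        for combo in itertools.combinations(var_sites, k):
            m = round(base + sum(d for _, d in combo), 6)
            results.setdefault(m, combo)
    return sorted(results.items())
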