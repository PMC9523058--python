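"""Genetic code tables, translation, ORF prediction and sequence I/O.

The central objects are :class:`GeneticCodeTable` (an NCBI translation
table with explicit start/stop codon sets), :class:`Contig` and
:class:`GeneModel`.  Translation table 15 is identical to the standard
bacterial/archaeal table 11 except that the amber stop codon TAG encodes
glutamine (Q); detecting usage of that table in phage genomes is what the
rest of the package is about.

Gene prediction here is a deterministic maximal-ORF caller: in each of the
six reading frames, every stop-to-stop interval contributes at most one
gene, running from the first (most upstream) start codon to the
terminating stop.  There is no coding-statistics or RBS scoring; absolute
gene inventories will differ from a trained gene finder, but the
code-11 vs code-15 contrast that drives code assignment is preserved
because both predictions use the same caller.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP = "*"
DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Start-codon sets used for ORF calling.  Code 15 initiates only at ATG;
#: for code 11 we use the three common bacterial starts rather than the
#: full 7-codon NCBI list, which would inflate spurious short ORFs.
START_CODON_OVERRIDES = {11: frozenset({"ATG", "GTG", "TTG"}), 15: frozenset({"ATG"})}


class UnsupportedCodeError(ValueError):
    """Raised for a translation-table id outside the NCBI registry."""


class FrameError(ValueError):
    """Raised when a CDS length is not a multiple of three."""


class FastaParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class GeneticCodeTable:
    """A translation table: 64-codon map plus start/stop codon sets."""

    code_id: int
    codon_map: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def __post_init__(self):
        if len(self.codon_map) != 64:
            raise ValueError("codon_map must cover exactly 64 codons")
        stops = {c for c, aa in self.codon_map.items() if aa == STOP}
        if stops != set(self.stop_codons):
            raise ValueError("stop_codons inconsistent with codon_map")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons


def load_code_table(code_id: int) -> GeneticCodeTable:
    """Load an NCBI translation table by id (11 and 15 are the ones used here).

    Code 15 maps TAG to Q and initiates only at ATG; any table in the NCBI
    registry can be loaded, with Biopython's start codons used where no
    override is defined.
    """
    try:
        bio = _BioCodonTable.unambiguous_dna_by_id[int(code_id)]
    except KeyError as exc:
        raise UnsupportedCodeError(f"unsupported translation table id: {code_id!r}") from exc
    codon_map = dict(bio.forward_table)
    for stop in bio.stop_codons:
        codon_map[stop] = STOP
    starts = START_CODON_OVERRIDES.get(int(code_id), frozenset(bio.start_codons))
    return GeneticCodeTable(
        code_id=int(code_id),
        codon_map=codon_map,
        start_codons=frozenset(starts),
        stop_codons=frozenset(bio.stop_codons),
    )


@dataclass
class Contig:
    contig_id: str
    sequence: str
    topology: str = "linear"  # linear|circular; circular contigs are linearized

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"contig {self.contig_id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A predicted ORF.  Coordinates are 0-based half-open on the forward axis;
    minus-strand proteins are read from the reverse complement."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    code_id: int
    protein: str
    includes_stop_codon: bool = True

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad span [{self.start},{self.end})")
        if (self.end - self.start) % 3:
            raise FrameError(f"{self.gene_id}: span not a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        expect = (self.end - self.start) // 3 - (1 if self.includes_stop_codon else 0)
        if len(self.protein) != expect:
            raise ValueError(
                f"{self.gene_id}: protein length {len(self.protein)} != {expect}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def cds(self, contig: Contig) -> str:
        """Coding sequence in reading orientation (includes stop if present)."""
        span = contig.sequence[self.start : self.end]
        return reverse_complement(span) if self.strand == "-" else span


def translate(cds: str, table: GeneticCodeTable, stop_policy: str = "truncate") -> str:
    """Codon-wise translation of a CDS.

    stop_policy: ``truncate`` stops at the first stop codon (residues before
    it are returned), ``error`` raises on any stop, ``readthrough`` emits
    ``*`` and continues.  Codons containing N translate to ``X`` and never
    act as stops.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    if stop_policy not in ("truncate", "error", "readthrough"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        aa = table.codon_map[codon]
        if aa == STOP:
            if stop_policy == "truncate":
                break
            if stop_policy == "error":
                raise ValueError(f"internal stop codon {codon} at {i}")
        out.append(aa)
    return "".join(out)


def _scan_frame(
    seq: str, frame: int, table: GeneticCodeTable, min_protein_len: int
) -> Iterable[tuple[int, int, bool]]:
    """Yield (start, end, includes_stop) ORF spans in `seq` coordinates for
    one forward frame.  Each stop-to-stop interval yields at most one ORF,
    from its first start codon."""
    n = len(seq)
    first_start = None
    last_full = frame + ((n - frame) // 3) * 3
    for pos in range(frame, last_full, 3):
        codon = seq[pos : pos + 3]
        if "N" in codon:  # N codons neither start nor stop
            continue
        if table.is_stop(codon):
            if first_start is not None:
                if (pos - first_start) // 3 >= min_protein_len:
                    yield first_start, pos + 3, True
                first_start = None
        elif first_start is None and table.is_start(codon):
            first_start = pos
    if first_start is not None and (last_full - first_start) // 3 >= min_protein_len:
        # runs off the contig edge: no terminating stop
        yield first_start, last_full, False


def predict_orfs(
    contig: Contig, table: GeneticCodeTable, min_protein_len: int = 30
) -> list[GeneModel]:
    """Six-frame maximal-ORF prediction under the given code.

    Within each stop-to-stop interval of each frame the ORF runs from the
    first in-frame start codon to the terminating stop (or the contig edge,
    flagged ``includes_stop_codon=False``).  Only ORFs whose protein is at
    least ``min_protein_len`` residues are returned, sorted by start.
    """
    if min_protein_len < 0:
        raise ValueError("min_protein_len must be >= 0")
    n = len(contig)
    found: list[GeneModel] = []
    fwd = contig.sequence
    rev = reverse_complement(fwd)
    for strand, seq in (("+", fwd), ("-", rev)):
        for frame in range(3):
            for s, e, has_stop in _scan_frame(seq, frame, table, min_protein_len):
                protein = translate(seq[s : e - 3] if has_stop else seq[s:e], table)
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = n - e, n - s
                found.append(
                    GeneModel(
                        gene_id="",
                        contig_id=contig.contig_id,
                        start=start,
                        end=end,
                        strand=strand,
                        code_id=table.code_id,
                        protein=protein,
                        includes_stop_codon=has_stop,
                    )
                )
    found.sort(key=lambda g: (g.start, g.end, g.strand))
    for i, g in enumerate(found, 1):
        g.gene_id = f"{contig.contig_id}|c{table.code_id}|{i:04d}"
    return found


def select_nonoverlapping(genes: list[GeneModel]) -> list[GeneModel]:
    """Greedy one-gene-per-locus selection: longest ORFs first, discarding
    any ORF overlapping an already-selected one on the same contig.

    A maximal six-frame ORF scan emits heavily overlapping calls in all
    frames; a gene set, in the Prodigal sense, keeps one gene per locus.
    Deterministic: ties break by (start, end, strand).
    """
    chosen: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in sorted(genes, key=lambda g: (-(g.end - g.start), g.start, g.end, g.strand)):
        spans = occupied.setdefault(g.contig_id, [])
        if any(g.start < e and s < g.end for s, e in spans):
            continue
        spans.append((g.start, g.end))
        chosen.append(g)
    chosen.sort(key=lambda g: (g.contig_id, g.start, g.end, g.strand))
    return chosen


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a DNA FASTA into Contigs (uppercased; validated against ACGTN).

    Parse errors report the offending line number.
    """
    contigs: list[Contig] = []
    cur_id: str | None = None
    cur_seq: list[str] = []
    seen: set[str] = set()

    def flush(line_no: int):
        if cur_id is None:
            return
        if not cur_seq:
            raise FastaParseError(f"record {cur_id!r} has no sequence", line_no)
        contigs.append(Contig(cur_id, "".join(cur_seq)))

    line_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                cur_id = line[1:].split()[0] if line[1:].strip() else ""
                if not cur_id:
                    raise FastaParseError("empty FASTA header", line_no)
                if cur_id in seen:
                    raise FastaParseError(f"duplicate id {cur_id!r}", line_no)
                seen.add(cur_id)
                cur_seq = []
            else:
                if cur_id is None:
                    raise FastaParseError("sequence before first header", line_no)
                chunk = line.upper()
                bad = set(chunk) - DNA_ALPHABET
                if bad:
                    raise FastaParseError(f"invalid characters {sorted(bad)}", line_no)
                cur_seq.append(chunk)
        flush(line_no if contigs or cur_id else 0)
    return contigs


def write_fasta(records: Iterable[Contig] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write contigs or (id, sequence) pairs as wrapped FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, Contig):
            rid, seq = rec.contig_id, rec.sequence
        else:
            rid, seq = rec
        out.append(SeqRecord(Seq(seq), id=rid, description=""))
    if not out:
        raise ValueError("refusing to write an empty FASTA")
    SeqIO.write(out, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA as (id, sequence) pairs via Bio.SeqIO."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def read_gff3(path: str | Path, contigs: dict[str, Contig]) -> list[GeneModel]:
    """Read CDS features written by :func:`write_gff3` back into GeneModels.

    Proteins are re-derived by translating the genomic span under the
    ``code_id`` attribute, so the file round-trips losslessly.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig_id, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype != "CDS":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            code_id = int(attr["code_id"])
            has_stop = attr.get("includes_stop_codon", "true") == "true"
            table = load_code_table(code_id)
            s0, e0 = int(start) - 1, int(end)
            span = contigs[contig_id].sequence[s0:e0]
            cds = reverse_complement(span) if strand == "-" else span
            if has_stop:
                cds = cds[:-3]
            genes.append(
                GeneModel(
                    gene_id=attr["ID"],
                    contig_id=contig_id,
                    start=s0,
                    end=e0,
                    strand=strand,
                    code_id=code_id,
                    protein=translate(cds, table, stop_policy="readthrough"),
                    includes_stop_codon=has_stop,
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "ambercode") -> None:
    """Write gene models as GFF3 CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};code_id={g.code_id};"
                f"includes_stop_codon={str(g.includes_stop_codon).lower()}"
            )
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        source,
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )
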