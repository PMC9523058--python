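"""Synthetic genomes, search databases, PSMs and de novo tags.

The generator emulates the structure the analysis assumes: a contig whose
first half carries genes written in genetic code 15 (in-frame TAG codons
encoding Q), whose second half carries standard code-11 genes, and whose
two halves form opposed GC-skew replichores (leading strand G-rich).
Tryptic peptides are sampled from the true proteome with Gaussian
target/decoy score distributions, and recoded peptides receive de novo
tags with configurable per-residue confidence levels.

Every planted code-15 gene is preceded by an in-frame TAA (with a short
non-start spacer), so the maximal-ORF caller recovers planted genes
exactly, and upstream-extension boundary cases occur naturally.

Incorrect PSMs follow the concatenated-search competition model: each
junk spectrum lands in target or decoy space with probability 1/2, which
is what makes the classical decoy count an unbiased estimate of the
number of incorrect target matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .evidence import PSM
from .proteodb import ProteinRecord, digest
from .seqcore import Contig, GeneModel, load_code_table, translate

_STOPS_ALL = ("TAA", "TGA", "TAG")
_BASES = np.array(list("ACGT"))


class CapacityError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset."""

    seed: int = 1
    contig_len: int = 99_000  # just under the >=100 kb rule tier
    n_genes_code15: int = 30
    n_genes_code11: int = 30
    gene_len_codons: tuple[int, int] = (350, 550)  # inclusive range, incl. start+stop
    gap_nt: tuple[int, int] = (30, 90)  # intergenic gap range (phage genomes are gene-dense)
    spacer_codons: tuple[int, int] = (0, 6)  # in-frame codons between TAA and ATG
    tag_per_gene: float = 12.0  # Poisson mean of in-frame TAGs per code-15 gene (~2.7% of codons)
    min_tag_frac: float = 1.0  # fraction of code-15 genes forced to have >= 1 TAG
    gc_content: float = 0.34  # crAss-like phages are AT-rich
    gc_bias: float = 0.2  # leading-strand skew (G-C)/(G+C)
    peptide_sample_rate: float = 0.3
    target_score_mean: float = 30.0
    target_score_sd: float = 5.0
    decoy_score_mean: float = 15.0
    decoy_score_sd: float = 5.0
    noise: float = 0.4  # fraction of PSMs that are incorrect
    denovo_rate: float = 0.8  # recoded peptides receiving a high-confidence tag
    tag_conf_high: tuple[float, float] = (92.0, 99.5)
    tag_conf_low: tuple[float, float] = (55.0, 88.0)

    def __post_init__(self):
        for frac in (self.peptide_sample_rate, self.noise, self.denovo_rate, self.min_tag_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")


@dataclass
class GroundTruth:
    genes: list[GeneModel]
    tag_positions: list[tuple[int, str]]  # (forward-axis codon start, gene_id)
    origin_pos: int
    terminus_pos: int
    psm_labels: pd.DataFrame | None = None


def _nt_probs(gc: float, bias: float, leading: bool) -> np.ndarray:
    """Base probabilities A,C,G,T at GC content `gc` with a leading-strand
    skew of `bias` ((G-C)/(G+C); mirrored on the lagging strand).

    An AT-rich background matches the phages being emulated and gives
    shifted/reverse reading frames a realistic stop-codon supply."""
    at = (1.0 - gc) / 2
    d = bias if leading else -bias
    return np.array([at, gc / 2 * (1 - d), gc / 2 * (1 + d), at])


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)]) if n else ""


def _random_codon(rng: np.random.Generator, probs: np.ndarray, exclude: frozenset[str]) -> str:
    while True:
        codon = "".join(_BASES[rng.choice(4, size=3, p=probs)])
        if codon not in exclude:
            return codon


def simulate_genome(config: SimConfig) -> tuple[Contig, GroundTruth]:
    """Build the two-replichore, two-code contig and its ground truth.

    Deterministic for a fixed seed.  Code-15 genes occupy the first half
    (leading strand, G-rich), code-11 genes the second half (C-rich); all
    genes are on the forward strand.
    """
    rng = np.random.default_rng(config.seed)
    table15 = load_code_table(15)
    L = config.contig_len
    half = L // 2
    chunks: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    tag_positions: list[tuple[int, str]] = []

    def emit(s: str):
        nonlocal pos
        chunks.append(s)
        pos += len(s)

    for code_id, n_genes, region_end, leading in (
        (15, config.n_genes_code15, half, True),
        (11, config.n_genes_code11, L, False),
    ):
        probs = _nt_probs(config.gc_content, config.gc_bias, leading)
        # body codons must not terminate the ORF under the gene's own code
        exclude = frozenset(_STOPS_ALL)
        for i in range(n_genes):
            gap = int(rng.integers(config.gap_nt[0], config.gap_nt[1] + 1))
            spacer = int(rng.integers(config.spacer_codons[0], config.spacer_codons[1] + 1))
            n_codons = int(rng.integers(config.gene_len_codons[0], config.gene_len_codons[1] + 1))
            n_body = n_codons - 2  # minus start and stop codons
            need = gap + 3 + 3 * spacer + 3 * n_codons
            if pos + need > region_end:
                raise CapacityError(
                    f"code-{code_id} gene {i + 1} does not fit before position {region_end}"
                )
            emit(_random_seq(rng, gap, probs))
            emit("TAA")  # in-frame boundary stop immediately upstream
            # spacer codons: never a start codon, never a TAA/TGA boundary
            emit("".join(_random_codon(rng, probs, frozenset({"ATG", "TAA", "TGA"})) for _ in range(spacer)))
            gene_start = pos
            gene_id = f"truth|c{code_id}|{len(genes) + 1:03d}"
            body = [_random_codon(rng, probs, exclude) for _ in range(n_body)]
            if code_id == 15:
                n_tag = int(rng.poisson(config.tag_per_gene))
                if n_tag == 0 and rng.random() < config.min_tag_frac:
                    n_tag = 1
                n_tag = min(n_tag, max(n_body - 1, 0))
                sites = rng.choice(np.arange(1, n_body), size=n_tag, replace=False) if n_tag else []
                for s in sites:
                    body[int(s)] = "TAG"
                    tag_positions.append((gene_start + 3 + 3 * int(s), gene_id))
            cds = "ATG" + "".join(body) + "TAA"
            emit(cds)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig_id="sim_contig",
                    start=gene_start,
                    end=pos,
                    strand="+",
                    code_id=code_id,
                    protein=translate(cds[:-3], table15),
                    includes_stop_codon=True,
                )
            )
        emit(_random_seq(rng, region_end - pos, probs))

    contig = Contig("sim_contig", "".join(chunks))
    truth = GroundTruth(
        genes=genes,
        tag_positions=tag_positions,
        origin_pos=0,
        terminus_pos=half,
    )
    for p, gid in tag_positions:
        assert contig.sequence[p : p + 3] == "TAG", "planted TAG not present in sequence"
    return contig, truth


# ---------------------------------------------------------------------------
# PSM / tag simulation


def _recoded_residue_indices(gene: GeneModel, tag_positions: list[tuple[int, str]]) -> set[int]:
    """Protein residue indices of planted TAG codons (codon 0 is the start)."""
    return {(p - gene.start) // 3 for p, gid in tag_positions if gid == gene.gene_id}


def simulate_psms(
    db: list[ProteinRecord],
    truth: GroundTruth,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample PSMs and de novo tags from the database and ground truth.

    Returns ``(psm_table, tag_table, labels)`` in the TSV dialects the
    evidence module consumes.  Correct PSMs draw peptides from the true
    proteome and scores from the target Gaussian; incorrect PSMs carry
    shuffled sequences with null scores and land in target or decoy space
    with probability 1/2 each.
    """
    if not db:
        raise ValueError("empty protein database")
    rng = np.random.default_rng((config.seed + 20_011) % 2**31 if seed is None else seed)
    targets = [r for r in db if not r.is_decoy]
    decoys = [r for r in db if r.is_decoy]

    # enumerate candidate tryptic peptides of the true proteome
    candidates: list[tuple[str, GeneModel, int]] = []  # (peptide, gene, offset)
    seen: set[str] = set()
    for gene in truth.genes:
        for pep in digest(gene.protein, max_missed=1, specificity="full", min_len=6, max_len=40):
            if pep.sequence not in seen:
                seen.add(pep.sequence)
                candidates.append((pep.sequence, gene, pep.start_in_protein[0]))

    psm_rows = []
    tag_rows = []
    label_rows = []
    n_true = 0
    for pep, gene, off in candidates:
        if rng.random() >= config.peptide_sample_rate:
            continue
        parents = [r.record_id for r in targets if pep in r.sequence]
        if not parents:
            continue
        n_true += 1
        score = float(rng.normal(config.target_score_mean, config.target_score_sd))
        psm_rows.append({"peptide": pep, "score": round(score, 4), "parents": ";".join(parents)})
        label_rows.append({"peptide": pep, "is_true": True, "is_decoy_psm": False})

        recoded = _recoded_residue_indices(gene, truth.tag_positions)
        covered = sorted(r - off for r in recoded if off <= r < off + len(pep))
        emit_tag = False
        lo, hi = config.tag_conf_low, config.tag_conf_high
        if covered:
            emit_tag = True
            band = hi if rng.random() < config.denovo_rate else lo
        elif rng.random() < 0.2:  # occasional tags on ordinary peptides
            emit_tag = True
            band = hi
        if emit_tag:
            conf = np.round(rng.uniform(band[0], band[1], size=len(pep)), 1)
            tag_rows.append(
                {
                    "tag": pep,
                    "alc": round(float(conf.mean()), 2),
                    "residue_conf": ",".join(str(c) for c in conf),
                }
            )

    n_null = int(round(n_true * config.noise / max(1.0 - config.noise, 1e-9)))
    for i in range(n_null):
        src = candidates[int(rng.integers(len(candidates)))][0]
        shuffled = "".join(np.array(list(src))[rng.permutation(len(src))])
        score = float(rng.normal(config.decoy_score_mean, config.decoy_score_sd))
        if rng.random() < 0.5 and decoys:
            parent = decoys[int(rng.integers(len(decoys)))].record_id
            is_decoy = True
        else:
            parent = targets[int(rng.integers(len(targets)))].record_id
            is_decoy = False
        psm_rows.append({"peptide": shuffled, "score": round(score, 4), "parents": parent})
        label_rows.append({"peptide": shuffled, "is_true": False, "is_decoy_psm": is_decoy})

    psm_df = pd.DataFrame(psm_rows, columns=["peptide", "score", "parents"])
    tag_df = pd.DataFrame(tag_rows, columns=["tag", "alc", "residue_conf"])
    labels = pd.DataFrame(label_rows, columns=["peptide", "is_true", "is_decoy_psm"])
    return psm_df, tag_df, labels


def simulate_tda_scores(
    n_correct: int = 5000,
    n_incorrect: int = 10_000,
    config: SimConfig | None = None,
    seed: int = 1,
) -> tuple[list[PSM], dict[str, bool]]:
    """Score-only PSM simulation for FDR calibration studies.

    ``n_correct`` correct target PSMs draw from the target Gaussian;
    ``n_incorrect`` junk PSMs draw from the null Gaussian and land in
    target or decoy space with probability 1/2 (competition), so the
    decoy count estimates the incorrect-target count without bias.
    Returns the PSMs and a peptide -> is_correct label map.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    psms: list[PSM] = []
    labels: dict[str, bool] = {}
    scores_t = rng.normal(cfg.target_score_mean, cfg.target_score_sd, n_correct)
    for i in range(n_correct):
        pep = f"TRUE{i:06d}"
        psms.append(PSM(pep, float(scores_t[i]), ["phage-code15|sim"]))
        labels[pep] = True
    scores_n = rng.normal(cfg.decoy_score_mean, cfg.decoy_score_sd, n_incorrect)
    to_decoy = rng.random(n_incorrect) < 0.5
    for i in range(n_incorrect):
        pep = f"JUNK{i:06d}"
        parent = "DECOY_phage-code15|sim" if to_decoy[i] else "phage-code11|sim"
        psms.append(PSM(pep, float(scores_n[i]), [parent], is_decoy=bool(to_decoy[i])))
        labels[pep] = False
    return psms, labels
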