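"""Synthetic genomes, gene families, transcripts and read sets.

The generator emulates the statistical structure the downstream analysis
assumes: tandem, nearly identical paralogs (optionally interrupted by
assembly N-gaps), 3'-UTR intron-retention isoforms and alternative poly(A)
ends, and fixed-length read sets with per-gene abundance weights and
per-base quality strings (301-nt reads by default, matching the sequencing
run the study analysed).

Paralogs are derived from a single family ancestor by per-site substitution.
Substitutions never touch the start/stop codons, the signal-peptide codons or
the conserved cysteines, and never introduce a stop or a new cysteine into
the mature region, so the class-defining architecture survives mutation --
mirroring the conservation the real families show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import synthetic_panel
from .curation import GeneRecord, TranscriptRecord
from .sequence_io import ReadRecord, ScaffoldSeq, revcomp

_BASES = "ACGT"

#: codons by amino acid for resampling substitutions
_CODONS_BY_AA: Dict[str, list] = {}
for _aa, _c in synthetic_panel.CODON.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_c)
for _aa, _c in synthetic_panel.ALT_CODON.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_c)

_STOPS = {"TAA", "TAG", "TGA"}

#: ancestor templates: representative panel gene per family
_FAMILY_TEMPLATE = {
    "defensin": "defensin_g2",
    "termicin": "termicin_g1",
    "drosomycin": "drosomycin_g2",
    "attacin_like": "attacin-like_g1",
    "blattellicin": "blattellicin_g1",
}

#: signal-peptide codon count protected from substitution, per family
_SIGNAL_CODONS = {"defensin": 22, "termicin": 19, "drosomycin": 19,
                  "attacin_like": 19, "blattellicin": 22}


@dataclass
class FamilySpec:
    """Parameters of one synthetic AMP gene family."""

    family: str
    n_genes: int = 4
    mutation_rate: float = 0.02  # per-nucleotide substitution prob between paralogs
    tandem: bool = True
    gap_prob: float = 0.0  # probability a gene's locus is hit by an N-gap
    utr5_len: int = 40
    utr3_len: int = 60
    utr3_intron_len: int = 0  # > 0: each locus carries a 3'-UTR intron
    spacer_len: int = 300

    def __post_init__(self):
        if self.family not in _FAMILY_TEMPLATE:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.mutation_rate <= 1 or not 0 <= self.gap_prob <= 1:
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class ReadSimSpec:
    """Parameters of a synthetic sequencing run."""

    read_len: int = 301
    n_reads: int = 10000
    weights: Dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.0
    seed: int = 0
    qual_mean: float = 36.0
    qual_sd: float = 3.0

    def __post_init__(self):
        w = list(self.weights.values())
        if w and (min(w) < 0 or max(w) <= 0):
            raise ValueError("weights must be >= 0 with at least one > 0")


# ---------------------------------------------------------------------------
# family generation
# ---------------------------------------------------------------------------


def _protected_codons(family: str, codons: List[str]) -> set:
    """Codon indices substitutions must not touch."""
    protected = {0, len(codons) - 1}  # start codon and stop
    protected.update(range(_SIGNAL_CODONS[family]))
    for i, c in enumerate(codons[:-1]):
        if c in _CODONS_BY_AA.get("C", ()):  # conserved cysteines
            protected.add(i)
    return protected


def _mutate_cds(cds: str, family: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution applied codon-wise with architecture guards."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    protected = _protected_codons(family, codons)
    p_codon = 1.0 - (1.0 - rate) ** 3
    for i in range(len(codons)):
        if i in protected or rng.random() >= p_codon:
            continue
        cur = codons[i]
        for _attempt in range(10):
            pos = int(rng.integers(3))
            base = _BASES[int(rng.integers(4))]
            if base == cur[pos]:
                continue
            cand = cur[:pos] + base + cur[pos + 1 :]
            # guards: no stops, no new cysteine in the mature region
            if cand in _STOPS or cand in _CODONS_BY_AA["C"]:
                continue
            codons[i] = cand
            break
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=n))


@dataclass
class SyntheticGene:
    """One generated gene with its mRNA parts and genomic span.

    ``intron`` (possibly empty) sits inside the 3' UTR at ``intron_cut`` on
    the genomic copy; the canonical mRNA splices it out.
    """

    record: GeneRecord
    utr5: str
    utr3: str
    intron: str = ""
    intron_cut: int = 0  # 0-based offset within utr3

    @property
    def mrna(self) -> str:
        return self.utr5 + self.record.cds + self.utr3

    @property
    def genomic(self) -> str:
        if not self.intron:
            return self.mrna
        return (self.utr5 + self.record.cds
                + self.utr3[: self.intron_cut] + self.intron
                + self.utr3[self.intron_cut :])


def make_family(spec: FamilySpec, seed: int = 0) -> Tuple[List[SyntheticGene], List[ScaffoldSeq]]:
    """Generate a paralogous family plus the scaffold(s) carrying it.

    Every gene's protein satisfies its family architecture; paralogs derive
    from one panel ancestor by guarded per-site substitution; genes are
    placed in tandem with intergenic spacers; with probability ``gap_prob``
    a gene's 3' flank is overwritten by an assembly N-gap.
    """
    rng = np.random.default_rng(seed)
    ancestor = synthetic_panel.panel_cds()[_FAMILY_TEMPLATE[spec.family]]
    min_len = (_SIGNAL_CODONS[spec.family] + 71 + 81) * 3
    if spec.family == "blattellicin" and len(ancestor) < min_len:
        raise ValueError("blattellicin shorter than signal + Glx + domain is infeasible")

    genes: List[SyntheticGene] = []
    parts: List[str] = [_random_dna(rng, spec.spacer_len)]
    pos = len(parts[0])
    sid = f"scf_{spec.family}_1"
    for i in range(1, spec.n_genes + 1):
        cds = _mutate_cds(ancestor, spec.family, spec.mutation_rate, rng)
        utr5 = _random_dna(rng, spec.utr5_len)
        utr3 = _random_dna(rng, spec.utr3_len) + "A" * 8
        intron, cut = "", 0
        if spec.utr3_intron_len >= 4:
            intron = "GT" + _random_dna(rng, spec.utr3_intron_len - 4) + "AG"
            cut = len(utr3) // 2
        locus = utr5 + cds + utr3[:cut] + intron + utr3[cut:] if intron \
            else utr5 + cds + utr3
        gapped = rng.random() < spec.gap_prob
        if gapped:  # the assembly gap overwrites the gene's 3' flank
            locus = locus[: len(locus) - 20] + "N" * 40
        name = f"{spec.family}_s{i}"
        start = pos + 1
        rec = GeneRecord(
            name=name,
            family=spec.family,
            scaffold=sid if spec.tandem else f"scf_{spec.family}_{i}",
            exons=[(start + len(utr5), start + len(utr5) + len(cds) - 1, "+")],
            cds=cds,
            gap_flags=[(start + len(locus) - 40, start + len(locus) - 1)] if gapped else [],
        )
        genes.append(SyntheticGene(rec, utr5, utr3, intron, cut))
        spacer = _random_dna(rng, spec.spacer_len)
        parts.extend([locus, spacer])
        pos += len(locus) + len(spacer)

    if spec.tandem:
        scaffolds = [ScaffoldSeq.from_seq(sid, "".join(parts))]
    else:
        scaffolds = []
        for g in genes:
            seq = _random_dna(rng, 100) + g.genomic + _random_dna(rng, 100)
            scaffolds.append(ScaffoldSeq.from_seq(g.record.scaffold, seq))
    return genes, scaffolds


# ---------------------------------------------------------------------------
# isoforms
# ---------------------------------------------------------------------------


def make_isoforms(
    gene: SyntheticGene,
    intron_len: int = 453,
    mode: str = "intron",
    seed: int = 0,
) -> List[TranscriptRecord]:
    """Two transcript isoforms of one gene with identical CDS.

    ``mode='intron'``: a GT..AG intron of ``intron_len`` nt is retained in or
    spliced from the 3' UTR, so the two 3' UTRs differ by exactly
    ``intron_len`` nt.  The gene's own genomic intron is used when present
    (so both isoforms place on the generated scaffold); otherwise a fresh
    one is drawn.  ``mode='polya'``: the second isoform uses an upstream
    poly(A) end (3' UTR shortened by ``intron_len``).
    """
    if intron_len < 4:
        raise ValueError("intron length must be at least 4 (GT..AG)")
    rng = np.random.default_rng(seed)
    cds = gene.record.cds
    base = gene.record.name
    if mode == "intron":
        if len(gene.utr3) < 2:
            raise ValueError("3' UTR too short to host an intron")
        if gene.intron:
            intron, cut = gene.intron, gene.intron_cut
        else:
            intron = "GT" + _random_dna(rng, intron_len - 4) + "AG"
            cut = len(gene.utr3) // 2
        retained = gene.utr5 + cds + gene.utr3[:cut] + intron + gene.utr3[cut:]
        spliced = gene.utr5 + cds + gene.utr3
        pair = [(f"{base}_i1", spliced), (f"{base}_i2", retained)]
    elif mode == "polya":
        if len(gene.utr3) <= intron_len:
            raise ValueError("3' UTR shorter than the poly(A) shift")
        long_ = gene.utr5 + cds + gene.utr3
        short = gene.utr5 + cds + gene.utr3[: len(gene.utr3) - intron_len]
        pair = [(f"{base}_i1", long_), (f"{base}_i2", short)]
    else:
        raise ValueError(f"unknown isoform mode {mode!r}")
    span = (len(gene.utr5) + 1, len(gene.utr5) + len(cds))
    return [TranscriptRecord(tid, seq, span, family=gene.record.family) for tid, seq in pair]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    transcripts: Sequence[tuple], sim: ReadSimSpec
) -> Tuple[List[ReadRecord], float]:
    """Draw reads from transcripts proportionally to their weights.

    ``transcripts`` is a sequence of (id, sequence).  Positions are uniform,
    strands uniform, per-base errors independent; read ids carry the source
    transcript.  Returns ``(reads, run_size_gb)``; byte-identical output
    under a fixed seed.
    """
    rng = np.random.default_rng(sim.seed)
    ids = [t[0] for t in transcripts]
    seqs = [t[1].upper() for t in transcripts]
    for tid, s in zip(ids, seqs):
        if len(s) < sim.read_len:
            raise ValueError(f"transcript {tid} shorter than read length")
    w = np.array([sim.weights.get(tid, 0.0) for tid in ids], dtype=float)
    if w.sum() <= 0:
        raise ValueError("all weights are zero")
    p = w / w.sum()
    src = rng.choice(len(ids), size=sim.n_reads, p=p)
    reads: List[ReadRecord] = []
    for r_i, t_i in enumerate(src):
        seq = seqs[t_i]
        start = int(rng.integers(len(seq) - sim.read_len + 1))
        frag = seq[start : start + sim.read_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if sim.error_rate > 0:
            frag = list(frag)
            errs = np.nonzero(rng.random(sim.read_len) < sim.error_rate)[0]
            for e in errs:
                frag[e] = _BASES[(_BASES.index(frag[e]) + 1 + int(rng.integers(3))) % 4] \
                    if frag[e] in _BASES else frag[e]
            frag = "".join(frag)
        qual = np.clip(np.rint(rng.normal(sim.qual_mean, sim.qual_sd, sim.read_len)), 2, 41)
        reads.append(ReadRecord(f"r{r_i}|{ids[t_i]}", frag, tuple(int(q) for q in qual)))
    run_size_gb = sim.n_reads * sim.read_len / 1e9
    return reads, run_size_gb
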