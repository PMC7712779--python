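"""Bundled synthetic panel: the printed 39-gene catalogue plus a synthetic
sequence panel realising it.

The gene *table* (``data/table1.tsv``) is the published catalogue of the 39
Blattella germanica AMP genes (names, products, CDS/protein lengths, Pfam
domains, scaffold placements).  The *sequences* shipped here are synthetic:
deterministic stand-ins built to satisfy every architectural constraint the
catalogue and family descriptions state --

* per-gene CDS and protein lengths exactly as in the table
  (``prot = cds/3 - 1``);
* hydrophobic signal peptides of 18-22 aa (termicins: residues 1-19);
* 6 conserved mature-region cysteines in defensins, 8 in drosomycins;
* a toxin-like domain at residues 30-63 of the 64-aa termicins, and a single
  S/A difference at site 13 as the only variable column among the three;
* attacin-like proteins of 118-119 aa with a C-terminal 81-aa attacin block
  and ~20% K+R overall;
* blattellicins > 200 aa with a 20-aa signal plus two extra residues (the
  second a proline), a Glx-rich segment > 70 aa, the attacin block and a
  C-terminal RK;
* 150-nt diagnostic windows at CDS 41-190 pairwise distinct across the 16
  defensins except defensin_g3/defensin_g5, and four polymorphic sites
  spread over the three termicin CDS.

Being synthetic, the panel reproduces the architecture and the counting
structure of the real gene set, not its actual residues.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

from .amp_classifier import DomainProfile, build_profile
from .sequence_io import GeneTableRow, ScaffoldSeq, read_gene_table

FAMILY_OF_PREFIX = {
    "defensin": "defensin",
    "termicin": "termicin",
    "drosomycin": "drosomycin",
    "attacin-like": "attacin_like",
    "blattellicin": "blattellicin",
}

#: the 17 genes used for whole-CDS expression screening across runs
SELECTED_17 = [
    "defensin_g2", "defensin_g3", "defensin_g7", "defensin_g9",
    "defensin_g11", "defensin_g13", "defensin_g15",
    "termicin_g1",
    "drosomycin_g1", "drosomycin_g5", "drosomycin_g6",
    "drosomycin_g11", "drosomycin_g12",
    "attacin-like_g1", "attacin-like_g2",
    "blattellicin_g1", "blattellicin_g4",
]

# ---------------------------------------------------------------------------
# protein building blocks
# ---------------------------------------------------------------------------

_SIG_CORE = "LFVILVLFVILVLFVILVLF"


def _signal(length: int) -> str:
    """Hydrophobic signal peptide of the requested length (M-K-core-A)."""
    if not 15 <= length <= 30:
        raise ValueError("signal length outside 15-30")
    return "MK" + _SIG_CORE[: length - 3] + "A"


# defensin: 40-aa C-terminal block, cysteines at 3,16,20,30,36,38
_DEF_DOM = "ATCDLLSGFGVNDSACAAHCLLRGNRGGYCNGKGVCVCRN"

# drosomycin: 47-aa block with 8 cysteines
_drs = list("DKALSGRYHGPNFSDSAKAAHARALGRKGGSADGKLSATYRNHGAEL")
for _i in (3, 12, 17, 24, 31, 38, 40, 47):
    _drs[_i - 1] = "C"
_DRS_DOM = "".join(_drs)

# termicin: 34-aa toxin-like block (protein positions 30-63)
_TER_DOM = "DAFDTLNEGHVKGFAENLLDQSACKLAGGHCITR"
_TER_LINK = "NDPQDAGFTE"

# attacin: 81-aa glycine-rich block, 18 K/R, no Cys
_att = list("GKDAGLNHKV" * 8 + "G")
for _i, _aa in [(4, "R"), (74, "R"), (15, "E"), (35, "E"), (55, "E"),
                (63, "T"), (27, "F"), (47, "Y"), (67, "S"), (77, "L")]:
    _att[_i] = _aa
_ATT_DOM = "".join(_att)

# divergent variant used by attacin-like_g2 (K/R count preserved)
_att2 = list(_ATT_DOM)
for _i, _aa in zip((2, 12, 22, 32, 42, 52, 62, 72), "TSNQAVLI"):
    _att2[_i] = _aa
_ATT_DOM2 = "".join(_att2)

_ATT_LINK = "NKDTPEGFRSDLKAGKRT"   # 18 aa, 5 K/R
_ATT_LINK2 = _ATT_LINK + "G"       # 19 aa for the one-codon-longer paralog

_DEF_LINKS = {
    74: "QNRPVYHAGLKSTDK",          # 15
    71: "NRPVYHAGLKST",             # 12
    81: "QNRPVYHAGLKSTDKAGRN",      # 19
    75: "QNRPVYHAGLKSTDKR",         # 16
    63: "NRPKG",                    # 5
}
_DEF_SIGLEN = {74: 19, 71: 19, 81: 22, 75: 19, 63: 18}


def _glx(n: int) -> str:
    return ("QQE" * (n // 3 + 1))[:n]


def _blat_linker(n: int) -> str:
    blk = list(("KNDAGLSHKVGE" * (n // 12 + 1))[:n])
    for i in range(5, n, 12):
        blk[i] = "R"
    return "".join(blk)


def _defensin_protein(prot_len: int) -> str:
    sig = _signal(_DEF_SIGLEN[prot_len])
    link = _DEF_LINKS[prot_len]
    prot = sig + link + _DEF_DOM
    assert len(prot) == prot_len, (prot_len, len(prot))
    return prot


def _termicin_protein(site13: str) -> str:
    sig = list(_signal(19))
    sig[12] = site13
    prot = "".join(sig) + _TER_LINK + _TER_DOM + "N"
    assert len(prot) == 64
    return prot


def _drosomycin_protein(prot_len: int) -> str:
    if prot_len == 66:
        prot = _signal(19) + _DRS_DOM
    else:  # 71: five extra residues between signal and domain
        prot = _signal(19) + "GNQGS" + _DRS_DOM
    assert len(prot) == prot_len
    return prot


def _attacin_like_protein(which: int) -> str:
    if which == 2:
        prot = _signal(19) + _ATT_LINK2 + _ATT_DOM2
        assert len(prot) == 119
    else:
        prot = _signal(19) + _ATT_LINK + _ATT_DOM
        assert len(prot) == 118
    return prot


_BLAT_GLX = {1: 100, 2: 92, 3: 110, 4: 95}


def _blattellicin_protein(which: int, prot_len: int) -> str:
    glx_len = _BLAT_GLX[which]
    linker_len = prot_len - 20 - 2 - glx_len - 81 - 2
    prot = _signal(20) + "QP" + _glx(glx_len) + _blat_linker(linker_len) + _ATT_DOM + "RK"
    assert len(prot) == prot_len, (prot_len, len(prot))
    return prot


# ---------------------------------------------------------------------------
# CDS construction
# ---------------------------------------------------------------------------

CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}
ALT_CODON = {
    "A": "GCC", "C": "TGT", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTT",
    "N": "AAC", "P": "CCA", "Q": "CAA", "R": "CGC", "S": "AGT",
    "T": "ACA", "V": "GTT", "Y": "TAC",
}


def _codons(protein: str) -> list:
    return [CODON[aa] for aa in protein] + ["TAA"]


_AA_OF_CODON = {c: a for a, c in CODON.items()}
_AA_OF_CODON.update({c: a for a, c in ALT_CODON.items()})
_AA_OF_CODON["TCT"] = "S"  # termicin site-13 serine codon


def _syn_mark(codons: list, target: int) -> int:
    """Swap the first synonymously-swappable (still-canonical) codon at or
    after ``target`` (1-based) for its alternative; returns the index used."""
    for i in range(target - 1, len(codons) - 1):
        aa = _AA_OF_CODON[codons[i]]
        if aa in ALT_CODON and codons[i] == CODON[aa]:
            codons[i] = ALT_CODON[aa]
            return i + 1
    raise ValueError("no swappable codon found")


# ---------------------------------------------------------------------------
# the 39-gene panel
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def load_table1() -> tuple:
    """The published 39-row gene table, parsed and length-checked."""
    path = resources.files("amp_arsenal").joinpath("data/table1.tsv")
    with resources.as_file(path) as p:
        return tuple(read_gene_table(p))


@lru_cache(maxsize=1)
def panel_proteins() -> dict:
    """Synthetic proteins for all 39 genes, keyed by gene name."""
    prots = {}
    for row in load_table1():
        fam = row.gene.split("_g")[0]
        idx = int(row.gene.split("_g")[1])
        if fam == "defensin":
            prots[row.gene] = _defensin_protein(row.prot_len)
        elif fam == "termicin":
            prots[row.gene] = _termicin_protein("A" if idx == 3 else "S")
        elif fam == "drosomycin":
            prots[row.gene] = _drosomycin_protein(row.prot_len)
        elif fam == "attacin-like":
            prots[row.gene] = _attacin_like_protein(idx)
        else:
            prots[row.gene] = _blattellicin_protein(idx, row.prot_len)
        assert len(prots[row.gene]) == row.prot_len
    return prots


@lru_cache(maxsize=1)
def panel_cds() -> dict:
    """Synthetic CDS for all 39 genes (lengths as printed; marker
    substitutions make the diagnostic-window structure match the study)."""
    prots = panel_proteins()
    cds = {}
    for row in load_table1():
        fam = row.gene.split("_g")[0]
        idx = int(row.gene.split("_g")[1])
        codons = _codons(prots[row.gene])
        if fam == "defensin":
            if idx in (3, 5):
                _syn_mark(codons, 19)       # shared -> identical 41-190 window
                if idx == 5:
                    _syn_mark(codons, 65)   # outside the window: distinct gene
            else:
                _syn_mark(codons, 15 + 2 * (idx - 1))
        elif fam == "termicin":
            # S/A codons at site 13 chosen to differ at one nucleotide only
            codons[12] = "TCT" if prots[row.gene][12] == "S" else "GCT"
            if idx == 2:
                _syn_mark(codons, 25)
            elif idx == 3:
                _syn_mark(codons, 40)
                _syn_mark(codons, 50)
        elif fam == "drosomycin":
            _syn_mark(codons, 21 + 2 * (idx - 1))
        elif fam == "attacin-like":
            if idx == 3:  # nine synonymous differences from attacin-like_g1
                for t in (8, 12, 16, 20, 24, 28, 32, 36, 95):
                    _syn_mark(codons, t)
        else:  # blattellicin: distinct 5' ends
            for k in range(3):
                _syn_mark(codons, 24 + 5 * idx + 2 * k)
        if row.scaffold == "Unplaced":
            # genes absent from the assembly: densely spaced synonymous
            # differences so no >=31-nt anchor survives against sibling loci
            for t in range(6, len(codons) - 2, 8):
                _syn_mark(codons, t)
        seq = "".join(codons)
        assert len(seq) == row.cds_len, (row.gene, len(seq), row.cds_len)
        cds[row.gene] = seq
    return cds


@lru_cache(maxsize=1)
def panel_domain_blocks() -> dict:
    """Per-gene diagnostic-domain subsequence used to train the profiles."""
    prots = panel_proteins()
    blocks = {}
    for row in load_table1():
        fam = row.gene.split("_g")[0]
        p = prots[row.gene]
        if fam == "defensin":
            blocks[row.gene] = ("Defensin_2", p[-40:])
        elif fam == "termicin":
            blocks[row.gene] = ("Toxin_37", p[29:63])
        elif fam == "drosomycin":
            blocks[row.gene] = ("Gamma-thionin", p[-47:])
        elif fam == "attacin-like":
            blocks[row.gene] = ("Attacin_C", p[-81:])
        else:
            blocks[row.gene] = ("Attacin_C", p[-83:-2])
    return blocks


@lru_cache(maxsize=1)
def panel_profiles() -> dict:
    """Family-domain profiles trained on the bundled panel."""
    grouped: dict = {}
    for name, (dom, block) in panel_domain_blocks().items():
        grouped.setdefault(dom, []).append(block)
    return {dom: build_profile(dom, blocks) for dom, blocks in grouped.items()}


# ---------------------------------------------------------------------------
# mRNAs and scaffolds for transcript/genome reconciliation
# ---------------------------------------------------------------------------

_UTR5_HEAD = "GGTACACTTGAGCATCTG"
_UTR3 = "TAGCATCAACTGTGATCCTGAACGTATTGCAGTTAAAAAA"


def _barcode(i: int) -> str:
    """12-nt gene barcode; distinct indices differ by >= 2 nt."""
    return "".join("AC" if (i >> b) & 1 else "TG" for b in range(6))


@lru_cache(maxsize=1)
def panel_mrnas() -> dict:
    """Synthetic mRNA per gene: tagged 5'UTR + CDS + common 3'UTR.

    Returns ``{gene: (mrna, cds_span)}`` with a 1-based inclusive CDS span.
    """
    out = {}
    for i, row in enumerate(load_table1()):
        if row.scaffold == "Unplaced":
            rng = np.random.default_rng(777 + i)
            utr5 = "".join(rng.choice(list("ACGT"), 34))
            utr3 = "".join(rng.choice(list("ACGT"), 34)) + "AAAAAA"
        else:
            utr5 = _UTR5_HEAD + _barcode(i) + "CAAC"
            utr3 = _UTR3
        seq = utr5 + panel_cds()[row.gene] + utr3
        out[row.gene] = (seq, (len(utr5) + 1, len(utr5) + row.cds_len))
    return out


@lru_cache(maxsize=1)
def panel_scaffolds() -> dict:
    """Synthetic scaffolds: placed genes laid out in tandem with spacers.

    Scaffold ids and gene-to-scaffold assignment follow the printed table;
    one spacer on the defensin_g3 scaffold carries an N-gap, mirroring the
    assembly gap reported there.
    """
    rng = np.random.default_rng(20201203)
    mrnas = panel_mrnas()
    per_scaffold: dict = {}
    for row in load_table1():
        if row.scaffold != "Unplaced":
            per_scaffold.setdefault(row.scaffold, []).append(row.gene)
    scaffolds = {}
    for sid, genes in per_scaffold.items():
        parts = ["".join(rng.choice(list("ACGT"), 150))]
        for g in genes:
            parts.append(mrnas[g][0])
            spacer = "".join(rng.choice(list("ACGT"), 150))
            if sid == "PYGN01003429" and g == "defensin_g3":
                spacer = spacer[:50] + "N" * 40 + spacer[90:]
            parts.append(spacer)
        scaffolds[sid] = ScaffoldSeq.from_seq(sid, "".join(parts))
    return scaffolds


# ---------------------------------------------------------------------------
# attacin-family alignment (for trimming/phylogeny)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def attacin_alignment() -> tuple:
    """Gapped alignment of the 7 attacin-family proteins plus its trim spec.

    Layout: 22 N-terminal columns, a padded variable middle, the 81-column
    attacin block, and 2 tail columns.  Returns ``(alignment_dict,
    (domain_start, domain_end))`` with 1-based inclusive domain columns.
    """
    prots = panel_proteins()
    names = [r.gene for r in load_table1()
             if r.gene.startswith(("attacin-like", "blattellicin"))]
    pieces = {}
    for n in names:
        p = prots[n]
        if n.startswith("blattellicin"):
            head, mid, dom, tail = p[:22], p[22:-83], p[-83:-2], p[-2:]
        else:
            head, mid, dom, tail = p[:22], p[22:-81], p[-81:], "--"
        pieces[n] = (head, mid, dom, tail)
    maxmid = max(len(m) for _, m, _, _ in pieces.values())
    aln = {
        n: head + mid + "-" * (maxmid - len(mid)) + dom + tail
        for n, (head, mid, dom, tail) in pieces.items()
    }
    domain_block = (22 + maxmid + 1, 22 + maxmid + 81)
    return aln, domain_block
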