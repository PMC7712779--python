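"""Transcript/genome reconciliation into a curated gene catalogue.

The decision rules implemented here distinguish, for a pair of same-family
transcripts:

* **isoform**  - identical CDS and the same genomic placement, differing only
  in UTR intron retention or the 3' end (alternative poly(A));
* **paralog**  - placed at distinct loci (even with identical CDS), or at
  least 3 total mRNA differences (substitutions counted per site, each indel
  event counted once);
* **allele**   - unplaced or co-placed with at most 2 total differences.

Placement replaces a spliced aligner with exact-anchor chaining: maximal
exact matches of at least ``min_anchor`` nt are chained colinearly on one
scaffold and strand; chain gaps on the scaffold are annotated as introns
(GT..AG checked) or assembly-gap interruptions.  A transcript is *placed*
when anchors cover at least 90% of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

from Bio import Align

from . import synthetic_panel
from .amp_classifier import annotate
from .protein_metrics import translate
from .sequence_io import DNA_ALPHABET, GeneTableRow, ScaffoldSeq, revcomp

MIN_ANCHOR = 31
MIN_COVERAGE = 0.9
PARALOG_MIN_DIFFS = 3
UNPLACED = "Unplaced"

FAMILY_ORDER = ("defensin", "termicin", "drosomycin", "attacin_like", "blattellicin")
FAMILY_DISPLAY = {
    "defensin": "defensin",
    "termicin": "termicin",
    "drosomycin": "drosomycin",
    "attacin_like": "attacin-like",
    "blattellicin": "blattellicin",
}
FAMILY_PFAM = {
    "defensin": ("PF01097", "Defensin_2"),
    "termicin": ("PF11415", "Toxin_37"),
    "drosomycin": ("PF00304", "Gamma-thionin"),
    "attacin_like": ("PF03769", "Attacin_C"),
    "blattellicin": ("PF03769", "Attacin_C"),
}

DEFAULT_KEYWORDS = ("defense", "drosomycin", "tenecin", "phormicin", "attacin", "coleoptericin")
DEFAULT_EXCLUSIONS = ("giant-lens protein", "putative defense protein 3")


@dataclass
class Placement:
    scaffold: str
    strand: str  # '+' or '-'
    blocks: List[tuple]  # (t_start, t_end, s_start, s_end) 1-based inclusive
    coverage: float
    introns: List[tuple] = field(default_factory=list)  # (s_start, s_end, canonical)
    gap_flags: List[tuple] = field(default_factory=list)

    @property
    def span(self) -> tuple:
        return (min(b[2] for b in self.blocks), max(b[3] for b in self.blocks))


@dataclass
class TranscriptRecord:
    id: str
    mrna: str
    cds_span: tuple  # (start, end) 1-based inclusive within mrna
    family: Optional[str] = None
    placement: Optional[Placement] = None

    @property
    def cds(self) -> str:
        s, e = self.cds_span
        if not (1 <= s <= e <= len(self.mrna)):
            raise ValueError(f"{self.id}: CDS span {self.cds_span} outside mRNA")
        return self.mrna[s - 1 : e]


@dataclass
class GeneRecord:
    name: str
    family: str
    scaffold: str  # scaffold id or 'Unplaced'
    exons: List[tuple]  # (start, end, strand) on scaffold
    cds: str
    gap_flags: List[tuple] = field(default_factory=list)
    equivalent_locus: str = ""
    isoforms: List[TranscriptRecord] = field(default_factory=list)

    @property
    def protein(self) -> str:
        return translate(self.cds)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _anchor_blocks(transcript: str, scaffold: str, k: int) -> List[tuple]:
    """Maximal exact-match blocks >= k nt as (t_start, t_end, s_start, s_end),
    0-based half-open internally, returned 1-based inclusive."""
    index: Dict[str, list] = {}
    for i in range(len(scaffold) - k + 1):
        index.setdefault(scaffold[i : i + k], []).append(i)
    blocks = set()
    covered: Dict[int, list] = {}  # diagonal -> [(t_start, t_end) 0-based half-open]
    for t in range(len(transcript) - k + 1):
        kmer = transcript[t : t + k]
        for s in index.get(kmer, ()):
            diag = s - t
            if any(ts <= t < te for ts, te in covered.get(diag, ())):
                continue  # already inside a maximal block on this diagonal
            ts, ss = t, s
            while ts > 0 and ss > 0 and transcript[ts - 1] == scaffold[ss - 1]:
                ts -= 1
                ss -= 1
            te, se = t + k, s + k
            while te < len(transcript) and se < len(scaffold) and transcript[te] == scaffold[se]:
                te += 1
                se += 1
            covered.setdefault(diag, []).append((ts, te))
            blocks.add((ts + 1, te, ss + 1, se))
    return sorted(blocks)


def _chain(blocks: List[tuple], tlen: int) -> tuple:
    """Colinear chain maximising covered transcript bases (DP, O(B^2))."""
    if not blocks:
        return [], 0.0
    blocks = sorted(blocks)
    n = len(blocks)
    cover = [b[1] - b[0] + 1 for b in blocks]
    score = cover[:]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            bi, bj = blocks[i], blocks[j]
            if bi[1] < bj[0] and bi[3] < bj[2]:  # colinear, non-overlapping
                cand = score[i] + cover[j]
                if cand > score[j]:
                    score[j] = cand
                    prev[j] = i
    best = max(range(n), key=lambda j: score[j])
    chain = []
    while best != -1:
        chain.append(blocks[best])
        best = prev[best]
    chain.reverse()
    return chain, sum(b[1] - b[0] + 1 for b in chain) / tlen


def place_transcript(
    transcript: TranscriptRecord,
    scaffolds: Iterable[ScaffoldSeq],
    min_anchor: int = MIN_ANCHOR,
    min_coverage: float = MIN_COVERAGE,
) -> Optional[Placement]:
    """Best exact-anchor chain placement of a transcript, or None (unplaced)."""
    seq = transcript.mrna.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{transcript.id}: non-DNA characters {sorted(bad)}")
    best: Optional[Placement] = None
    for scf in scaffolds:
        for strand, tseq in (("+", seq), ("-", revcomp(seq))):
            blocks = _anchor_blocks(tseq, scf.seq, min_anchor)
            chain, coverage = _chain(blocks, len(tseq))
            if not chain:
                continue
            if best is None or coverage > best.coverage:
                best = Placement(scf.id, strand, chain, coverage)
                _annotate_chain_gaps(best, scf)
    if best is None or best.coverage < min_coverage:
        return None
    return best


def _annotate_chain_gaps(placement: Placement, scf: ScaffoldSeq) -> None:
    """Classify inter-block scaffold gaps as introns or assembly-gap hits."""
    placement.introns = []
    placement.gap_flags = []
    for a, b in zip(placement.blocks, placement.blocks[1:]):
        gs, ge = a[3] + 1, b[2] - 1
        if gs > ge:
            continue
        seg = scf.seq[gs - 1 : ge]
        overlaps_gap = any(not (ge < s or gs > e) for s, e in scf.gaps)
        if overlaps_gap:
            placement.gap_flags.append((gs, ge))
        else:
            canonical = seg[:2] == "GT" and seg[-2:] == "AG"
            placement.introns.append((gs, ge, canonical))
    # flanking assembly gaps immediately beside the placed span
    span = placement.span
    for s, e in scf.gaps:
        if abs(s - span[1]) <= 20 or abs(e - span[0]) <= 20:
            placement.gap_flags.append((s, e))


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------


_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=2, mismatch_score=-1,
    open_gap_score=-5, extend_gap_score=-0.5,
)


def mrna_differences(a: str, b: str) -> int:
    """Total differences between two mRNAs: one per substituted site, one per
    indel event (a multi-base indel counts once).

    Affine gap costs keep a contiguous deletion as a single event instead of
    scattering it over cost-equivalent fragments.
    """
    if a == b:
        return 0
    aln = _ALIGNER.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    diffs = 0
    in_gap = False
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-":
            if not in_gap:
                diffs += 1
                in_gap = True
        else:
            in_gap = False
            if ca != cb:
                diffs += 1
    return diffs


def _co_placed(p1: Optional[Placement], p2: Optional[Placement]) -> Optional[bool]:
    """True if same locus, False if distinct loci, None if either unplaced."""
    if p1 is None or p2 is None:
        return None
    if p1.scaffold != p2.scaffold:
        return False
    s1, e1 = p1.span
    s2, e2 = p2.span
    return not (e1 < s2 or e2 < s1)


def classify_pair(t1: TranscriptRecord, t2: TranscriptRecord) -> str:
    """'isoform' | 'allele' | 'paralog' for two same-family transcripts."""
    if t1.family != t2.family:
        raise ValueError(f"different families: {t1.family} vs {t2.family}")
    same_locus = _co_placed(t1.placement, t2.placement)
    if same_locus is False:
        return "paralog"  # distinct loci, even with identical CDS
    if t1.cds == t2.cds and same_locus is True:
        return "isoform"  # UTR intron retention / alternative 3' end
    diffs = mrna_differences(t1.mrna, t2.mrna)
    if diffs >= PARALOG_MIN_DIFFS:
        return "paralog"
    return "allele"


# ---------------------------------------------------------------------------
# keyword screen
# ---------------------------------------------------------------------------


def keyword_screen(
    products: Dict[str, str],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
) -> List[str]:
    """Case-insensitive substring screen of product names.

    Returns ids whose product matches any keyword and none of the exclusion
    product names, preserving input order.
    """
    kws = [k.lower() for k in keywords]
    excl = [e.lower() for e in exclusions]
    retained = []
    for pid, product in products.items():
        p = product.lower()
        if any(k in p for k in kws) and not any(e in p for e in excl):
            retained.append(pid)
    return retained


# ---------------------------------------------------------------------------
# catalogue building
# ---------------------------------------------------------------------------


def _find_occurrences(cds: str, scaffold: str) -> List[int]:
    """Non-overlapping exact occurrence starts (0-based) of cds in scaffold."""
    hits, i = [], scaffold.find(cds)
    while i != -1:
        hits.append(i)
        i = scaffold.find(cds, i + len(cds))
    return hits


def build_catalogue(
    transcripts: Sequence[TranscriptRecord],
    scaffolds: Iterable[ScaffoldSeq],
    domain_hits=None,
    profiles: Optional[dict] = None,
    min_anchor: int = MIN_ANCHOR,
    log: Optional[list] = None,
) -> List[GeneRecord]:
    """Reconcile classified transcripts with the genome into gene records.

    Transcripts are classified by architecture (unless ``domain_hits`` is
    supplied), placed on the scaffolds, merged when isoforms/alleles, split
    when a placed CDS occurs at multiple loci (tandem duplicates), flagged
    when their placement touches assembly gaps, and named
    ``family_gN`` -- families in fixed order, genes numbered by scaffold then
    coordinate with unplaced genes last.
    """
    if profiles is None:
        profiles = synthetic_panel.panel_profiles()
    scaffolds = list(scaffolds)
    scaffold_by_id = {s.id: s for s in scaffolds}
    log = log if log is not None else []

    for t in transcripts:
        if t.family is None:
            ann = annotate(t.id, translate(t.cds), profiles, domain_hits)
            t.family = ann.class_label
        if t.placement is None:
            t.placement = place_transcript(t, scaffolds, min_anchor)
            log.append(
                f"{t.id}: family={t.family} "
                + (
                    f"placed {t.placement.scaffold}:{t.placement.span}"
                    if t.placement
                    else "UNPLACED"
                )
            )

    # group same-family transcripts: merge isoform/allele pairs (union-find)
    parent = {t.id: t.id for t in transcripts}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_family: Dict[str, list] = {}
    for t in transcripts:
        by_family.setdefault(t.family, []).append(t)
    for fam, members in by_family.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                verdict = classify_pair(members[i], members[j])
                if verdict in ("isoform", "allele"):
                    parent[find(members[i].id)] = find(members[j].id)
                    log.append(f"{members[i].id} ~ {members[j].id}: {verdict} (merged)")

    groups: Dict[str, list] = {}
    for t in transcripts:
        groups.setdefault(find(t.id), []).append(t)

    # scaffold regions already claimed by some transcript's placement
    claimed: Dict[str, list] = {}
    for t in transcripts:
        if t.placement is not None:
            claimed.setdefault(t.placement.scaffold, []).append(t.placement.span)

    records: List[GeneRecord] = []
    for members in groups.values():
        rep = max(members, key=lambda t: (t.placement is not None, len(t.cds), t.id))
        fam = rep.family
        if rep.placement is None:
            records.append(
                GeneRecord(
                    name="", family=fam, scaffold=UNPLACED, exons=[],
                    cds=rep.cds, isoforms=list(members),
                )
            )
            continue
        pl = rep.placement
        records.append(
            GeneRecord(
                name="", family=fam, scaffold=pl.scaffold,
                exons=[(b[2], b[3], pl.strand) for b in pl.blocks],
                cds=rep.cds, gap_flags=list(pl.gap_flags),
                isoforms=list(members),
            )
        )
        # tandem split: extra exact copies of the CDS at loci no transcript
        # claims become additional gene records
        scf = scaffold_by_id[pl.scaffold]
        if pl.strand == "+":
            for start0 in _find_occurrences(rep.cds, scf.seq):
                s, e = start0 + 1, start0 + len(rep.cds)
                spans = claimed.get(pl.scaffold, [])
                if any(not (e < a or s > b) for a, b in spans):
                    continue
                claimed.setdefault(pl.scaffold, []).append((s, e))
                log.append(f"{rep.id}: extra CDS copy at {pl.scaffold}:{s}-{e} "
                           "-> tandem split")
                records.append(
                    GeneRecord(
                        name="", family=fam, scaffold=pl.scaffold,
                        exons=[(s, e, "+")], cds=rep.cds,
                        isoforms=list(members),
                    )
                )

    # naming: family order, then scaffold id / coordinate, unplaced last
    def sort_key(r: GeneRecord):
        fam_i = FAMILY_ORDER.index(r.family) if r.family in FAMILY_ORDER else len(FAMILY_ORDER)
        if r.scaffold == UNPLACED:
            return (fam_i, 1, "", 0, r.isoforms[0].id if r.isoforms else "")
        return (fam_i, 0, r.scaffold, r.exons[0][0] if r.exons else 0, "")

    records.sort(key=sort_key)
    counters: Dict[str, int] = {}
    for r in records:
        counters[r.family] = counters.get(r.family, 0) + 1
        r.name = f"{FAMILY_DISPLAY.get(r.family, r.family)}_g{counters[r.family]}"
    return records


def catalogue_to_table(records: Sequence[GeneRecord]) -> List[GeneTableRow]:
    """Emit the catalogue as 9-column gene-table rows."""
    rows = []
    for i, r in enumerate(records, 1):
        code, pfname = FAMILY_PFAM.get(r.family, ("", ""))
        rows.append(
            GeneTableRow(
                no=i,
                gene=r.name,
                product=FAMILY_DISPLAY.get(r.family, r.family).capitalize(),
                cds_len=len(r.cds),
                prot_len=len(r.cds) // 3 - 1,
                pfam_code=code,
                pfam_name=pfname,
                scaffold=r.scaffold,
                equivalent_cds=r.equivalent_locus,
            )
        )
    return rows
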