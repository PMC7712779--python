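"""Architecture-based classification of antimicrobial peptides.

Five classes are recognised from domain architecture:

* defensin        - C-terminal defensin domain, 6 cysteines in the mature region
* termicin        - toxin-like (Toxin_37) domain
* drosomycin      - gamma-thionin domain, 8 cysteines in the mature region
* attacin_like    - C-terminal attacin domain, short protein (~100-130 aa)
* blattellicin    - attacin domain plus a long Glx-rich segment (> 70 aa of
                    mostly Q/E) and overall length > 200 aa

Domain detection uses ungapped log-odds scans against per-family
position-frequency profiles (built from the bundled panel proteins), or an
externally supplied domain-hit table which then takes precedence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .protein_metrics import AMINO_ACIDS
from .sequence_io import DomainHit

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SMALL_RESIDUES = set("AGSCT")
GLX = set("QE")

UNCLASSIFIED = "unclassified"
FAMILIES = ("defensin", "termicin", "drosomycin", "attacin_like", "blattellicin")

#: Pfam-style display names for the class-diagnostic domains
DOMAIN_NAMES = {
    "defensin": "Defensin_2",
    "termicin": "Toxin_37",
    "drosomycin": "Gamma-thionin",
    "attacin_like": "Attacin_C",
    "blattellicin": "Attacin_C",
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_BG = 1.0 / len(AMINO_ACIDS)


@dataclass
class DomainAnnotation:
    """Architecture annotation of a single protein (1-based spans)."""

    protein_id: str
    signal: Optional[tuple] = None
    glx_region: Optional[tuple] = None  # (start, end, density)
    family_domain: Optional[tuple] = None  # (name, start, end, score)
    all_domains: tuple = ()
    class_label: str = UNCLASSIFIED


# ---------------------------------------------------------------------------
# signal peptide
# ---------------------------------------------------------------------------

_CORE_WIN = 8
_CORE_MEAN = 1.6
_SEARCH_PREFIX = 25
_CLEAVE_MIN, _CLEAVE_MAX = 15, 30


def predict_signal_peptide(protein: str) -> Optional[tuple]:
    """Hydropathy heuristic for an N-terminal secretion signal.

    Looks for a hydrophobic core (>= 8 consecutive residues with mean
    Kyte-Doolittle hydropathy >= 1.6) within the first 25 residues; the
    cleavage site is the first small residue (A/G/S/C/T) after that core,
    clamped to positions 15-30.  Returns the 1-based inclusive span
    ``(1, L)`` or None.
    """
    bad = set(protein) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    if len(protein) < 30:
        return None
    prefix = protein[:_SEARCH_PREFIX]
    h = [KYTE_DOOLITTLE[aa] for aa in prefix]
    core_end = None
    first_win_end = None
    for i in range(len(h) - _CORE_WIN + 1):
        if sum(h[i : i + _CORE_WIN]) / _CORE_WIN >= _CORE_MEAN:
            if first_win_end is None:
                first_win_end = i + _CORE_WIN  # 1-based position of window end
            core_end = i + _CORE_WIN
        elif first_win_end is not None:
            break  # core is the run of qualifying windows containing the first
    if first_win_end is None:
        return None
    lo = max(_CLEAVE_MIN, first_win_end)
    for pos in range(lo, min(_CLEAVE_MAX, len(protein)) + 1):
        if protein[pos - 1] in SMALL_RESIDUES:
            return (1, pos)
    # no small residue in range: cleave right after the core
    return (1, min(max(core_end + 1, _CLEAVE_MIN), _CLEAVE_MAX))


def mature_region(protein: str, signal: Optional[tuple]) -> str:
    return protein[signal[1] :] if signal else protein


# ---------------------------------------------------------------------------
# Glx-rich region
# ---------------------------------------------------------------------------


def find_glx_region(
    protein: str, min_len: int = 71, min_density: float = 0.6
) -> Optional[tuple]:
    """Longest substring whose Q+E density is >= ``min_density``.

    Returns ``(start, end, density)`` 1-based inclusive, or None when the
    longest qualifying substring is shorter than ``min_len``.  Ties on length
    are broken toward the smaller start.

    Uses the prefix-sum reduction: a window has density >= t iff the
    transformed weights (indicator - t) sum to >= 0 over it, so the longest
    window ends at j with the earliest prefix minimum <= P[j].
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not 0 < min_density <= 1:
        raise ValueError("min_density must be in (0, 1]")
    n = len(protein)
    if n == 0:
        return None
    w = np.fromiter((1.0 if aa in GLX else 0.0 for aa in protein), float, n) - min_density
    prefix = np.concatenate([[0.0], np.cumsum(w)])
    # prefix_min[i] = min(prefix[0..i]); non-increasing by construction
    prefix_min = np.minimum.accumulate(prefix)
    best_len, best_start = 0, 0
    for j in range(1, n + 1):
        # earliest i with prefix[i] <= prefix[j]; prefix_min is non-increasing
        i = int(np.searchsorted(-prefix_min, -prefix[j] - 1e-12, side="left"))
        if i < j and j - i > best_len:
            best_len, best_start = j - i, i
    if best_len < min_len:
        return None
    seg = protein[best_start : best_start + best_len]
    density = sum(1 for aa in seg if aa in GLX) / best_len
    return (best_start + 1, best_start + best_len, density)


# ---------------------------------------------------------------------------
# family-domain profiles
# ---------------------------------------------------------------------------


@dataclass
class DomainProfile:
    """Ungapped position-frequency profile for one family domain."""

    name: str
    matrix: np.ndarray  # (length, 20) probabilities
    threshold: float

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def score_window(self, window: str) -> float:
        return float(
            sum(
                math.log2(self.matrix[i, _AA_INDEX[aa]] / _BG)
                for i, aa in enumerate(window)
                if aa in _AA_INDEX
            )
        )

    def best_hit(self, protein: str) -> Optional[tuple]:
        """Best-scoring window as (start, end, score), or None if too short."""
        L = self.length
        if len(protein) < L:
            return None
        best = None
        for s in range(len(protein) - L + 1):
            sc = self.score_window(protein[s : s + L])
            if best is None or sc > best[2]:
                best = (s + 1, s + L, sc)
        return best


def build_profile(
    name: str, domain_blocks: Sequence, pseudocount: float = 0.5
) -> DomainProfile:
    """Build a profile from equal-length ungapped domain sequences.

    The reporting threshold is set to half the weakest training-sequence
    score (floored at 10 bits): comfortably recovers every training protein
    while rejecting cross-family and shuffled decoys, and leaves headroom for
    the divergence accumulated between paralogs.
    """
    lengths = {len(b) for b in domain_blocks}
    if len(lengths) != 1:
        raise ValueError(f"{name}: domain blocks have unequal lengths {lengths}")
    L = lengths.pop()
    counts = np.full((L, len(AMINO_ACIDS)), pseudocount)
    for block in domain_blocks:
        for i, aa in enumerate(block):
            counts[i, _AA_INDEX[aa]] += 1.0
    matrix = counts / counts.sum(axis=1, keepdims=True)
    prof = DomainProfile(name, matrix, threshold=-np.inf)
    min_score = min(prof.score_window(b) for b in domain_blocks)
    prof.threshold = max(0.5 * min_score, 10.0)
    return prof


def score_family_domain(
    protein: str,
    profiles: dict,
    protein_id: str = "",
    hit_table: Optional[Iterable] = None,
) -> tuple:
    """Best family-domain call for one protein.

    Returns ``(best_hit_or_None, all_hits)`` where hits are
    ``(name, start, end, score)``.  If ``hit_table`` (externally produced
    domain hits) is given it takes precedence over profile scanning.
    """
    if hit_table is not None:
        hits = [
            (h.domain, h.start, h.end, h.score)
            for h in hit_table
            if h.protein_id == protein_id
        ]
        hits.sort(key=lambda h: -h[3])
        return (hits[0] if hits else None), tuple(hits)
    hits = []
    for prof in profiles.values():
        bh = prof.best_hit(protein)
        if bh is not None and bh[2] >= prof.threshold:
            hits.append((prof.name, bh[0], bh[1], bh[2]))
    hits.sort(key=lambda h: -h[3])
    return (hits[0] if hits else None), tuple(hits)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

GLX_MIN_LEN = 71
GLX_MIN_DENSITY = 0.6
BLATTELLICIN_MIN_LEN = 200
ATTACIN_LIKE_RANGE = (100, 130)


def classify(protein: str, annotation: DomainAnnotation) -> str:
    """Apply the architecture rules to an annotated protein."""
    dom = annotation.family_domain
    if dom is None:
        return UNCLASSIFIED
    name = dom[0]
    mature = mature_region(protein, annotation.signal)
    n_cys = mature.count("C")
    if name == "Defensin_2":
        return "defensin" if n_cys == 6 else UNCLASSIFIED
    if name == "Gamma-thionin":
        return "drosomycin" if n_cys == 8 else UNCLASSIFIED
    if name == "Toxin_37":
        return "termicin"
    if name == "Attacin_C":
        glx = annotation.glx_region
        if glx is not None and len(protein) > BLATTELLICIN_MIN_LEN:
            return "blattellicin"
        lo, hi = ATTACIN_LIKE_RANGE
        if glx is None and lo <= len(protein) <= hi:
            return "attacin_like"
    return UNCLASSIFIED


def annotate(
    protein_id: str,
    protein: str,
    profiles: dict,
    hit_table: Optional[Iterable] = None,
) -> DomainAnnotation:
    """Full architecture annotation + class label for one protein."""
    signal = predict_signal_peptide(protein) if len(protein) >= 30 else None
    glx = find_glx_region(protein, GLX_MIN_LEN, GLX_MIN_DENSITY)
    best, allh = score_family_domain(protein, profiles, protein_id, hit_table)
    ann = DomainAnnotation(
        protein_id=protein_id,
        signal=signal,
        glx_region=glx,
        family_domain=best,
        all_domains=allh,
    )
    ann.class_label = classify(protein, ann)
    return ann


# ---------------------------------------------------------------------------
# translated six-frame screen
# ---------------------------------------------------------------------------


def _six_frames(seq: str):
    rc = str(Seq(seq).reverse_complement())
    for s in (seq, rc):
        for off in range(3):
            frame = s[off:]
            frame = frame[: len(frame) - len(frame) % 3]
            if frame:
                yield str(Seq(frame).translate(table=1))


def screen_transcripts(transcripts: Sequence, profiles: dict):
    """Six-frame translated family screen of nucleotide records.

    Every record is translated in all six frames, each stop-free fragment is
    scanned against every family profile, and per-record family
    presence/absence is reported (a blattellicin transcript registers through
    its attacin domain alone; the Glx region is not required for presence).

    Returns a DataFrame indexed by record id with one boolean column per
    domain profile, plus an ``any_amp`` column.
    """
    import pandas as pd

    rows = {}
    for rid, seq in transcripts:
        present = {name: False for name in profiles}
        for prot in _six_frames(seq.upper()):
            for frag in prot.split("*"):
                for name, prof in profiles.items():
                    if present[name] or len(frag) < prof.length:
                        continue
                    bh = prof.best_hit(frag)
                    if bh is not None and bh[2] >= prof.threshold:
                        present[name] = True
        rows[rid] = present
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(profiles))
    df.index.name = "record"
    df["any_amp"] = df.any(axis=1) if len(df.columns) else False
    return df
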