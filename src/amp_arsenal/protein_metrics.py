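"""Protein-level metrics: translation, composition, isoelectric point,
pairwise differences and logo (position-frequency) matrices.

The isoelectric point uses a Henderson-Hasselbalch charge model with the
EMBOSS pKa set by default; the table is swappable so published values from
other scales can be reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: EMBOSS pKa values; positive groups carry +1 below their pKa.
EMBOSS_PKA = {
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
    "Nterm": 8.6,
    "Cterm": 3.6,
}
_NEGATIVE = ("D", "E", "C", "Y")
_POSITIVE = ("H", "K", "R")


class TranslationError(ValueError):
    pass


def translate(cds: str) -> str:
    """Translate a complete CDS (standard code, single terminal stop).

    The returned protein has length ``len(cds)/3 - 1``; an internal stop or a
    missing terminal stop is an error.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate(table=1))
    if not prot.endswith("*"):
        raise TranslationError("CDS does not end with a stop codon")
    body = prot[:-1]
    if "*" in body:
        raise TranslationError(f"internal stop codon at aa {body.index('*') + 1}")
    if "X" in body:
        raise TranslationError("ambiguous codon in CDS")
    return body


@dataclass
class CompositionProfile:
    """Amino-acid composition (percent) of one protein or a protein group."""

    group_id: str
    freq: dict
    pct_positive: float  # K + R
    pct_glx: float  # Q + E


def composition(proteins: Sequence, group_id: str = "group") -> CompositionProfile:
    """Composition over the concatenated length of the group."""
    if not proteins:
        raise ValueError("composition of an empty group is undefined")
    concat = "".join(proteins)
    n = len(concat)
    freq = {aa: 100.0 * concat.count(aa) / n for aa in AMINO_ACIDS}
    return CompositionProfile(
        group_id=group_id,
        freq=freq,
        pct_positive=freq["K"] + freq["R"],
        pct_glx=freq["Q"] + freq["E"],
    )


def net_charge(protein: str, pH: float, pka: dict | None = None) -> float:
    """Net Henderson-Hasselbalch charge of the full chain at a given pH."""
    pka = pka or EMBOSS_PKA
    pos = 10 ** pka["Nterm"] / (10 ** pka["Nterm"] + 10**pH)
    for aa in _POSITIVE:
        k = pka[aa]
        pos += protein.count(aa) * 10**k / (10**k + 10**pH)
    neg = 10**pH / (10 ** pka["Cterm"] + 10**pH)
    for aa in _NEGATIVE:
        k = pka[aa]
        neg += protein.count(aa) * 10**pH / (10**k + 10**pH)
    return pos - neg


def isoelectric_point(protein: str, pka: dict | None = None, tol: float = 1e-6) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Charge is strictly decreasing in pH, so bisection always converges; the
    interval is narrowed below ``tol`` pH units (charge curves can be nearly
    flat around the zero crossing, so convergence is on pH, not on charge).
    """
    bad = set(protein) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def drop_gap_columns(alignment: Sequence) -> list:
    """Complete deletion: remove every column containing a gap character."""
    lengths = {len(s) for s in alignment}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    keep = [i for i in range(lengths.pop()) if all(s[i] not in "-." for s in alignment)]
    return ["".join(s[i] for i in keep) for s in alignment]


def pairwise_differences(proteins: Sequence, complete_deletion: bool = True):
    """Pairwise difference counts and the number of variable columns.

    Sequences must be pre-aligned (equal length).  With complete deletion,
    gap-containing columns are dropped before counting.

    Returns ``(matrix, n_variable_sites)`` where matrix is a symmetric
    DataFrame of per-pair differing-site counts.
    """
    seqs = list(proteins)
    if complete_deletion:
        seqs = drop_gap_columns(seqs)
    n = len(seqs)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            mat[i, j] = mat[j, i] = d
    ncol = len(seqs[0]) if seqs else 0
    n_variable = sum(1 for i in range(ncol) if len({s[i] for s in seqs}) > 1)
    labels = [f"seq{i + 1}" for i in range(n)]
    return pd.DataFrame(mat, index=labels, columns=labels), n_variable


def logo_matrix(alignment: Sequence) -> pd.DataFrame:
    """Per-column residue frequencies of an alignment.

    Gaps are excluded from each column's denominator; all-gap columns are
    emitted as NA rows.  Rows are 1-based alignment positions, columns the 20
    amino acids.
    """
    seqs = list(alignment)
    if not seqs:
        return pd.DataFrame(columns=list(AMINO_ACIDS))
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    rows = []
    for i in range(len(seqs[0])):
        col = [s[i] for s in seqs if s[i] not in "-."]
        if not col:
            rows.append({aa: np.nan for aa in AMINO_ACIDS})
        else:
            rows.append({aa: col.count(aa) / len(col) for aa in AMINO_ACIDS})
    df = pd.DataFrame(rows, columns=list(AMINO_ACIDS))
    df.index = range(1, len(rows) + 1)
    return df


def write_logo_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="position")
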