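"""Diagnostic windows: fixed-length CDS segments that discriminate
near-identical paralogs for exact-match read counting.

Discrimination is defined by exact window identity (matching the downstream
100%-identity counting), never by edit distance.  Genes whose windows clash
are reported jointly, not silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

DEFAULT_WINDOW_LEN = 150


@dataclass(frozen=True)
class DiagnosticWindow:
    """One gene's window at a fixed CDS offset (1-based inclusive start)."""

    gene: str
    start: int
    length: int
    seq: str
    unique: bool
    clash_set: frozenset  # other genes sharing the identical window


def windows_at(family_cds: Dict[str, str], start: int, length: int = DEFAULT_WINDOW_LEN) -> List[DiagnosticWindow]:
    """Cut every gene's window at the same offset and compute clash sets."""
    if start < 1 or length < 1:
        raise ValueError("start and length must be >= 1")
    end = start + length - 1
    for g, cds in family_cds.items():
        if len(cds) < end:
            raise ValueError(f"{g}: CDS length {len(cds)} < window end {end}")
    cut = {g: cds[start - 1 : end] for g, cds in family_cds.items()}
    by_seq: Dict[str, list] = {}
    for g, w in cut.items():
        by_seq.setdefault(w, []).append(g)
    out = []
    for g, w in cut.items():
        others = frozenset(x for x in by_seq[w] if x != g)
        out.append(DiagnosticWindow(g, start, length, w, not others, others))
    return out


def n_discriminated(windows: List[DiagnosticWindow]) -> int:
    return sum(1 for w in windows if w.unique)


def best_offset(family_cds: Dict[str, str], length: int = DEFAULT_WINDOW_LEN) -> tuple:
    """Exhaustive search for the smallest offset maximising the number of
    genes uniquely discriminated by their window.

    Returns ``(start, n_discriminated)``; requires every CDS >= length.
    """
    min_len = min(len(c) for c in family_cds.values())
    if min_len < length:
        raise ValueError(f"shortest CDS ({min_len}) is below window length {length}")
    best = (1, -1)
    for start in range(1, min_len - length + 2):
        n = n_discriminated(windows_at(family_cds, start, length))
        if n > best[1]:
            best = (start, n)
    return best
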