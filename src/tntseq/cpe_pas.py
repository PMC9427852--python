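"""CPE and PAS cis-element detection in 3'-UTRs.

The cytoplasmic polyadenylation element (CPE, canonical UUUUAU / UUUUAAU)
and the polyadenylation signal (PAS, canonical AAUAAA / AUUAAA) jointly
license cytoplasmic polyadenylation and translational activation of
maternal mRNAs during oocyte maturation. A gene is called "paired" when at
least one CPE lies next to one or more PAS within a proximity window
(default 100 nucleotides), measured between the nearest ends of the two
elements (0 for overlapping elements), window-inclusive.

Element consensus strings are IUPAC patterns and fully configurable; the
shipped defaults follow the standard CPE/PAS literature definitions.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_CPE_PATTERNS = ("UUUUAU", "UUUUAAU")
DEFAULT_PAS_PATTERNS = ("AAUAAA", "AUUAAA")
DEFAULT_WINDOW = 100

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


def _normalise(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        expand = IUPAC[ch]
        parts.append(expand if len(expand) == 1 else f"[{expand}]")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_consensus(sequence: str, pattern: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) IUPAC matches."""
    if not pattern:
        raise ValueError("empty pattern")
    seq = _normalise(sequence)
    return [m.start() for m in _iupac_regex(pattern).finditer(seq)]


def scan_elements(sequence: str, patterns: Sequence[str]) -> list[tuple[int, int]]:
    """Merged, sorted (start, end) intervals of matches to any of the patterns."""
    ivs = []
    for pat in patterns:
        for start in scan_consensus(sequence, pat):
            ivs.append((start, start + len(pat)))
    return sorted(set(ivs))


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Distance between nearest ends of two half-open intervals; 0 if overlapping."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return b[0] - a[1] if a[1] <= b[0] else a[0] - b[1]


def pair_within(cpe_intervals: Iterable[tuple[int, int]],
                pas_intervals: Iterable[tuple[int, int]],
                window: int = DEFAULT_WINDOW
                ) -> tuple[bool, list[tuple[int, int, int]]]:
    """CPE-PAS pairs with nearest-end gap <= window (inclusive).

    Returns ``(paired, pairs)`` where each pair is
    ``(cpe_start, pas_start, gap)``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pairs = []
    for cpe in cpe_intervals:
        for pas in pas_intervals:
            g = _gap(tuple(cpe), tuple(pas))
            if g <= window:
                pairs.append((cpe[0], pas[0], g))
    return bool(pairs), pairs


def annotate_gene_set(utrs: Mapping[str, str],
                      cpe_patterns: Sequence[str] = DEFAULT_CPE_PATTERNS,
                      pas_patterns: Sequence[str] = DEFAULT_PAS_PATTERNS,
                      window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-gene CPE/PAS counts, positions and pairing status.

    Genes with a missing or empty UTR sequence are skipped and logged.
    Positions are 0-based element starts; ``pair_gaps`` lists the
    nearest-end gaps of all pairs within the window.
    """
    if not cpe_patterns or not pas_patterns:
        raise ValueError("pattern lists must be non-empty")
    rows = []
    skipped = 0
    for gid, seq in utrs.items():
        if not seq:
            skipped += 1
            continue
        cpe = scan_elements(seq, cpe_patterns)
        pas = scan_elements(seq, pas_patterns)
        paired, pairs = pair_within(cpe, pas, window)
        rows.append({
            "gene_id": gid,
            "n_cpe": len(cpe),
            "n_pas": len(pas),
            "paired": paired,
            "cpe_positions": ";".join(str(s) for s, _ in cpe),
            "pas_positions": ";".join(str(s) for s, _ in pas),
            "pair_gaps": ";".join(str(g) for _, _, g in pairs),
        })
    if skipped:
        log.info("skipped %d gene(s) with missing UTR sequence", skipped)
    return pd.DataFrame(rows, columns=["gene_id", "n_cpe", "n_pas", "paired",
                                       "cpe_positions", "pas_positions",
                                       "pair_gaps"]).set_index("gene_id")
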