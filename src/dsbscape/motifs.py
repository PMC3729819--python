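"""Exhaustive no-mismatch genomic search for degenerate gapped consensus motifs.

The default pattern is the yeast Gal4 DNA-binding-domain recognition
sequence CGG-N11-CCG (17 bp). The pattern is its own reverse complement,
so a forward-strand scan is strand-complete and each genomic occurrence
is reported once as an interval.

Matching semantics: a pattern ``N`` matches A/C/G/T in the genome but not
an ambiguous/unsequenced genome ``N``; fixed pattern positions never match
genome ``N`` either. Lowercase (soft-masked) genome sequence is treated as
sequence. Overlapping occurrences are all reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

GAL4_PATTERN = "CGG" + "N" * 11 + "CCG"


def expand_pattern(pattern: str) -> str:
    """Expand run-length syntax like ``CGGN{11}CCG`` into plain IUPAC."""
    def repl(m: re.Match) -> str:
        return m.group(1) * int(m.group(2))
    return re.sub(r"([A-Za-z])\{(\d+)\}", repl, pattern)


@dataclass(frozen=True)
class ConsensusPattern:
    """An IUPAC consensus, e.g. the 17-bp Gal4 site CGGN11CCG."""

    pattern: str = GAL4_PATTERN
    name: str = "Gal4"
    _regex: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        pat = expand_pattern(self.pattern).upper()
        if len(pat) < 1:
            raise ValidationError("pattern must be non-empty")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValidationError(f"invalid IUPAC symbols in pattern: {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)
        # lookahead regex reports overlapping occurrences
        body = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pat)
        object.__setattr__(self, "_regex", re.compile(f"(?=({body}))"))

    def __len__(self) -> int:
        return len(self.pattern)


def reverse_complement(sequence: str) -> str:
    """Standard IUPAC reverse complement; an involution."""
    bad = set(sequence.upper()) - set(IUPAC)
    if bad:
        raise ValidationError(f"non-IUPAC characters: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


def scan_sequence(sequence: str, pattern: ConsensusPattern) -> np.ndarray:
    """Start positions of every exact (no-mismatch) occurrence in one sequence."""
    seq = sequence.upper()
    return np.fromiter(
        (m.start() for m in pattern._regex.finditer(seq)), dtype=np.int64
    )


def scan_consensus(
    genome: dict[str, str], pattern: ConsensusPattern | str | None = None
) -> pd.DataFrame:
    """Exhaustive forward-strand scan of a genome for a consensus pattern.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence string.
    pattern
        ConsensusPattern or IUPAC string; defaults to the Gal4 consensus.

    Returns
    -------
    DataFrame with columns chrom, start, end, name, sorted by
    (chrom, start). Each occurrence appears once as a genomic interval;
    for palindromic patterns such as the Gal4 consensus this is also the
    complete double-stranded site universe.
    """
    if pattern is None:
        pattern = ConsensusPattern()
    elif isinstance(pattern, str):
        pattern = ConsensusPattern(pattern=pattern, name=pattern)
    rows = []
    for chrom in sorted(genome):
        starts = scan_sequence(genome[chrom], pattern)
        if starts.size:
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "start": starts,
                "end": starts + len(pattern),
                "name": pattern.name,
            }))
    if not rows:
        return pd.DataFrame({"chrom": [], "start": [], "end": [], "name": []})
    return pd.concat(rows, ignore_index=True)


def expected_match_count(
    genome_length: int,
    pattern: ConsensusPattern | None = None,
    base_probs: dict[str, float] | None = None,
) -> float:
    """Expected occurrence count under an i.i.d. base-composition null.

    Sums, over the ``genome_length - len + 1`` alignments, the product of
    per-position probabilities that the genome base is one the pattern
    symbol allows. With uniform bases the Gal4 consensus has per-alignment
    probability (1/4)^6, i.e. one expected hit per 4,096 bp.
    """
    if pattern is None:
        pattern = ConsensusPattern()
    if base_probs is None:
        base_probs = {b: 0.25 for b in "ACGT"}
    tot = sum(base_probs.values())
    if not np.isclose(tot, 1.0) or any(p < 0 for p in base_probs.values()):
        raise ValidationError("base probabilities must be non-negative and sum to 1")
    n_align = genome_length - len(pattern) + 1
    if n_align <= 0:
        return 0.0
    p = 1.0
    for sym in pattern.pattern:
        p *= sum(base_probs.get(b, 0.0) for b in IUPAC[sym])
    return n_align * p
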