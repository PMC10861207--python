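"""Naive reference implementations for cross-validation.

These deliberately share no code with the production paths: the motif
oracle tests every window against the motif's concrete expansion instead
of using the regex scanner.  They are slow and exist only so tests and
validation scripts can compare two independent routes to the same
answer.
"""

from __future__ import annotations

from .regulatory import SKN1_MOTIFS

_RC = str.maketrans("ACGT", "TGCA")


def brute_force_scan(seq: str, motifs=SKN1_MOTIFS, both_strands: bool = True):
    """All motif occurrences by window-by-window expansion membership.

    Returns sorted (start, strand, pattern) tuples on the same
    coordinate convention as :func:`nemaspan.regulatory.scan_motifs`.
    """
    found = []
    for motif in motifs:
        k = len(motif.pattern)
        words = motif.expansion
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if window in words:
                found.append((i, "+", motif.pattern))
            if both_strands and window.translate(_RC)[::-1] in words:
                found.append((i, "-", motif.pattern))
    return sorted(found)
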