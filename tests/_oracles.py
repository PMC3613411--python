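"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive expected values by the dumbest correct
method available (O(nm) dynamic programming in pure Python, direct codon
table lookups, column-by-column tallies) so they share no code with the
implementation paths they check.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def gotoh_glocal_score(ref: str, window: str,
                       match: float = 1.0, mismatch: float = -1.0,
                       gap_open: float = -4.0,
                       gap_extend: float = -1.0) -> float:
    """Affine-gap global alignment score of ``ref`` against ``window``
    with free end gaps on the window side (pure-Python Gotoh).

    ``gap_open`` is the cost of the first base of a gap, ``gap_extend``
    of each additional base.
    """
    m, n = len(ref), len(window)
    # M: ends in aligned pair; X: ends with ref base unaligned (gap in
    # window row); Y: ends with window base unaligned (gap in ref row).
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, n + 1):
        Y[0][j] = 0.0  # leading window overhang is free
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if ref[i - 1] == window[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open,
                          X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open,
                          Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    # trailing window overhang is free: best over last row, any j
    best = NEG_INF
    for j in range(n + 1):
        best = max(best, M[m][j], X[m][j])
    if m == 0:
        best = 0.0
    return best


#: Independent codon table (IUPAC standard code, table 1), written out by
#: amino acid rather than by codon so a transcription error in one table
#: is unlikely to be mirrored in the other.
_BY_AA = {
    "F": ["TTT", "TTC"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"],
    "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"],
    "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "*": ["TAA", "TAG", "TGA"],
}
CODON_TO_AA = {codon: aa for aa, codons in _BY_AA.items() for codon in codons}


def translate_oracle(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        out.append(CODON_TO_AA.get(cds[i : i + 3].upper(), "X"))
    return "".join(out)


def stop_scan_oracle(cds: str) -> list[int]:
    """0-based codon indices of in-frame stops, excluding the last codon."""
    stops = []
    for ci in range(len(cds) // 3 - 1):
        if CODON_TO_AA.get(cds[3 * ci : 3 * ci + 3]) == "*":
            stops.append(ci)
    return stops


def unique_substitution_tally(sa: str, sb: str, so: str) -> tuple[int, int]:
    """Position-by-position unique-substitution tally (complete cases)."""
    n_a = n_b = 0
    for ra, rb, ro in zip(sa, sb, so):
        if any(c in "-X" for c in (ra, rb, ro)):
            continue
        if ra != rb and rb == ro:
            n_a += 1
        if rb != ra and ra == ro:
            n_b += 1
    return n_a, n_b
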