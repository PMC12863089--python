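"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the local-alignment
oracle is a plain-Python Gotoh dynamic program over Biopython's BLOSUM62
(the package aligner runs through biotite), and the colocalization oracle
is exhaustive pairwise enumeration.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def blosum62(a: str, b: str) -> float:
    return float(_BLOSUM62[a][b])


def gotoh_local(
    query: str,
    subject: str,
    gap_open: int = 11,
    gap_extend: int = 1,
):
    """Affine-gap Smith–Waterman; a gap of length k costs open + k*extend.

    Returns (score, qstart, qend, sstart, send, identities, length) of one
    optimal local alignment (1-based inclusive coordinates), or
    (0, ...) zeros when no alignment has positive score.
    """
    n, m = len(query), len(subject)
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes subject)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in subject (consumes query)
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - first)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - first)
            diag = H[i - 1][j - 1] + blosum62(query[i - 1], subject[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best_pos is None:
        return 0.0, 0, 0, 0, 0, 0, 0

    # traceback one optimal path (diagonal preferred, then E, then F)
    i, j = best_pos
    identities = length = 0
    state = "H"
    qend, send = i, j
    while i > 0 and j > 0 and not (state == "H" and H[i][j] == 0.0):
        if state == "H":
            diag = H[i - 1][j - 1] + blosum62(query[i - 1], subject[j - 1])
            if H[i][j] == diag:
                identities += query[i - 1] == subject[j - 1]
                length += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            length += 1
            if E[i][j] == H[i][j - 1] - first:
                state = "H"
            j -= 1
        else:
            length += 1
            if F[i][j] == H[i - 1][j] - first:
                state = "H"
            i -= 1
    return best, i + 1, qend, j + 1, send, identities, length


def nearest_by_enumeration(phaE_end: int, candidates):
    """argmin over |start - phaE_end| with (distance, start, gene_id) ties."""
    return min(candidates, key=lambda c: (abs(c.start - phaE_end), c.start, c.gene_id))
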