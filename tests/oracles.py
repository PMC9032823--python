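"""Independent brute-force oracles used by the test suite.

These are deliberately naive pure-Python implementations, written before
and independently of the package's alignment path, so agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import itertools

# BLOSUM62, copied from the NCBI matrix (upper triangle spelled out in full
# via symmetry at load time)
_BLOSUM62_TEXT = """
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  X
A  4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0  0
R -1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3 -1
N -2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3 -1
D -2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3 -1
C  0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1 -2
Q -1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2 -1
E -1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2 -1
G  0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3 -1
H -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3 -1
I -1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3 -1
L -1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1 -1
K -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2 -1
M -1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1 -1
F -2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1 -1
P -1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2 -2
S  1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2  0
T  0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0  0
W -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3 -2
Y -2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1 -1
V  0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4 -1
X  0 -1 -1 -1 -2 -1 -1 -1 -1 -1 -1 -1 -1 -1 -2  0  0 -2 -1 -1 -1
"""


def _parse_blosum62() -> dict[tuple[str, str], int]:
    lines = [ln for ln in _BLOSUM62_TEXT.strip().splitlines()]
    header = lines[0].split()
    matrix: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        row = parts[0]
        for col, val in zip(header, parts[1:]):
            matrix[(row, col)] = int(val)
    return matrix


BLOSUM62 = _parse_blosum62()


def sw_affine_score(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], int] = BLOSUM62,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Naive O(nm) Gotoh local alignment score.

    A gap of length g costs gap_open + g*gap_extend (BLAST convention).
    Returns the best local score (0 if no positive-scoring cell exists).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion from a)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend
            )
            F[i][j] = max(
                F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend
            )
            sub = H[i - 1][j - 1] + matrix[(a[i - 1], b[j - 1])]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def exhaustive_pan_core(family_members: list[set[str]], subset: set[str]) -> tuple[int, int]:
    """Pan and core family counts for one genome subset, by direct scan."""
    pan = sum(1 for mem in family_members if mem & subset)
    core = sum(1 for mem in family_members if subset <= mem)
    return pan, core


def exhaustive_medians(
    family_members: list[set[str]], genomes: list[str], n: int
) -> tuple[float, float]:
    """Median pan/core over all C(G, n) subsets, via brute enumeration."""
    pans, cores = [], []
    for combo in itertools.combinations(genomes, n):
        p, c = exhaustive_pan_core(family_members, set(combo))
        pans.append(p)
        cores.append(c)

    def med(vals: list[int]) -> float:
        vals = sorted(vals)
        k = len(vals)
        if k % 2:
            return float(vals[k // 2])
        return (vals[k // 2 - 1] + vals[k // 2]) / 2.0

    return med(pans), med(cores)
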