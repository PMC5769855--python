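"""Linear algebra over GF(2) with integer-bitmask columns.

A matrix is a list of columns; each column is a Python ``int`` whose set
bits are the row indices of the nonzero entries.  This representation keeps
boundary-matrix ranks and membership tests exact and fast at the problem
sizes this package targets (tens to a few thousand simplices).
"""

from __future__ import annotations


def rank(columns: list[int]) -> int:
    """Rank of a GF(2) matrix given as bitmask columns."""
    pivots: dict[int, int] = {}  # pivot row -> reduced column
    r = 0
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                pivots[low] = col
                r += 1
                break
    return r


def in_span(columns: list[int], target: int) -> bool:
    """Whether ``target`` lies in the column span of the matrix."""
    pivots: dict[int, int] = {}
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                pivots[low] = col
                break
    while target:
        low = target.bit_length() - 1
        if low in pivots:
            target ^= pivots[low]
        else:
            return False
    return True


def solve_affine(columns: list[int], target: int) -> tuple[int | None, list[int]]:
    """Solve ``M x = target`` over GF(2).

    Returns ``(particular, kernel_basis)`` where both the particular
    solution and each kernel basis vector are bitmasks over column indices.
    ``particular`` is None when the system is inconsistent.  The kernel
    basis spans all homogeneous solutions, so the full solution set is
    ``particular ^ (any XOR-combination of kernel basis vectors)``.
    """
    pivots: dict[int, tuple[int, int]] = {}  # pivot row -> (reduced col, combo mask)
    kernel: list[int] = []
    for j, col in enumerate(columns):
        combo = 1 << j
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                pcol, pcombo = pivots[low]
                col ^= pcol
                combo ^= pcombo
            else:
                pivots[low] = (col, combo)
                break
        if col == 0:
            kernel.append(combo)
    combo = 0
    while target:
        low = target.bit_length() - 1
        if low in pivots:
            pcol, pcombo = pivots[low]
            target ^= pcol
            combo ^= pcombo
        else:
            return None, kernel
    return combo, kernel
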