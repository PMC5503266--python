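"""Exact rational linear solvers used by the fixation-probability engines.

Two routes, both returning certified exact solutions:

* :func:`solve_sparse` — fraction-preserving Gaussian elimination on a
  sparse row representation (dict-of-columns).  No pivot search is needed
  for the absorbing-chain systems we feed it (they are M-matrices, so the
  diagonal pivots are provably nonzero), but a zero pivot triggers a
  partial-pivoting fallback on numerator/denominator bit length.

* :func:`solve_dixon` — Dixon p-adic lifting: LU factorisation modulo a
  word-sized prime (vectorised with numpy), iterative lifting of the
  solution digits, rational reconstruction, and a final *exact*
  verification of ``A x = b``.  Orders of magnitude faster than direct
  elimination once the system has more than a few hundred unknowns,
  because the expensive O(n^3) work happens over machine integers.

Scalars are elements of sympy's ``QQ`` domain (gmpy-backed where
available).  Rows are ``dict[int, QQ]``; the right-hand side a list.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from sympy.polys.domains import QQ

__all__ = ["QQ", "SingularMatrixError", "solve_sparse", "solve_dixon", "solve_exact"]

_ZERO = QQ(0)
_ONE = QQ(1)

# Primes just below 2^20: pivot products stay well inside int64 during the
# modular elimination (p^2 < 2^40, row dots < 2^40 * n).
_PRIMES = (1048573, 1048571, 1048559, 1048549, 1048517, 1048507)


class SingularMatrixError(ValueError):
    """The coefficient matrix is (exactly) singular."""


def _bitlen(q) -> int:
    return q.numerator.bit_length() + q.denominator.bit_length()


def solve_sparse(rows: Sequence[dict], b: Sequence, pivoting: bool = False):
    """Solve ``A x = b`` exactly, A given as sparse rows of QQ entries.

    Eliminates in index order; for popcount-ordered absorbing-chain systems
    this confines fill-in to the natural layer band.  ``pivoting`` selects
    partial pivoting by minimal bit length (only needed for general
    matrices; absorbing-chain systems have a safe diagonal).
    """
    n = len(rows)
    rows = [dict(r) for r in rows]
    b = list(b)
    order = list(range(n))  # row permutation (identity unless pivoting kicks in)

    for i in range(n):
        ri = order[i]
        if pivoting or not rows[ri].get(i):
            cand = [order[j] for j in range(i, n) if rows[order[j]].get(i)]
            if not cand:
                raise SingularMatrixError(f"no pivot in column {i}")
            best = min(cand, key=lambda rj: _bitlen(rows[rj][i]))
            j = order.index(best)
            order[i], order[j] = order[j], order[i]
            ri = order[i]
        row = rows[ri]
        piv = row[i]
        inv = _ONE / piv
        for k in list(row):
            if k > i:
                row[k] *= inv
        b[ri] *= inv
        row[i] = _ONE
        for j in range(i + 1, n):
            rj = rows[order[j]]
            f = rj.pop(i, None)
            if f:
                for k, val in row.items():
                    if k > i:
                        cur = rj.get(k)
                        rj[k] = (cur - f * val) if cur is not None else -f * val
                b[order[j]] -= f * b[ri]
    x = [_ZERO] * n
    for i in range(n - 1, -1, -1):
        ri = order[i]
        acc = b[ri]
        for k, val in rows[ri].items():
            if k > i:
                acc -= val * x[k]
        x[i] = acc
    return x


# ---------------------------------------------------------------------------
# Dixon lifting
# ---------------------------------------------------------------------------


def _to_integer_rows(rows, b):
    """Clear denominators row-wise; returns integer rows, integer rhs."""
    int_rows, int_b = [], []
    for r, bi in zip(rows, b):
        dens = [int(v.denominator) for v in r.values()]
        dens.append(int(bi.denominator))
        lcm = 1
        for d in dens:
            lcm = lcm * d // math.gcd(lcm, d)
        int_rows.append({k: int(v.numerator) * (lcm // int(v.denominator)) for k, v in r.items()})
        int_b.append(int(bi.numerator) * (lcm // int(bi.denominator)))
    return int_rows, int_b


def _lu_mod_p(rows_int, n, p):
    """Dense LU (with partial pivoting by row swap) of A mod p.

    Returns (lu, perm) with L below the unit diagonal and U on/above, or
    raises SingularMatrixError if A is singular modulo p.
    """
    A = np.zeros((n, n), dtype=np.int64)
    for i, r in enumerate(rows_int):
        for j, v in r.items():
            A[i, j] = v % p
    perm = np.arange(n)
    for k in range(n):
        if A[k, k] == 0:
            nz = np.nonzero(A[k:, k])[0]
            if nz.size == 0:
                raise SingularMatrixError(f"singular modulo {p} at column {k}")
            j = k + int(nz[0])
            A[[k, j]] = A[[j, k]]
            perm[[k, j]] = perm[[j, k]]
        inv = pow(int(A[k, k]), -1, p)
        A[k + 1:, k] = A[k + 1:, k] * inv % p
        if k + 1 < n:
            A[k + 1:, k + 1:] = (A[k + 1:, k + 1:] - np.outer(A[k + 1:, k], A[k, k + 1:])) % p
    return A, perm


def _lu_solve_mod_p(lu, perm, rhs, p):
    n = lu.shape[0]
    y = rhs[perm].copy()
    for i in range(1, n):
        y[i] = (y[i] - int(lu[i, :i] @ y[:i])) % p
    x = y
    for i in range(n - 1, -1, -1):
        if i + 1 < n:
            x[i] = (x[i] - int(lu[i, i + 1:] @ x[i + 1:])) % p
        x[i] = x[i] * pow(int(lu[i, i]), -1, p) % p
    return x


def _rational_reconstruct(u: int, m: int):
    """Standard EEA-based reconstruction of x = r/t with |r|, |t| <= sqrt(m/2)."""
    bound = math.isqrt(m // 2)
    r0, r1 = m, u % m
    t0, t1 = 0, 1
    while r1 > bound:
        q = r0 // r1
        r0, r1 = r1, r0 - q * r1
        t0, t1 = t1, t0 - q * t1
    if abs(t1) > bound or t1 == 0 or math.gcd(r1, t1) != 1:
        return None
    return (r1, t1) if t1 > 0 else (-r1, -t1)


def solve_dixon(rows: Sequence[dict], b: Sequence, max_iters: int = 100000):
    """Solve ``A x = b`` exactly by p-adic lifting with exact verification."""
    n = len(rows)
    rows_int, b_int = _to_integer_rows(rows, b)
    lu = perm = None
    for p in _PRIMES:
        try:
            lu, perm = _lu_mod_p(rows_int, n, p)
            break
        except SingularMatrixError:
            continue
    else:
        raise SingularMatrixError("matrix singular modulo all trial primes (likely exactly singular)")

    sparse_items = [list(r.items()) for r in rows_int]
    residual = list(b_int)
    digits = []
    pk = 1  # p^(number of digits)
    next_check = 8
    while len(digits) < max_iters:
        rp = np.array([ri % p for ri in residual], dtype=np.int64)
        y = _lu_solve_mod_p(lu, perm, rp, p)
        digits.append(y)
        yl = [int(v) for v in y]
        residual = [
            (residual[i] - sum(a * yl[j] for j, a in sparse_items[i])) // p
            for i in range(n)
        ]
        pk *= p
        if len(digits) >= next_check or all(ri == 0 for ri in residual):
            x_mod = _digits_to_int(digits, p)
            sol = []
            for i in range(n):
                rec = _rational_reconstruct(x_mod[i], pk)
                if rec is None:
                    sol = None
                    break
                sol.append(QQ(rec[0], rec[1]))
            if sol is not None and _verify(rows, b, sol):
                return sol
            next_check *= 2
    raise SingularMatrixError("Dixon lifting failed to converge")


def _digits_to_int(digits, p):
    n = len(digits[0])
    out = [0] * n
    for d in reversed(digits):
        for i in range(n):
            out[i] = out[i] * p + int(d[i])
    return out


def _verify(rows, b, x) -> bool:
    for r, bi in zip(rows, b):
        acc = _ZERO
        for j, a in r.items():
            acc += a * x[j]
        if acc != bi:
            return False
    return True


def solve_exact(rows: Sequence[dict], b: Sequence, pivoting: bool = False):
    """Dispatch: direct elimination for small systems, Dixon lifting for large."""
    if len(rows) <= 150:
        return solve_sparse(rows, b, pivoting=pivoting)
    return solve_dixon(rows, b)
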