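"""Thomas-algorithm tridiagonal solvers.

The implicit diffusion sweeps reduce to many tridiagonal systems per mesh
strip.  All systems along one axis share the same matrix, so the forward
elimination coefficients are factored once and reused across strips
(`TridiagonalOperator`).  A general single-system solver is kept for
arbitrary matrices.
"""

from __future__ import annotations

import numpy as np

__all__ = ["thomas_solve", "TridiagonalOperator", "ZeroPivotError"]


class ZeroPivotError(ZeroDivisionError):
    """Raised when forward elimination encounters a zero pivot."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"zero pivot at row {index} during Thomas elimination")


def thomas_solve(sub_diag, diag, super_diag, rhs):
    """Solve a single tridiagonal system A x = rhs.

    Parameters
    ----------
    sub_diag : array_like, shape (n,)
        Sub-diagonal; entry 0 is ignored.
    diag : array_like, shape (n,)
        Main diagonal.
    super_diag : array_like, shape (n,)
        Super-diagonal; entry n-1 is ignored.
    rhs : array_like, shape (n,)
        Right-hand side.

    Returns
    -------
    ndarray, shape (n,)
        The solution vector.  Input arrays are left untouched so they can
        be reused across strips.
    """
    a = np.asarray(sub_diag, dtype=float)
    b = np.asarray(diag, dtype=float)
    c = np.asarray(super_diag, dtype=float)
    r = np.asarray(rhs, dtype=float)
    n = b.shape[0]
    if not (a.shape[0] == c.shape[0] == r.shape[0] == n):
        raise ValueError("sub_diag, diag, super_diag and rhs must share length")

    cp = np.empty(n)
    rp = np.empty(n)
    if b[0] == 0.0:
        raise ZeroPivotError(0)
    cp[0] = c[0] / b[0]
    rp[0] = r[0] / b[0]
    for i in range(1, n):
        denom = b[i] - a[i] * cp[i - 1]
        if denom == 0.0:
            raise ZeroPivotError(i)
        cp[i] = c[i] / denom
        rp[i] = (r[i] - a[i] * rp[i - 1]) / denom

    x = np.empty(n)
    x[-1] = rp[-1]
    for i in range(n - 2, -1, -1):
        x[i] = rp[i] - cp[i] * x[i + 1]
    return x


class TridiagonalOperator:
    """Pre-factored constant-coefficient tridiagonal solve, batched over strips.

    Represents the matrix with sub/super diagonal ``-a`` and main diagonal
    ``1 + 2a`` in the interior, ``1 + a`` at both ends (backward-Euler
    diffusion with zero-flux finite-volume boundaries), where
    ``a = D * dt / dx**2``.  ``solve`` acts on the *last* axis of an
    arbitrary-shaped right-hand side.
    """

    def __init__(self, n: int, a: float):
        if n < 1:
            raise ValueError("system size must be >= 1")
        if a < 0:
            raise ValueError("diffusion coefficient a must be >= 0")
        self.n = n
        self.a = a
        diag = np.full(n, 1.0 + 2.0 * a)
        if n >= 1:
            diag[0] = 1.0 + a
            diag[-1] = 1.0 + a
        if n == 1:
            diag[0] = 1.0
        # forward elimination factors, shared by every strip
        self._cp = np.empty(n)
        self._denom = np.empty(n)
        self._denom[0] = diag[0]
        self._cp[0] = -a / diag[0]
        for i in range(1, n):
            self._denom[i] = diag[i] - (-a) * self._cp[i - 1]
            self._cp[i] = -a / self._denom[i]
        if np.any(self._denom == 0.0):
            raise ZeroPivotError(int(np.argmax(self._denom == 0.0)))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve along the last axis of ``rhs`` (any leading batch shape)."""
        r = np.asarray(rhs, dtype=float)
        n = self.n
        if r.shape[-1] != n:
            raise ValueError("last axis of rhs must match system size")
        a = self.a
        x = np.empty_like(r)
        x[..., 0] = r[..., 0] / self._denom[0]
        for i in range(1, n):
            x[..., i] = (r[..., i] + a * x[..., i - 1]) / self._denom[i]
        for i in range(n - 2, -1, -1):
            x[..., i] -= self._cp[i] * x[..., i + 1]
        return x

    def dense(self) -> np.ndarray:
        """Dense matrix form (for oracle comparisons in tests)."""
        n, a = self.n, self.a
        m = np.zeros((n, n))
        for i in range(n):
            m[i, i] = 1.0 + 2.0 * a
            if i > 0:
                m[i, i - 1] = -a
            if i < n - 1:
                m[i, i + 1] = -a
        m[0, 0] = 1.0 + a
        m[-1, -1] = 1.0 + a
        if n == 1:
            m[0, 0] = 1.0
        return m
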