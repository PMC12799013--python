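"""Tensor algebra and proximal operators.

Third-order tensors are handled in the t-product framework: a tensor
``X`` of shape ``(n, p, t)`` is multiplied, decomposed and thresholded
slice-wise in the discrete Fourier domain along its third mode.  For the
dual-network case ``t = 2`` the transform is particularly transparent:
the two transform slices of ``W = [W1, W2]`` are ``W1 + W2`` and
``W1 - W2``.

The proximal operators here are the building blocks of the ADMM solver
in :mod:`stacn.denoise`:

* :func:`matrix_svt` — singular value thresholding, the proximal map of
  the nuclear norm;
* :func:`tensor_schatten_prox` — proximal map of the tensor Schatten
  p-norm (p = 1 reduces to slice-wise SVT in the transform domain);
* :func:`row_l21_prox` — proximal map of the l2,1 norm, inducing
  row- or column-structured sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkTensor",
    "TSVDFactors",
    "t_product",
    "t_transpose",
    "t_identity",
    "t_svd",
    "tensor_schatten_norm",
    "tensor_schatten_prox",
    "matrix_svt",
    "row_l21_prox",
    "schatten_scalar_prox",
]


@dataclass
class NetworkTensor:
    """Stack of the two learned cell networks, expression first.

    ``slices[0]`` is the expression network ``W_e`` and ``slices[1]``
    the spatial network ``W_s``; both are real ``n x n`` matrices.
    """

    slices: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        a, b = self.slices
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("network slices must be square matrices")
        if a.shape != b.shape:
            raise ValueError(
                f"slice shapes differ: {a.shape} vs {b.shape}"
            )

    @property
    def n(self) -> int:
        return self.slices[0].shape[0]

    def to_array(self) -> np.ndarray:
        """Return the ``(n, n, 2)`` ndarray with frontal slices stacked."""
        return np.stack(self.slices, axis=2)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "NetworkTensor":
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("expected an (n, n, 2) array")
        return cls((np.ascontiguousarray(arr[:, :, 0]), np.ascontiguousarray(arr[:, :, 1])))


@dataclass
class TSVDFactors:
    """Truncated t-SVD factors ``W ~= U * S * V^T`` (t-product).

    ``U`` is ``n x d x t``, ``S`` is ``d x d x t`` and f-diagonal in the
    transform domain with nonincreasing nonnegative diagonal, ``V`` is
    ``m x d x t``.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return t_product(t_product(self.U, self.S), t_transpose(self.V))

    def transform_singular_values(self) -> np.ndarray:
        """Singular values per transform slice, shape ``(t, d)``."""
        Sf = np.fft.fft(self.S, axis=2)
        d = self.S.shape[0]
        return np.stack([Sf[:, :, i].diagonal().real for i in range(self.S.shape[2])])


def _as_tensor(x) -> np.ndarray:
    if isinstance(x, NetworkTensor):
        return x.to_array()
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a 3-way tensor")
    return arr


def t_product(Xt: np.ndarray, Yt: np.ndarray) -> np.ndarray:
    """t-product of ``(n, p, t)`` and ``(p, q, t)`` tensors.

    Computed as slice-wise matrix products in the DFT domain along the
    third mode, equivalent to the block-circulant matrix product.
    """
    Xt = _as_tensor(Xt)
    Yt = _as_tensor(Yt)
    if Xt.shape[1] != Yt.shape[0] or Xt.shape[2] != Yt.shape[2]:
        raise ValueError(
            f"t_product dimension mismatch: {Xt.shape} * {Yt.shape}"
        )
    Xf = np.fft.fft(Xt, axis=2)
    Yf = np.fft.fft(Yt, axis=2)
    Zf = np.einsum("ijk,jlk->ilk", Xf, Yf)
    return np.real(np.fft.ifft(Zf, axis=2))


def t_transpose(Xt: np.ndarray) -> np.ndarray:
    """Tensor transpose: transpose each frontal slice and reverse slices 2..t."""
    Xt = _as_tensor(Xt)
    out = np.empty((Xt.shape[1], Xt.shape[0], Xt.shape[2]))
    out[:, :, 0] = Xt[:, :, 0].T
    for i in range(1, Xt.shape[2]):
        out[:, :, i] = Xt[:, :, Xt.shape[2] - i].T
    return out


def t_identity(n: int, t: int = 2) -> np.ndarray:
    """Identity tensor: identity matrix in slice 1, zeros elsewhere."""
    out = np.zeros((n, n, t))
    out[:, :, 0] = np.eye(n)
    return out


def _fft_slices_svd(Wf: np.ndarray, d: int):
    """SVD of every transform slice, exploiting conjugate symmetry.

    Returns complex arrays ``Uf (n,d,t)``, ``sf (t,d)``, ``Vf (m,d,t)``
    with conjugate-symmetric slices so the inverse FFT is real.
    """
    n, m, t = Wf.shape
    Uf = np.empty((n, d, t), dtype=complex)
    sf = np.empty((t, d))
    Vf = np.empty((m, d, t), dtype=complex)
    half = t // 2 + 1
    for i in range(half):
        U, s, Vh = np.linalg.svd(Wf[:, :, i], full_matrices=False)
        Uf[:, :, i] = U[:, :d]
        sf[i] = s[:d]
        Vf[:, :, i] = Vh[:d].conj().T
        j = (t - i) % t
        if j != i:
            Uf[:, :, j] = Uf[:, :, i].conj()
            sf[j] = sf[i]
            Vf[:, :, j] = Vf[:, :, i].conj()
    return Uf, sf, Vf


def t_svd(W, d: int | None = None) -> TSVDFactors:
    """Truncated t-SVD ``W = U * S * V^T`` via slice-wise SVD in the DFT domain.

    For third-mode length 2 the transform slices are ``W1 + W2`` and
    ``W1 - W2``, so both slice SVDs are real.
    """
    Wt = _as_tensor(W)
    n, m, t = Wt.shape
    if d is None:
        d = min(n, m)
    if d > min(n, m):
        raise ValueError(f"d={d} exceeds min matrix dimension {min(n, m)}")
    Wf = np.fft.fft(Wt, axis=2)
    Uf, sf, Vf = _fft_slices_svd(Wf, d)
    Sf = np.zeros((d, d, t), dtype=complex)
    for i in range(t):
        np.fill_diagonal(Sf[:, :, i], sf[i])
    U = np.real(np.fft.ifft(Uf, axis=2))
    S = np.real(np.fft.ifft(Sf, axis=2))
    V = np.real(np.fft.ifft(Vf, axis=2))
    return TSVDFactors(U=U, S=S, V=V)


def matrix_svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: minimizer of ``tau*||Z||_* + 0.5*||Z - M||_F^2``."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau == 0:
        return np.array(M, dtype=float, copy=True)
    U, s, Vh = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vh[keep]


def schatten_scalar_prox(sigma: np.ndarray, tau: float, p: float) -> np.ndarray:
    """Scalar proximal map ``argmin_x tau*x^p + 0.5*(x - sigma)^2`` for x >= 0.

    For p = 1 this is soft thresholding.  For 0 < p < 1 the generalized
    soft-thresholding rule applies: values at or below the critical
    threshold map to zero, larger values are refined by fixed-point /
    Newton iteration on ``x = sigma - tau*p*x^(p-1)`` to 1e-10.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    sigma = np.asarray(sigma, dtype=float)
    if tau == 0:
        return sigma.copy()
    if p == 1:
        return np.maximum(sigma - tau, 0.0)
    # critical point of the GST rule
    tau_star = (2 * tau * (1 - p)) ** (1 / (2 - p)) + tau * p * (
        2 * tau * (1 - p)
    ) ** ((p - 1) / (2 - p))
    out = np.zeros_like(sigma)
    mask = sigma > tau_star
    x = sigma[mask].copy()
    s = sigma[mask]
    for _ in range(200):
        x_new = s - tau * p * np.power(x, p - 1)
        # Newton step on f(x) = x + tau*p*x^(p-1) - sigma for stability
        f = x_new + tau * p * np.power(x_new, p - 1) - s
        fp = 1 + tau * p * (p - 1) * np.power(x_new, p - 2)
        step = np.where(fp > 1e-12, f / np.where(fp == 0, 1.0, fp), 0.0)
        x_next = np.maximum(x_new - step, 1e-15)
        if np.all(np.abs(x_next - x) < 1e-12):
            x = x_next
            break
        x = x_next
    out[mask] = x
    return out


def tensor_schatten_norm(W, p: float = 1.0) -> float:
    """Tensor Schatten p-norm cost ``(1/t) * sum_i sum_k sigma_k(What_i)^p``.

    Summed over all singular values of every transform-domain slice; for
    p = 1 this is the standard tensor nuclear norm.  The 1/t factor makes
    the norm consistent with the Frobenius inner product under the
    unnormalized DFT (Parseval), so :func:`tensor_schatten_prox` with
    threshold ``tau`` is exactly its proximal map.
    """
    Wt = _as_tensor(W)
    Wf = np.fft.fft(Wt, axis=2)
    total = 0.0
    for i in range(Wt.shape[2]):
        s = np.linalg.svd(Wf[:, :, i], compute_uv=False)
        total += float(np.sum(np.power(s, p)))
    return total / Wt.shape[2]


def _shrink_slice(M: np.ndarray, tau: float, p: float):
    """Singular-value shrinkage of one (possibly complex) matrix slice.

    Real symmetric slices go through the eigendecomposition (singular
    values are the absolute eigenvalues), which is substantially faster
    than a full SVD at equal accuracy.
    """
    if np.isrealobj(M) and M.shape[0] == M.shape[1] and np.allclose(M, M.T, atol=1e-12):
        w, V = np.linalg.eigh(M)
        s = schatten_scalar_prox(np.abs(w), tau, p)
        return (V * (np.sign(w) * s)) @ V.T, s
    U, s_in, Vh = np.linalg.svd(M, full_matrices=False)
    s = schatten_scalar_prox(s_in, tau, p)
    return (U * s) @ Vh, s


def tensor_schatten_prox(W, tau: float, p: float = 1.0, domain: str = "fourier",
                         return_sv: bool = False):
    """Proximal map of the tensor Schatten p-norm.

    Shrinks the singular values of each transform-domain slice with the
    scalar prox and transforms back; at p = 1 this equals applying
    :func:`matrix_svt` to each transform slice.  ``domain='raw'`` applies
    the shrinkage to the raw frontal slices instead (no DFT).
    With ``return_sv`` the shrunk singular values per (transform) slice
    are returned alongside, letting callers evaluate the Schatten norm
    of the output without a second decomposition.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    is_network = isinstance(W, NetworkTensor)
    Wt = _as_tensor(W)
    n, m, t = Wt.shape
    sv = []
    if domain == "raw":
        out = np.empty_like(Wt)
        for i in range(t):
            out[:, :, i], s = _shrink_slice(Wt[:, :, i], tau, p)
            sv.append(s)
    elif domain == "fourier":
        Wf = np.fft.fft(Wt, axis=2)
        Zf = np.empty_like(Wf)
        sv = [None] * t
        half = t // 2 + 1
        for i in range(half):
            Zi, s = _shrink_slice(Wf[:, :, i].real if t == 2 else Wf[:, :, i], tau, p)
            Zf[:, :, i] = Zi
            sv[i] = s
            j = (t - i) % t
            if j != i:
                Zf[:, :, j] = Zf[:, :, i].conj()
                sv[j] = s
        out = np.real(np.fft.ifft(Zf, axis=2))
    else:
        raise ValueError("domain must be 'fourier' or 'raw'")
    res = NetworkTensor.from_array(out) if is_network else out
    if return_sv:
        return res, np.stack(sv)
    return res


def row_l21_prox(E: np.ndarray, tau: float, axis: str = "rows") -> np.ndarray:
    """Proximal map of the l2,1 norm: group soft-thresholding of row/column norms.

    Each vector ``v`` along the chosen axis becomes
    ``max(0, 1 - tau/||v||_2) * v``.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    E = np.asarray(E, dtype=float)
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    ax = 1 if axis == "rows" else 0
    norms = np.linalg.norm(E, axis=ax, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > tau, 1.0 - tau / np.where(norms == 0, 1.0, norms), 0.0)
    return E * scale
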