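"""Joint denoising of the dual cell networks by constrained ADMM.

The model couples two self-representation problems — one on the
expression features, one on the spatial adjacency — through a low-rank
penalty on the network tensor stacking both learned graphs:

    min  ||[W_e, W_s]||_Sp  +  lambda * ||[E_e; E_s]||_{2,1}
    s.t. P_e D   = P_e D  W_e + E_e,   W_e = W_e',  P_e P_e' = I
         P_s A   = P_s A  W_s + E_s,   W_s = W_s',  P_s P_s' = I

with D the feature x cell expression matrix (cells as columns), A the
spatial adjacency, P_v row-orthonormal projections, and the noise
matrices stacked over the shared cell axis so a cell is flagged noisy
jointly across views. The tensor Schatten p-norm (p = 1: tensor nuclear
norm) ties the two networks together in a shared low-rank structure.

The solver splits the Schatten term with one auxiliary tensor variable,
alternates proximal updates, and ascends the multipliers under an
increasing penalty — the standard inexact augmented-Lagrangian scheme
for low-rank representation models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .tensor import (
    NetworkTensor,
    TSVDFactors,
    row_l21_prox,
    t_svd,
    tensor_schatten_prox,
)

__all__ = [
    "DenoiseConfig",
    "DenoiseState",
    "DenoiseResult",
    "init_state",
    "admm_solve",
    "extract_compatible_features",
    "features_from_networks",
    "export_denoised_expression",
    "save_denoise_result",
]


@dataclass
class DenoiseConfig:
    """Solver hyperparameters.

    lambda_noise weights the l2,1 noise term; with ``normalize_views``
    on (both data views rescaled to unit mean column norm, making the
    tradeoff scale-invariant and the views commensurate) values of a few
    tenths let the networks absorb shared structure while cell-wise
    noise drains into E; values much above ~0.5 make noise so expensive
    that the networks also fit it. p is the Schatten exponent (1 = nuclear
    norm); d the number of learned features per view; proj_rank the
    projection rank (None = full feature rank per view). mu0/mu_max/rho
    control the augmented Lagrangian penalty schedule, tol_primal the
    relative feasibility tolerance on both equality constraints.
    """

    lambda_noise: float = 0.3
    p: float = 1.0
    d: int = 50
    proj_rank: int | None = None
    normalize_views: bool = True
    mu0: float = 1e-3
    mu_max: float = 1e8
    rho: float = 1.2
    tol_primal: float = 1e-6
    max_iter: int = 400
    seed: int = 0
    update_projections: bool = True
    schatten_domain: str = "fourier"

    def __post_init__(self) -> None:
        if self.lambda_noise <= 0:
            raise ValueError("lambda_noise must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if not 0 < self.tol_primal < 1:
            raise ValueError("tol_primal must lie in (0, 1)")
        if min(self.mu0, self.mu_max, self.d, self.max_iter) <= 0:
            raise ValueError("mu0, mu_max, d and max_iter must be positive")


@dataclass
class DenoiseState:
    """All primal and dual iterates of the solver."""

    We: np.ndarray
    Ws: np.ndarray
    Ee: np.ndarray
    Es: np.ndarray
    Pe: np.ndarray
    Ps: np.ndarray
    Je: np.ndarray
    Js: np.ndarray
    Ye: np.ndarray
    Ys: np.ndarray
    Le: np.ndarray
    Ls: np.ndarray
    mu: float
    iter: int = 0
    primal_residuals: list = field(default_factory=list)


@dataclass
class DenoiseResult:
    """Final state plus the learned compatible cell features."""

    state: DenoiseState
    features: np.ndarray
    tensor_factors: TSVDFactors
    converged: bool
    objective_trace: list


def init_state(D: np.ndarray, A: np.ndarray, cfg: DenoiseConfig) -> DenoiseState:
    """Deterministic cold start: zero networks/noise, canonical-basis projections."""
    D = np.asarray(D, dtype=float)
    A = np.asarray(A, dtype=float)
    q, n = D.shape
    if A.shape != (n, n):
        raise ValueError(
            f"spatial adjacency is {A.shape}, expected ({n}, {n}) to match D's cell axis"
        )
    re = q if cfg.proj_rank is None else cfg.proj_rank
    rs = n if cfg.proj_rank is None else min(cfg.proj_rank, n)
    if re > q:
        raise ValueError(f"proj_rank={re} exceeds expression feature dimension {q}")
    Z = np.zeros((n, n))
    return DenoiseState(
        We=Z.copy(),
        Ws=Z.copy(),
        Ee=np.zeros((re, n)),
        Es=np.zeros((rs, n)),
        Pe=np.eye(re, q),
        Ps=np.eye(rs, n),
        Je=Z.copy(),
        Js=Z.copy(),
        Ye=np.zeros((re, n)),
        Ys=np.zeros((rs, n)),
        Le=Z.copy(),
        Ls=Z.copy(),
        mu=cfg.mu0,
    )


def _sym_hollow(W: np.ndarray) -> np.ndarray:
    """Project onto symmetric matrices with zero diagonal."""
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return W


def _solve_view(M: np.ndarray, E: np.ndarray, Y: np.ndarray, J: np.ndarray,
                L: np.ndarray, mu: float) -> np.ndarray:
    """W-update: ridge-regularized least squares of the linearized constraint.

    Minimizes ||M - M W - E + Y/mu||_F^2 + ||W - J + L/mu||_F^2 over W,
    then projects onto the symmetric hollow matrices.
    """
    n = M.shape[1]
    G = M.T @ M
    rhs = M.T @ (M - E + Y / mu) + J - L / mu
    W = scipy.linalg.solve(G + np.eye(n), rhs, assume_a="pos")
    return _sym_hollow(W)


def _procrustes_update(P: np.ndarray, Dmat: np.ndarray, W: np.ndarray,
                       E: np.ndarray, Y: np.ndarray, mu: float) -> np.ndarray:
    """P-update: orthogonal Procrustes on the cross-product with the residual target."""
    C = Dmat - Dmat @ W          # q x n
    B = E - Y / mu               # r x n
    G = B @ C.T                  # r x q
    if np.linalg.norm(G) < 1e-12:
        return P
    U, _, Vh = np.linalg.svd(G, full_matrices=False)
    return U @ Vh


def admm_solve(D: np.ndarray, A: np.ndarray, cfg: DenoiseConfig | None = None) -> DenoiseResult:
    """Run the ADMM solver on expression features D (feature x cell) and adjacency A.

    Iterates: (1) Schatten-prox update of the auxiliary network tensor,
    (2) per-view least-squares W-updates followed by symmetric/hollow
    projection, (3) joint column-wise l2,1 shrinkage of the stacked
    noise, (4) Procrustes projection updates, (5) dual ascent and
    penalty growth. Declares convergence when both relative constraint
    residuals fall below ``tol_primal``; non-convergence returns a
    result with ``converged=False`` and a warning rather than raising.
    """
    cfg = cfg or DenoiseConfig()
    D = np.asarray(D, dtype=float)
    A = np.asarray(A, dtype=float)
    if not (np.isfinite(D).all() and np.isfinite(A).all()):
        raise ValueError("inputs contain non-finite values")
    if np.abs(A - A.T).max() > 1e-8 * max(1.0, np.abs(A).max()):
        raise ValueError("spatial adjacency must be symmetric")
    if cfg.normalize_views:
        # unit mean column norm per view: scale-invariant lambda, balanced views
        D = D / max(np.linalg.norm(D, axis=0).mean(), 1e-12)
        A = A / max(np.linalg.norm(A, axis=0).mean(), 1e-12)
    st = init_state(D, A, cfg)
    n = A.shape[0]
    lam = cfg.lambda_noise
    objective_trace: list[float] = []
    converged = False

    Me = st.Pe @ D
    Ms = st.Ps @ A
    for it in range(cfg.max_iter):
        mu = st.mu
        # (1) auxiliary tensor <- prox of the Schatten penalty at W + L/mu
        Jt, J_sv = tensor_schatten_prox(
            np.stack([st.We + st.Le / mu, st.Ws + st.Ls / mu], axis=2),
            1.0 / mu,
            cfg.p,
            domain=cfg.schatten_domain,
            return_sv=True,
        )
        st.Je, st.Js = Jt[:, :, 0], Jt[:, :, 1]
        # (2) network updates
        st.We = _solve_view(Me, st.Ee, st.Ye, st.Je, st.Le, mu)
        st.Ws = _solve_view(Ms, st.Es, st.Ys, st.Js, st.Ls, mu)
        # (3) joint noise update over the shared cell axis
        Re = Me - Me @ st.We + st.Ye / mu
        Rs = Ms - Ms @ st.Ws + st.Ys / mu
        E = row_l21_prox(np.vstack([Re, Rs]), lam / mu, axis="columns")
        st.Ee, st.Es = E[: Re.shape[0]], E[Re.shape[0]:]
        # (4) projection updates; a square orthogonal P only rotates the
        # noise basis (column norms invariant), so only true rank
        # reductions are updated
        if cfg.update_projections:
            if st.Pe.shape[0] < st.Pe.shape[1]:
                st.Pe = _procrustes_update(st.Pe, D, st.We, st.Ee, st.Ye, mu)
                Me = st.Pe @ D
            if st.Ps.shape[0] < st.Ps.shape[1]:
                st.Ps = _procrustes_update(st.Ps, A, st.Ws, st.Es, st.Ys, mu)
                Ms = st.Ps @ A
        # (5) dual ascent on the true residuals, penalty growth
        res_e_mat = Me - Me @ st.We - st.Ee
        res_s_mat = Ms - Ms @ st.Ws - st.Es
        st.Ye = st.Ye + mu * res_e_mat
        st.Ys = st.Ys + mu * res_s_mat
        st.Le = st.Le + mu * (st.We - st.Je)
        st.Ls = st.Ls + mu * (st.Ws - st.Js)
        st.mu = min(cfg.mu_max, cfg.rho * mu)
        st.iter = it + 1

        den_e = max(np.linalg.norm(Me), 1e-12)
        den_s = max(np.linalg.norm(Ms), 1e-12)
        res_e = np.linalg.norm(res_e_mat) / den_e
        res_s = np.linalg.norm(res_s_mat) / den_s
        # splitting residual: the Schatten term acts on J, so W must meet it
        den_w = max(np.linalg.norm(st.We), np.linalg.norm(st.Ws), 1e-12)
        res_j = max(
            np.linalg.norm(st.We - st.Je), np.linalg.norm(st.Ws - st.Js)
        ) / den_w
        st.primal_residuals.append(max(res_e, res_s))
        # objective evaluated at the auxiliary tensor (spectrum already known)
        obj = float(np.power(J_sv, cfg.p).sum()) / J_sv.shape[0] + lam * float(
            np.linalg.norm(np.vstack([st.Ee, st.Es]), axis=0).sum()
        )
        objective_trace.append(obj)
        if not np.isfinite(obj) or not np.isfinite(st.We).all():
            raise FloatingPointError(
                f"non-finite values in solver iterate at iteration {it + 1}"
            )
        if res_e < cfg.tol_primal and res_s < cfg.tol_primal and res_j < cfg.tol_primal:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"solver did not reach tol_primal={cfg.tol_primal} within "
            f"{cfg.max_iter} iterations (last residual "
            f"{st.primal_residuals[-1]:.2e})"
        )
    d = min(cfg.d, n)
    factors = t_svd(np.stack([st.We, st.Ws], axis=2), d=d)
    features = features_from_networks(st.We, st.Ws, d, joint=True)
    return DenoiseResult(
        state=st,
        features=features,
        tensor_factors=factors,
        converged=converged,
        objective_trace=objective_trace,
    )


def _truncated_symmetric_svd(M: np.ndarray, d: int):
    U, s, _ = np.linalg.svd(M)
    return U[:, :d], s[:d]


def features_from_networks(We: np.ndarray, Ws: np.ndarray, d: int,
                           joint: bool = True) -> np.ndarray:
    """Compatible cell features from the two learned networks.

    ``joint=True`` decomposes the network tensor: the left factors of
    the two transform-domain slices (We + Ws and We - Ws) are truncated
    to d columns and scaled by the square root of their singular values.
    ``joint=False`` is the concatenation ablation: each view's network
    is decomposed separately by matrix SVD. Rows (cells) are
    L2-normalized in both modes.
    """
    n = We.shape[0]
    if d > n:
        raise ValueError(f"d={d} exceeds number of cells {n}")
    if joint:
        U1, s1 = _truncated_symmetric_svd(We + Ws, d)
        U2, s2 = _truncated_symmetric_svd(We - Ws, d)
    else:
        U1, s1 = _truncated_symmetric_svd(We, d)
        U2, s2 = _truncated_symmetric_svd(Ws, d)
    F = np.hstack([U1 * np.sqrt(s1), U2 * np.sqrt(s2)])
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    return F / np.where(norms == 0, 1.0, norms)


def extract_compatible_features(result: DenoiseResult, d: int) -> np.ndarray:
    """Truncate the learned factors to d features per view (rows = cells)."""
    st = result.state
    return features_from_networks(st.We, st.Ws, d, joint=True)


def save_denoise_result(result: DenoiseResult, outdir, cfg: DenoiseConfig | None = None,
                        cell_ids=None) -> dict:
    """Serialize a solve: networks as MatrixMarket, features as CSV,
    objective trace as TSV, config as a key=value text file."""
    import pandas as pd
    import scipy.sparse as spsp
    from pathlib import Path
    from scipy.io import mmwrite

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, M in (("We", result.state.We), ("Ws", result.state.Ws)):
        paths[name] = outdir / f"{name}.mtx"
        mmwrite(paths[name], spsp.coo_matrix(M))
    n, f = result.features.shape
    ids = cell_ids if cell_ids is not None else [f"cell_{i}" for i in range(n)]
    df = pd.DataFrame(result.features, columns=[f"f{j:03d}" for j in range(f)])
    df.insert(0, "cell_id", list(ids))
    paths["features"] = outdir / "features.csv"
    df.to_csv(paths["features"], index=False)
    paths["objective"] = outdir / "objective_trace.tsv"
    pd.DataFrame(
        {"iteration": range(1, len(result.objective_trace) + 1),
         "objective": result.objective_trace,
         "primal_residual": result.state.primal_residuals}
    ).to_csv(paths["objective"], sep="\t", index=False)
    if cfg is not None:
        paths["config"] = outdir / "config.txt"
        paths["config"].write_text(
            "".join(f"{k} = {v}\n" for k, v in vars(cfg).items())
        )
    return paths


def export_denoised_expression(slice_, We: np.ndarray) -> np.ndarray:
    """One-step graph smoothing of the expression matrix along the learned network.

    Each cell's profile is replaced by the weighted mean of its learned
    neighbors and itself, with self-loop weight 2 so the cell's own
    value dominates: X_hat = rownormalize(|We| + |We'| + 2 I) X.
    """
    X = slice_.dense() if hasattr(slice_, "dense") else np.asarray(slice_, dtype=float)
    n = X.shape[0]
    if We.shape != (n, n):
        raise ValueError(f"We is {We.shape}, expected ({n}, {n})")
    R = np.abs(We) + np.abs(We.T) + 2.0 * np.eye(n)
    R = R / R.sum(axis=1, keepdims=True)
    return R @ X
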