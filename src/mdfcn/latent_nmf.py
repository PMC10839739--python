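"""Latent network extraction by per-band non-negative matrix factorization.

The group tensor's frequency slices (reliable connection x window*subject
matrices) are individually approximated by a low-rank non-negative product
W H and aggregated back into tensor form. The low-rank reconstruction — not
the factors — is the latent representation: it suppresses window-to-window
and subject-to-subject fluctuations while preserving the non-negative
connectivity structure that the subsequent tensor decomposition consumes.

The factorization rank is chosen by an entropy-based effective rank: with
singular values sigma_k normalized to p_k = sigma_k / sum(sigma), the
effective rank is round(exp(-sum p_k ln p_k)). Equal singular values give
the full dimension, a rank-1 spectrum gives 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import GroupTensor

__all__ = [
    "NMFModel",
    "LatentTensor",
    "effective_rank",
    "select_nmf_rank",
    "nmf",
    "extract_latent",
]


@dataclass
class NMFModel:
    W: np.ndarray  # (rows, rank), >= 0
    H: np.ndarray  # (rank, cols), >= 0
    rank: int
    rel_error: float
    error_history: np.ndarray  # relative error after each HALS sweep

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class LatentTensor:
    """Low-rank latent group tensor, same geometry as the masked GroupTensor."""

    values: np.ndarray  # (connection, window*subject, band)
    ranks: list[int]  # selected NMF rank per band
    rel_errors: list[float]
    subject_blocks: list[tuple[int, int]]
    subject_ids: list[str]
    mask: np.ndarray
    pair_index: np.ndarray
    band_names: list[str]


def effective_rank(singular_values: np.ndarray, cap: int = 40) -> int:
    """Entropy-based effective rank of a singular spectrum.

    round(exp(H)) with H the Shannon entropy of the sum-normalized positive
    singular values, floored at 1 and capped at ``cap``.
    """
    s = np.asarray(singular_values, dtype=float)
    s = s[s > 0]
    if s.size == 0:
        raise ValueError("all-zero singular spectrum")
    p = s / s.sum()
    H = -(p * np.log(p)).sum()
    return int(np.clip(round(np.exp(H)), 1, cap))


def select_nmf_rank(matrix: np.ndarray, cap: int = 40) -> int:
    """Effective rank of a matrix's raw (uncentered) singular spectrum."""
    M = np.asarray(matrix, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix")
    s = np.linalg.svd(M, compute_uv=False)
    if not (s > 0).any():
        return 1  # all-zero slice: degenerate rank-1 model
    return min(effective_rank(s, cap=cap), min(M.shape))


def _nndsvda(X: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (zeros filled with the mean)."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], rank))
    H = np.zeros((rank, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for r in range(1, rank):
        u, v = U[:, r], Vt[r]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        npu, npv = np.linalg.norm(up), np.linalg.norm(vp)
        nnu, nnv = np.linalg.norm(un), np.linalg.norm(vn)
        if npu * npv >= nnu * nnv:
            sig, uu, vv = npu * npv, up / max(npu, 1e-30), vp / max(npv, 1e-30)
        else:
            sig, uu, vv = nnu * nnv, un / max(nnu, 1e-30), vn / max(nnv, 1e-30)
        W[:, r] = np.sqrt(S[r] * sig) * uu
        H[r] = np.sqrt(S[r] * sig) * vv
    avg = X.mean()
    W[W <= 0] = avg
    H[H <= 0] = avg
    return W, H


def _hals_sweep(X, W, H, rng) -> None:
    """One full HALS sweep updating W then H in place (objective never increases)."""
    rank = W.shape[1]
    # update W given H
    G = H @ H.T
    P = X @ H.T
    for r in range(rank):
        denom = G[r, r]
        if denom < 1e-30:
            H[r] = 1e-6 * rng.random(H.shape[1])
            G = H @ H.T
            P = X @ H.T
            denom = G[r, r]
        W[:, r] = np.clip(W[:, r] + (P[:, r] - W @ G[:, r]) / denom, 0.0, None)
    # update H given W
    G = W.T @ W
    P = W.T @ X
    for r in range(rank):
        denom = G[r, r]
        if denom < 1e-30:
            W[:, r] = 1e-6 * rng.random(W.shape[0])
            G = W.T @ W
            P = W.T @ X
            denom = G[r, r]
        H[r] = np.clip(H[r] + (P[r] - G[r] @ H) / denom, 0.0, None)


def _rel_error(X, W, H, normX2) -> float:
    # ||X - WH||^2 = ||X||^2 - 2<W^T X, H> + <W^T W, H H^T>
    e2 = normX2 - 2.0 * np.sum((W.T @ X) * H) + np.sum((W.T @ W) * (H @ H.T))
    return float(np.sqrt(max(e2, 0.0) / normX2)) if normX2 > 0 else 0.0


def nmf(
    matrix: np.ndarray,
    rank: int,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> NMFModel:
    """Best-of-restarts HALS non-negative matrix factorization.

    Restart 0 uses NNDSVDa initialization; the remaining restarts use seeded
    random initializations. Each run stops when the relative Frobenius error
    improves by less than ``tol`` between sweeps, and the model with the
    lowest final error wins.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    if not 1 <= rank <= min(X.shape):
        raise ValueError(f"rank must lie in [1, {min(X.shape)}]")
    normX2 = float((X * X).sum())
    if normX2 == 0.0:
        return NMFModel(
            W=np.zeros((X.shape[0], rank)), H=np.zeros((rank, X.shape[1])),
            rank=rank, rel_error=0.0, error_history=np.zeros(1),
        )
    best: NMFModel | None = None
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, restart]))
        if restart == 0:
            W, H = _nndsvda(X, rank)
        else:
            scale = np.sqrt(X.mean() / rank)
            W = scale * rng.random((X.shape[0], rank))
            H = scale * rng.random((rank, X.shape[1]))
        history = []
        prev = np.inf
        for _ in range(max_iter):
            _hals_sweep(X, W, H, rng)
            err = _rel_error(X, W, H, normX2)
            history.append(err)
            if prev - err < tol * max(prev, 1e-30):
                break
            prev = err
        model = NMFModel(W=W, H=H, rank=rank, rel_error=history[-1],
                         error_history=np.array(history))
        if best is None or model.rel_error < best.rel_error:
            best = model
    return best


def extract_latent(
    group: GroupTensor,
    seed: int = 0,
    rank_cap: int = 40,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LatentTensor:
    """Per-band NMF of the group tensor, aggregated back to tensor form.

    Each band slice gets its own automatically selected rank and its own
    factorization; the latent slice is the reconstruction W H.
    """
    values = np.empty_like(group.values)
    ranks: list[int] = []
    errors: list[float] = []
    for b in range(group.values.shape[2]):
        slice_b = group.values[:, :, b]
        if not slice_b.any():
            values[:, :, b] = 0.0
            ranks.append(1)
            errors.append(0.0)
            continue
        rank = select_nmf_rank(slice_b, cap=rank_cap)
        model = nmf(slice_b, rank, seed=seed + b, n_restarts=n_restarts,
                    tol=tol, max_iter=max_iter)
        values[:, :, b] = model.reconstruct()
        ranks.append(rank)
        errors.append(model.rel_error)
    return LatentTensor(
        values=values,
        ranks=ranks,
        rel_errors=errors,
        subject_blocks=group.subject_blocks,
        subject_ids=group.subject_ids,
        mask=group.mask,
        pair_index=group.pair_index,
        band_names=group.band_names,
    )
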