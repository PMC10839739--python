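"""Non-negative canonical polyadic decomposition of the latent tensor.

The latent connection x (window*subject) x band tensor is expressed as a
sum of R rank-1 components, each the outer product of a non-negative
connection factor a_r, temporal factor b_r and spectral factor c_r:

    T  ~=  sum_r  a_r  (outer)  b_r  (outer)  c_r

CPD generalizes the matrix SVD to tensors and, unlike the matrix case, is
essentially unique (up to permutation and scaling) under mild conditions,
which is what makes the components interpretable as subnetworks. The
number of components reuses the entropy-based effective rank, applied to
the singular spectrum of the mode-1 (connection) unfolding.

After fitting, the temporal factors are block averaged within each
subject's window block, turning the components into descriptions of
connectivity across connections, subjects and bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .connectivity import _as_str
from .latent_nmf import LatentTensor, effective_rank

__all__ = [
    "CPDModel",
    "SubjectCPDModel",
    "select_cpd_order",
    "nncpd",
    "block_average",
    "subject_cpd",
    "save_subject_cpd",
    "load_subject_cpd",
]


@dataclass
class CPDModel:
    """Rank-R non-negative CPD. A: connection, B: window*subject, C: band.

    Columns of A and C are normalized to unit sum with the scale absorbed
    into B, so ``reconstruct()`` is invariant to the normalization.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    R: int
    fit: float  # relative Frobenius reconstruction error

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.A, self.B, self.C)


@dataclass
class SubjectCPDModel:
    """CPD with the temporal mode collapsed to one loading per subject."""

    A: np.ndarray
    B_subject: np.ndarray  # (n_subjects, R)
    C: np.ndarray
    R: int
    fit: float
    subject_ids: list[str]
    mask: np.ndarray
    pair_index: np.ndarray
    band_names: list[str]


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding (C-ordered columns of the remaining modes)."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def khatri_rao(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product; rows of P vary slower (C order)."""
    R = P.shape[1]
    return (P[:, None, :] * Q[None, :, :]).reshape(-1, R)


def select_cpd_order(latent: LatentTensor | np.ndarray, cap: int = 20) -> int:
    """Entropy-based component count from the connection-mode unfolding."""
    T = latent.values if isinstance(latent, LatentTensor) else np.asarray(latent)
    if T.size == 0:
        raise ValueError("empty tensor")
    s = np.linalg.svd(unfold(T, 0), compute_uv=False)
    if not (s > 0).any():
        return 1
    return effective_rank(s, cap=cap)


def _mttkrp(T: np.ndarray, factors: list[np.ndarray], mode: int) -> np.ndarray:
    """Matricized-tensor times Khatri-Rao product for one mode."""
    subs = ["ir", "jr", "kr"]
    subs[mode] = ""
    operands = [T] + [f for m, f in enumerate(factors) if m != mode]
    spec = "ijk," + ",".join(s for s in subs if s) + "->" + "ijk"[mode] + "r"
    return np.einsum(spec, *operands, optimize=True)


def _init_factors(T: np.ndarray, R: int, restart: int, rng) -> list[np.ndarray]:
    """SVD-abs initialization for restart 0, seeded random otherwise."""
    factors = []
    for mode in range(3):
        dim = T.shape[mode]
        if restart == 0:
            U, _, _ = np.linalg.svd(unfold(T, mode), full_matrices=False)
            k = min(R, U.shape[1])
            F = np.abs(U[:, :k])
            if k < R:
                F = np.hstack([F, rng.random((dim, R - k))])
        else:
            F = rng.random((dim, R))
        factors.append(F + 1e-9)
    return factors


def nncpd(
    tensor: np.ndarray,
    R: int,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-7,
    max_iter: int = 1000,
    drop_degenerate: bool = True,
) -> CPDModel:
    """Best-of-restarts non-negative ALS fit with HALS inner updates.

    The relative Frobenius error is tracked per sweep and the objective is
    non-increasing within a run (exact block-coordinate updates). Components
    whose factors collapse to zero are dropped with a warning and R reduced.
    """
    T = np.asarray(tensor, dtype=float)
    if T.ndim != 3:
        raise ValueError("expected a 3-way tensor")
    if (T < 0).any():
        raise ValueError("CPD input must be non-negative")
    if R < 1:
        raise ValueError("R must be >= 1")
    normT2 = float((T * T).sum())
    if normT2 == 0.0:
        zero = [np.zeros((T.shape[m], R)) for m in range(3)]
        return CPDModel(A=zero[0], B=zero[1], C=zero[2], R=R, fit=0.0)

    best: tuple[float, list[np.ndarray]] | None = None
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, restart]))
        F = _init_factors(T, R, restart, rng)
        prev = np.inf
        err = np.inf
        for _ in range(max_iter):
            for mode in range(3):
                M = _mttkrp(T, F, mode)
                G = np.ones((R, R))
                for m, f in enumerate(F):
                    if m != mode:
                        G *= f.T @ f
                X = F[mode]
                for r in range(R):
                    denom = G[r, r]
                    if denom < 1e-30:
                        X[:, r] = 1e-9
                        continue
                    X[:, r] = np.clip(X[:, r] + (M[:, r] - X @ G[:, r]) / denom, 0.0, None)
            e2 = normT2 - 2.0 * np.sum(M * F[2]) + np.sum((F[2].T @ F[2]) * G)
            err = float(np.sqrt(max(e2, 0.0) / normT2))
            if prev - err < tol * max(prev, 1e-30):
                break
            prev = err
        if best is None or err < best[0]:
            best = (err, [f.copy() for f in F])

    fit, (A, B, C) = best[0], best[1]
    # drop components that died during optimization
    norms = np.array(
        [np.linalg.norm(A[:, r]) * np.linalg.norm(B[:, r]) * np.linalg.norm(C[:, r])
         for r in range(R)]
    )
    keep = norms > 1e-12 * max(norms.max(), 1e-30)
    if drop_degenerate and not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} degenerate (zero) CPD component(s)",
            RuntimeWarning,
            stacklevel=2,
        )
        A, B, C = A[:, keep], B[:, keep], C[:, keep]
        R = int(keep.sum())
    # normalization: unit-sum columns in A and C, scale absorbed into B
    for r in range(R):
        sa, sc = A[:, r].sum(), C[:, r].sum()
        if sa > 0:
            A[:, r] /= sa
        if sc > 0:
            C[:, r] /= sc
        B[:, r] *= sa * sc
    return CPDModel(A=A, B=B, C=C, R=R, fit=fit)


def block_average(B: np.ndarray, windows_per_subject: int, n_subjects: int) -> np.ndarray:
    """Collapse the temporal factor to one loading per subject (block mean)."""
    B = np.asarray(B)
    if B.shape[0] != windows_per_subject * n_subjects:
        raise ValueError(
            f"temporal factor has {B.shape[0]} rows; expected "
            f"{windows_per_subject} x {n_subjects}"
        )
    return B.reshape(n_subjects, windows_per_subject, -1).mean(axis=1)


def subject_cpd(
    latent: LatentTensor,
    R: int | None = None,
    seed: int = 0,
    order_cap: int = 20,
    **cpd_kwargs,
) -> SubjectCPDModel:
    """Fit the non-negative CPD to a latent tensor and block-average B.

    ``R=None`` selects the order automatically via the entropy criterion.
    """
    if R is None:
        R = select_cpd_order(latent, cap=order_cap)
    model = nncpd(latent.values, R, seed=seed, **cpd_kwargs)
    w = latent.subject_blocks[0][1] - latent.subject_blocks[0][0]
    Bbar = block_average(model.B, w, len(latent.subject_blocks))
    return SubjectCPDModel(
        A=model.A,
        B_subject=Bbar,
        C=model.C,
        R=model.R,
        fit=model.fit,
        subject_ids=latent.subject_ids,
        mask=latent.mask,
        pair_index=latent.pair_index,
        band_names=latent.band_names,
    )


def save_subject_cpd(path, model: SubjectCPDModel) -> None:
    with h5py.File(path, "w") as f:
        for name in ("A", "B_subject", "C"):
            f.create_dataset(name, data=getattr(model, name))
        f.create_dataset("mask", data=model.mask.astype(np.uint8))
        f.create_dataset("pair_index", data=model.pair_index)
        f.attrs["R"] = model.R
        f.attrs["fit"] = model.fit
        f.attrs["subject_ids"] = [s.encode() for s in model.subject_ids]
        f.attrs["band_names"] = [b.encode() for b in model.band_names]


def load_subject_cpd(path) -> SubjectCPDModel:
    with h5py.File(path, "r") as f:
        return SubjectCPDModel(
            A=f["A"][()],
            B_subject=f["B_subject"][()],
            C=f["C"][()],
            R=int(f.attrs["R"]),
            fit=float(f.attrs["fit"]),
            subject_ids=[_as_str(s) for s in f.attrs["subject_ids"]],
            mask=f["mask"][()].astype(bool),
            pair_index=f["pair_index"][()],
            band_names=[_as_str(b) for b in f.attrs["band_names"]],
        )
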