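import numpy as np
import pandas as pd
import pytest

from mdfcn.bands import BandScheme
from mdfcn.cpd_decomposition import SubjectCPDModel


@pytest.fixture
def two_band_scheme():
    return BandScheme((("theta", 4.0, 8.0), ("alpha", 8.0, 13.0)))


def make_subject_model(
    A: np.ndarray,
    B_subject: np.ndarray,
    C: np.ndarray,
    mask: np.ndarray | None = None,
) -> SubjectCPDModel:
    """Assemble a SubjectCPDModel directly from factor matrices."""
    n_conn, R = A.shape
    if mask is None:
        mask = np.ones(n_conn, dtype=bool)
    # smallest parcel count whose pair count covers the connections
    P = 2
    while P * (P - 1) // 2 < mask.size:
        P += 1
    pad = P * (P - 1) // 2 - mask.size
    full_mask = np.concatenate([mask, np.zeros(pad, dtype=bool)])
    iu = np.column_stack(np.triu_indices(P, k=1))
    return SubjectCPDModel(
        A=A,
        B_subject=B_subject,
        C=C,
        R=R,
        fit=0.0,
        subject_ids=[f"S{k:03d}" for k in range(B_subject.shape[0])],
        mask=full_mask,
        pair_index=iu,
        band_names=[f"band{k}" for k in range(C.shape[0])],
    )


def make_phenotypes(scores: np.ndarray, ages: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [f"S{k:03d}" for k in range(len(scores))],
            "score": scores,
            "conceptional_age": ages,
        }
    )


def greedy_congruence(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Per-column cosine similarity after greedy maximum matching."""
    Fn = F / (np.linalg.norm(F, axis=0, keepdims=True) + 1e-30)
    Gn = G / (np.linalg.norm(G, axis=0, keepdims=True) + 1e-30)
    C = Fn.T @ Gn
    used: set[int] = set()
    out = []
    for r in range(F.shape[1]):
        cands = [c for c in range(G.shape[1]) if c not in used]
        best = max(cands, key=lambda c: C[r, c])
        used.add(best)
        out.append(C[r, best])
    return np.array(out)
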