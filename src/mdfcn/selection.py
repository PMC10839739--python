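"""Component selection, phenotype correlation and permutation calibration.

Stage 5 of the pipeline asks: which subset of the CPD components, when used
to reconstruct a per-band connection x subject network, best correlates
with a phenotype score? The search is exhaustive over all non-empty
component subsets. For each candidate subset the reconstruction is
standardized per subject (median removed, median absolute deviation set to
one), every connection is correlated with the score by a partial Spearman
coefficient controlling for conceptional age, significance is assessed by
Benjamini-Hochberg FDR at 5% within the (band, score, direction) family,
and three quality terms are combined by their geometric mean:

    F = ( density * mean|rho| * mean R^2 )^(1/3)

where density is the fraction of reliable connections that survive FDR
with the requested sign, mean|rho| averages their partial correlations and
mean R^2 averages per-connection linear-fit goodness of fit. Selections
whose density falls below a floor (default 2.5%) are flagged empty.

Calibration uses a permutation null: subject rows of the connectivity
matrix are shuffled jointly (scores and covariate fixed) and the full
correlation + FDR pipeline recomputed, yielding an empirical distribution
of null network densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cpd_decomposition import SubjectCPDModel

__all__ = [
    "SelectionResult",
    "DensityNull",
    "reconstruct_subset",
    "standardize",
    "partial_spearman",
    "partial_spearman_matrix",
    "bh_adjust",
    "fitness",
    "select_components",
    "permutation_null",
    "compare_group_scores",
]


# ---------------------------------------------------------------------------
# reconstruction and standardization
# ---------------------------------------------------------------------------

def reconstruct_subset(
    model: SubjectCPDModel, S: tuple[int, ...] | list[int], band: int
) -> np.ndarray:
    """Connection x subject reconstruction from a component subset.

    ``values[c, s] = sum_{r in S} A[c, r] * B_subject[s, r] * C[band, r]``.
    """
    S = tuple(S)
    if len(S) == 0:
        raise ValueError("component subset must be non-empty")
    if any(not 0 <= r < model.R for r in S):
        raise ValueError(f"component index out of range (R = {model.R})")
    idx = list(S)
    return model.A[:, idx] @ (model.B_subject[:, idx] * model.C[band, idx]).T


def standardize(values: np.ndarray, on_zero_mad: str = "error", eps: float = 1e-12) -> np.ndarray:
    """Per-subject robust standardization: remove median, set raw MAD to 1.

    Columns are subjects. The raw median absolute deviation is used (no
    1.4826 normal-consistency factor). A zero-MAD subject raises by
    default; ``on_zero_mad="epsilon"`` divides by ``eps`` instead.
    """
    V = np.asarray(values, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("need at least 2 connections per subject")
    med = np.median(V, axis=0, keepdims=True)
    mad = np.median(np.abs(V - med), axis=0, keepdims=True)
    zero = mad[0] <= 0
    if zero.any():
        if on_zero_mad == "error":
            raise ValueError(
                f"zero MAD for subject column(s) {np.nonzero(zero)[0].tolist()}"
            )
        mad = np.where(mad <= 0, eps, mad)
    return (V - med) / mad


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------

def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for z.

    All three vectors are rank-transformed (average ranks on ties) and the
    first-order partial Pearson correlation is computed on the ranks; the
    p-value uses the t approximation with n - 3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = x.size
    if not (y.size == n and z.size == n):
        raise ValueError("x, y, z must have equal length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    rho = partial_spearman_matrix(x[None, :], y, z)[0][0]
    p = _partial_p(np.array([rho]), n)[0]
    return float(rho), float(p)


def _pearson_rows(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of R with vector v."""
    Rc = R - R.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Rc * Rc).sum(axis=1) * (vc * vc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, Rc @ vc / np.where(denom > 0, denom, 1.0), np.nan)


def _partial_p(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 3) / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 3)
    return np.where(np.isnan(rho), 1.0, p)


def partial_spearman_matrix(
    X: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise partial Spearman of a (connections x subjects) matrix.

    Returns (rho, p) vectors; constant rows yield rho = NaN, p = 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    rx = _rank(X, axis=1)
    ry = _rank(np.asarray(y, dtype=float))
    rz = _rank(np.asarray(z, dtype=float))
    r_xy = _pearson_rows(rx, ry)
    r_xz = _pearson_rows(rx, rz)
    r_yz = _pearson_rows(ry[None, :], rz)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
        rho = np.where(den > 1e-12, (r_xy - r_xz * r_yz) / np.where(den > 1e-12, den, 1.0), np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    return rho, _partial_p(rho, n)


def bh_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted q-values, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_adj, reject


def fitness(density: float, mean_abs_rho: float, mean_r2: float) -> float:
    """Geometric mean of the three selection criteria (0 if any term is 0)."""
    terms = (density, mean_abs_rho, mean_r2)
    for t in terms:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"fitness terms must lie in [0, 1], got {terms}")
    if any(t == 0.0 for t in terms):
        return 0.0
    return float(np.cbrt(density * mean_abs_rho * mean_r2))


# ---------------------------------------------------------------------------
# exhaustive component selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the exhaustive subset search for one (score, band, direction)."""

    score_name: str
    band: int
    direction: str  # "pos" or "neg"
    subset: tuple[int, ...]
    density: float
    mean_abs_rho: float
    mean_r2: float
    fitness: float
    significant: np.ndarray  # indices into the reliable-connection axis
    rho: np.ndarray  # partial Spearman per reliable connection (chosen subset)
    q_values: np.ndarray
    empty: bool  # True when best density < floor
    n_subjects: int = 0


def _evaluate_subset(
    model: SubjectCPDModel,
    S: tuple[int, ...],
    band: int,
    score: np.ndarray,
    age: np.ndarray,
    direction: str,
    fdr_q: float,
) -> tuple[float, float, float, float, np.ndarray, np.ndarray, np.ndarray]:
    vals = reconstruct_subset(model, S, band)
    Z = standardize(vals, on_zero_mad="epsilon")
    rho, p = partial_spearman_matrix(Z, score, age)
    q_adj, reject = bh_adjust(p, q=fdr_q)
    sign_ok = rho > 0 if direction == "pos" else rho < 0
    sig = np.nonzero(reject & np.nan_to_num(sign_ok, nan=False))[0]
    m = Z.shape[0]
    d = sig.size / m
    if sig.size == 0:
        return 0.0, 0.0, 0.0, 0.0, sig, rho, q_adj
    mean_abs_rho = float(np.abs(rho[sig]).mean())
    r2 = _pearson_rows(Z[sig], score) ** 2
    mean_r2 = float(np.nan_to_num(r2, nan=0.0).mean())
    F = fitness(d, mean_abs_rho, mean_r2)
    return d, mean_abs_rho, mean_r2, F, sig, rho, q_adj


def iter_subsets(R: int):
    """Non-empty subsets of range(R), smallest first, lexicographic within size."""
    for size in range(1, R + 1):
        yield from combinations(range(R), size)


def select_components(
    model: SubjectCPDModel,
    phenotypes,
    score: str,
    band: int,
    direction: str = "pos",
    density_floor: float = 0.025,
    fdr_q: float = 0.05,
    max_R: int = 20,
) -> SelectionResult:
    """Exhaustive search for the component subset maximizing the fitness.

    ``phenotypes`` is a DataFrame indexed like the model's subject order
    (matched on ``subject_id``) providing the score column and
    ``conceptional_age``. Subjects with a missing score or covariate are
    dropped from this analysis only. Ties in fitness resolve to the
    smaller subset, then lexicographically (the enumeration order).
    """
    if direction not in ("pos", "neg"):
        raise ValueError("direction must be 'pos' or 'neg'")
    if model.R > max_R:
        raise ValueError(f"R = {model.R} exceeds the exhaustive-search cap {max_R}")
    pheno = phenotypes.set_index("subject_id").reindex(model.subject_ids)
    ok = pheno[score].notna() & pheno["conceptional_age"].notna()
    if not ok.any():
        raise ValueError(f"no subject has both {score!r} and conceptional_age")
    y = pheno.loc[ok, score].to_numpy(dtype=float)
    z = pheno.loc[ok, "conceptional_age"].to_numpy(dtype=float)
    sub_model = SubjectCPDModel(
        A=model.A,
        B_subject=model.B_subject[ok.to_numpy()],
        C=model.C,
        R=model.R,
        fit=model.fit,
        subject_ids=[s for s, keep in zip(model.subject_ids, ok) if keep],
        mask=model.mask,
        pair_index=model.pair_index,
        band_names=model.band_names,
    )
    best = None
    for S in iter_subsets(model.R):
        d, mrho, mr2, F, sig, rho, q_adj = _evaluate_subset(
            sub_model, S, band, y, z, direction, fdr_q
        )
        if best is None or F > best[0]:
            best = (F, S, d, mrho, mr2, sig, rho, q_adj)
    F, S, d, mrho, mr2, sig, rho, q_adj = best
    return SelectionResult(
        score_name=score,
        band=band,
        direction=direction,
        subset=S,
        density=d,
        mean_abs_rho=mrho,
        mean_r2=mr2,
        fitness=F,
        significant=sig,
        rho=rho,
        q_values=q_adj,
        empty=bool(d < density_floor),
        n_subjects=int(ok.sum()),
    )


# ---------------------------------------------------------------------------
# permutation null and group comparison
# ---------------------------------------------------------------------------

@dataclass
class DensityNull:
    """Empirical null distribution of network densities under permutation."""

    densities_pos: np.ndarray
    densities_neg: np.ndarray
    n_perm: int

    def tail_prob(self, d: float, direction: str = "pos") -> float:
        """Empirical P(null density >= d)."""
        dens = self.densities_pos if direction == "pos" else self.densities_neg
        return float((dens >= d).mean())


def permutation_null(
    values: np.ndarray,
    score: np.ndarray,
    age: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> DensityNull:
    """Null densities by jointly permuting subjects of the connectivity matrix.

    Each permutation shuffles the subject columns of ``values`` as a block
    (scores and covariate stay put), preserving the inter-connection
    dependence structure, then recomputes partial Spearman + BH and records
    the positive- and negative-direction densities.
    """
    V = np.asarray(values, dtype=float)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = V.shape[1]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    rng = np.random.default_rng(seed)
    # ranks are permutation-equivariant: rank once, permute columns after
    rx = _rank(V, axis=1)
    ry = _rank(np.asarray(score, dtype=float))
    rz = _rank(np.asarray(age, dtype=float))
    m = V.shape[0]
    pos = np.empty(n_perm)
    neg = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        rxp = rx[:, perm]
        r_xy = _pearson_rows(rxp, ry)
        r_xz = _pearson_rows(rxp, rz)
        r_yz = _pearson_rows(ry[None, :], rz)[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            den = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
            rho = np.where(den > 1e-12, (r_xy - r_xz * r_yz) / np.where(den > 1e-12, den, 1.0), np.nan)
        rho = np.clip(rho, -1.0, 1.0)
        p = _partial_p(rho, n)
        _, reject = bh_adjust(p, q=fdr_q)
        pos[k] = (reject & (rho > 0)).sum() / m
        neg[k] = (reject & (rho < 0)).sum() / m
    return DensityNull(densities_pos=pos, densities_neg=neg, n_perm=n_perm)


def compare_group_scores(scores_a, scores_b) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum comparison of two score samples.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise (scipy's Mann-Whitney U, which is the rank-sum test up to a
    constant shift of the statistic).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
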