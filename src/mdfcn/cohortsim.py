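"""Synthetic cohorts with planted, phenotype-linked phase coupling.

Every downstream stage of the pipeline (connectivity tensors, latent
factorization, component selection, multiplex metrics) is validated against
cohorts generated here, because they carry exact ground truth: which parcel
pairs are phase-coupled, in which band, at what lag, and how strongly each
subject expresses the coupling.

The generator synthesizes band-limited signals directly, one matrix per
frequency band, since that is what the connectivity stage consumes:

* background activity is zero-phase band-filtered white noise per parcel,
  scaled to standard deviation ``noise_sd``;
* each planted edge ``(i, j, band, lag)`` adds a shared band-limited
  component to parcel ``i`` and a Hilbert-phase-shifted copy (lag radians)
  to parcel ``j``, scaled by ``coupling_gain`` times a per-subject coupling
  strength. A constant, non-zero lag produces a same-sign imaginary
  cross-spectrum, the regime where dwPLI approaches 1;
* per-subject coupling strengths are a fixed uniform grid assigned to
  subjects through a Gaussian copula so that their Spearman correlation
  with the emitted phenotype score equals ``score_link`` in expectation;
* every subject additionally carries an idiosyncratic weak coupling
  network — a random subset of parcel pairs phase-coupled at random lags
  and amplitudes, independent of the score. This emulates the intersubject
  variability that dominates real cohorts (each infant has their own
  connectivity fingerprint) and that the group-level factorization is
  designed to suppress; without it, the score-linked coupling would be the
  only subject-level variance in the tensor, an unrealistically easy null.

Conceptional ages are drawn uniformly in [40, 44] weeks, independent of the
score, so the covariate is non-confounding by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import BandScheme, default_band_scheme
from .connectivity import CohortSignals, _as_str, bandsplit

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "generate_fidelity_mask",
    "save_cohort",
    "load_cohort",
]


@dataclass
class SyntheticConfig:
    """Ground-truth description of a synthetic cohort.

    ``planted_edges`` is a list of ``(i, j, band_index, lag_radians)``; the
    same per-subject coupling strength scales every planted edge.
    ``score_link`` in [-1, 1] is the target Spearman correlation between
    coupling strength and the emitted score.
    """

    n_subjects: int
    n_parcels: int = 58
    duration_s: float = 180.0
    fs: float = 100.0
    band_scheme: BandScheme = field(default_factory=default_band_scheme)
    planted_edges: list[tuple[int, int, int, float]] = field(default_factory=list)
    coupling_gain: float = 1.0
    score_link: float = 0.8
    noise_sd: float = 1.0
    strength_range: tuple[float, float] = (0.2, 1.0)
    hetero_coupling: float = 0.5
    hetero_density: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_parcels < 2:
            raise ValueError("need n_subjects >= 1 and n_parcels >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be >= 0")
        if not -1.0 <= self.score_link <= 1.0:
            raise ValueError("score_link must lie in [-1, 1]")
        if self.hetero_coupling < 0 or not 0.0 <= self.hetero_density <= 1.0:
            raise ValueError("hetero_coupling must be >= 0 and hetero_density in [0, 1]")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be an integer sample count")
        self.band_scheme.validate_nyquist(self.fs)
        for i, j, b, _ in self.planted_edges:
            if not (0 <= i < self.n_parcels and 0 <= j < self.n_parcels) or i == j:
                raise ValueError(f"planted edge ({i}, {j}) out of range or degenerate")
            if not 0 <= b < self.band_scheme.n_bands:
                raise ValueError(f"planted edge band index {b} out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def _unit_band_noise(rng: np.random.Generator, n: tuple[int, ...] | int, fs: float,
                     band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian noise normalized to unit standard deviation."""
    x = bandsplit(rng.standard_normal(n), fs, band)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _hilbert_shift(u: np.ndarray, lag: float) -> np.ndarray:
    """Shift every spectral component of ``u`` by ``lag`` radians.

    Re[(u + i H(u)) e^{-i lag}] delays the analytic phase by ``lag``; for a
    narrowband signal this is the conventional constant-phase-lag copy.
    """
    a = hilbert(u)
    return np.real(a * np.exp(-1j * lag))


def _copula_linked_strengths(
    rng: np.random.Generator, n: int, rho_s: float, strength_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Coupling-strength grid linked to a Gaussian score at Spearman rho_s.

    The per-subject strengths are a fixed uniform grid (so the marginal
    distribution never depends on the link), assigned by the ranks of a
    Gaussian variable correlated with the score at the Pearson level
    ``2 sin(pi rho_s / 6)`` — the value whose Gaussian-copula Spearman
    correlation equals ``rho_s``.
    """
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z = rng.standard_normal((n, 2))
    z1 = z[:, 0]
    z2 = rho_p * z[:, 0] + np.sqrt(max(0.0, 1.0 - rho_p**2)) * z[:, 1]
    grid = np.linspace(strength_range[0], strength_range[1], n)
    # rank-assign: the subject with the r-th smallest z1 gets the r-th grid value
    strengths = np.empty(n)
    strengths[np.argsort(z1)] = grid
    return strengths, z2


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[CohortSignals, pd.DataFrame, pd.DataFrame]:
    """Generate signals, phenotypes and the ground-truth edge table.

    Returns
    -------
    cohort
        :class:`CohortSignals` with one (parcels x samples) matrix per band
        and subject.
    phenotypes
        DataFrame with ``subject_id``, ``score``, ``conceptional_age`` and
        the latent ``coupling_strength`` (ground truth, not an input to the
        pipeline).
    truth
        DataFrame of planted edges: ``i, j, band, lag, gain``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    strengths, scores = _copula_linked_strengths(
        rng, n, config.score_link, config.strength_range
    )
    ages = rng.uniform(40.0, 44.0, size=n)

    # planted edges grouped by band for the synthesis loop
    by_band: dict[int, list[tuple[int, int, float]]] = {}
    for i, j, b, lag in config.planted_edges:
        by_band.setdefault(b, []).append((i, j, lag))

    pairs = np.column_stack(np.triu_indices(config.n_parcels, k=1))
    n_hetero = int(round(config.hetero_density * pairs.shape[0]))

    subjects: dict[str, dict[str, np.ndarray]] = {}
    for s in range(n):
        sid = f"S{s:03d}"
        bands: dict[str, np.ndarray] = {}
        for b, (name, low, high) in enumerate(config.band_scheme):
            X = config.noise_sd * _unit_band_noise(
                rng, (config.n_parcels, config.n_samples), config.fs, (low, high)
            )
            # subject-idiosyncratic weak coupling on a random pair subset
            if n_hetero > 0 and config.hetero_coupling > 0:
                chosen = rng.choice(pairs.shape[0], size=n_hetero, replace=False)
                amps = config.hetero_coupling * config.noise_sd * rng.uniform(0, 1, n_hetero)
                lags = rng.uniform(np.pi / 6, 5 * np.pi / 6, n_hetero)
                U = _unit_band_noise(
                    rng, (n_hetero, config.n_samples), config.fs, (low, high)
                )
                Ushift = np.real(hilbert(U, axis=-1) * np.exp(-1j * lags[:, None]))
                for k, pidx in enumerate(chosen):
                    i, j = pairs[pidx]
                    X[i] += amps[k] * U[k]
                    X[j] += amps[k] * Ushift[k]
            # score-linked planted coupling
            for i, j, lag in by_band.get(b, []):
                u = _unit_band_noise(rng, config.n_samples, config.fs, (low, high))
                amp = config.coupling_gain * strengths[s]
                X[i] += amp * u
                X[j] += amp * _hilbert_shift(u, lag)
            bands[name] = X
        subjects[sid] = bands

    cohort = CohortSignals(subjects=subjects, fs=config.fs, band_scheme=config.band_scheme)
    phenotypes = pd.DataFrame(
        {
            "subject_id": list(subjects),
            "score": scores,
            "conceptional_age": ages,
            "coupling_strength": strengths,
        }
    )
    truth = pd.DataFrame(
        [
            {"i": i, "j": j, "band": b, "lag": lag, "gain": config.coupling_gain}
            for i, j, b, lag in config.planted_edges
        ],
        columns=["i", "j", "band", "lag", "gain"],
    )
    return cohort, phenotypes, truth


def generate_fidelity_mask(n_pairs: int, n_reject: int, seed: int = 0) -> np.ndarray:
    """Boolean reliability mask with ``n_reject`` pairs rejected uniformly.

    Mirrors the head-model-derived fidelity template consumed by the
    connectivity stage: for the 58-parcel geometry, rejecting 525 of the
    1653 pairs leaves 1128 reliable connections.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    if not 0 <= n_reject <= n_pairs:
        raise ValueError("need 0 <= n_reject <= n_pairs")
    if n_reject == n_pairs:
        raise ValueError("cannot reject every pair: mask must keep >= 1 connection")
    rng = np.random.default_rng(seed)
    mask = np.ones(n_pairs, dtype=bool)
    mask[rng.choice(n_pairs, size=n_reject, replace=False)] = False
    return mask


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def save_cohort(
    out_dir,
    cohort: CohortSignals,
    phenotypes: pd.DataFrame,
    truth: pd.DataFrame,
    mask: np.ndarray | None = None,
) -> None:
    """Write signals.h5 (/subjects/<id>/<band>), phenotypes.csv, truth.tsv, mask.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "signals.h5", "w") as f:
        f.attrs["fs"] = cohort.fs
        f.attrs["band_names"] = [b.encode() for b in cohort.band_scheme.names]
        f.attrs["band_edges"] = np.array(
            [[low, high] for _, low, high in cohort.band_scheme]
        )
        g = f.create_group("subjects")
        for sid, bands in cohort.subjects.items():
            sg = g.create_group(sid)
            for name, arr in bands.items():
                sg.create_dataset(name, data=arr, compression="gzip")
    phenotypes.to_csv(out / "phenotypes.csv", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if mask is not None:
        pd.DataFrame({"reliable": np.asarray(mask).astype(int)}).to_csv(
            out / "mask.csv", index=False
        )


def load_cohort(path) -> CohortSignals:
    """Read a signals.h5 container written by :func:`save_cohort`."""
    with h5py.File(path, "r") as f:
        names = [_as_str(b) for b in f.attrs["band_names"]]
        edges = np.asarray(f.attrs["band_edges"])
        scheme = BandScheme(
            tuple((n, float(lo), float(hi)) for n, (lo, hi) in zip(names, edges))
        )
        subjects = {
            sid: {name: grp[name][()] for name in names}
            for sid, grp in f["subjects"].items()
        }
        return CohortSignals(subjects=subjects, fs=float(f.attrs["fs"]), band_scheme=scheme)
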