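"""End-to-end orchestration: signals -> group tensor -> latent -> CPD ->
selection -> multiplex metrics, with serialized artifacts per stage.

Each stage consumes only the previous stage's artifact, so a run can be
restarted from any intermediate file. A JSON report records shapes,
selected ranks, the CPD order, densities and fitness values per analysis,
and every seed, making the automatic model-order choices auditable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohortsim import load_cohort
from .connectivity import cohort_group_tensor, save_group_tensor
from .latent_nmf import extract_latent
from .cpd_decomposition import subject_cpd, save_subject_cpd
from .selection import select_components
from .multiplex_metrics import build_multiplex, multiplex_metrics, write_graphml

log = logging.getLogger("mdfcn")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (one phenotype subgroup)."""

    signals: str
    phenotypes: str
    mask: str
    out_dir: str
    scores: list[str] = field(default_factory=lambda: ["score"])
    directions: list[str] = field(default_factory=lambda: ["pos", "neg"])
    win_len_s: float = 2.0
    overlap: float = 0.5
    fdr_q: float = 0.05
    density_floor: float = 0.025
    n_perm: int = 10_000
    nmf_rank_cap: int = 40
    cpd_order_cap: int = 20
    exhaustive_cap: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))

    def validate(self) -> None:
        for label in ("signals", "phenotypes", "mask"):
            p = getattr(self, label)
            if not Path(p).exists():
                raise FileNotFoundError(f"[config] {label} file not found: {p}")
        if not 0.0 < self.overlap < 1.0:
            raise ValueError("[config] overlap must lie in (0, 1)")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("[config] fdr_q must lie in (0, 1)")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # re-tag with the failing stage
                raise RuntimeError(f"[stage {name}] {exc}") from exc
            log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the JSON-serializable run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "select").mkdir(exist_ok=True)
    (out / "metrics").mkdir(exist_ok=True)

    report: dict = {"config": asdict(config)}

    phenotypes = pd.read_csv(config.phenotypes)
    mask = pd.read_csv(config.mask)["reliable"].to_numpy(dtype=bool)

    cohort = _stage("load")(load_cohort)(config.signals)

    group = _stage("connectivity")(cohort_group_tensor)(
        cohort, mask, config.win_len_s, config.overlap
    )
    save_group_tensor(out / "group.h5", group)
    report["group_tensor_shape"] = list(group.values.shape)

    latent = _stage("latent")(extract_latent)(
        group, seed=config.seed, rank_cap=config.nmf_rank_cap
    )
    report["nmf_ranks"] = latent.ranks
    report["nmf_rel_errors"] = latent.rel_errors

    model = _stage("cpd")(subject_cpd)(
        latent, seed=config.seed, order_cap=config.cpd_order_cap
    )
    save_subject_cpd(out / "cpd.h5", model)
    report["cpd_order"] = model.R
    report["cpd_fit"] = model.fit

    analyses = []
    metrics_by_analysis = {}
    run_select = _stage("selection")(select_components)
    for score in config.scores:
        for direction in config.directions:
            band_results = []
            for band in range(len(model.band_names)):
                res = run_select(
                    model,
                    phenotypes,
                    score,
                    band,
                    direction=direction,
                    density_floor=config.density_floor,
                    fdr_q=config.fdr_q,
                    max_R=config.exhaustive_cap,
                )
                band_results.append(res)
                _write_edges(out / "select" / f"{score}_{direction}_band{band}.tsv",
                             res, model)
                analyses.append(
                    {
                        "score": score,
                        "direction": direction,
                        "band": band,
                        "subset": list(res.subset),
                        "density": res.density,
                        "mean_abs_rho": res.mean_abs_rho,
                        "mean_r2": res.mean_r2,
                        "fitness": res.fitness,
                        "empty": res.empty,
                        "n_subjects": res.n_subjects,
                    }
                )
            net = build_multiplex(
                band_results, model.mask, _n_parcels(model), model.band_names
            )
            m = multiplex_metrics(net)
            metrics_by_analysis[f"{score}_{direction}"] = m
            write_graphml(out / "metrics" / f"{score}_{direction}.graphml", net)
            _write_metrics(out / "metrics" / f"{score}_{direction}.csv", m)

    report["analyses"] = analyses
    report["seed"] = config.seed
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    return report


def _n_parcels(model) -> int:
    return int(model.pair_index.max()) + 1


def _write_edges(path, res, model) -> None:
    reliable_pairs = model.pair_index[model.mask]
    rows = [
        {
            "i": int(reliable_pairs[c, 0]),
            "j": int(reliable_pairs[c, 1]),
            "band": res.band,
            "rho": float(res.rho[c]),
            "q": float(res.q_values[c]),
            "direction": res.direction,
        }
        for c in res.significant
    ]
    pd.DataFrame(rows, columns=["i", "j", "band", "rho", "q", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def _write_metrics(path, metrics: dict) -> None:
    flat = {}
    for key, val in metrics.items():
        arr = np.atleast_1d(np.asarray(val, dtype=float)).ravel()
        flat[key] = [";".join(f"{v:.6g}" for v in arr)]
    pd.DataFrame(flat).to_csv(path, index=False)
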