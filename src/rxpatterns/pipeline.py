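"""End-to-end orchestration: simulate -> window -> EFA -> assign -> profile.

``run_pipeline`` realises the whole analysis for every period window and
writes a reproducible report bundle: per-period scree table, loadings,
factor correlations, fit indices, salient clusters, memberships, prevalence
and descriptive tables, plus a manifest recording the config hash, seed and
library versions.  Identical config + seed yields a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import assign_members, cluster_prevalence, salient_items
from .correlation import correlation
from .factor import extract, factor_scores, fit_indices
from .parallel import parallel_analysis
from .profiles import (
    DEFAULT_AGE_BANDS,
    demographic_composition,
    disease_prevalence,
    link_diagnoses,
    yearly_visit_counts,
)
from .synthetic import (
    CohortSpec,
    SyntheticDataset,
    default_truth,
    generate_dataset,
    read_dataset,
    write_dataset,
)
from .utils import InvalidSpecError
from .windows import (
    apply_min_support_filter,
    build_matrix,
    polypharmacy_flags,
    truncate_codes,
    windows_from_pairs,
)


@dataclass
class RunConfig:
    """Declarative run description; every analysis threshold is a named key."""

    # data source: either a simulation block or a directory of input CSVs
    simulate: dict | None = None
    input_dir: str | None = None
    # windowing
    windows: tuple = ((0, 5), (5, 10), (10, 15), (15, 20))
    coding: str = "binary"
    min_support: int = 10
    code_prefix_length: int | None = None
    # EFA
    correlation_method: str = "pearson"
    extraction: str = "minres"
    rotation: str = "oblimin"
    n_factors: str | int = "auto"  # "auto" = parallel analysis
    pa_n_sims: int = 100
    pa_percentile: float = 95.0
    # assignment / reporting
    salience_threshold: float = 0.30
    min_drugs: int = 3
    min_meds: int = 3
    top_k_diseases: int = 8
    decimals: int = 2
    category_map: dict = field(default_factory=dict)
    diagnosis_labels: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        if "windows" in raw:
            raw["windows"] = tuple(tuple(w) for w in raw["windows"])
        return cls(**raw)

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise InvalidSpecError("config needs exactly one of `simulate` or `input_dir`")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise InvalidSpecError(f"input_dir {self.input_dir!r} does not exist")
        windows_from_pairs(self.windows)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.md5(blob).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> str:
    return f"# rxpatterns v{__version__} config_hash={cfg.config_hash()} seed={cfg.seed}"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg) + "\n")
        df.to_csv(fh, index=index, lineterminator="\n", float_format="%.10g")


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    payload = {"provenance": {"config_hash": cfg.config_hash(), "seed": cfg.seed}, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def simulate_dataset(cfg: RunConfig) -> SyntheticDataset:
    """Build the synthetic linked extract described by the config's simulate block."""
    sim = dict(cfg.simulate or {})
    truth_kw = sim.pop("truth", {})
    spec = CohortSpec(seed=cfg.seed, periods=cfg.windows, **sim)
    truth = default_truth(spec, **truth_kw)
    return generate_dataset(spec, truth)


def run_pipeline(cfg: RunConfig, out_dir, dataset: SyntheticDataset | None = None) -> dict:
    """Execute the full analysis and write the report bundle under out_dir.

    Returns a summary dict (per-period factor counts, prevalences, fit
    indices) mirroring run_manifest.json.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    run_warnings: list[str] = []

    if dataset is not None:
        patients, med_events, dx_events = dataset.patients, dataset.med_events, dataset.dx_events
    elif cfg.simulate is not None:
        dataset = simulate_dataset(cfg)
        write_dataset(dataset, out / "input_data")
        patients, med_events, dx_events = dataset.patients, dataset.med_events, dataset.dx_events
    else:
        patients, med_events, dx_events = read_dataset(cfg.input_dir)

    med_events = truncate_codes(med_events, cfg.code_prefix_length)
    windows = windows_from_pairs(cfg.windows)
    summary: dict = {"periods": {}}

    for win in windows:
        tag = f"period{win.index}"
        stage = "build_matrix"
        try:
            matrix = build_matrix(med_events, patients, win, coding=cfg.coding)
            flags, poly_pct = polypharmacy_flags(matrix, min_meds=cfg.min_meds)
            matrix, dropped = apply_min_support_filter(matrix, cfg.min_support)
            if dropped:
                log_lines.append(f"{tag}: dropped {len(dropped)} low-support codes: {dropped}")

            stage = "parallel_analysis"
            corr = correlation(matrix, method=cfg.correlation_method)
            pa = parallel_analysis(matrix, n_sims=cfg.pa_n_sims, percentile=cfg.pa_percentile, seed=cfg.seed)
            n_factors = pa.n_factors_suggested if cfg.n_factors == "auto" else int(cfg.n_factors)
            n_factors = max(1, min(n_factors, matrix.shape[1] // 2))
            scree = pd.DataFrame(
                {
                    "component": np.arange(1, len(pa.observed_eigenvalues) + 1),
                    "observed_eigenvalue": pa.observed_eigenvalues,
                    "reference_eigenvalue": pa.reference_eigenvalues,
                }
            )
            _write_csv(scree, out / f"{tag}_scree.csv", cfg)

            stage = "extract"
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = extract(corr, n_factors, method=cfg.extraction, rotation=cfg.rotation)
                fit = fit_indices(model)
                scores = factor_scores(model, matrix)
            run_warnings += [f"{tag}: {w.message}" for w in caught]
            _write_csv(model.loadings_frame(), out / f"{tag}_loadings.csv", cfg, index=True)
            _write_csv(
                pd.DataFrame(
                    model.factor_correlations,
                    index=[f"F{k+1}" for k in range(n_factors)],
                    columns=[f"F{k+1}" for k in range(n_factors)],
                ),
                out / f"{tag}_phi.csv",
                cfg,
                index=True,
            )
            _write_json(
                {
                    "rmsr": fit.rmsr,
                    "rmsea": fit.rmsea,
                    "rmsea_ci90": list(fit.rmsea_ci90),
                    "tli": fit.tli,
                    "tli_x100": fit.tli_x100,
                    "chi_square": fit.chi_square,
                    "dof": fit.dof,
                    "good_fit_rmsea_le_0.05": fit.good_fit,
                    "n_factors": n_factors,
                    "n_factors_suggested": pa.n_factors_suggested,
                    "explained_variance": json.loads(model.explained_variance.to_json()),
                },
                out / f"{tag}_fit.json",
                cfg,
            )
            score_df = pd.DataFrame(
                scores, columns=[f"F{k+1}" for k in range(n_factors)]
            ).assign(patient_id=matrix.patient_ids)
            _write_csv(
                score_df[["patient_id"] + [f"F{k+1}" for k in range(n_factors)]],
                out / f"{tag}_scores.csv",
                cfg,
            )

            stage = "assign_members"
            sets = salient_items(model, threshold=cfg.salience_threshold)
            assignment = assign_members(matrix, sets, min_drugs=cfg.min_drugs)
            clusters = pd.DataFrame(
                [
                    {"period": win.index, "factor": s.factor_index, "medication_code": c, "loading": l}
                    for s in sets
                    for c, l in zip(s.medication_codes, s.loadings)
                ]
            )
            _write_csv(clusters, out / f"{tag}_clusters.csv", cfg)
            membership = pd.DataFrame(
                [
                    {"period": win.index, "factor": f, "patient_id": pid}
                    for f, mem in sorted(assignment.members.items())
                    for pid in sorted(mem)
                ]
            )
            _write_csv(membership, out / f"{tag}_membership.csv", cfg)
            prev = cluster_prevalence(assignment, decimals=cfg.decimals)
            _write_csv(prev, out / f"{tag}_prevalence.csv", cfg)

            stage = "profiles"
            linked = link_diagnoses(assignment, dx_events, patients, win)
            table2 = disease_prevalence(
                linked, assignment.sizes(), top_k=cfg.top_k_diseases,
                decimals=cfg.decimals, labels=cfg.diagnosis_labels,
            )
            _write_csv(table2, out / f"{tag}_table2.csv", cfg)
            table1 = demographic_composition(assignment, patients, DEFAULT_AGE_BANDS, decimals=cfg.decimals)
            _write_csv(table1, out / f"{tag}_table1.csv", cfg)

            summary["periods"][win.index] = {
                "cohort_size": assignment.cohort_size,
                "n_medications": matrix.shape[1],
                "polypharmacy_prevalence_pct": poly_pct,
                "n_factors": n_factors,
                "n_factors_suggested": pa.n_factors_suggested,
                "rmsr": fit.rmsr,
                "rmsea": fit.rmsea,
                "tli_x100": fit.tli_x100,
                "cluster_prevalence_pct": {
                    int(r.factor): float(r.prevalence_pct) for r in prev.itertuples()
                },
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed for period {win.index}: {exc}") from exc

    if cfg.category_map:
        visits = yearly_visit_counts(med_events, patients, cfg.category_map, "medication_code")
        _write_csv(visits, out / "visits_by_year.csv", cfg)

    (out / "run.log").write_text("\n".join(log_lines) + ("\n" if log_lines else ""))
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "rxpatterns": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "warnings": run_warnings,
        "summary": summary,
    }
    _write_json(manifest, out / "run_manifest.json", cfg)
    return summary
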