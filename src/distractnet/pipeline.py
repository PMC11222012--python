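"""End-to-end orchestration: simulate/ingest -> preprocess -> connectivity ->
topology -> features -> classify -> stats, from a single config.

Each stage consumes only the outputs of the previous stage, so stages are
independently re-runnable; ``run`` chains them and writes a deterministic
artifact directory::

    outdir/
      cohort/            epoch matrices + manifest (synthetic runs)
      matrices/          per-state mean connectivity matrices (+ sidecars)
      features.tsv       the per-epoch feature table
      sweeps/            per-(estimator, band) sweep validation TSVs
      reports/           classification reports (JSON) + ROC curves (TSV)
      contrasts/         ANOVA contrast tables and difference-map edge lists
      provenance.json    config hash, package version, seeds

Rerunning with the same config reproduces byte-identical feature tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

import distractnet
from distractnet.bands import BAND_ORDER, CANONICAL_BANDS
from distractnet.connectivity import (
    ESTIMATORS,
    ConnectivityMatrix,
    SLParams,
    SpectralParams,
    coh_matrix,
    plv_matrix,
    sl_matrix,
)
from distractnet.io import (
    read_cohort,
    read_cohort_spec,
    write_cohort,
    write_matrix,
)
from distractnet.preprocessing import LabeledEpoch, bandpass, decompose_bands
from distractnet.recognition import (
    CLASSIFIERS,
    build_feature_table,
    feature_importance,
    train_evaluate,
)
from distractnet.stats import contrast_table, difference_top_k
from distractnet.synthetic import CohortSpec, generate_cohort
from distractnet.topology import SparsitySweep, TopologyProfile, sweep_and_validate, topology_profile

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: Path
    synthetic: CohortSpec | None = None
    manifest: Path | None = None
    estimators: tuple[str, ...] = ESTIMATORS
    bands: tuple[str, ...] = BAND_ORDER
    decomposition: str = "wavelet"
    apply_bandpass: bool = False  # synthetic cohorts are already band-limited
    sl_params: SLParams = field(default_factory=SLParams)
    spectral_params: SpectralParams = field(default_factory=SpectralParams)
    sweep: SparsitySweep = field(default_factory=SparsitySweep)
    classifiers: tuple[str, ...] = ("gboost",)
    tasks: tuple[str, ...] = ("binary", "ternary")
    split: str = "epoch"
    seed: int = 0
    validate_sweep: bool = False
    write_epoch_matrices: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.synthetic is None) == (self.manifest is None):
            raise ValueError("exactly one of synthetic spec or manifest must be given")
        if self.manifest is not None and not Path(self.manifest).exists():
            raise ValueError(f"manifest {self.manifest} does not exist")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimator(s) {sorted(unknown)}; choose from {ESTIMATORS}")
        unknown = set(self.bands) - set(CANONICAL_BANDS)
        if unknown:
            raise ValueError(f"unknown band(s) {sorted(unknown)}")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifier(s) {sorted(unknown)}; choose from {CLASSIFIERS}")
        if self.decomposition not in ("wavelet", "fir"):
            raise ValueError(f"unknown decomposition {self.decomposition!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {"outdir": Path(raw.pop("outdir"))}
        if "synthetic" in raw:
            spec = raw.pop("synthetic")
            if isinstance(spec, str):
                kwargs["synthetic"] = read_cohort_spec(spec)
            else:
                from distractnet.io import StateCouplingSpec  # noqa: F401

                kwargs["synthetic"] = _cohort_spec_from_dict(spec)
        if "manifest" in raw:
            kwargs["manifest"] = Path(raw.pop("manifest"))
        for key in ("sl_params",):
            if key in raw:
                kwargs[key] = SLParams(**raw.pop(key))
        if "spectral_params" in raw:
            kwargs["spectral_params"] = SpectralParams(**raw.pop("spectral_params"))
        if "sweep" in raw:
            kwargs["sweep"] = SparsitySweep(**raw.pop("sweep"))
        for key in ("estimators", "bands", "classifiers", "tasks"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cohort_spec_from_dict(d: Mapping) -> CohortSpec:
    from distractnet.synthetic import StateCouplingSpec

    d = dict(d)
    specs = {}
    for k, v in d.pop("state_specs", {}).items():
        v = dict(v)
        if v.get("coupled_groups") is not None:
            v["coupled_groups"] = tuple(tuple(g) for g in v["coupled_groups"])
        specs[k] = StateCouplingSpec(**v)
    if specs:
        d["state_specs"] = specs
    return CohortSpec(**d)


def epoch_connectivity(
    epoch: LabeledEpoch,
    estimators: Sequence[str] = ESTIMATORS,
    bands: Sequence[str] = BAND_ORDER,
    sl_params: SLParams | None = None,
    spectral_params: SpectralParams | None = None,
) -> dict[tuple[str, str], ConnectivityMatrix]:
    """All (estimator, band) connectivity matrices of one decomposed epoch."""
    if not epoch.bands:
        raise ValueError("epoch has no band decomposition; run decompose_bands first")
    out: dict[tuple[str, str], ConnectivityMatrix] = {}
    for band in bands:
        sig = epoch.bands[band]
        for est in estimators:
            if est == "SL":
                out[(est, band)] = sl_matrix(sig, sl_params, epoch.channels, band)
            elif est == "PLV":
                out[(est, band)] = plv_matrix(sig, epoch.channels, band)
            else:
                out[(est, band)] = coh_matrix(
                    sig, epoch.fs, CANONICAL_BANDS[band], spectral_params, epoch.channels
                )
    return out


def extract_features(
    epochs: Sequence[LabeledEpoch],
    estimators: Sequence[str] = ESTIMATORS,
    bands: Sequence[str] = BAND_ORDER,
    sl_params: SLParams | None = None,
    spectral_params: SpectralParams | None = None,
    sweep: SparsitySweep | None = None,
    decomposition: str = "wavelet",
    collect_matrices: bool = False,
    matrix_sink=None,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], np.ndarray]]:
    """Decompose epochs, compute connectivity and topology, assemble features.

    Returns the feature table and, when requested, running per-state mean
    connectivity matrices keyed (state, estimator, band) for the stats stage.
    ``matrix_sink(epoch, matrices)`` is called with every epoch's matrix map
    when given (used to serialize per-epoch matrices).
    """
    sweep = sweep or SparsitySweep()
    profiles: list[tuple[LabeledEpoch, dict[tuple[str, str], TopologyProfile]]] = []
    sums: dict[tuple[str, str, str], np.ndarray] = {}
    counts: dict[str, int] = {}
    for ep in epochs:
        if not ep.bands:
            decompose_bands(ep, method=decomposition)
        mats = epoch_connectivity(ep, estimators, bands, sl_params, spectral_params)
        if matrix_sink is not None:
            matrix_sink(ep, mats)
        prof = {key: topology_profile(m, sweep) for key, m in mats.items()}
        profiles.append((ep, prof))
        if collect_matrices:
            counts[ep.state] = counts.get(ep.state, 0) + 1
            for (est, band), m in mats.items():
                key = (ep.state, est, band)
                sums[key] = sums.get(key, 0) + m.values
        ep.bands = {}  # free band arrays once consumed
    table = build_feature_table(profiles, estimators, bands)
    means = {
        (st, est, band): total / counts[st]
        for (st, est, band), total in sums.items()
    }
    return table, means


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    t_start = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.time()
    if config.synthetic is not None:
        epochs = generate_cohort(config.synthetic)
        write_cohort(epochs, out / "cohort")
    else:
        epochs = read_cohort(config.manifest)
    timings["ingest"] = time.time() - t0
    logger.info("stage ingest: %d epochs (%.1fs)", len(epochs), timings["ingest"])

    t0 = time.time()
    if config.apply_bandpass:
        for ep in epochs:
            rec = bandpass(ep.as_recording())
            ep.samples = rec.samples
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    sink = None
    if config.write_epoch_matrices:
        def sink(ep, mats):  # noqa: E306 - per-epoch matrix serializer
            for (est, band), m in mats.items():
                name = f"sub{ep.subject:02d}_{ep.state}_ep{ep.epoch_index:03d}_{est}_{band}.tsv"
                write_matrix(m, mat_dir / name)

    table, means = None, {}
    try:
        table, means = extract_features(
            epochs,
            config.estimators,
            config.bands,
            config.sl_params,
            config.spectral_params,
            config.sweep,
            config.decomposition,
            collect_matrices=True,
            matrix_sink=sink,
        )
    except Exception as exc:
        raise RuntimeError(f"stage connectivity/topology failed: {exc}") from exc
    timings["features"] = time.time() - t0
    table.to_csv(out / "features.tsv", sep="\t", index=False, float_format="%.10g")
    logger.info("stage features: %s table (%.1fs)", table.shape, timings["features"])

    for (st, est, band), values in means.items():
        np.fill_diagonal(values, 0.0)
        mat = ConnectivityMatrix(np.clip(values, 0, 1), est, band)
        write_matrix(mat, mat_dir / f"mean_{st}_{est}_{band}.tsv")

    if config.validate_sweep:
        t0 = time.time()
        sweep_dir = out / "sweeps"
        sweep_dir.mkdir(exist_ok=True)
        for (st, est, band), values in means.items():
            pts = sweep_and_validate(
                ConnectivityMatrix(np.clip(values, 0, 1), est, band),
                config.sweep,
                seed=config.seed,
            )
            pd.DataFrame(
                [
                    {
                        "sparsity": p.sparsity,
                        "mean_degree": p.mean_degree,
                        "degree_ok": p.degree_ok,
                        "sigma": p.sigma,
                        "sigma_ok": p.sigma_ok,
                    }
                    for p in pts
                ]
            ).to_csv(sweep_dir / f"sweep_{st}_{est}_{band}.tsv", sep="\t", index=False)
        timings["sweep_validation"] = time.time() - t0

    t0 = time.time()
    rep_dir = out / "reports"
    rep_dir.mkdir(exist_ok=True)
    for task in config.tasks:
        for clf in config.classifiers:
            report = train_evaluate(
                table, task=task, classifier=clf, seed=config.seed, split=config.split
            )
            blob = {
                "task": report.task,
                "classifier": report.classifier,
                "classes": report.classes,
                "cv_accuracy": report.cv_accuracy,
                "cv_scores": report.cv_scores.tolist(),
                "test_accuracy": report.test_accuracy,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
                "confusion": report.confusion.tolist(),
                "roc_auc": report.roc_auc,
                "cv_config": report.cv_config,
            }
            if clf in ("rf", "gboost"):
                imp = feature_importance(report)
                blob["importance_top10"] = imp.ranking.head(10).to_dict("records")
                blob["estimator_share"] = imp.estimator_share
                blob["band_share"] = imp.band_share
            (rep_dir / f"{task}_{clf}.json").write_text(json.dumps(blob, indent=1))
            for cname, (fpr, tpr) in report.roc_curves.items():
                pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                    rep_dir / f"{task}_{clf}_roc_{cname}.tsv", sep="\t", index=False
                )
    timings["classify"] = time.time() - t0

    t0 = time.time()
    con_dir = out / "contrasts"
    con_dir.mkdir(exist_ok=True)
    strength_cols = [c for c in table.columns if c.endswith("_V")]
    contrasts = contrast_table(table, columns=strength_cols)
    contrasts.to_csv(con_dir / "strength_anova.tsv", sep="\t", index=False)
    topo_cols = [c for c in table.columns if not c.endswith("_V") and c not in ("state", "subject", "epoch")]
    contrast_table(table, columns=topo_cols).to_csv(
        con_dir / "topology_anova.tsv", sep="\t", index=False
    )
    for est in config.estimators:
        for band in config.bands:
            for st in ("cognitive", "visual"):
                key_a, key_b = (st, est, band), ("normal", est, band)
                if key_a in means and key_b in means:
                    dm = difference_top_k(means[key_a], means[key_b])
                    stem = f"diff_{st}_minus_normal_{est}_{band}"
                    dm.edge_list().to_csv(
                        con_dir / f"{stem}.tsv", sep="\t", index=False
                    )
                    np.savetxt(
                        con_dir / f"{stem}_matrix.tsv",
                        dm.difference,
                        delimiter="\t",
                        fmt="%.10g",
                    )
    timings["stats"] = time.time() - t0

    provenance = {
        "package_version": distractnet.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_epochs": len(epochs),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 2),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out
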