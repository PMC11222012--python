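"""Readers and writers for the pipeline's on-disk formats.

Connectivity matrices travel as square tab-delimited text with a JSON
sidecar recording estimator, band, channel labels and parameters; cohorts
as one numeric matrix file per epoch plus a TSV manifest (subject, state,
epoch, path, fs); annotations as TSV (onset_s, duration_s, state).  EDF
recordings are read through MNE when it is installed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from distractnet.connectivity import ConnectivityMatrix
from distractnet.preprocessing import Annotation, LabeledEpoch, Recording
from distractnet.synthetic import CohortSpec, StateCouplingSpec


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, mat.values, delimiter="\t", fmt="%.10g")
    sidecar = {
        "estimator": mat.estimator,
        "band": mat.band,
        "channels": mat.channels,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a matrix + sidecar; symmetry and bounds are re-validated."""
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ConnectivityMatrix(values, meta["estimator"], meta["band"], meta.get("channels", []))


def write_cohort(epochs: Sequence[LabeledEpoch], outdir: str | Path) -> Path:
    """Write one matrix file per epoch plus a TSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ep in epochs:
        name = f"sub{ep.subject:02d}_{ep.state}_ep{ep.epoch_index:03d}.tsv"
        np.savetxt(outdir / name, ep.samples, delimiter="\t", fmt="%.8g")
        rows.append(
            {
                "subject": ep.subject,
                "state": ep.state,
                "epoch": ep.epoch_index,
                "path": name,
                "fs": ep.fs,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest: str | Path) -> list[LabeledEpoch]:
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    epochs = []
    for row in table.itertuples():
        samples = np.atleast_2d(np.loadtxt(manifest.parent / row.path, delimiter="\t"))
        epochs.append(
            LabeledEpoch(
                samples,
                float(row.fs),
                str(row.state),
                subject=int(row.subject),
                epoch_index=int(row.epoch),
            )
        )
    return epochs


def read_annotations(path: str | Path) -> list[Annotation]:
    table = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "state"}
    if not required <= set(table.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    return [
        Annotation(float(r.onset_s), float(r.duration_s), str(r.state))
        for r in table.itertuples()
    ]


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["state_specs"] = {
        k: dataclasses.asdict(v) for k, v in spec.state_specs.items()
    }
    return d


def write_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    path = Path(path)
    text = (
        yaml.safe_dump(_spec_to_dict(spec), sort_keys=False)
        if path.suffix in (".yaml", ".yml")
        else json.dumps(_spec_to_dict(spec), indent=1)
    )
    path.write_text(text)


def read_cohort_spec(path: str | Path) -> CohortSpec:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    state_specs = {}
    for k, v in raw.pop("state_specs", {}).items():
        v = dict(v)
        if v.get("coupled_groups") is not None:
            v["coupled_groups"] = tuple(tuple(g) for g in v["coupled_groups"])
        state_specs[k] = StateCouplingSpec(**v)
    return CohortSpec(state_specs=state_specs, **raw)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF recording through MNE (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install distractnet[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names))
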