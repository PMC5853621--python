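"""Plain-text serialisation of pipeline artifacts.

Runs are tab-separated T x N matrices with a JSON metadata sidecar;
parcellations, masks and metric tables are TSV; binary networks are Matrix
Market sparse files; ground truth and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .connectome import BinaryNetwork
from .containers import ConfoundSet, Parcellation, RunSeries
from .synth import Cohort, CohortSpec, GroundTruth

__all__ = [
    "run_basename",
    "write_run",
    "read_run",
    "write_confounds",
    "read_confounds",
    "write_parcellation",
    "read_parcellation",
    "write_cohort",
    "read_cohort",
    "write_binary_network",
    "read_binary_network",
]


def run_basename(subject: str, state: str, encoding: str) -> str:
    return f"{subject}_{state}_{encoding}"


def write_run(run: RunSeries, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = run_basename(run.subject, run.state, run.encoding)
    path = out_dir / f"{base}.tsv"
    np.savetxt(path, run.data, delimiter="\t", fmt="%.10g")
    meta = {
        "subject": run.subject,
        "state": run.state,
        "encoding": run.encoding,
        "tr": run.tr,
        "n_timepoints": run.n_timepoints,
        "n_roi": run.n_roi,
    }
    (out_dir / f"{base}.json").write_text(json.dumps(meta, indent=1))
    return path


def read_run(path: Path) -> RunSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.loadtxt(path, delimiter="\t")
    return RunSeries(
        data=data,
        tr=meta["tr"],
        subject=meta["subject"],
        state=meta["state"],
        encoding=meta["encoding"],
    )


def write_confounds(conf: ConfoundSet, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(conf.columns, columns=conf.names).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_confounds(path: Path) -> ConfoundSet:
    frame = pd.read_csv(path, sep="\t")
    return ConfoundSet(columns=frame.to_numpy(), names=list(frame.columns))


def write_parcellation(parc: Parcellation, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parc.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_parcellation(path: Path) -> Parcellation:
    return Parcellation.from_frame(pd.read_csv(path, sep="\t"))


def write_cohort(cohort: Cohort, out_dir: Path) -> Path:
    """Write every run, confound table, the parcellation, covariates and
    ground truth of a cohort under ``out_dir``."""
    out_dir = Path(out_dir)
    runs_dir = out_dir / "runs"
    conf_dir = out_dir / "confounds"
    for run in cohort.runs:
        write_run(run, runs_dir)
    for key, conf in cohort.confounds.items():
        write_confounds(conf, conf_dir / f"{run_basename(*key)}.tsv")
    write_parcellation(cohort.parcellation, out_dir / "parcellation.tsv")
    cohort.covariates.to_csv(out_dir / "covariates.tsv", sep="\t", index=False)
    truth = {
        "communities": {s: v.tolist() for s, v in cohort.truth.communities.items()},
        "act_mask": {
            t: v.astype(int).tolist() for t, v in cohort.truth.act_mask.items()
        },
        "task_regressors": {
            t: v.tolist() for t, v in cohort.truth.task_regressors.items()
        },
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth))
    (out_dir / "cohort_spec.json").write_text(
        json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(cohort.spec).items()},
            indent=1,
        )
    )
    return out_dir


def read_cohort(out_dir: Path) -> Cohort:
    out_dir = Path(out_dir)
    spec_dict = json.loads((out_dir / "cohort_spec.json").read_text())
    for key in ("states", "encodings"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = CohortSpec(**spec_dict)
    truth_raw = json.loads((out_dir / "ground_truth.json").read_text())
    truth = GroundTruth(
        communities={
            s: np.asarray(v, dtype=int)
            for s, v in truth_raw["communities"].items()
        },
        act_mask={
            t: np.asarray(v, dtype=bool) for t, v in truth_raw["act_mask"].items()
        },
        task_regressors={
            t: np.asarray(v, dtype=float)
            for t, v in truth_raw["task_regressors"].items()
        },
    )
    runs, confounds = [], {}
    for subject in spec.subjects:
        for state in spec.states:
            for encoding in spec.encodings:
                base = run_basename(subject, state, encoding)
                runs.append(read_run(out_dir / "runs" / f"{base}.tsv"))
                confounds[(subject, state, encoding)] = read_confounds(
                    out_dir / "confounds" / f"{base}.tsv"
                )
    return Cohort(
        spec=spec,
        parcellation=read_parcellation(out_dir / "parcellation.tsv"),
        truth=truth,
        runs=runs,
        confounds=confounds,
        covariates=pd.read_csv(out_dir / "covariates.tsv", sep="\t"),
    )


def write_binary_network(net: BinaryNetwork, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(path), sparse.coo_matrix(net.adjacency),
        comment=f"subject={net.subject} state={net.state} density={net.density}",
    )
    return path


def read_binary_network(path: Path, density: float | None = None) -> BinaryNetwork:
    mat = spio.mmread(str(path)).toarray()
    if density is None:
        n = mat.shape[0]
        density = float(np.triu(mat, 1).sum() / (n * (n - 1) / 2))
    return BinaryNetwork(adjacency=mat, density=density)
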