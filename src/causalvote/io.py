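"""Experiment manifests and on-disk interchange.

A suite lives on disk as a YAML manifest plus one CSV per experiment
(comma-separated, UTF-8, header row of variable names, cells are level
labels)::

    experiments:
      - id: obs1
        path: obs1.csv
        targets: []
      - id: int1
        path: int1.csv
        targets: [either]
    domain:            # optional; inferred from the data when absent
      visit: ["no", "yes"]

Domains are inferred as the union of observed levels across *all*
experiments (sorted lexicographically) so that count-table shapes agree
across experiments even when a clamped variable never shows some level.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (
    CategoricalDomain,
    ExperimentDataset,
    ExperimentSuite,
    dag_to_dot,
    write_dag,
)
from .vote import ConsensusNetwork

__all__ = ["read_suite", "write_suite", "write_outputs"]


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed CSV {path}: {exc}") from exc
    if frame.empty:
        raise ValueError(f"empty dataset: {path}")
    return frame


def read_suite(manifest_path) -> ExperimentSuite:
    """Load a suite from a YAML manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "experiments" not in manifest:
        raise ValueError(f"manifest {manifest_path} lacks an 'experiments' list")
    entries = manifest["experiments"]
    ids = [str(e["id"]) for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("experiment ids must be unique")
    tables = []
    for entry in entries:
        path = manifest_path.parent / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"dataset file not found: {path}")
        tables.append(_read_csv(path))
    declared = manifest.get("domain")
    if declared:
        domain = CategoricalDomain({v: tuple(lv) for v, lv in declared.items()})
    else:
        domain = CategoricalDomain.infer(tables)
    experiments = []
    for entry, table in zip(entries, tables):
        targets = [str(t) for t in entry.get("targets", [])]
        for t in targets:
            if t not in domain.variables:
                raise ValueError(
                    f"experiment {entry['id']!r} declares target {t!r} "
                    f"which is not a variable of the suite"
                )
        experiments.append(
            ExperimentDataset(
                str(entry["id"]), table, domain, declared_targets=targets
            )
        )
    return ExperimentSuite(experiments)


def write_suite(suite: ExperimentSuite, out_dir, truth=None, plans=None) -> Path:
    """Write per-experiment CSVs plus a manifest; returns the manifest path.

    ``truth`` (a Dag) and ``plans`` (hidden intervention plans) are
    oracle-only artifacts written alongside when given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for exp in suite:
        fname = f"{exp.experiment_id}.csv"
        exp.table.to_csv(out_dir / fname, index=False)
        entries.append(
            {
                "id": exp.experiment_id,
                "path": fname,
                "targets": sorted(exp.declared_targets),
            }
        )
    manifest = {
        "experiments": entries,
        "domain": {v: list(suite.domain.levels(v)) for v in suite.domain.variables},
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    if truth is not None:
        write_dag(truth, out_dir / "truth.tsv")
    if plans is not None:
        payload = [
            None
            if p is None
            else {
                "primary_target": p.primary_target,
                "clamp_value": p.clamp_value,
                "fat_hand": dict(p.fat_hand),
            }
            for p in plans
        ]
        # oracle-only file: records the hidden off-target clamps that the
        # learner must never see
        with open(out_dir / "hidden_plans.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    return manifest_path


def write_outputs(consensus: ConsensusNetwork, out_dir, run_config: dict | None = None) -> dict:
    """Write consensus DAG, arc tables and a machine-readable run manifest.

    Everything needed to re-run bit-identically (config values, seeds,
    package version, skipped arcs) lands in ``run.json``.  Returns the
    mapping of artifact names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    write_dag(consensus.dag, out_dir / "consensus.tsv")
    files["consensus"] = "consensus.tsv"
    (out_dir / "consensus.dot").write_text(dag_to_dot(consensus.dag), encoding="utf-8")
    files["dot"] = "consensus.dot"

    consensus.averaged_table.to_frame().to_csv(out_dir / "arcs_averaged.csv", index=False)
    files["averaged_table"] = "arcs_averaged.csv"
    for i, table in enumerate(consensus.per_experiment_tables, start=1):
        name = f"arcs_experiment_{i}.csv"
        table.to_frame().to_csv(out_dir / name, index=False)
        files[f"table_{i}"] = name

    run = {
        "version": __version__,
        "config": run_config or {},
        "skipped_arcs": [
            {"from": u, "to": v, "prob": p, "reason": reason}
            for u, v, p, reason in consensus.skipped_arcs
        ],
        "never_observable": sorted(
            list(pair) for pair in consensus.averaged_table.never_observable
        ),
        "n_consensus_arcs": len(consensus.dag.edges),
        "files": files,
    }
    with open(out_dir / "run.json", "w", encoding="utf-8") as fh:
        json.dump(run, fh, indent=2, sort_keys=True)
    files["run"] = "run.json"
    return files
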