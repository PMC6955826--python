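"""End-to-end run: time-courses -> FNC -> graph measures -> group tests.

``run_pipeline`` is a pure function of (input files, configuration,
seeds): per subject it assembles the connectivity matrix and its nodal
measures, stacks everything into a tidy table, runs the between-group
Welch comparisons, writes all tables, and returns a structured run
report (library versions, seeds, parameters, output paths).
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .exceptions import InvalidArgumentError, SchemaError
from .groupstats import compare_groups
from .io import read_timecourses, write_table
from .network import (
    FNCMatrix,
    SurrogateEdgeRule,
    build_fnc,
    compute_metrics,
    metrics_to_records,
)
from .synthetic import generate_cohort
from .timecourses import TimeCourseSet

__all__ = ["run_pipeline", "fnc_edge_records"]


def _versions() -> dict[str, str]:
    out = {}
    for pkg in ("fnconn", "numpy", "scipy", "pandas", "networkx", "scikit-learn"):
        try:
            out[pkg] = version(pkg)
        except PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out


def _load_subjects(input_dir: Path) -> list[TimeCourseSet]:
    files = sorted(input_dir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no *.tsv time-course files in {input_dir}")
    subjects = []
    for f in files:
        tcs = read_timecourses(f)
        tcs.meta.setdefault("subject", f.stem)
        if "group" not in tcs.meta:
            raise SchemaError(f"{f}: sidecar must name the subject's group")
        subjects.append(tcs)
    return subjects


def _collect_subjects(config: PipelineConfig) -> list[TimeCourseSet]:
    if config.input_dir is not None:
        return _load_subjects(Path(config.input_dir))
    if config.cohort is None:
        raise InvalidArgumentError("config needs either a cohort or an input_dir")
    cohort = generate_cohort(config.cohort.build())
    return [tcs for group in sorted(cohort) for tcs in cohort[group]]


def fnc_edge_records(fnc: FNCMatrix) -> pd.DataFrame:
    """Long-format edge table of one FNC matrix (upper triangle)."""
    rows = []
    base = {k: fnc.meta.get(k) for k in ("subject", "group") if k in fnc.meta}
    for i in range(fnc.n_nodes):
        for j in range(i + 1, fnc.n_nodes):
            rows.append(
                {
                    **base,
                    "rsn_i": fnc.labels[i],
                    "rsn_j": fnc.labels[j],
                    "dcor": fnc.weights[i, j],
                    "lag": int(fnc.lags[i, j]) if fnc.lags is not None else 0,
                    "p": float(fnc.pvalues[i, j]) if fnc.pvalues is not None else np.nan,
                    "retained": bool(fnc.retained[i, j]),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Writes ``metrics.tsv`` (one row per subject x node-or-average x
    measure), ``fnc_edges.tsv`` (one row per subject x network pair) and
    ``comparisons.tsv`` (one row per measure x node x group pair) under
    ``config.output_dir``, plus ``report.json``; returns the report.
    """
    subjects = _collect_subjects(config)
    labels0 = subjects[0].labels
    for tcs in subjects[1:]:
        if tcs.labels != labels0:
            raise SchemaError(
                f"inconsistent component labels across subjects "
                f"({tcs.meta.get('subject', '?')})"
            )

    rule = config.analysis.edge_rule.build()
    metrics_frames, edge_frames = [], []
    for k, tcs in enumerate(subjects):
        subject_rule = rule
        if isinstance(rule, SurrogateEdgeRule):
            # per-subject surrogate seed, reproducible from the config seed
            sub_seed = int(
                np.random.SeedSequence(entropy=rule.seed, spawn_key=(k,)).generate_state(1)[0]
                % (2**31)
            )
            subject_rule = SurrogateEdgeRule(
                alpha=rule.alpha, n_surrogates=rule.n_surrogates, seed=sub_seed
            )
        fnc = build_fnc(tcs, max_lag=config.analysis.max_lag, edge_rule=subject_rule)
        edge_frames.append(fnc_edge_records(fnc))
        metrics_frames.append(metrics_to_records(compute_metrics(fnc)))

    metrics = pd.concat(metrics_frames, ignore_index=True)
    edges = pd.concat(edge_frames, ignore_index=True)
    comparisons = compare_groups(
        metrics,
        pairs=tuple(config.analysis.pairs),
        alpha=config.analysis.alpha,
        family=config.analysis.bonferroni_family,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": str(write_table(metrics, out / "metrics.tsv")),
        "fnc_edges": str(write_table(edges, out / "fnc_edges.tsv")),
        "comparisons": str(write_table(comparisons, out / "comparisons.tsv")),
    }
    report = {
        "versions": _versions(),
        "config": config.model_dump(),
        "n_subjects": len(subjects),
        "groups": sorted({t.meta.get("group") for t in subjects}),
        "outputs": paths,
        "n_significant": int(comparisons["significant"].sum()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
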