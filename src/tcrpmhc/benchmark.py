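"""Leave-one-out benchmarking, method comparison, and summaries.

For every structure in a template database, the structure is removed
from the candidate pool and modelled from the remaining templates; the
model is then evaluated against the held-out native.  Four identity caps
(99.9%, 95%, 90% and 80%) generate models of decreasing template
similarity, so accuracy can be read as a function of how close the best
available template is.  A target with no surviving candidate at some cap
is recorded as SKIPPED and excluded from medians and comparisons.

Method comparisons use the two-sided Wilcoxon signed-rank test on paired
per-target metric values (scipy's implementation; ties between the two
methods are discarded, the standard zero-handling convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    InsufficientDataError,
    Kind,
    NoTemplateError,
    TcrPmhcError,
)
from .builder import ModellingJob, Stage, graft_build
from .metrics import evaluate_model
from .selection import (
    Method,
    SelectionConfig,
    default_scheme,
    query_from_entry,
    select_templates,
)
from .templatedb import TemplateDB

__all__ = [
    "LOO_THRESHOLDS",
    "LooRecord",
    "ComparisonResult",
    "loo_run",
    "compare_methods",
    "summarize",
    "records_to_frame",
]

#: the four leave-one-out identity caps
LOO_THRESHOLDS = (0.999, 0.95, 0.90, 0.80)

_STAGE_FOR_KIND = {
    Kind.PMHC: Stage.PMHC,
    Kind.TCR: Stage.TCR,
    Kind.TCRPMHC: Stage.ASSEMBLY,
}


@dataclass
class LooRecord:
    """One (target, threshold, method) leave-one-out outcome."""

    target_id: str
    threshold: float | None
    method: Method
    status: str = "OK"
    n_candidates_after_cap: int = 0
    chosen: list[str] = field(default_factory=list)
    metrics: dict[str, float | str] = field(default_factory=dict)
    seed: int = 0

    def as_row(self) -> dict:
        row = {
            "target_id": self.target_id,
            "threshold": self.threshold,
            "method": str(self.method),
            "status": self.status,
            "n_candidates_after_cap": self.n_candidates_after_cap,
            "chosen": ";".join(self.chosen),
            "seed": self.seed,
        }
        row.update(self.metrics)
        return row


@dataclass
class ComparisonResult:
    """Paired Wilcoxon signed-rank comparison between two methods."""

    method_a: Method
    method_b: Method
    metric: str
    statistic: float
    p_value: float
    n_pairs: int
    median_a: float
    median_b: float
    degenerate: bool = False
    zero_handling: str = "wilcox (discard zero differences)"

    def as_dict(self) -> dict:
        return {
            "method_a": str(self.method_a),
            "method_b": str(self.method_b),
            "metric": self.metric,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "degenerate": self.degenerate,
            "zero_handling": self.zero_handling,
        }


def _derived_seed(base: int, *indices: int) -> int:
    """Deterministic sub-seed below 2**31 for one LOO cell."""
    ss = np.random.SeedSequence([base, *indices])
    return int(ss.generate_state(1)[0] % (2**31))


def loo_run(
    db: TemplateDB,
    thresholds: Sequence[float | None] = LOO_THRESHOLDS,
    methods: Sequence[Method | str] = (Method.MULTI_WEIGHTED,),
    seed: int = 0,
) -> list[LooRecord]:
    """Leave-one-out over every entry in a database.

    Each target is modelled in a single comparative stage against its own
    database (pMHC databases yield pMHC models, complex databases yield
    full-complex models) and evaluated against the held-out native.
    Per-record failures never abort the run; they surface as SKIPPED
    records with the reason in ``metrics["reason"]``.
    """
    if len(db) == 0:
        raise NoTemplateError("database is empty")
    methods = [Method(m) for m in methods]
    stage = _STAGE_FOR_KIND[db.kind]
    scheme = default_scheme(db.kind)
    records: list[LooRecord] = []
    for t_idx, target_id in enumerate(db.ids()):
        entry = db.entries[target_id]
        native = entry.structure
        query = query_from_entry(entry)
        for th_idx, threshold in enumerate(thresholds):
            for m_idx, method in enumerate(methods):
                cell_seed = _derived_seed(seed, t_idx, th_idx, m_idx)
                config = SelectionConfig(
                    method=method,
                    identity_cap=threshold,
                    seed=cell_seed,
                )
                record = LooRecord(
                    target_id=target_id,
                    threshold=threshold,
                    method=method,
                    seed=cell_seed,
                )
                try:
                    selection = select_templates(
                        query, db, config, scheme=scheme, exclude=[target_id]
                    )
                    record.n_candidates_after_cap = len(selection.ranked)
                    record.chosen = list(selection.chosen)
                    job = ModellingJob(
                        target_sequences=native.sequences(),
                        stage=stage,
                        selection=selection,
                        templates={
                            cid: db.entries[cid] for cid in selection.chosen
                        },
                        profiles=db.profiles,
                        model_id=f"{target_id}_loo",
                        target_alignments=dict(entry.alignments),
                    )
                    model = graft_build(job)
                    record.metrics = evaluate_model(model.structure, native)
                except TcrPmhcError as exc:
                    record.status = "SKIPPED"
                    record.metrics = {"reason": str(exc)}
                records.append(record)
    return records


def records_to_frame(records: Sequence[LooRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def compare_methods(
    records: Sequence[LooRecord],
    method_a: Method | str,
    method_b: Method | str,
    metric: str = "tcr_pmhc_rmsd",
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-target values.

    Records are paired on (target, threshold); targets modelled by only
    one method (or SKIPPED) are excluded.  When every pair is tied the
    test statistic is undefined and the result is flagged degenerate
    with p = 1.
    """
    method_a, method_b = Method(method_a), Method(method_b)
    values: dict[tuple[str, float | None], dict[Method, float]] = {}
    for rec in records:
        if rec.status != "OK" or metric not in rec.metrics:
            continue
        if rec.method in (method_a, method_b):
            values.setdefault((rec.target_id, rec.threshold), {})[
                rec.method
            ] = float(rec.metrics[metric])
    pairs = [
        (v[method_a], v[method_b])
        for v in values.values()
        if method_a in v and method_b in v
    ]
    if len(pairs) < 6:
        raise InsufficientDataError(
            f"only {len(pairs)} paired records; need at least 6"
        )
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    if np.allclose(a, b):
        return ComparisonResult(
            method_a=method_a,
            method_b=method_b,
            metric=metric,
            statistic=float("nan"),
            p_value=1.0,
            n_pairs=len(pairs),
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
            degenerate=True,
        )
    stat, p = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided"
    )
    return ComparisonResult(
        method_a=method_a,
        method_b=method_b,
        metric=metric,
        statistic=float(stat),
        p_value=float(p),
        n_pairs=len(pairs),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


_METRIC_COLUMNS = (
    "tcr_pmhc_rmsd",
    "tcr_rmsd",
    "pmhc_rmsd",
    "peptide_rmsd",
    "tm_score",
    "fnat",
    "lrms",
    "irms",
    "dockq",
)


def summarize(records: Sequence[LooRecord]) -> pd.DataFrame:
    """Median and IQR of each metric per (method, threshold).

    SKIPPED records contribute to the skip count only.  Rows with
    threshold "pooled" aggregate a method over all thresholds, since
    per-target medians are sometimes reported pooled over the four caps.
    """
    frame = records_to_frame(records)
    if frame.empty:
        return pd.DataFrame(
            columns=["method", "threshold", "n", "n_skipped"]
        )
    rows = []
    groups = [
        ((m, t), g)
        for (m, t), g in frame.groupby(["method", "threshold"], dropna=False)
    ]
    groups += [
        ((m, "pooled"), g) for m, g in frame.groupby("method", dropna=False)
    ]
    for (method, threshold), group in groups:
        ok = group[group["status"] == "OK"]
        row: dict = {
            "method": method,
            "threshold": threshold,
            "n": len(ok),
            "n_skipped": int((group["status"] == "SKIPPED").sum()),
        }
        for col in _METRIC_COLUMNS:
            if col in ok.columns and ok[col].notna().any():
                series = ok[col].dropna().astype(float)
                row[f"{col}_median"] = float(series.median())
                row[f"{col}_iqr"] = float(
                    series.quantile(0.75) - series.quantile(0.25)
                )
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(
    records: Sequence[LooRecord],
    comparisons: Sequence[ComparisonResult],
    out_dir: str | Path,
) -> None:
    """records.tsv, summary.tsv and comparisons.json in a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(
        out_dir / "records.tsv", sep="\t", index=False
    )
    summarize(records).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    (out_dir / "comparisons.json").write_text(
        json.dumps([c.as_dict() for c in comparisons], indent=1)
    )
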