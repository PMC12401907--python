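"""Orchestration: measure pullbacks, pair phases, build the Table-2-style report."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coregistration, geometry, io, stats
from .angles import arcs_overlap, normalize_deg
from .coregistration import PairedFrame, Pullback
from .errors import AnalysisError, OctBiasError
from .stats import LOWER_POSITIVE

logger = logging.getLogger(__name__)

#: Report variables, in presentation order, mapped to measurement columns.
REPORT_VARIABLES = [
    ("D_cib", "d_cib"),
    ("D_cio", "d_cio"),
    ("D_cmb", "d_cmb"),
    ("D_cmo", "d_cmo"),
    ("Final burr size", "final_burr_size"),
    ("Touch angle", "touch_angle_deg"),
    ("MinLD", "min_ld_mm"),
    ("MaxLD", "max_ld_mm"),
]


@dataclass(frozen=True)
class RunConfig:
    """Tolerances and analysis options threaded through a pipeline run."""

    gap_tol: float = geometry.DEFAULT_GAP_TOL
    dtheta: float = geometry.DEFAULT_DTHETA
    eps_bias: float = geometry.DEFAULT_EPS_BIAS
    correlation: str = "spearman"
    bootstrap_b: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gap_tol, self.dtheta, self.eps_bias) <= 0:
            raise AnalysisError("all tolerances must be > 0")


def run_measure(pullbacks: Sequence[Pullback],
                config: RunConfig = RunConfig()) -> tuple[pd.DataFrame, dict]:
    """Measure every frame of every pullback.

    Returns the measurement table (stable column order) and a reconciliation
    of counts: ``analyzable + dropped == total``; failures are logged with a
    reason, never silently discarded.
    """
    rows: list[dict] = []
    dropped: dict[str, int] = {}
    total = 0
    for pb in pullbacks:
        for cs in pb.frames:
            total += 1
            try:
                rec = geometry.measure_frame(
                    cs, gap_tol=config.gap_tol, dtheta=config.dtheta,
                    eps_bias=config.eps_bias)
            except OctBiasError as exc:
                reason = type(exc).__name__
                dropped[reason] = dropped.get(reason, 0) + 1
                logger.warning("%s/%s frame %d dropped: %s",
                               pb.patient_id, pb.phase, cs.frame_id, exc)
                continue
            rows.append(io.record_to_row(pb.patient_id, pb.phase, cs, rec))
    counts = {"total": total, "analyzable": len(rows),
              "dropped": sum(dropped.values()), "dropped_by_reason": dropped}
    return io.measurements_frame(rows), counts


def run_pair(pre_pullbacks: Sequence[Pullback], post_pullbacks: Sequence[Pullback],
             config: RunConfig = RunConfig()
             ) -> tuple[pd.DataFrame, list[PairedFrame]]:
    """Align and pair every patient's phases; returns the paired table and pairs."""
    post_by_id = {pb.patient_id: pb for pb in post_pullbacks}
    rows, all_pairs = [], []
    for pre in pre_pullbacks:
        post = post_by_id.get(pre.patient_id)
        if post is None:
            logger.warning("%s: no post pullback, skipped", pre.patient_id)
            continue
        offset = coregistration.align(pre, post)
        pairs = coregistration.resample_pairs(
            pre, post, offset, gap_tol=config.gap_tol, dtheta=config.dtheta,
            eps_bias=config.eps_bias)
        all_pairs.extend(pairs)
        rows.extend(io.pairs_rows(pre.patient_id, pairs))
    return io.pairs_frame(rows), all_pairs


def coincidence_from_table(paired: pd.DataFrame) -> tuple[Optional[float], int]:
    """Quadrant/dissection coincidence recomputed from a paired-frames table."""
    pos = paired[paired["post_dissection"].astype(bool)]
    if pos.empty:
        return None, 0
    hits = 0
    for _, row in pos.iterrows():
        quad = (normalize_deg(row["bias_angle_deg"] - 45.0),
                normalize_deg(row["bias_angle_deg"] + 45.0))
        arc = (row["post_dissection_arc_start"], row["post_dissection_arc_end"])
        hits += int(arcs_overlap(arc, quad))
    return 100.0 * hits / len(pos), len(pos)


def run_analysis(paired: pd.DataFrame, patient_meta: Optional[pd.DataFrame] = None,
                 config: RunConfig = RunConfig()) -> dict:
    """Univariate + ROC report over the paired table.

    ``paired`` carries one row per coregistered frame pair (pre measurements
    plus the post dissection outcome).  ``patient_meta`` optionally supplies
    ``patient_id``/``final_burr_size`` for the burr-size row.  Returns a report
    dict with the per-variable table (presentation order fixed), the DeLong
    comparison of the two largest AUCs, coincidence/entrapment summaries and a
    cluster-bootstrap sensitivity block.
    """
    if paired.empty:
        raise AnalysisError("empty paired table")
    y_all = paired["post_dissection"].astype(bool).astype(int).to_numpy()
    if y_all.min() == y_all.max():
        raise AnalysisError("single-class outcome: analysis impossible")
    if paired["patient_id"].nunique() < 2:
        raise AnalysisError("need at least 2 patients")

    work = paired.copy()
    if patient_meta is not None:
        work = work.merge(
            patient_meta[["patient_id", "final_burr_size"]],
            on="patient_id", how="left")
    else:
        work["final_burr_size"] = np.nan

    table_rows = []
    oriented: dict[str, tuple[np.ndarray, np.ndarray, str]] = {}
    for label, column in REPORT_VARIABLES:
        sub = work[[column, "post_dissection", "patient_id"]].dropna(subset=[column])
        x = sub[column].to_numpy(dtype=float)
        y = sub["post_dissection"].astype(bool).astype(int).to_numpy()
        row: dict = {"variable": label, "n": len(sub)}
        try:
            r, p_r = stats.univariate_r(x, y, method=config.correlation)
            roc = stats.empirical_roc(x, y, direction="auto")
        except OctBiasError as exc:
            logger.warning("%s: skipped (%s)", label, exc)
            row.update({k: np.nan for k in
                        ("r", "r_p", "auc", "ci_low", "ci_high", "sensitivity",
                         "specificity", "cutoff", "youden")})
            row["direction"] = None
            table_rows.append(row)
            continue
        row.update({
            "r": r, "r_p": p_r, "auc": roc.auc,
            "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "cutoff": roc.cutoff, "youden": roc.youden,
            "direction": roc.direction,
        })
        table_rows.append(row)
        oriented[label] = (x, y, roc.direction)

    table = pd.DataFrame(table_rows)

    # DeLong comparison of the two largest AUCs, on their common rows
    ranked = table.dropna(subset=["auc"]).sort_values("auc", ascending=False)
    delong: Optional[dict] = None
    if len(ranked) >= 2:
        lab1, lab2 = ranked["variable"].iloc[0], ranked["variable"].iloc[1]
        col1 = dict(REPORT_VARIABLES)[lab1]
        col2 = dict(REPORT_VARIABLES)[lab2]
        sub = work[[col1, col2, "post_dissection"]].dropna()
        y = sub["post_dissection"].astype(bool).astype(int).to_numpy()
        if 0 < y.sum() < len(y):
            s1 = sub[col1].to_numpy(dtype=float)
            s2 = sub[col2].to_numpy(dtype=float)
            if oriented[lab1][2] == LOWER_POSITIVE:
                s1 = -s1
            if oriented[lab2][2] == LOWER_POSITIVE:
                s2 = -s2
            try:
                auc1, auc2, z, p = stats.delong_test(s1, s2, y)
                delong = {"variable_1": lab1, "variable_2": lab2,
                          "auc_1": auc1, "auc_2": auc2, "z": z, "p": p,
                          "n": len(sub)}
            except OctBiasError as exc:
                delong = {"variable_1": lab1, "variable_2": lab2,
                          "error": str(exc)}

    coincidence, n_diss = coincidence_from_table(paired)
    pos = paired[paired["post_dissection"].astype(bool)]
    entrapment = (None if pos.empty
                  else 100.0 * pos["post_catheter_subintimal"].astype(bool).mean())

    # cluster-bootstrap sensitivity block for the top-AUC variable
    bootstrap: Optional[dict] = None
    if len(ranked) >= 1:
        lab = ranked["variable"].iloc[0]
        col = dict(REPORT_VARIABLES)[lab]
        sub = work[[col, "post_dissection", "patient_id"]].dropna(subset=[col])
        y = sub["post_dissection"].astype(bool).astype(int).to_numpy()
        if 0 < y.sum() < len(y) and sub["patient_id"].nunique() >= 2:
            auc, lo, hi = stats.cluster_bootstrap_auc(
                sub[col].to_numpy(dtype=float), y,
                sub["patient_id"].to_numpy(),
                B=config.bootstrap_b, seed=config.seed)
            bootstrap = {"variable": lab, "auc": auc, "ci_low": lo,
                         "ci_high": hi, "B": config.bootstrap_b,
                         "note": "cluster bootstrap surrogate for GEE"}

    return {
        "seed": config.seed,
        "n_pairs": int(len(paired)),
        "n_patients": int(paired["patient_id"].nunique()),
        "n_dissection": int(n_diss),
        "table": table,
        "delong": delong,
        "coincidence_rate_pct": coincidence,
        "entrapment_rate_pct": entrapment,
        "cluster_bootstrap": bootstrap,
    }


def report_to_json(report: dict) -> dict:
    """JSON-safe view of a report dict (table flattened to records)."""
    out = dict(report)
    out["table"] = report["table"].to_dict(orient="records")
    return out
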