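"""Batch-level quality control applied before any biological analysis.

Four rules, in the order the pipeline applies them:

1. **Ribitol gate** — every oocyte-derived or pooled-QC sample carries a
   ribitol internal-standard spike; samples whose ribitol signal deviates
   from the batch median by more than 10% are discarded (the median is used
   as the reference because it is robust to the very outliers the gate
   removes).
2. **Drift-peak removal** — a matrix row is removed when its abundance is
   monotonically associated with injection order (Spearman rank correlation
   >= 0.8) consistently in every sample role, i.e. independently of any
   biological variable.
3. **Blank subtraction** — rows whose mean signal in derivatized blanks
   reaches 10% of the mean biological signal are column contaminants and are
   removed.
4. **Internal-peak stripping** — ribitol and the n-alkane ladder are removed
   from the analysis matrix; ribitol is retained separately as the
   negative-control channel of the profiling output.

The full pass is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import AbundanceMatrix

__all__ = ["QCReport", "ribitol_gate", "remove_drift_peaks",
           "blank_subtraction", "strip_internal_peaks", "apply_qc"]

_GATED_ROLES = ("transporter", "uninjected", "qc_pool", "standard_mix")


@dataclass
class QCReport:
    ribitol: pd.DataFrame | None = None          # per-sample height/deviation/keep
    discarded_samples: list = field(default_factory=list)
    removed_drift_peaks: list = field(default_factory=list)
    removed_blank_contaminants: list = field(default_factory=list)
    qc_pool_cv: pd.Series | None = None          # per-metabolite CV across QC pools
    log: list = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = []
        if self.ribitol is not None:
            lines.append("# ribitol internal-standard gate")
            lines.append(self.ribitol.to_csv(sep="\t").rstrip())
        lines.append("# removed drift peaks\t" +
                     ",".join(self.removed_drift_peaks))
        lines.append("# removed blank contaminants\t" +
                     ",".join(self.removed_blank_contaminants))
        lines.extend("# " + entry for entry in self.log)
        return "\n".join(lines) + "\n"


def ribitol_gate(matrix: AbundanceMatrix, tolerance: float = 0.10,
                 report: QCReport | None = None) -> AbundanceMatrix:
    """Discard samples whose ribitol deviates > ``tolerance`` from the batch
    median. Samples with no ribitol measurement are discarded with reason
    "IS missing". Blanks carry no internal standard and are exempt."""
    report = report if report is not None else QCReport()
    gated = matrix.samples.index[matrix.samples["role"].isin(_GATED_ROLES)]
    heights = matrix.samples.loc[gated, "ribitol_height"]
    finite = heights.dropna()
    median = float(finite.median()) if len(finite) else float("nan")
    rows, discard = [], []
    for sid in gated:
        h = heights.loc[sid]
        if pd.isna(h):
            rows.append({"sample_id": sid, "ribitol_height": np.nan,
                         "deviation": np.nan, "keep": False,
                         "reason": "IS missing"})
            discard.append(sid)
            continue
        dev = abs(h - median) / median
        keep = dev <= tolerance
        rows.append({"sample_id": sid, "ribitol_height": h,
                     "deviation": dev, "keep": keep,
                     "reason": "" if keep else f"deviation {dev:.1%} > "
                     f"{tolerance:.0%}"})
        if not keep:
            discard.append(sid)
    report.ribitol = pd.DataFrame(rows).set_index("sample_id")
    report.discarded_samples.extend(discard)
    report.log.append(f"ribitol gate: {len(discard)}/{len(gated)} samples "
                      "discarded")
    out = matrix.drop_samples(discard)
    out.log.append(f"ribitol_gate removed {len(discard)} samples")
    return out


def remove_drift_peaks(matrix: AbundanceMatrix, threshold: float = 0.8,
                       min_samples_per_role: int = 3,
                       report: QCReport | None = None) -> AbundanceMatrix:
    """Remove rows rising monotonically with injection order in every role.

    The association must hold with Spearman rank correlation >= ``threshold``
    in each role having enough samples — a signal tied to injection order
    *independently of the biological variables* is an instrumental artefact.
    """
    report = report if report is not None else QCReport()
    order = matrix.samples["injection_order"]
    removed = []
    roles = matrix.samples["role"].unique()
    for met in matrix.metabolites:
        corrs = []
        for role in roles:
            cols = matrix.samples.index[matrix.samples["role"] == role]
            if len(cols) < min_samples_per_role:
                continue
            vals = matrix.values.loc[met, cols].astype(float)
            if vals.nunique() <= 1:
                corrs.append(0.0)
                continue
            rho = stats.spearmanr(order.loc[cols], vals).statistic
            corrs.append(float(rho))
        if corrs and all(c >= threshold for c in corrs):
            removed.append(met)
    report.removed_drift_peaks.extend(removed)
    report.log.append(f"drift filter: removed {removed}")
    out = matrix.drop_metabolites(removed)
    out.log.append(f"remove_drift_peaks removed {removed}")
    return out


def blank_subtraction(matrix: AbundanceMatrix, threshold: float = 0.10,
                      report: QCReport | None = None) -> AbundanceMatrix:
    """Remove rows whose mean blank signal reaches ``threshold`` of the mean
    biological signal (boundary counts as contaminated). Censored floor
    values count as zero signal on the blank side."""
    report = report if report is not None else QCReport()
    blanks = matrix.samples.index[matrix.samples["role"] == "blank"]
    bio = matrix.samples.index[matrix.samples["role"].isin(
        ["transporter", "uninjected"])]
    if len(blanks) == 0:
        report.log.append("blank subtraction skipped: no blanks in batch")
        out = matrix.copy()
        out.log.append("blank_subtraction: no blanks, no-op")
        return out
    removed = []
    for met in matrix.metabolites:
        blank_vals = matrix.values.loc[met, blanks].astype(float).copy()
        blank_vals[matrix.censored.loc[met, blanks]] = 0.0
        bio_mean = float(matrix.values.loc[met, bio].mean()) if len(bio) else 0.0
        if bio_mean <= 0:
            continue
        if float(blank_vals.mean()) >= threshold * bio_mean:
            removed.append(met)
    report.removed_blank_contaminants.extend(removed)
    report.log.append(f"blank filter: removed {removed}")
    out = matrix.drop_metabolites(removed)
    out.log.append(f"blank_subtraction removed {removed}")
    return out


def strip_internal_peaks(matrix: AbundanceMatrix,
                         report: QCReport | None = None) -> AbundanceMatrix:
    """Drop ribitol and alkane rows from the analysis matrix, keeping the
    ribitol heights aside as the profiling negative-control channel."""
    report = report if report is not None else QCReport()
    internal = [m for m in matrix.metabolites
                if m == "Ribitol" or m.endswith(" alkane")]
    out = matrix.drop_metabolites(internal)
    if "Ribitol" in matrix.values.index:
        out.negative_control = matrix.values.loc["Ribitol"].copy()
    elif matrix.negative_control is not None:
        out.negative_control = matrix.negative_control.copy()
    report.log.append(f"stripped internal peaks: {internal}")
    out.log.append(f"strip_internal_peaks removed {internal}")
    return out


def apply_qc(matrix: AbundanceMatrix, ribitol_tolerance: float = 0.10,
             drift_threshold: float = 0.8, blank_threshold: float = 0.10):
    """Full QC pass in protocol order. Returns ``(matrix, QCReport)``."""
    report = QCReport()
    out = ribitol_gate(matrix, ribitol_tolerance, report)
    out = remove_drift_peaks(out, drift_threshold, report=report)
    out = blank_subtraction(out, blank_threshold, report)
    out = strip_internal_peaks(out, report)
    qc_cols = out.samples.index[out.samples["role"] == "qc_pool"]
    if len(qc_cols) >= 2:
        vals = out.values[qc_cols]
        report.qc_pool_cv = (vals.std(axis=1, ddof=1) /
                             vals.mean(axis=1)).rename("qc_pool_cv")
    return out, report
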