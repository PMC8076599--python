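"""Substrate profiling: dual fold-change / absolute-difference statistics.

For every metabolite and timepoint the profile reports

* **fold change** — mean transporter-sample signal divided by the mean signal
  of matched un-injected oocytes incubated in the same medium for the same
  time, cancelling endogenous drift;
* **absolute delta** — mean transporter signal minus mean un-injected signal,
  which exposes transport of metabolites whose endogenous pools are so large
  that the fold change stays near 1 (the anionic amino acids);
* **paired t-test p-value** — two-sided, on raw transporter-sample values
  between the first and last timepoint, paired by replicate batch, reported
  without multiple-testing adjustment (a Benjamini-Hochberg column is
  provided but not used for calls).

A metabolite is called *accumulated* when the change is significant
(p < 0.05) and either the fold change exceeds the negative-control band
(1 +- 0.1, the band the ribitol internal standard defines) or the absolute
delta is consistently positive across replicates and exceeds an absolute
floor; *depleted* symmetrically; otherwise *unchanged*. Ribitol itself is
excluded from calls and reported as the negative-control row.

Exchanger (antiporter) experiments are profiled in two phases: preloading
(post-preload vs baseline) and medium incubation (post-medium vs
post-preload), each phase receiving control-corrected deltas, signs and
paired p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

__all__ = ["ProfileParams", "SubstrateProfile", "fold_change",
           "absolute_delta", "replicate_deltas", "paired_test",
           "compute_profile", "call_substrates", "exchanger_profile",
           "write_heatmap_tables"]

_PHASES = ("baseline", "preloaded", "medium")


@dataclass(frozen=True)
class ProfileParams:
    alpha: float = 0.05
    #: fold-change no-change band, mirroring the ribitol control band 1 +- 0.1
    fc_band: float = 0.10
    #: absolute-delta floor (abundance units; 2x the detection floor)
    delta_floor: float = 1000.0


@dataclass
class SubstrateProfile:
    fold_change: pd.DataFrame            # metabolite x timepoint label
    absolute_delta: pd.DataFrame
    replicate_deltas: dict               # label -> metabolite x replicate
    p_values: pd.Series
    p_bh: pd.Series
    significant: pd.Series
    fc_detected: pd.Series
    delta_detected: pd.Series
    calls: pd.Series
    ribitol_fc: pd.Series | None = None          # per timepoint label
    ribitol_fc_per_sample: pd.Series | None = None
    phase_signs: pd.DataFrame | None = None      # exchanger mode
    phase_pvalues: pd.DataFrame | None = None
    phase_deltas: pd.DataFrame | None = None
    params: ProfileParams = field(default_factory=ProfileParams)

    @property
    def labels(self) -> list[str]:
        return list(self.fold_change.columns)


def _cols(matrix: AbundanceMatrix, role: str, label) -> pd.Index:
    s = matrix.samples
    return s.index[(s["role"] == role) & (s["timepoint"] == label)]


def _labels(matrix: AbundanceMatrix) -> list[str]:
    seen = []
    for lab in matrix.samples.loc[
            matrix.samples["role"].isin(["transporter", "uninjected"]),
            "timepoint"]:
        if lab not in seen:
            seen.append(lab)
    return seen


def _check_matched(matrix: AbundanceMatrix, labels) -> None:
    for lab in labels:
        tx = _cols(matrix, "transporter", lab)
        ui = _cols(matrix, "uninjected", lab)
        if len(tx) == 0 or len(ui) == 0:
            raise ValueError(f"timepoint {lab!r}: missing transporter or "
                             "matched un-injected samples")


def fold_change(matrix: AbundanceMatrix,
                labels=None) -> pd.DataFrame:
    """FC(m, t) = mean transporter signal / mean un-injected signal.

    The detection floor (500) guarantees a positive denominator. The ribitol
    negative-control row is included when the matrix carries one.
    """
    labels = labels or _labels(matrix)
    _check_matched(matrix, labels)
    out = {}
    for lab in labels:
        tx = matrix.values[_cols(matrix, "transporter", lab)].mean(axis=1)
        ui = matrix.values[_cols(matrix, "uninjected", lab)].mean(axis=1)
        assert (ui > 0).all(), "floored values cannot give a zero denominator"
        out[lab] = tx / ui
    fc = pd.DataFrame(out)
    if matrix.negative_control is not None and "Ribitol" not in fc.index:
        rib = {}
        for lab in labels:
            tx = matrix.negative_control[_cols(matrix, "transporter", lab)]
            ui = matrix.negative_control[_cols(matrix, "uninjected", lab)]
            rib[lab] = float(tx.mean() / ui.mean())
        fc.loc["Ribitol"] = pd.Series(rib)
    return fc


def absolute_delta(matrix: AbundanceMatrix, labels=None) -> pd.DataFrame:
    """Delta(m, t) = mean transporter signal - mean un-injected signal."""
    labels = labels or _labels(matrix)
    _check_matched(matrix, labels)
    out = {}
    for lab in labels:
        tx = matrix.values[_cols(matrix, "transporter", lab)].mean(axis=1)
        ui = matrix.values[_cols(matrix, "uninjected", lab)].mean(axis=1)
        out[lab] = tx - ui
    return pd.DataFrame(out)


def replicate_deltas(matrix: AbundanceMatrix, label) -> pd.DataFrame:
    """Per-replicate transporter-minus-control differences at one timepoint."""
    s = matrix.samples
    out = {}
    for rep in sorted(s.loc[s["role"] == "transporter", "replicate"].unique()):
        tx = s.index[(s["role"] == "transporter") & (s["timepoint"] == label)
                     & (s["replicate"] == rep)]
        ui = s.index[(s["role"] == "uninjected") & (s["timepoint"] == label)
                     & (s["replicate"] == rep)]
        if len(tx) == 0 or len(ui) == 0:
            continue
        out[rep] = (matrix.values[tx].mean(axis=1)
                    - matrix.values[ui].mean(axis=1))
    return pd.DataFrame(out)


def paired_test(matrix: AbundanceMatrix, metabolite: str,
                label0=None, label1=None, role: str = "transporter") -> float:
    """Two-sided paired t-test on raw values between two timepoints.

    Pairs are replicate batches. Identical paired values (zero variance of
    the differences) return p = 1.0; fewer than two pairs return NaN.
    """
    labels = _labels(matrix)
    label0 = label0 if label0 is not None else labels[0]
    label1 = label1 if label1 is not None else labels[-1]
    s = matrix.samples
    x0, x1 = [], []
    reps = sorted(s.loc[s["role"] == role, "replicate"].unique())
    for rep in reps:
        c0 = s.index[(s["role"] == role) & (s["timepoint"] == label0)
                     & (s["replicate"] == rep)]
        c1 = s.index[(s["role"] == role) & (s["timepoint"] == label1)
                     & (s["replicate"] == rep)]
        if len(c0) and len(c1):
            x0.append(float(matrix.values.loc[metabolite, c0].mean()))
            x1.append(float(matrix.values.loc[metabolite, c1].mean()))
    if len(x0) < 2:
        return float("nan")
    diffs = np.asarray(x1) - np.asarray(x0)
    if np.allclose(diffs.std(ddof=1), 0.0):
        return 1.0 if np.allclose(diffs, 0.0) else 0.0
    return float(stats.ttest_rel(x1, x0).pvalue)


def _consistent_sign(row: pd.Series, positive: bool) -> bool:
    # every replicate must agree in direction; with e=3 repeats this is the
    # guard that keeps noisy high-abundance metabolites out of the calls
    vals = row.dropna().to_numpy()
    if vals.size == 0:
        return False
    return bool((vals > 0).all() if positive else (vals < 0).all())


def compute_profile(matrix: AbundanceMatrix,
                    params: ProfileParams | None = None) -> SubstrateProfile:
    """Full two-timepoint substrate profile with calls."""
    params = params or ProfileParams()
    labels = _labels(matrix)
    fc = fold_change(matrix, labels)
    delta = absolute_delta(matrix, labels)
    rep_d = {lab: replicate_deltas(matrix, lab) for lab in labels}
    mets = [m for m in matrix.metabolites if m != "Ribitol"]
    pvals = pd.Series({m: paired_test(matrix, m) for m in mets})
    finite = pvals.dropna()
    bh = pd.Series(np.nan, index=pvals.index)
    if len(finite):
        bh.loc[finite.index] = multipletests(finite.values,
                                             method="fdr_bh")[1]
    significant = pvals < params.alpha
    end = labels[-1]

    fc_det, d_det, calls = {}, {}, {}
    for m in mets:
        sig = bool(significant[m])
        fc_end, d_end = float(fc.loc[m, end]), float(delta.loc[m, end])
        reps = rep_d[end].loc[m] if m in rep_d[end].index else pd.Series(dtype=float)
        fc_up = fc_end > 1.0 + params.fc_band
        fc_down = fc_end < 1.0 - params.fc_band
        d_up = d_end > params.delta_floor and _consistent_sign(reps, True)
        d_down = d_end < -params.delta_floor and _consistent_sign(reps, False)
        fc_det[m] = sig and (fc_up or fc_down)
        d_det[m] = sig and (d_up or d_down)
        up, down = fc_up or d_up, fc_down or d_down
        if sig and up and not down:
            calls[m] = "accumulated"
        elif sig and down and not up:
            calls[m] = "depleted"
        else:
            calls[m] = "unchanged"

    rib_fc = fc.loc["Ribitol"] if "Ribitol" in fc.index else None
    rib_per_sample = None
    if matrix.negative_control is not None:
        vals = {}
        for lab in labels:
            ui_mean = float(matrix.negative_control[
                _cols(matrix, "uninjected", lab)].mean())
            for role in ("transporter", "uninjected"):
                for sid in _cols(matrix, role, lab):
                    vals[sid] = float(matrix.negative_control[sid] / ui_mean)
        rib_per_sample = pd.Series(vals)

    return SubstrateProfile(
        fold_change=fc, absolute_delta=delta, replicate_deltas=rep_d,
        p_values=pvals, p_bh=bh, significant=significant,
        fc_detected=pd.Series(fc_det), delta_detected=pd.Series(d_det),
        calls=pd.Series(calls), ribitol_fc=rib_fc,
        ribitol_fc_per_sample=rib_per_sample, params=params)


def call_substrates(profile: SubstrateProfile) -> pd.Series:
    """Per-metabolite substrate call (ribitol excluded)."""
    return profile.calls


def exchanger_profile(matrix: AbundanceMatrix,
                      params: ProfileParams | None = None) -> SubstrateProfile:
    """Two-phase profile for preload/efflux exchanger experiments.

    Expects the three phase columns: ``baseline`` (before preloading),
    ``preloaded`` (after the preloading incubation) and ``medium`` (after the
    subsequent medium incubation). Phase 1 (``preload``) compares preloaded
    vs baseline; phase 2 (``medium``) compares medium vs preloaded. Signs
    are those of the control-corrected delta change within each phase.
    """
    params = params or ProfileParams()
    labels = _labels(matrix)
    missing = [p for p in _PHASES if p not in labels]
    if missing:
        raise ValueError(f"exchanger profile needs phase columns {_PHASES}; "
                         f"missing {missing}")
    profile = compute_profile(matrix, params)
    delta = profile.absolute_delta
    mets = [m for m in matrix.metabolites if m != "Ribitol"]
    signs, pvals, deltas = {}, {}, {}
    for phase, (lab0, lab1) in (("preload", ("baseline", "preloaded")),
                                ("medium", ("preloaded", "medium"))):
        change = delta[lab1] - delta[lab0]
        rep_change = (replicate_deltas(matrix, lab1)
                      - replicate_deltas(matrix, lab0))
        p = pd.Series({m: paired_test(matrix, m, lab0, lab1) for m in mets})
        sig = p < params.alpha
        marks = {}
        for m in mets:
            # a printed sign needs significance AND every replicate's
            # control-corrected change agreeing in direction
            if sig[m] and _consistent_sign(rep_change.loc[m],
                                           positive=change[m] > 0):
                marks[m] = "+" if change[m] > 0 else "-"
            else:
                marks[m] = ""
        signs[phase] = pd.Series(marks)
        pvals[phase], deltas[phase] = p, change.loc[mets]
    profile.phase_signs = pd.DataFrame(signs)
    profile.phase_pvalues = pd.DataFrame(pvals)
    profile.phase_deltas = pd.DataFrame(deltas)
    return profile


def _mark(val: float, p: float, alpha: float) -> str:
    star = "*" if (p == p and p < alpha) else ""
    return f"{val:.4g}{star}"


def write_heatmap_tables(profile: SubstrateProfile):
    """Render the FC and delta heat-map matrices as TSV strings.

    Significant entries carry an asterisk; the ribitol negative-control row
    and conversion-product rows are retained. Returns ``(fc_tsv, delta_tsv)``.
    """
    labels = profile.labels
    fc_lines = ["metabolite\t" + "\t".join(labels)]
    d_lines = ["metabolite\t" + "\t".join(labels)]
    for m in profile.fold_change.index:
        p = profile.p_values.get(m, float("nan"))
        fc_cells = [_mark(profile.fold_change.loc[m, lab], p,
                          profile.params.alpha) for lab in labels]
        fc_lines.append(m + "\t" + "\t".join(fc_cells))
        if m in profile.absolute_delta.index:
            d_cells = [_mark(profile.absolute_delta.loc[m, lab], p,
                             profile.params.alpha) for lab in labels]
            d_lines.append(m + "\t" + "\t".join(d_cells))
    return "\n".join(fc_lines) + "\n", "\n".join(d_lines) + "\n"
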