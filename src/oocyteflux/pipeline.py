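"""End-to-end orchestration: simulate -> identify -> QC -> quantify -> profile.

``run_simulate`` writes a synthetic batch (one peak-list CSV per injection
plus a manifest) from a serializable :class:`PipelineConfig`; ``run_profile``
re-reads a batch directory and executes the analysis chain:

1. per-run retention-index calibration from the co-injected alkane ladder;
2. three-criterion library identification of every peak (standard-mix runs
   in the batch provide criterion-2 confirmation for the amino acids);
3. quantifier-ion (EIC) height extraction into the metabolite x sample
   abundance matrix, with unidentified components merged across samples by
   retention-index centroid;
4. the QC pass (ribitol gate, drift-peak removal, blank subtraction,
   internal-peak stripping);
5. per-amino-acid linear calibration and absolute quantification of the
   un-injected baseline samples;
6. substrate profiling (two-phase profiling when the batch has preload
   phases) and report writing.

Everything is deterministic under a fixed seed: the same config reproduces
byte-identical batch files and reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import qc as qc_mod
from .identify import IdentificationParams, identify_peak
from .library import AMINO_ACIDS, load_reference_library
from .matrix import AbundanceMatrix
from .peaks import extract_eic_height
from .profiles import (ProfileParams, SubstrateProfile, compute_profile,
                       exchanger_profile, write_heatmap_tables)
from .quantify import fit_calibration, quantify_sample
from .rindex import fit_ri_map
from .simulate import (ExperimentDesign, InstrumentParams, generate_batch,
                       get_transporter, write_batch, read_batch,
                       MODIFIED_L15_UM, ND96_UM)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_profile",
           "build_abundance_matrix", "PipelineError"]

_MEDIA = {"L15": MODIFIED_L15_UM, "ND96": ND96_UM}


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable run configuration; config + seed reproduce a run
    byte-identically."""

    transporter: str = "uninjected"
    medium: str = "L15"
    timepoints: tuple[float, ...] = (0.0, 4.0)
    n_replicates: int = 3
    n_oocytes_per_sample: int = 12
    seed: int = 0
    preload: tuple[str, float, float] | None = None
    drift_enabled: bool = True
    ribitol_tolerance: float = 0.10
    drift_threshold: float = 0.8
    blank_threshold: float = 0.10
    alpha: float = 0.05
    fc_band: float = 0.10
    delta_floor: float = 1000.0

    def to_design(self) -> ExperimentDesign:
        if self.medium not in _MEDIA:
            raise PipelineError(f"unknown medium preset {self.medium!r}; "
                                f"available: {sorted(_MEDIA)}")
        return ExperimentDesign(
            transporter=get_transporter(self.transporter),
            medium=dict(_MEDIA[self.medium]),
            timepoints=tuple(self.timepoints),
            n_replicates=self.n_replicates,
            n_oocytes_per_sample=self.n_oocytes_per_sample,
            preload=tuple(self.preload) if self.preload else None,
            drift_enabled=self.drift_enabled,
            seed=self.seed,
            instrument=InstrumentParams(),
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("timepoints") is not None:
            d["timepoints"] = tuple(d["timepoints"])
        if d.get("preload"):
            d["preload"] = tuple(d["preload"])
        return cls(**d)


def run_simulate(config: PipelineConfig, outdir) -> Path:
    """Generate and write one synthetic batch. Returns the batch directory."""
    outdir = Path(outdir)
    design = config.to_design()
    runs, manifest = generate_batch(design)
    write_batch(runs, manifest, outdir)
    meta = {"config": asdict(config), "config_hash": config.config_hash(),
            "seed": config.seed, "n_injections": len(runs)}
    (outdir / "batch_meta.json").write_text(json.dumps(meta, indent=1,
                                                       default=list))
    logger.info("simulated batch: %d injections -> %s", len(runs), outdir)
    return outdir


# ---------------------------------------------------------------------------

def _pseudo_peaks(run, calib):
    """Peak-level runs already carry apex spectra; wrap them with assigned
    RIs so the identification layer sees the detected-peak interface."""
    from .rindex import assign_ri

    class _P:
        __slots__ = ("metabolite", "apex_time_s", "height", "area",
                     "spectrum", "symmetry", "assigned_ri")

    out = []
    for p in run.peaks:
        q = _P()
        q.metabolite = p.metabolite   # ground-truth tag; not used for ID
        q.apex_time_s = p.apex_time_s
        q.height = p.height
        q.area = p.area
        q.spectrum = p.spectrum
        q.symmetry = 1.0
        q.assigned_ri = assign_ri(p.apex_time_s, calib)
        out.append(q)
    return out


def _confirmed_by_standards(runs, library, id_params, floor):
    """Amino acids (plus ornithine) confirmed by same-batch standard mixes."""
    confirmed = set()
    targets = [rec for rec in library
               if rec.name in set(AMINO_ACIDS) | {"Ornithine"}]
    for run in runs:
        if run.role != "standard_mix":
            continue
        calib = fit_ri_map(run.alkane_times.items())
        for rec in targets:
            res = extract_eic_height(run, rec.quantifier_mz,
                                     rec.retention_index, calib,
                                     id_params.ri_window, floor)
            if not res.censored:
                confirmed.add(rec.name)
    return confirmed


def build_abundance_matrix(runs, manifest: pd.DataFrame,
                           id_params: IdentificationParams | None = None,
                           floor: float = 500.0,
                           return_identifications: bool = False):
    """Identify peaks and extract quantifier-ion heights for every injection.

    Rows are the library metabolites identified in at least one biological
    sample, plus ribitol, plus unidentified components grouped across samples
    by retention-index centroid (merge radius = the centroid-distance
    parameter). Values below the detection floor are floored and flagged.
    """
    id_params = id_params or IdentificationParams()
    library = load_reference_library()
    by_name = {rec.name: rec for rec in library}
    confirmed = _confirmed_by_standards(runs, library, id_params, floor)

    calibs = {run.sample_id: fit_ri_map(run.alkane_times.items())
              for run in runs}

    identified_names: set[str] = set()
    unknown_obs: list[tuple[str, float, float]] = []  # sample, ri, height
    ident_rows: list[dict] = []
    for run in runs:
        calib = calibs[run.sample_id]
        for k, peak in enumerate(_pseudo_peaks(run, calib)):
            ident = identify_peak(peak, library, id_params,
                                  standard_confirmed_names=confirmed)
            ident_rows.append({
                "sample_id": run.sample_id, "peak": k,
                "assigned_ri": round(peak.assigned_ri, 2),
                "name": ident.name or "", "criterion": ident.criterion,
                "forward_score": round(ident.forward_score, 1),
                "reverse_score": round(ident.reverse_score, 1),
                "ri_error": round(ident.ri_error, 3)
                if ident.ri_error == ident.ri_error else "",
                "qualifier_pass": ident.qualifier_pass,
                "standard_confirmed": ident.standard_confirmed,
                "is_conversion_product": ident.is_conversion_product})
            if ident.criterion == "unidentified":
                unknown_obs.append((run.sample_id, peak.assigned_ri,
                                    peak.height))
            elif run.role in ("transporter", "uninjected", "qc_pool"):
                identified_names.add(ident.name)

    # cluster unidentified components across samples: single linkage on the
    # sorted RIs with the centroid-distance merge radius, so retention jitter
    # cannot split one component into two matrix rows
    unknown_obs.sort(key=lambda o: o[1])
    clusters: list[dict] = []
    for sid, ri, h in unknown_obs:
        if clusters and ri - clusters[-1]["last_ri"] <= \
                id_params.centroid_distance:
            cl = clusters[-1]
            cl["obs"][sid] = max(cl["obs"].get(sid, 0.0), h)
            cl["ris"].append(ri)
            cl["last_ri"] = ri
        else:
            clusters.append({"obs": {sid: h}, "ris": [ri], "last_ri": ri})
    for cl in clusters:
        cl["centroid"] = sum(cl["ris"]) / len(cl["ris"])

    row_names = sorted(identified_names | {"Ribitol"})
    values, censored = {}, {}
    for run in runs:
        calib = calibs[run.sample_id]
        col, cen = {}, {}
        for name in row_names:
            rec = by_name[name]
            res = extract_eic_height(run, rec.quantifier_mz,
                                     rec.retention_index, calib,
                                     id_params.ri_window, floor)
            col[name], cen[name] = res.height, res.censored
        values[run.sample_id], censored[run.sample_id] = col, cen
    vdf = pd.DataFrame(values)
    cdf = pd.DataFrame(censored)
    for cl in clusters:
        if len(cl["obs"]) < 2:
            continue  # single-sample spikes are not matrix rows
        name = f"unknown_RI{cl['centroid']:.0f}"
        vdf.loc[name] = pd.Series(cl["obs"]).reindex(vdf.columns).fillna(floor)
        cdf.loc[name] = pd.Series(cl["obs"]).reindex(vdf.columns).isna()

    samples = manifest.copy()
    rib = vdf.loc["Ribitol"].where(~cdf.loc["Ribitol"])
    samples["ribitol_height"] = rib
    samples.loc[samples["role"] == "blank", "ribitol_height"] = float("nan")
    keep_cols = [c for c in ("role", "transporter", "timepoint", "replicate",
                             "injection_order", "kind", "rf_group",
                             "std_nmol", "ribitol_height")
                 if c in samples.columns]
    matrix = AbundanceMatrix(values=vdf, samples=samples[keep_cols],
                             censored=cdf)
    if return_identifications:
        return matrix, pd.DataFrame(ident_rows)
    return matrix


def _fit_batch_calibrations(matrix: AbundanceMatrix):
    """Per-amino-acid OLS curves from the batch's calibration-series runs.

    Standards are run grouped by comparative response factor, so each curve
    is read only from its own group's series (a metabolite can bleed into
    another group's runs as a conversion product — e.g. ornithine from
    arginine in the low-Rf series — and those points carry the wrong nominal
    amounts).
    """
    s = matrix.samples
    series = s.index[(s.get("kind") == "calibration")]
    rf_class = {rec.name: rec.rf_class for rec in load_reference_library()}
    curves = {}
    for name in matrix.metabolites:
        if name not in rf_class:
            continue
        pts = []
        for sid in series:
            if s.loc[sid, "rf_group"] != rf_class[name]:
                continue
            if matrix.censored.loc[name, sid]:
                continue
            pts.append((float(s.loc[sid, "std_nmol"]),
                        float(matrix.values.loc[name, sid])))
        if len(pts) >= 3:
            curves[name] = fit_calibration(pts, metabolite=name,
                                           rf_group=rf_class[name])
    return curves


@dataclass
class ProfileResult:
    matrix: AbundanceMatrix
    qc_report: qc_mod.QCReport
    profile: SubstrateProfile
    calibrations: dict
    quantified: pd.DataFrame | None
    identifications: pd.DataFrame | None = None


def run_profile(batch_dir, config: PipelineConfig | None = None,
                outdir=None) -> ProfileResult:
    """Execute the full analysis chain on a written batch directory."""
    config = config or PipelineConfig()
    batch_dir = Path(batch_dir)
    if not (batch_dir / "manifest.tsv").exists():
        raise PipelineError(f"stage input missing: {batch_dir}/manifest.tsv "
                            "(run simulate first)")
    runs, manifest = read_batch(batch_dir)
    n_bio = int(manifest["role"].isin(["transporter", "uninjected"]).sum())
    if n_bio == 0:
        raise PipelineError("no biological samples in batch")

    matrix, identifications = build_abundance_matrix(
        runs, manifest, return_identifications=True)
    logger.info("matrix: %d metabolites x %d samples", *matrix.values.shape)

    qc_matrix, report = qc_mod.apply_qc(
        matrix, ribitol_tolerance=config.ribitol_tolerance,
        drift_threshold=config.drift_threshold,
        blank_threshold=config.blank_threshold)
    n_bio_kept = int(qc_matrix.samples["role"].isin(
        ["transporter", "uninjected"]).sum())
    if n_bio_kept < 0.5 * n_bio:
        raise PipelineError(
            f"QC discarded {n_bio - n_bio_kept}/{n_bio} biological samples")

    curves = _fit_batch_calibrations(qc_matrix)
    quantified = None
    labels = [lab for lab in qc_matrix.samples["timepoint"].unique()
              if lab in ("t0", "baseline")]
    if curves and labels:
        s = qc_matrix.samples
        base_cols = s.index[(s["role"] == "uninjected")
                            & (s["timepoint"] == labels[0])]
        rows = []
        for name, curve in curves.items():
            if name not in qc_matrix.values.index or curve.slope <= 0:
                continue
            h = float(qc_matrix.values.loc[name, base_cols].mean())
            content = quantify_sample(h, curve, config.n_oocytes_per_sample)
            rows.append({"metabolite": name,
                         "concentration_um": content.concentration_um,
                         "pmol_per_oocyte": content.content_pmol_per_oocyte,
                         "adjusted_r2": curve.adjusted_r2,
                         "curve_accepted": curve.accepted})
        if rows:
            quantified = pd.DataFrame(rows).set_index("metabolite")

    params = ProfileParams(alpha=config.alpha, fc_band=config.fc_band,
                           delta_floor=config.delta_floor)
    phases = set(qc_matrix.samples["timepoint"])
    if {"baseline", "preloaded", "medium"} <= phases:
        profile = exchanger_profile(qc_matrix.biological(), params)
    else:
        profile = compute_profile(qc_matrix.biological(), params)

    result = ProfileResult(matrix=qc_matrix, qc_report=report,
                           profile=profile, calibrations=curves,
                           quantified=quantified,
                           identifications=identifications)
    if outdir is not None:
        _write_reports(result, Path(outdir))
    return result


def _write_reports(result: ProfileResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fc_tsv, d_tsv = write_heatmap_tables(result.profile)
    (outdir / "fold_change.tsv").write_text(fc_tsv)
    (outdir / "absolute_delta.tsv").write_text(d_tsv)
    (outdir / "qc_report.tsv").write_text(result.qc_report.to_tsv())
    if result.identifications is not None:
        result.identifications.to_csv(outdir / "identification_report.tsv",
                                      sep="\t", index=False)
    calls = {"calls": result.profile.calls.to_dict(),
             "p_values": {k: (None if v != v else v)
                          for k, v in result.profile.p_values.items()}}
    if result.profile.phase_signs is not None:
        calls["phase_signs"] = {
            ph: result.profile.phase_signs[ph].to_dict()
            for ph in result.profile.phase_signs.columns}
    (outdir / "substrate_calls.json").write_text(json.dumps(calls, indent=1))
    if result.quantified is not None:
        result.quantified.to_csv(outdir / "quantified_baseline.tsv", sep="\t")
    if result.calibrations:
        rows = [{"metabolite": n, "rf_group": c.rf_group, "slope": c.slope,
                 "intercept": c.intercept, "adjusted_r2": c.adjusted_r2,
                 "accepted": c.accepted}
                for n, c in result.calibrations.items()]
        pd.DataFrame(rows).set_index("metabolite").to_csv(
            outdir / "calibration_report.tsv", sep="\t")
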