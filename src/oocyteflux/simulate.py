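"""Synthetic single-oocyte transport experiments rendered as GC-MS batches.

The generator has two layers:

1. **Pool dynamics** — intracellular amounts (pmol/oocyte) of every library
   metabolite integrated on a fixed 0.01 h Euler grid. Symporters follow
   competitive Michaelis-Menten influx from the (effectively infinite) medium;
   antiporters perform obligatory 1:1 exchange that conserves the summed
   intracellular amount over the substrate set while relaxing each substrate
   toward its trans-side saturation share; endogenous metabolic drift
   (branched-chain amino acids falling, anionic amino acids / glutamine / TCA
   intermediates rising over a 4 h incubation) applies to every oocyte,
   injected or not. Medium depletion is neglected (2 ml of medium vs nL of
   oocyte volume).

2. **Instrument rendering** — each pooled extract (12 oocytes by default)
   becomes one injection: peaks placed by inverting the run's alkane RT<->RI
   map at each TMS variant's library retention index (plus Gaussian RI
   jitter), heights proportional to amount x response factor with lognormal
   noise, on-column conversion (arginine->ornithine, Glu/Gln->pyroglutamate),
   a ribitol internal standard, a drifting contaminant that grows with
   injection order, and a column contaminant visible in blanks.

Batches mirror the bench protocol: a pooled-QC injection at the start and
after every 8 injections, blanks at both ends, a 21-component amino-acid
standard mix at start/middle/end (the five low-response amino acids at 10x
mass), and a 6-point calibration series per response-factor group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import (
    AMINO_ACIDS,
    ENDOGENOUS_PMOL,
    ENDOGENOUS_SUPPLEMENT_PMOL,
    LOW_RF_AMINO_ACIDS,
    MetaboliteRecord,
    TransporterModel,
    get_transporter,
    load_reference_library,
)
from .matrix import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentParams", "ExperimentDesign", "PoolState", "RenderedPeak",
    "ChromatogramRun", "MODIFIED_L15_UM", "ND96_UM", "DRIFT_RATES_PER_H",
    "simulate_pools", "render_run", "generate_batch", "render_scans",
    "simulate_abundance_matrix", "write_batch", "read_batch",
]

#: Modified biomimetic L-15 medium: free amino-acid concentrations (uM).
#: Fixture values; note the deliberately low tryptophan and anionic levels.
MODIFIED_L15_UM = {
    "Valine": 850, "Leucine": 960, "Isoleucine": 1900, "Proline": 1200,
    "Glycine": 2000, "Serine": 1900, "Alanine": 2500, "Threonine": 2500,
    "Aspartic acid": 50, "Methionine": 500, "Cysteine": 990,
    "Glutamic acid": 50, "Phenylalanine": 760, "Asparagine": 1890,
    "Glutamine": 2050, "Arginine": 2870, "Lysine": 510, "Histidine": 1600,
    "Tyrosine": 1650, "Tryptophan": 98,
}

#: Plain ND96 assay buffer: no amino acids.
ND96_UM: dict[str, float] = {}

#: Endogenous drift of un-injected oocytes over a 4 h medium incubation,
#: as first-order rates (1/h). Signs and >2-fold magnitudes follow the
#: observed divergence: BCAA fall >2-fold; aspartate, glutamine and TCA
#: intermediates rise >2-fold.
DRIFT_RATES_PER_H = {
    "Valine": math.log(0.38) / 4.0,
    "Leucine": math.log(0.38) / 4.0,
    "Isoleucine": math.log(0.38) / 4.0,
    "Aspartic acid": math.log(2.4) / 4.0,
    "Glutamine": math.log(2.2) / 4.0,
    "Glutamic acid": 0.10,
    "Citric acid": math.log(2.5) / 4.0,
    "Sucrose": 0.05,
}

#: Detector response per nmol in the vial, by response-factor class.
RESPONSE_PER_NMOL = {"high": 12000.0, "medium": 8000.0, "low": 5000.0}

#: Calibration-series amounts (nmol) per response-factor group, bracketing
#: the amounts a 12-oocyte pooled extract actually contains.
CALIBRATION_NMOL = {
    "high": (0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
    "medium": (0.25, 0.5, 1.0, 2.0, 4.0, 6.0),
    "low": (0.25, 0.5, 1.0, 2.0, 4.0, 6.0),
}

_CONTAMINANT_DRIFT = "drifting contaminant"
_CONTAMINANT_COLUMN = "column contaminant"
_CONTAMINANT_SPECTRA = {
    _CONTAMINANT_DRIFT: ((281, 1.0), (355, 0.6), (429, 0.3)),
    _CONTAMINANT_COLUMN: ((207, 1.0), (281, 0.5), (96, 0.2)),
}
_CONTAMINANT_RI = {_CONTAMINANT_DRIFT: 2050.0, _CONTAMINANT_COLUMN: 2450.0}


@dataclass(frozen=True)
class InstrumentParams:
    """Rendering parameters for one GC-MS batch."""

    response_per_nmol: dict = field(
        default_factory=lambda: dict(RESPONSE_PER_NMOL))
    height_cv: float = 0.05          # lognormal CV on peak heights
    ri_jitter_sd: float = 0.5        # Gaussian jitter on apex RI (RI units)
    spectrum_cv: float = 0.05        # lognormal CV on fragment intensities
    ribitol_nmol: float = 3.0        # nominal internal-standard load
    ribitol_cv: float = 0.03         # pipetting CV of the IS spike
    detection_floor: float = 500.0   # minimum reportable abundance
    rt_intercept_s: float = 15.0     # true RT(RI) map: rt = a + b*RI
    rt_slope_s_per_ri: float = 0.3125
    rt_shift_sd_s: float = 2.0       # per-run retention drift
    rt_scale_sd: float = 0.001
    peak_sigma_s: float = 2.5        # chromatographic peak width (Gaussian sd)
    scan_hz: float = 3.6
    contaminants: bool = True
    run_seconds: float = 1260.0      # 21 min program


@dataclass(frozen=True)
class ExperimentDesign:
    """One transporter-expression experiment: incubation design plus noise
    model. Defaults are the bench protocol's conditions (12 pooled stage-5/6
    oocytes per sample, 3 experimental repeats, 0 and 4 h timepoints)."""

    transporter: TransporterModel
    medium: dict = field(default_factory=lambda: dict(MODIFIED_L15_UM))
    preload: tuple[str, float, float] | None = None  # (name, uM, duration h)
    timepoints: tuple[float, ...] = (0.0, 4.0)
    n_oocytes_per_sample: int = 12
    n_replicates: int = 3
    oocyte_volume_nl: float = 365.0
    seed: int = 0
    drift_enabled: bool = True
    pool_cv: float = 0.10            # between-replicate lognormal CV on pools
    exchange_rate_per_h: float = 0.25
    dt_h: float = 0.01
    instrument: InstrumentParams = field(default_factory=InstrumentParams)

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be sorted")
        if any(c < 0 for c in self.medium.values()):
            raise ValueError("medium concentrations must be non-negative")
        if self.n_oocytes_per_sample < 1:
            raise ValueError("need at least one oocyte per sample")

    @property
    def phases(self) -> tuple[str, ...]:
        return ("baseline", "preloaded", "medium") if self.preload else ()


@dataclass
class PoolState:
    """Per-replicate intracellular amounts (pmol/oocyte) at sampled times."""

    times: tuple[float, ...]                 # hours, cumulative
    labels: tuple[str, ...]                  # phase or timepoint label
    amounts: pd.DataFrame                    # metabolites x sampled times

    def at(self, label: str) -> pd.Series:
        return self.amounts[label]


@dataclass(frozen=True)
class RenderedPeak:
    metabolite: str            # library name or contaminant tag
    variant: str
    apex_time_s: float
    height: float
    area: float
    spectrum: tuple[tuple[int, float], ...]


@dataclass
class ChromatogramRun:
    """One rendered GC-MS injection (peak-level representation)."""

    sample_id: str
    role: str                  # uninjected | transporter | blank | qc_pool | standard_mix
    injection_order: int
    peaks: list[RenderedPeak]
    alkane_times: dict[int, float]
    ribitol_height: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [self.alkane_times[n] for n in sorted(self.alkane_times)]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.sample_id}: alkane times not increasing")
        if any(p.height < 0 for p in self.peaks):
            raise ValueError(f"{self.sample_id}: negative peak height")


# ---------------------------------------------------------------------------
# pool dynamics

def _initial_pools(design: ExperimentDesign, replicate: int) -> pd.Series:
    """Endogenous pools for one replicate batch of oocytes.

    The draw is seeded by (seed, replicate) only, so transporter-expressing
    and un-injected samples of the same replicate share sibling oocytes from
    the same donor batch — the matched-control structure the downstream
    normalization assumes.
    """
    rng = np.random.default_rng([design.seed, 7919, replicate])
    base = dict(ENDOGENOUS_PMOL)
    base.update(ENDOGENOUS_SUPPLEMENT_PMOL)
    names = list(base)
    sigma = math.sqrt(math.log(1.0 + design.pool_cv ** 2))
    noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=len(names)))
    vals = np.array([base[n] for n in names]) * noise
    return pd.Series(vals, index=names)


def _fluxes(amounts: pd.Series, medium: dict, model: TransporterModel,
            k_exchange: float) -> pd.Series:
    """Transporter-mediated d(amount)/dt in pmol/oocyte/h."""
    names = list(amounts.index)
    flux = _fluxes_arr(amounts.to_numpy(float), names, medium, model,
                       k_exchange)
    return pd.Series(flux, index=amounts.index)


def _fluxes_arr(a: np.ndarray, names: list, medium: dict,
                model: TransporterModel, k_exchange: float) -> np.ndarray:
    flux = np.zeros_like(a)
    if model.mechanism == "none" or not model.substrates:
        return flux
    idx = {n: i for i, n in enumerate(names)}
    subs = [s for s in model.substrates if s in idx]
    sat = np.array([medium.get(s, 0.0) / model.substrates[s][0]
                    for s in subs])
    total_sat = float(sat.sum())
    if total_sat == 0.0:
        return flux
    cols = np.array([idx[s] for s in subs], dtype=int)
    if model.mechanism in ("symport", "uniport"):
        vmax = np.array([model.substrates[s][1] for s in subs])
        flux[cols] = vmax * sat / (1.0 + total_sat)
    elif model.mechanism == "antiport":
        pool_total = float(a[cols].sum())
        target = sat / total_sat * pool_total
        flux[cols] = k_exchange * (target - a[cols])
    return flux


def _integrate(amounts: pd.Series, medium: dict, model: TransporterModel,
               design: ExperimentDesign, duration_h: float) -> pd.Series:
    """Fixed-step explicit Euler over ``duration_h`` hours."""
    if duration_h <= 0:
        return amounts.copy()
    names = list(amounts.index)
    a = amounts.to_numpy(float).copy()
    drift = np.zeros_like(a)
    if design.drift_enabled:
        for i, name in enumerate(names):
            drift[i] = DRIFT_RATES_PER_H.get(name, 0.0)
    static = not drift.any() and (model.mechanism == "none"
                                  or not model.substrates)
    if static:  # no dynamics at all: the pools are constant
        return amounts.copy()
    n_steps = max(1, round(duration_h / design.dt_h))
    dt = duration_h / n_steps
    for _ in range(n_steps):
        a = a + dt * (drift * a + _fluxes_arr(a, names, medium, model,
                                              design.exchange_rate_per_h))
        if (a < 0).any():
            clipped = [names[i] for i in np.flatnonzero(a < 0)]
            logger.warning("negative pool amounts clipped to 0: %s", clipped)
            a[a < 0] = 0.0
    return pd.Series(a, index=amounts.index)


def simulate_pools(design: ExperimentDesign,
                   transporter: TransporterModel | None = None) -> list[PoolState]:
    """Integrate intracellular pools for every replicate.

    For a plain design, samples are taken at ``design.timepoints`` of the
    medium incubation. For a preload design the three sampled states are the
    baseline, the end of the preloading incubation, and the end of the
    subsequent medium incubation.
    """
    model = transporter if transporter is not None else design.transporter
    states = []
    for rep in range(design.n_replicates):
        a0 = _initial_pools(design, rep)
        if design.preload:
            name, conc, duration = design.preload
            snapshots = {"baseline": a0}
            a_pre = _integrate(a0, {name: conc}, model, design, duration)
            snapshots["preloaded"] = a_pre
            t_end = max(design.timepoints)
            snapshots["medium"] = _integrate(a_pre, design.medium, model,
                                             design, t_end)
            times = (0.0, duration, duration + t_end)
            labels = ("baseline", "preloaded", "medium")
        else:
            snapshots, prev_t, a = {}, 0.0, a0
            for t in design.timepoints:
                a = _integrate(a, design.medium, model, design, t - prev_t)
                snapshots[_tp_label(t)] = a
                prev_t = t
            times = tuple(design.timepoints)
            labels = tuple(_tp_label(t) for t in design.timepoints)
        states.append(PoolState(
            times=times, labels=labels,
            amounts=pd.DataFrame({lab: snapshots[lab] for lab in labels})))
    return states


def _tp_label(t: float) -> str:
    return f"t{t:g}"


# ---------------------------------------------------------------------------
# instrument rendering

def _rt_map(params: InstrumentParams, rng: np.random.Generator):
    a = params.rt_intercept_s + rng.normal(0.0, params.rt_shift_sd_s)
    b = params.rt_slope_s_per_ri * (1.0 + rng.normal(0.0, params.rt_scale_sd))
    return a, b


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _apply_conversion(content_nmol: dict[str, float],
                      library: list[MetaboliteRecord]) -> dict[str, float]:
    """Redistribute on-column conversion products (molar basis)."""
    out = dict(content_nmol)
    for rec in library:
        if rec.name not in content_nmol or not rec.conversion_products:
            continue
        amount = content_nmol[rec.name]
        lost = 0.0
        for product, fraction in rec.conversion_products:
            out[product] = out.get(product, 0.0) + fraction * amount
            lost += fraction
        out[rec.name] = amount * (1.0 - lost)
    return out


def render_run(content_nmol: dict[str, float], role: str, injection_order: int,
               params: InstrumentParams, rng: np.random.Generator,
               sample_id: str, library: list[MetaboliteRecord] | None = None,
               with_ribitol: bool = True, apply_conversion: bool = True,
               meta: dict | None = None) -> ChromatogramRun:
    """Render one injection from vial content (nmol per library metabolite).

    Every metabolite must exist in the reference library (hard failure
    otherwise). Peak apex times come from inverting the run's alkane RT<->RI
    map at the variant's library RI plus Gaussian jitter; heights are
    amount x response factor x variant proportion x lognormal noise.
    """
    library = library if library is not None else load_reference_library()
    by_name = {rec.name: rec for rec in library}
    unknown = [n for n in content_nmol if n not in by_name]
    if unknown:
        raise KeyError(f"metabolites not in reference library: {unknown}")

    a, b = _rt_map(params, rng)
    alkane_times = {int(rec.name[1:-7]): a + b * rec.retention_index
                    for rec in library if rec.metabolite_class == "alkane"}

    content = _apply_conversion(content_nmol, library) if apply_conversion \
        else dict(content_nmol)

    peaks: list[RenderedPeak] = []

    def add_peak(name, variant, ri, height, spectrum, pin_mz=None):
        # fragmentation-ratio noise on every ion except the quantifier
        # (pin_mz); total-signal variability is already in the height noise
        if height <= 0:
            return
        apex = a + b * (ri + rng.normal(0.0, params.ri_jitter_sd))
        area = height * params.peak_sigma_s * math.sqrt(2.0 * math.pi)
        noisy_spec = tuple(
            (mz, float(rel) if mz == pin_mz else float(rel * f))
            for (mz, rel), f in zip(
                spectrum, _lognoise(rng, params.spectrum_cv, len(spectrum))))
        peaks.append(RenderedPeak(name, variant, float(apex),
                                  float(height), float(area), noisy_spec))

    # alkane ladder: apex exactly on the run's RT map (the anchors themselves)
    for rec in library:
        if rec.metabolite_class == "alkane":
            h = 2.0e4 * float(_lognoise(rng, params.height_cv))
            area = h * params.peak_sigma_s * math.sqrt(2.0 * math.pi)
            peaks.append(RenderedPeak(rec.name, "parent",
                                      alkane_times[int(rec.name[1:-7])],
                                      h, area, rec.spectrum))

    for name, nmol in content.items():
        rec = by_name[name]
        rf = params.response_per_nmol[rec.rf_class]
        for label, proportion, vri in rec.tms_variants:
            h = nmol * rf * proportion * float(_lognoise(rng, params.height_cv))
            if h < 1.0:
                continue
            add_peak(name, label, vri, h, rec.spectrum,
                     pin_mz=rec.quantifier_mz)

    ribitol_height = None
    if with_ribitol:
        rec = by_name["Ribitol"]
        nominal = params.ribitol_nmol * (1.0 + rng.normal(0.0, params.ribitol_cv))
        ribitol_height = max(nominal, 0.0) * params.response_per_nmol[rec.rf_class]
        add_peak("Ribitol", "main", rec.retention_index, ribitol_height,
                 rec.spectrum, pin_mz=rec.quantifier_mz)

    if params.contaminants:
        drift_h = 800.0 + 450.0 * injection_order
        add_peak(_CONTAMINANT_DRIFT, "contaminant",
                 _CONTAMINANT_RI[_CONTAMINANT_DRIFT],
                 drift_h * float(_lognoise(rng, params.height_cv)),
                 _CONTAMINANT_SPECTRA[_CONTAMINANT_DRIFT])
        add_peak(_CONTAMINANT_COLUMN, "contaminant",
                 _CONTAMINANT_RI[_CONTAMINANT_COLUMN],
                 6000.0 * float(_lognoise(rng, params.height_cv)),
                 _CONTAMINANT_SPECTRA[_CONTAMINANT_COLUMN])

    peaks.sort(key=lambda p: p.apex_time_s)
    return ChromatogramRun(sample_id=sample_id, role=role,
                           injection_order=injection_order, peaks=peaks,
                           alkane_times=alkane_times,
                           ribitol_height=ribitol_height, meta=meta or {})


# ---------------------------------------------------------------------------
# batch assembly

def _pool_to_nmol(amounts: pd.Series, design: ExperimentDesign) -> dict[str, float]:
    factor = design.n_oocytes_per_sample / 1000.0
    return {name: float(val) * factor
            for name, val in amounts.items() if val > 0}


def _standard_mix_nmol(library: list[MetaboliteRecord]) -> dict[str, float]:
    """21-component standard: 20 amino acids + ornithine, 1 ug each, the five
    low-response amino acids at 10 ug."""
    out = {}
    by_name = {rec.name: rec for rec in library}
    for name in list(AMINO_ACIDS) + ["Ornithine"]:
        ug = 10.0 if name in LOW_RF_AMINO_ACIDS else 1.0
        out[name] = ug / by_name[name].mw * 1000.0
    return out


def generate_batch(design: ExperimentDesign):
    """Generate every injection of one batch plus its manifest.

    Returns ``(runs, manifest)`` where manifest is a DataFrame (one row per
    injection, injection order 1-based) recording sample role, transporter,
    timepoint/phase, replicate, standard amounts and the design seed.
    Regeneration with the same design is byte-identical.
    """
    library = load_reference_library()
    rng = np.random.default_rng([design.seed, 104729])
    model = design.transporter
    none_model = TransporterModel("uninjected", "none", {})

    pools_tx = simulate_pools(design, model)
    pools_ui = simulate_pools(design, none_model)

    # --- assemble the planned (pre-QC-interleave) injection list -----------
    planned = []  # (role, content or None, meta)

    def plan(role, content, **meta):
        planned.append((role, content, meta))

    std_mix = _standard_mix_nmol(library)
    plan("blank", None, kind="blank_start")
    plan("standard_mix", dict(std_mix), kind="std", position="start")

    bio_contents = []
    labels = design.phases or tuple(_tp_label(t) for t in design.timepoints)
    for rep in range(design.n_replicates):
        for label in labels:
            for role, pools in (("transporter", pools_tx),
                                ("uninjected", pools_ui)):
                content = _pool_to_nmol(pools[rep].at(label), design)
                bio_contents.append(content)
                plan(role, content, replicate=rep,
                     timepoint=label,
                     transporter=model.name if role == "transporter"
                     else "uninjected")

    plan("standard_mix", dict(std_mix), kind="std", position="mid")

    for rf_group, amounts in CALIBRATION_NMOL.items():
        members = [rec.name for rec in library
                   if rec.rf_class == rf_group
                   and rec.name in set(AMINO_ACIDS) | {"Ornithine"}]
        for level, nmol in enumerate(amounts):
            plan("standard_mix", {m: nmol for m in members},
                 kind="calibration", rf_group=rf_group,
                 series_level=level, std_nmol=nmol)

    plan("standard_mix", dict(std_mix), kind="std", position="end")
    plan("blank", None, kind="blank_end")

    # pooled QC: aliquot of every biological extract
    qc_content: dict[str, float] = {}
    for content in bio_contents:
        for name, nmol in content.items():
            qc_content[name] = qc_content.get(name, 0.0) + nmol
    qc_content = {k: v / len(bio_contents) for k, v in qc_content.items()}

    # interleave: QC first, then after every 8 injections
    sequence = []
    pending = list(planned)
    counter = 0
    sequence.append(("qc_pool", dict(qc_content), {"kind": "qc"}))
    while pending:
        sequence.append(pending.pop(0))
        counter += 1
        if counter % 8 == 0 and pending:
            sequence.append(("qc_pool", dict(qc_content), {"kind": "qc"}))

    runs, records = [], []
    for order, (role, content, meta) in enumerate(sequence, start=1):
        sid = f"{role}_{order:03d}"
        if role == "blank":
            run = render_run({}, role, order, design.instrument, rng, sid,
                             library=library, with_ribitol=False, meta=meta)
        elif role == "standard_mix":
            # standards derivatize like any extract: the same on-column
            # conversion applies, so calibration absorbs the conversion loss
            run = render_run(content, role, order, design.instrument, rng,
                             sid, library=library, with_ribitol=True,
                             meta=meta)
        else:
            run = render_run(content, role, order, design.instrument, rng,
                             sid, library=library, with_ribitol=True, meta=meta)
        runs.append(run)
        rec = {"sample_id": sid, "role": role, "injection_order": order,
               "replicate": meta.get("replicate", -1),
               "timepoint": meta.get("timepoint", ""),
               "transporter": meta.get("transporter", ""),
               "kind": meta.get("kind", "sample"),
               "rf_group": meta.get("rf_group", ""),
               "std_nmol": meta.get("std_nmol", float("nan")),
               "seed": design.seed}
        records.append(rec)
    manifest = pd.DataFrame(records).set_index("sample_id")
    return runs, manifest


# ---------------------------------------------------------------------------
# scan-level rendering (for the peak-detection path)

def render_scans(run: ChromatogramRun, params: InstrumentParams | None = None,
                 t_start: float | None = None, t_stop: float | None = None):
    """Expand a peak-level run into centroided scan data.

    Returns ``(scan_times_s, mz_axis, intensity)`` with ``intensity`` of shape
    (n_scans, n_mz): each peak is a Gaussian in time at its apex multiplied by
    its fragment spectrum across unit m/z bins.
    """
    params = params or InstrumentParams()
    if t_start is None:
        t_start = 0.0
    if t_stop is None:
        t_stop = params.run_seconds
    dt = 1.0 / params.scan_hz
    times = np.arange(t_start, t_stop, dt)
    mz_axis = np.arange(40, 601)
    intensity = np.zeros((times.size, mz_axis.size))
    sig = params.peak_sigma_s
    for peak in run.peaks:
        if peak.apex_time_s < t_start - 6 * sig or peak.apex_time_s > t_stop + 6 * sig:
            continue
        shape = np.exp(-0.5 * ((times - peak.apex_time_s) / sig) ** 2)
        for mz, rel in peak.spectrum:
            intensity[:, mz - 40] += peak.height * rel * shape
    return times, mz_axis, intensity


# ---------------------------------------------------------------------------
# fast path: abundance matrix without chromatogram rendering

def simulate_abundance_matrix(design: ExperimentDesign) -> AbundanceMatrix:
    """Simulate pools and render quantifier-ion heights directly into an
    :class:`AbundanceMatrix`, bypassing peak lists and identification.

    Used for statistical calibration at scale (hundreds of simulated batches);
    the height model (response factors, conversion, lognormal noise, ribitol
    internal standard, detection floor with censoring) is identical to the
    full rendering path.
    """
    library = load_reference_library()
    by_name = {rec.name: rec for rec in library}
    rng = np.random.default_rng([design.seed, 104729])
    model = design.transporter
    none_model = TransporterModel("uninjected", "none", {})
    pools = {"transporter": simulate_pools(design, model),
             "uninjected": simulate_pools(design, none_model)}
    params = design.instrument

    labels = design.phases or tuple(_tp_label(t) for t in design.timepoints)
    met_names = [rec.name for rec in library
                 if rec.metabolite_class not in ("alkane",)]
    cols, meta_rows = {}, []
    order = 0
    for rep in range(design.n_replicates):
        for label in labels:
            for role in ("transporter", "uninjected"):
                order += 1
                sid = f"{role}_r{rep}_{label}"
                content = _pool_to_nmol(pools[role][rep].at(label), design)
                content = _apply_conversion(content, library)
                heights = {}
                for name in met_names:
                    if name == "Ribitol":
                        continue
                    rec = by_name[name]
                    nmol = content.get(name, 0.0)
                    _, prop, _ = rec.dominant_variant
                    h = nmol * params.response_per_nmol[rec.rf_class] * prop \
                        * float(_lognoise(rng, params.height_cv))
                    heights[name] = h
                nominal = params.ribitol_nmol * (
                    1.0 + rng.normal(0.0, params.ribitol_cv))
                rib = max(nominal, 0.0) * params.response_per_nmol[
                    by_name["Ribitol"].rf_class]
                heights["Ribitol"] = rib
                cols[sid] = heights
                meta_rows.append({
                    "sample_id": sid, "role": role, "replicate": rep,
                    "timepoint": label, "injection_order": order,
                    "transporter": model.name if role == "transporter"
                    else "uninjected",
                    "ribitol_height": rib})
    values = pd.DataFrame(cols)
    censored = values < params.detection_floor
    values = values.clip(lower=params.detection_floor)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return AbundanceMatrix(values=values, samples=samples, censored=censored)


# ---------------------------------------------------------------------------
# plain-text writers/readers (one CSV per injection + TSV manifest)

def _spectrum_str(spec) -> str:
    return ";".join(f"{mz}:{rel:.6g}" for mz, rel in spec)


def _parse_spectrum(text: str):
    out = []
    for part in text.split(";"):
        mz, rel = part.split(":")
        out.append((int(mz), float(rel)))
    return tuple(out)


def write_batch(runs, manifest: pd.DataFrame, outdir) -> None:
    """Write a batch as one peak-list CSV per injection plus manifest.tsv."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = manifest.copy()
    man["file"] = [f"{sid}.csv" for sid in man.index]
    for run in runs:
        rows = [{"metabolite": p.metabolite, "variant": p.variant,
                 "apex_time_s": f"{p.apex_time_s:.6f}",
                 "height": f"{p.height:.6f}", "area": f"{p.area:.6f}",
                 "spectrum": _spectrum_str(p.spectrum)} for p in run.peaks]
        pd.DataFrame(rows).to_csv(outdir / f"{run.sample_id}.csv", index=False)
    man.to_csv(outdir / "manifest.tsv", sep="\t")


def read_batch(indir):
    """Read back a batch written by :func:`write_batch`.

    Alkane anchor times are recovered from the alkane peaks of each file, so
    the reader does not depend on any hidden rendering state.
    """
    from pathlib import Path
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t",
                           index_col="sample_id",
                           keep_default_na=False,
                           na_values=[""])
    runs = []
    for sid, row in manifest.iterrows():
        df = pd.read_csv(indir / row["file"], keep_default_na=False)
        peaks = [RenderedPeak(r["metabolite"], r["variant"],
                              float(r["apex_time_s"]), float(r["height"]),
                              float(r["area"]), _parse_spectrum(r["spectrum"]))
                 for _, r in df.iterrows()]
        alkane_times = {int(p.metabolite[1:-7]): p.apex_time_s
                        for p in peaks if p.metabolite.endswith(" alkane")}
        rib = [p.height for p in peaks if p.metabolite == "Ribitol"]
        run = ChromatogramRun(
            sample_id=sid, role=row["role"],
            injection_order=int(row["injection_order"]), peaks=peaks,
            alkane_times=alkane_times,
            ribitol_height=rib[0] if rib else None,
            meta={k: row[k] for k in ("replicate", "timepoint", "transporter",
                                      "kind", "rf_group", "std_nmol")
                  if k in row.index})
        runs.append(run)
    return runs, manifest


def design_for(transporter_name: str, **kwargs) -> ExperimentDesign:
    """Convenience constructor resolving a transporter fixture by name."""
    return ExperimentDesign(transporter=get_transporter(transporter_name),
                            **kwargs)
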