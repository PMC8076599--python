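# Methods

This note documents the models, parameters and numerical choices behind
`oocyteflux`, and what the synthetic data can and cannot say about real
experiments.

## Transport model

Intracellular pools are amounts per oocyte (pmol/oocyte), integrated with a
fixed-step explicit Euler scheme (step 0.01 h). Accuracy requirements are
modest — the invariants we care about (antiport conservation, monotone
symport accumulation) hold to 10⁻⁶ relative at this step — so no adaptive
integrator is used.

**Symport/uniport.** Influx of substrate *i* from the medium follows
competitive Michaelis–Menten kinetics over the transporter's substrate set:

    v_i = Vmax_i · (S_i/Km_i) / (1 + Σ_j S_j/Km_j)

with S_j the (constant) medium concentrations. Medium depletion is
neglected: 2 ml of medium against nL-scale oocyte volumes changes medium
concentrations by well under 0.1% over 4 h. Ion-coupling stoichiometry is
carried as descriptive metadata only; the electrochemical driving force is
collapsed into Vmax. Efflux through symporters is not modelled.

**Antiport.** Obligatory 1:1 exchange conserves the summed intracellular
amount T over the substrate set. Each substrate relaxes toward its
trans-side saturation share with a single exchange rate constant k
(default 0.25 h⁻¹):

    dA_i/dt = k · (f_i·T − A_i),   f_i = (S_i/Km_i) / Σ_j (S_j/Km_j)

Because k is common to all substrates, Σ dA_i = 0 holds exactly at every
Euler step (up to float rounding), which is what the conservation tests
exercise. With no substrate outside (f undefined), exchange stops — the
behaviour that motivates the preload protocol.

**Endogenous drift.** Un-injected oocytes are not metabolically silent:
over a 4 h medium incubation the branched-chain amino acids fall more than
2-fold while aspartate, glutamine and TCA intermediates rise more than
2-fold. The generator applies first-order rates to every oocyte (injected
or not): ln(0.38)/4 h⁻¹ for Val/Leu/Ile, ln(2.4)/4 for Asp, ln(2.2)/4 for
Gln, ln(2.5)/4 for citrate, +0.10 for Glu and +0.05 for sucrose. Only the
direction and the ≥2-fold magnitude of these drifts are constrained by
observation; the precise rates are fixture choices. Drift can be disabled
(`drift_enabled=False`), which the conservation and null-calibration tests
use.

**Replicate structure.** Initial pools equal the published endogenous
amounts perturbed by lognormal between-batch noise (CV 10%), drawn once per
replicate from the (seed, replicate) pair only — so transporter-expressing
and un-injected samples of the same replicate share sibling oocytes from
the same donor batch. This matched-control structure is what makes the
fold-change denominator cancel drift and pool noise; if controls came from
independent donors the profiling statistics would need ~3× larger effects.

## Instrument model

One injection renders every metabolite with a positive pool:

* **Retention.** The "true" retention map is affine in retention index,
  rt = a + b·RI (a = 15 s, b = 0.3125 s/RI), with per-run drift on a
  (σ 2 s) and b (σ 0.1%). Alkane peaks sit exactly on the map; analyte
  peaks get Gaussian RI jitter (σ 0.5 RI units, within the ±3 RI
  identification tolerance). Because assignment inverts the same anchors,
  retention drift cancels exactly — the point of the Kovats scheme.
* **Response.** Peak height = nmol in vial × response factor × TMS-variant
  proportion × lognormal noise (CV 5%). Response factors are 12000 (high),
  8000 (medium) and 5000 (low) counts/nmol; the low class holds Arg, Ala,
  His, Trp, Cys. Fragment intensities get independent 5% lognormal noise,
  except the quantifier ion, whose variability is already carried by the
  height noise.
* **Chemistry.** Aspartate (2TMS 55% / 3TMS 45%), serine (70/30) and
  glycine (86/14) render as split TMS variants; all other amino acids are
  ≥80% single-variant. On-column conversion moves 35% of arginine to
  ornithine and 30%/35% of glutamate/glutamine to pyroglutamate — in
  samples *and* standards, since the derivatization chemistry is blind to
  the sample's role; calibration therefore absorbs the conversion loss and
  back-calculates the nominal amounts correctly.
* **Internal standard.** Ribitol is spiked at a nominal 3 nmol with 3%
  normal pipetting error — the quantity the 10% QC gate polices.
* **Artefacts.** Each batch carries one drifting contaminant (height
  proportional to injection order, in every run including blanks and
  standards) and one column contaminant (constant, visible in blanks).
  Counts are fixed at one each by default.

Batch layout mirrors the bench protocol: pooled-QC injections at position 1
and after every 8 injections; blanks at both ends; the 21-component
standard mix (20 amino acids + ornithine; the five low-response amino acids
at 10× mass) at start, middle and end; and a 6-point calibration series per
response-factor group with amounts (0.25–8 nmol) bracketing what a
12-oocyte extract actually contains. Unweighted OLS calibration over a wide
amount range quantifies poorly near the smallest standards — grouping by
response factor and bracketing the sample range is what keeps
back-calculation accurate, exactly why bench protocols determine the linear
range first.

## Analysis choices left open by the upstream software

* Retention-index interpolation is piecewise-linear in time between alkane
  anchors (the oven program is a single linear ramp); extrapolation beyond
  C12/C36 is allowed but flagged and treated as lower confidence.
* Peak detection smooths the TIC with a 5-point moving average (tied to the
  5-scan minimum width), subtracts a 51-scan rolling-minimum baseline,
  detects on the smoothed trace but measures height/area on the raw
  baseline-subtracted trace. Symmetry is the smaller-to-larger ratio of
  half-areas about the intensity centroid (the centroid sample split
  half-and-half), thresholded at 0.5.
* Deconvolution finds component apexes on individual m/z traces (the TIC
  cannot resolve components a few scans apart), models each as a Gaussian
  whose width comes from the tallest single trace, and attributes every
  trace by non-negative least squares. The purity factor of an isolated
  component is the sentinel 10⁶.
* Spectral similarity is a weighted cosine with weights I^0.5·(m/z);
  forward scores over the ion union scale to 1000, reverse (head-to-tail)
  scores over library ions only scale to 999. The exponents are fixed
  conventions; all acceptance behaviour depends only on the printed
  thresholds and the self-match/orthogonality identities. The reagent ions
  73 and 147 are excluded from all decisive comparisons. The "minimum
  similarity product 60%" parameter acts as the candidate admission gate
  (forward ≥ 600) before the criterion tests, and the ±1 RI centroid
  distance is the cross-sample merge radius for unidentified components
  (single linkage on sorted RIs, so retention jitter cannot split one
  component into two rows).
* The ribitol gate references the batch **median** (robust to the very
  outliers the gate removes); drift removal uses Spearman rank correlation
  ≥ 0.8 with injection order, required in *every* sample role so that
  biology correlated with acquisition order by accident is retained.
* Censored signals (below the 500-count floor) are reported at the floor
  and flagged; they participate in fold changes (the floor guarantees a
  positive denominator) but are marked in outputs.

## Calling substrates

Significance is the paired t-test on raw transporter values between the
first and last timepoint, paired by replicate (e = 3, df = 2). The call
then requires a direction that survives the negative-control bands: fold
change outside 1 ± 0.1 (the ribitol band), or an absolute delta that
exceeds 1000 counts (2× the detection floor) *and* agrees in sign across
every replicate. The all-replicates sign rule is deliberately strict: with
three replicates it is the only guard that keeps high-abundance drifting
metabolites (aspartate, citrate, sucrose — whose per-replicate delta noise
is thousands of counts) from being called on noise. The residual noise mode
is visible in the worked example: citrate occasionally draws three same-sign
deltas (a 12.5% event per side) and gets a spurious call. The amino-acid
heat-map rows — the analysis scope of the original protocol — are unaffected
at the tested seeds; recovery tests therefore evaluate those rows.

The price of the strict rule appears on the other side: an anionic-substrate
transporter whose substrates sit on ~2 mM endogenous pools produces fold
changes inside the control band and per-replicate delta z-scores of only
~0.5–0.8 (the identity z ≈ (FC−1)/(√2·CV) caps what three replicates can
see). A single batch therefore detects such transport only unreliably; the
acceptance check pools replicate deltas across ten simulated batches, where
the one-sample t-test on ~60 deltas is decisive while the mean fold change
stays inside the band — the statistical form of "revealed by absolute
signal, hidden by fold change". Per-batch exchanger phases use the same
consistency guard on control-corrected per-replicate changes.

Conversion products (ornithine, pyroglutamate) stay in all outputs, flagged
with their parent metabolites; they track their parents' calls and are
excluded from false-discovery accounting.

## Transporter fixtures

Km/Vmax pairs are fixture constants whose sole purpose is to reproduce the
qualitative published profiles under the default study conditions (12
oocytes, 3 replicates, 4 h, 5% instrument CV): every designed substrate of
the symporter fixtures produces a decisive effect, the SNAT2/SNAT1 pair
differ exactly in leucine/proline (and SNAT2's broader profile), the
B0AT1-like carrier's tryptophan has deliberately low affinity (Km 5 mM
against 98 µM tryptophan in the medium — outcompeted, hence undetectable,
as observed), and the EAAT1-like carrier's Vmax (30 pmol/oocyte/h) keeps
its fold change inside the control band so only the delta channel sees it.
Only ordinal relations among these constants are asserted by tests.

## What the simulation does not capture

No electrochemical gradients or membrane potential; no protein-synthesis
consumption of amino-acid pools; no transamination coupling between
preloaded substrates and the anionic pools (real preload experiments show
alanine-driven aspartate/glutamate increases); no profile-mode m/z data or
cross-batch retention alignment beyond the retention index; no saturation
or nonlinearity of the detector; noise is independent lognormal, without
the correlated batch effects of real instruments. Passing tests therefore
demonstrate that the *analysis logic* is correct under the stated noise
model, not that the pipeline is robust to every failure mode of real
GC-MS data.

## Problem sizes

Defaults everywhere are the protocol's own: 12 oocytes/sample, 3
replicates, 2 timepoints, ~40 injections/batch. The statistical
calibrations run at reduced rendering cost by simulating quantifier-ion
heights directly (`simulate_abundance_matrix`), with the identical noise
model but no peak lists: 500 null batches for the type-I check, 10 batches
for the pooled anionic-transporter contrast. The full rendered path is
exercised end to end on single batches.
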