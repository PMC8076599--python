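# oocyteflux

Single-cell GC-MS substrate profiling of membrane transporters expressed in
*Xenopus laevis* oocytes — as a fully simulated, end-to-end tested pipeline.

## The problem

Amino-acid transporters are usually characterized one substrate at a time.
An alternative is metabolomic profiling: express a transporter in *X. laevis*
oocytes, incubate batches of 12 pooled stage-5/6 oocytes in a complex
biomimetic medium (modified L-15), and measure the intracellular metabolite
pools by GC-MS before and after incubation. Comparing transporter-expressing
oocytes with matched un-injected controls yields the transporter's
comprehensive substrate profile in one experiment — for symporters by
accumulation, for obligatory 1:1 exchangers (antiporters) via a
preload/efflux protocol.

`oocyteflux` implements both halves of that workflow for people developing
or teaching such analyses:

* a **synthetic-data generator** that simulates the transport biology
  (competitive Michaelis–Menten symport, conservation-respecting antiport,
  endogenous metabolic drift of un-injected oocytes) and renders complete
  GC-MS batches — alkane retention-index ladder (C12–C36), ribitol internal
  standard, TMS-derivative splitting, on-column conversion (Arg→ornithine,
  Glu/Gln→pyroglutamate), pooled-QC injections every 8 samples, blanks,
  amino-acid standard mixes and 6-point calibration series, with drifting
  and column contaminants;
* an **analysis pipeline** that takes such batches back to biology: Kovats
  retention-index calibration, peak detection/deconvolution, three-criterion
  spectral identification with qualifier-ion validation, internal-standard
  QC, absolute quantification, and the dual fold-change / absolute-delta
  substrate-profiling statistics with paired t-tests.

## The statistics at the core

For metabolite $m$ at timepoint $t$, with transporter-expressing samples
$x$ and matched un-injected controls $u$:

* fold change $\mathrm{FC}(m,t) = \bar{x}_{mt} / \bar{u}_{mt}$ — robust to
  endogenous drift, but blind to transport of metabolites with large
  endogenous pools (anionic amino acids sit at ~2 mM in the oocyte);
* absolute delta $\Delta(m,t) = \bar{x}_{mt} - \bar{u}_{mt}$ — exposes
  exactly those cases;
* significance: two-sided paired *t*-test on raw transporter-sample values
  between 0 h and 4 h, paired by replicate batch ($e = 3$), no
  multiple-testing correction (a Benjamini–Hochberg column is reported).

A metabolite is called **accumulated** when the change is significant
(p < 0.05) and either FC exceeds the negative-control band 1 ± 0.1 (the
band defined by the ribitol internal standard) or Δ is consistently
positive in every replicate and exceeds an absolute floor; **depleted**
symmetrically. Retention indices are piecewise-linear between alkane
anchors: between C$_a$ and C$_b$,
$\mathrm{RI}(t) = 100a + 100(b-a)\,(t-t_a)/(t_b-t_a)$.

Absolute quantification uses per-amino-acid ordinary-least-squares curves
(peak height vs nmol, six points, grouped by response factor; adjusted
R² ≥ 0.94 required) and converts to concentration through the oocyte's
water-accessible volume: pmol/oocyte = µM × 0.365.

## Worked example

`python examples/05_substrate_profile.py` simulates a SNAT2-like
(sodium-neutral-amino-acid symporter) batch, analyses it end to end and
prints:

```
metabolite            FC(4h)  delta(4h)        p  call
Alanine                 2.75       8993   0.0004  accumulated
Asparagine              1.58      13267   0.0008  accumulated
Citric acid             0.97      -2702   0.0048  depleted
Glutamine               1.18      12983   0.0007  accumulated
Glycine                 3.66       5696   0.0001  accumulated
Histidine               1.67       1869   0.0025  accumulated
Leucine                 1.80       1163   0.0265  accumulated
Methionine              1.64       2904   0.0010  accumulated
Proline                 1.58       9815   0.0365  accumulated
Pyroglutamic acid       1.13       8093   0.0248  accumulated
Serine                  2.00       6495   0.0008  accumulated
Threonine               3.08       6197   0.0007  accumulated

ribitol negative control: max |FC - 1| = 0.060 over 12 retained samples
```

Reading it: the recovered "accumulated" set is the SNAT2-like fixture's
substrate set — including leucine and proline, the substrates that
distinguish it from its close paralog SNAT1 — plus pyroglutamate, the known
GC-MS conversion product of the substrate glutamine. The ribitol internal
standard stays inside the 1 ± 0.1 negative-control band. (Citrate is a
drifting endogenous metabolite outside the amino-acid heat-map rows; its
call is a known noise mode discussed in `docs/methods.md`.)

`examples/04_identify_and_quantify.py` prints the absolute quantification
of the un-injected baseline — e.g. valine 488 µM / 178 pmol per oocyte
against the published endogenous pool of 499 µM / 182 pmol per oocyte.
`examples/06_exchanger_preload.py` shows the two-phase preload/efflux
profile of a LAT1-like exchanger.

## Layout

```
src/oocyteflux/
  library.py    packaged reference data: metabolite records, transporters
  data/         versioned JSON fixtures (see file headers for provenance)
  simulate.py   pool dynamics + GC-MS batch rendering
  rindex.py     Kovats retention-index calibration (alkane ladder)
  peaks.py      peak detection, deconvolution, EIC extraction
  identify.py   spectral scoring and the three identification criteria
  qc.py         ribitol gate, drift/blank filters, internal-peak stripping
  quantify.py   linear calibration and absolute quantification
  profiles.py   fold-change / delta profiling, calls, exchanger phases
  pipeline.py   orchestration; matrix.py  the metabolite x sample container
  cli.py        thin command-line front end
```

The library fixture schema (`data/metabolite_library.json`): one record per
metabolite with `name`, `class`, `retention_index`, `quantifier_mz` (the
EIC ion), `rf_class` (high/medium/low response factor), `mw`, `spectrum`
(list of `[mz, relative_intensity]`, max-normalized), `tms_variants`
(label/proportion/RI per TMS derivative) and `conversion_products`
(product/fraction). `data/transporters.json`: `name`, `mechanism`
(symport/antiport/uniport/none), `substrates` mapping name → [Km µM,
Vmax pmol/oocyte/h], and descriptive `stoichiometry`.
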