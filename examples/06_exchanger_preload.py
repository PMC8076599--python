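"""Exchanger profiling with the preload/efflux protocol.

Obligatory 1:1 exchangers do not change the summed substrate pool, so a
plain incubation shows little. Preloading the oocytes with 10 mM isoleucine
for 6 h drives an imbalance: during preloading the exchanger imports Ile in
exchange for preferred cytosolic substrates (efflux substrates deplete);
during the subsequent 4 h medium incubation the preloaded Ile exchanges back
out against the preferred extracellular substrates (influx substrates
accumulate). Signs are printed per phase for a LAT1-like exchanger.
"""

from oocyteflux import PipelineConfig, run_profile, run_simulate

cfg = PipelineConfig(transporter="LAT1-like", seed=1,
                     preload=("Isoleucine", 10000.0, 6.0))
batch = run_simulate(cfg, "scratch_example_lat1")
profile = run_profile(batch, cfg).profile

signs = profile.phase_signs
marked = signs[(signs["preload"] != "") | (signs["medium"] != "")]
print(f"{'metabolite':20s} {'preload':>8s} {'medium':>7s}")
for met, row in marked.iterrows():
    print(f"{met:20s} {row['preload']:>8s} {row['medium']:>7s}")
print("\n(+ = increased during that incubation step, - = decreased;"
      "\n preload: Ile in, efflux substrates out; medium: Ile out,"
      "\n influx substrates in)")
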