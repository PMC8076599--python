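"""Browse the packaged reference library and transporter fixtures.

Prints a few metabolite entries (retention index, quantifier ion, response
class) and the substrate table of the SNAT2-like symporter. The quantifier
ions are the EIC values used for quantification throughout the pipeline.
"""

from oocyteflux import load_reference_library, load_transporter_models

library = load_reference_library()
print(f"{len(library)} library records\n")
print(f"{'metabolite':22s} {'RI':>8s} {'EIC m/z':>8s} {'Rf class':>9s}")
for rec in library:
    if rec.name in ("Valine", "Leucine", "Isoleucine", "Glutamic acid",
                    "Ribitol", "Sucrose"):
        print(f"{rec.name:22s} {rec.retention_index:8.1f} "
              f"{rec.quantifier_mz:8d} {rec.rf_class:>9s}")

snat2 = next(m for m in load_transporter_models() if m.name == "SNAT2-like")
print(f"\n{snat2.name} ({snat2.mechanism}, {snat2.stoichiometry})")
for sub, (km, vmax) in sorted(snat2.substrates.items()):
    print(f"  {sub:15s} Km {km:5.0f} uM   Vmax {vmax:4.0f} pmol/oocyte/h")
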