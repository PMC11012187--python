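"""Build the 2^3 + 3-center experimental design and inspect factor coding.

The three extraction factors (solvent-to-solid ratio, time, temperature) are
coded to -1/0/+1; the 8 corner runs plus 3 center replicates give 11 runs
with 3 residual degrees of freedom for the 8-term model.
"""

import mae_lipidomics as ml

design = ml.default_design()
print(design.to_frame().to_string(index=False))
print()
print(f"{design.n_runs} runs: 8 factorial corners + 3 center replicates")
center = design.real[design.is_center][0]
print(
    "center point in real units:",
    f"{center[0]:g} mL/g solvent-to-solid, {center[1]:g} min, {center[2]:g} degC",
    "(the settings every run of the solvent-screening step used)",
)
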