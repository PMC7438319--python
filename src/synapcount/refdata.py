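"""Published summary statistics for mouse hippocampal CA1.

Layer-level means for PSD95/SAP102 puncta densities (SDM, puncta/100 um^2),
colocalization indexes, printed total puncta densities, asymmetric-synapse
densities (FIB-SEM, synapses/um^3), and the acquisition/stereology
aggregates of the CA1 study system.  These are reference inputs: the
pipeline recomputes conversion factors and extrapolations from them, and
uses them as the default magnitudes for the synthetic study conditions.

Note the printed total densities are per-section values averaged afterwards,
so they differ slightly from the closed formula applied to the printed
layer-mean densities.
"""

from __future__ import annotations

import pandas as pd

#: Layer means: dPSD95, dSAP102 (puncta/100 um^2), colocalization index c,
#: printed total puncta density, AS density (synapses/um^3).
CA1_LAYER_SUMMARY = pd.DataFrame(
    [
        ("SLM", 91.3103, 77.1788, 0.5840, 106.4372, 1.5958),
        ("SR", 118.4513, 122.7022, 0.6633, 145.1760, 2.3076),
        ("SO", 119.7759, 115.6872, 0.6741, 140.7479, 2.4887),
        ("all", 109.8458, 105.1894, 0.6404, 130.7871, 2.1307),
    ],
    columns=["layer", "dPSD95", "dSAP102", "c", "dTotal", "as_density"],
)

#: Log-normal size parameters (log-nm^2 scale), all-layers pools.
SIZE_LOGNORMAL = {
    "psd95_puncta": {"mu": 11.21, "sigma": 0.46, "n": 463_637},
    "AS": {"mu": 10.54, "sigma": 0.64, "n": 11_878},
    "SS": {"mu": 10.70, "sigma": 0.69, "n": 427},
}

#: FIB-SEM acquisition and stereology aggregates.
EM_AGGREGATES = {
    "n_stacks": 12,
    "n_sections_total": 3_316,
    "stack_volume_total_um3": 6_067.86,      # after shrinkage correction
    "frame_volume_total_um3": 4_905.07,
    "n_synapses_total": 10_460,
    "fraction_as_pct": 95.60,
}

#: Instrument geometry.
GEOMETRY = {
    "sdm_pixel_nm": 84.0,
    "sdm_field_um": 43.008,
    "em_pixel_nm": 5.0,
    "em_section_nm": 20.0,
    "em_image_px": (2048, 1536),
    "shrinkage_linear": 0.9508,
}
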