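"""Build a synthetic iota-carrageenan standard spectrum and classify it.

A noise-free spectrum is synthesized from the band positions measured on a
commercial iota-carrageenan standard, then pushed through baseline
correction, peak/shoulder detection and diagnostic band matching. The
printed row follows the band-table convention: a wavenumber when the band
is matched, "+" for a weak band, "-" for an absent one. The classifier
should call it iota: both iota-exclusive sulfate bands (DA2S near 805 and
DA2S* near 905 cm^-1) are present.
"""

from phycoftir import analyze_spectrum, simulate_spectrum
from phycoftir.band_model import render_cell

spectrum, planted = simulate_spectrum({"iota": 1.0}, seed=0)
report, profile = analyze_spectrum(spectrum, "carrageenan")

codes = report.library.codes()
print("\t".join(codes))
print("\t".join(render_cell(report[c]) for c in codes))
print(f"dominant type : {profile.dominant}")
print(f"colloid family: {profile.colloid_family}")
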