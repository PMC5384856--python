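"""Band reshaping from a field-induced frequency shift.

A pure shift of an absorption band produces a dispersive difference
spectrum (bleach + displaced enhancement).  The published arithmetic:
a 25 MV/cm field reduction at a = 0.4 cm^-1/(MV/cm) shifts the
symmetric PO2 stretch by 10 cm^-1.
"""

import shellfield as sf

coeff = sf.PO2_SYMMETRIC_STRETCH
for delta_e in (25.0, 5.0):
    print(f"ΔE = {delta_e:4.0f} MV/cm  →  Δν = {sf.stark_shift(delta_e, coeff):.1f} cm^-1")

band = sf.AbsorptionBand(center=1087.0, fwhm=20.0, amplitude=5.0)
ds = sf.difference_spectrum(band, sf.stark_shift(25.0, coeff))
sep = sf.extrema_separation(ds)
print(f"\nband: Gaussian at {band.center:g} cm^-1, FWHM {band.fwhm:g} cm^-1")
print(f"bleach/enhancement separation for a 10 cm^-1 shift: {sep:.1f} cm^-1")

small = sf.difference_spectrum(band, sf.stark_shift(5.0, coeff))
print(f"separation for a 2 cm^-1 shift: {sf.extrema_separation(small):.1f} cm^-1")
print("\nFor shifts small against the band width the separation saturates")
print("at the width scale (~2σ ≈ 17 cm^-1 here), so an observed splitting")
print("only reads out the shift directly when the shift is large.")
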