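# Molar extinction coefficients of oxy- and deoxy-hemoglobin.
# Source: S. Prahl, "Optical absorption of hemoglobin" compilation
# (Oregon Medical Laser Center; underlying data Gratzer & Kollias),
# tabulated there as log10 molar extinction in cm^-1/M and converted
# here to natural-log units of mm^-1 per uM (factor ln(10) * 1e-7).
# units: wavelength_nm, eps_HbO [mm^-1 uM^-1], eps_HbR [mm^-1 uM^-1]
wavelength_nm	eps_HbO	eps_HbR
760	1.349314864494511e-04	3.565599068203139e-04
830	2.242717880576200e-04	1.595783572848593e-04
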