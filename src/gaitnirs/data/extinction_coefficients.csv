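# Molar extinction coefficients of hemoglobin in water, compiled values
# (Gratzer/Kollias tabulation as distributed by the Oregon Medical Laser Center).
# Units: cm^-1 / (mol/L), base-10 logarithm convention (absorbance A = eps * c * L).
# gaitnirs converts these to the natural-log convention (multiply by ln 10) on load.
wavelength_nm,eps_hbo,eps_hhb
760,586.0,1548.52
850,1058.0,691.32
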