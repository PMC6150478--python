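# Synthetic stand-in configuration accompanying us_1990_2016_synthetic.csv.
# overstay_rate_2016: fraction of nonimmigrant visas issued whose holders
# remain (overstay beyond one year), on the visas-issued base used by the
# model; reconstructed from the public magnitude of FY2016 suspected
# in-country overstays (~6.3e5) over visas issued (~1.04e7).
overstay_rate_2016: 0.060
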