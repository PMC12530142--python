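# Molar extinction coefficients (cm^-1 uM^-1, natural-log convention) and pure-water
# absorption (cm^-1) at the NIR wavelengths used by the two- and eight-wavelength
# configurations. Chromophore order: HbO, Hb, CCO redox difference (oxidized - reduced).
# Values converted from decadic molar extinction compendia via ln(10) x 1e-6.
wavelength_nm,eps_hbo,eps_hb,eps_ccodiff,mua_water
690,6.355135e-04,4.724905e-03,3.246645e-03,0.0050
784,1.703913e-03,2.449951e-03,4.743325e-03,0.0231
800,1.878909e-03,1.754570e-03,6.055799e-03,0.0224
818,2.067721e-03,1.664769e-03,7.391298e-03,0.0255
830,2.242718e-03,1.595691e-03,8.059048e-03,0.0294
835,2.293375e-03,1.588784e-03,8.197203e-03,0.0317
851,2.445345e-03,1.593389e-03,7.897867e-03,0.0430
868,2.597316e-03,1.639441e-03,6.907755e-03,0.0500
881,2.689419e-03,1.683190e-03,6.124876e-03,0.0553
894,2.772312e-03,1.740754e-03,5.272920e-03,0.0626
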