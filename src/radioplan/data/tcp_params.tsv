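# Poisson TCP parameter sets. rho in cells/cm3, alpha in 1/Gy, alpha/beta in Gy.
# Set 1 is the primary parameterization; sets 2 and 3 are the sensitivity
# parameterizations for alternative alpha/beta values.
# CI columns are 95% bounds where published, else empty.
# Note: set 3 prostate_minus rho is encoded verbatim from the source table
# (0.5e5 with CI [4.2e5, 6.3e5]); the CI brackets the likely intended 5.0e5.
set	structure	rho	rho_ci_low	rho_ci_high	alpha	alpha_ci_low	alpha_ci_high	alpha_beta
1	gtv_union	2.8e8			0.1205			1.6
1	prostate_minus	5.4e5	4.5e5	6.9e5	0.1205			1.6
1	ctv_minus	1.2e4	1.0e4	1.4e4	0.1205			1.6
2	gtv_union	2.8e8			0.09631	0.09390	0.09758	1.2
2	prostate_minus	3.11e5	2.6e5	4.0e5	0.09631			1.2
2	ctv_minus	7.0e3	5.0e3	8.0e3	0.09631			1.2
3	gtv_union	2.8e8			0.16393	0.16010	0.16595	2.7
3	prostate_minus	0.5e5	4.2e5	6.3e5	0.16393			2.7
3	ctv_minus	1.1e4	1.0e4	1.3e4	0.16393			2.7
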