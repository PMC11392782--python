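gene_id	tissue	or_xy	ci_low	ci_high	p_smr	p_heidi	pp_h4
HIBCH	Liver	0.975	0.969	0.981	7.99e-5	0.467	0.85
HIBCH	Pancreas	0.966	0.957	0.975	1.71e-4	0.058	0.76
HIBCH	Visceral adipose tissue	0.954	0.943	0.966	1.40e-4	0.318	0.76
SPATA20	Liver	1.018	1.013	1.024	6.65e-4	0.007	2.74e-4
SPATA20	Pancreas	1.027	1.020	1.033	2.15e-5	0.058	5.81e-4
SPATA20	Visceral adipose tissue	1.019	1.015	1.024	1.25e-5	0.068	5.81e-4
STYXL1	Liver	1.028	1.017	1.039	8.85e-3	0.432	0.01
STYXL1	Pancreas	1.026	1.017	1.035	5.11e-3	0.203	1.66e-6
STYXL1	Visceral adipose tissue	1.020	1.013	1.026	2.11e-3	0.098	1.72e-6
TUFM	Pancreas	1.056	1.045	1.066	2.76e-8	0.024	0.82
TUFM	Visceral adipose tissue	1.228	1.18	1.279	3.60e-7	0.131	0.85
MTHFS	Pancreas	0.972	0.958	0.986	4.23e-2	0.173	1.75e-3
MTHFS	Visceral adipose tissue	1.017	1.009	1.025	2.76e-2	0.163	7.40e-4
DCXR	Visceral adipose tissue	1.112	1.071	1.155	4.73e-3	0.284	7.74e-3
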