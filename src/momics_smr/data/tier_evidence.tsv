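gene_id	layer	probe_id	or_xy	ci_low	ci_high	q_smr	pp_h4	tier_label
TUFM	methylation	cg00348858	0.917	0.902	0.933	1.77e-5	0.86	tier1
TUFM	expression	TUFM	1.029	1.025	1.034	1.08e-8	0.81	tier1
ISCA2	methylation	cg16374328	1.042	1.034	1.051	2.17e-5	0.99	tier1
ISCA2	expression	ISCA2	1.038	1.031	1.046	3.23e-6	0.99	tier1
HIBCH	expression	HIBCH	0.964	0.955	0.972	9.81e-4	0.82	tier1
HIBCH	protein	HIBCH	0.954	0.943	0.965	3.44e-4	0.81	tier1
COX19	methylation	cg22301154	1.053	1.040	1.066	5.25e-4	0.91	tier2
COX19	expression	COX19	1.056	1.036	1.076	3.00e-2	1.35e-17	tier2
COMT	methylation	cg19930203	1.051	1.032	1.071	4.88e-2	5.58e-3	tier2
COMT	protein	COMT	0.795	0.755	0.836	1.14e-4	0.94	tier2
GATM	methylation	cg11431346	0.926	0.902	0.951	3.21e-2	0.33	tier3
GATM	expression	GATM	1.025	1.018	1.033	7.98e-3	0.25	tier3
GATM	protein	GATM	1.083	1.059	1.109	4.29e-3	0.25	tier3
DCXR	methylation	cg07073120	0.933	0.913	0.953	1.71e-2	0.37	tier3
DCXR	expression	DCXR	1.020	1.014	1.026	1.02e-2	0.01	tier3
DCXR	protein	DCXR	1.223	1.169	1.280	1.49e-4	0.35	tier3
SPATA20	methylation	cg16020904	0.917	0.895	0.940	6.22e-3	4.14e-4	tier3
SPATA20	expression	SPATA20	1.017	1.013	1.021	2.58e-4	6.43e-4	tier3
SPATA20	protein	SPATA20	1.055	1.043	1.068	1.49e-4	5.27e-4	tier3
MRPL32	methylation	cg00365680	0.979	0.972	0.987	4.25e-2	0.11	tier3
MRPL32	expression	MRPL32	0.946	0.927	0.966	4.72e-2	1.17e-5	tier3
HADHA	methylation	cg08067268	0.981	0.975	0.988	2.68e-2	8.65e-6	tier3
HADHA	expression	HADHA	1.062	1.042	1.083	1.62e-2	1.05e-9	tier3
AIFM2	methylation	cg04859918	0.969	0.959	0.980	4.61e-2	1.04e-13	tier3
AIFM2	expression	AIFM2	0.947	0.930	0.965	2.35e-2	1.74e-19	tier3
SFXN5	methylation	cg03344820	0.925	0.901	0.949	2.62e-2	0.01	tier3
SFXN5	expression	SFXN5	1.097	1.069	1.125	3.80e-3	0.01	tier3
STYXL1	methylation	cg03592824	1.030	1.020	1.039	1.90e-2	0.22	tier3
STYXL1	expression	STYXL1	1.015	1.010	1.020	1.96e-2	1.74e-6	tier3
ACSM3	methylation	cg06478823	1.019	1.013	1.026	2.83e-2	9.39e-6	tier3
ACSM3	expression	ACSM3	0.930	0.908	0.953	2.35e-2	7.73e-6	tier3
SLC25A13	methylation	cg21022364	0.973	0.965	0.981	1.12e-2	0.32	tier3
SLC25A13	expression	SLC25A13	1.042	1.029	1.055	9.24e-3	0.24	tier3
MTHFS	expression	MTHFS	1.033	1.022	1.045	3.43e-2	2.69e-3	tier3
MTHFS	protein	MTHFS	1.030	1.019	1.041	3.25e-2	2.30e-3	tier3
MCL1	methylation	cg02961109	0.946	0.929	0.964	2.87e-2	5.75e-6	tier3
MCL1	protein	MCL1	1.085	1.064	1.105	2.13e-4	5.57e-9	tier3
ACADVL	methylation	cg03508063	1.066	1.046	1.087	1.16e-2	3.54e-3	tier3
ACADVL	protein	ACADVL	0.756	0.690	0.828	1.48e-2	0.01	tier3
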