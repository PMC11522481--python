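phenotype	n_case	n_control	reported_prevalence_pct
rheumatoid_arthritis	8040	329098	2.38
psoriasis	6595	330543	1.96
gout	9462	327676	2.81
inflammatory_bowel_disease	3703	333435	1.10
asthma	48234	288904	14.31
all_cause_dementia	4987	332151	1.48
alzheimers_disease	2060	335078	0.61
atrial_fibrillation	25839	311299	7.66
breast_cancer	14870	181027	7.59
colorectal_cancer	6869	330269	2.04
coronary_artery_disease	23184	313954	6.88
type_2_diabetes	25589	311549	7.59
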