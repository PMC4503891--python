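# Peptide species table for cardiac TnI and alpha-Tm label-free quantification.
# Charges are the assignments under which the computed monoisotopic m/z agrees
# with the reported ion m/z for each peptide (z=1 for KLQLK and ETLDLR, z=2
# otherwise). Retention times, peak widths and response factors are synthetic
# simulator constants (peaks non-overlapping by construction); start residues
# of reference peptides are not used by any computation and are set to 1.
# mods format: "pos:kind[;pos:kind]" with kinds phospho|met_sulfoxide|met_sulfone.
species_id	protein	sequence	start_residue	mods	charge	role	family	dephospho_target	rt_min	peak_sigma_min	response_factor
tni_analog_SSANYR	TnI	SSANYR	23	-	2	analog	tni_ser23_24	-	5.0	0.05	1.00
tni_mono_RSSpANYR	TnI	RSSANYR	22	3:phospho	2	phospho	tni_ser23_24	tni_analog_SSANYR	6.2	0.05	0.80
tni_bis_RRSpSpANYR	TnI	RRSSANYR	21	3:phospho;4:phospho	2	phospho	tni_ser23_24	tni_analog_SSANYR	7.4	0.05	0.70
tni_ref_YDVEAK	TnI	YDVEAK	1	-	2	reference	-	-	8.6	0.05	1.20
tni_ref_KLQLK	TnI	KLQLK	1	-	1	reference	-	-	9.8	0.05	0.90
tni_ref_ETLDLR	TnI	ETLDLR	1	-	1	reference	-	-	11.0	0.05	1.40
tni_ref_NITEIADLNQK	TnI	NITEIADLNQK	1	-	2	reference	-	-	12.2	0.05	1.10
tni_ref_IFDLR	TnI	IFDLR	1	-	2	reference	-	-	13.4	0.05	0.60
tni_cterm_NIDALSGMEGR	TnI	NIDALSGMEGR	195	-	2	cterm	tni_cterm	-	14.6	0.05	1.30
tni_cterm_NIDALSGmoxEGR	TnI	NIDALSGMEGR	195	8:met_sulfoxide	2	cterm	tni_cterm	-	15.8	0.05	1.30
tm_analog_M	Tm	AISEELDHALNDMTSI	269	-	2	analog	tm_ser283	-	17.0	0.05	1.00
tm_analog_Mox	Tm	AISEELDHALNDMTSI	269	13:met_sulfoxide	2	analog	tm_ser283	-	18.2	0.05	1.00
tm_analog_Mox2	Tm	AISEELDHALNDMTSI	269	13:met_sulfone	2	analog	tm_ser283	-	19.4	0.05	1.00
tm_phos_M	Tm	AISEELDHALNDMTSI	269	15:phospho	2	phospho	tm_ser283	tm_analog_M	20.6	0.05	0.85
tm_phos_Mox	Tm	AISEELDHALNDMTSI	269	13:met_sulfoxide;15:phospho	2	phospho	tm_ser283	tm_analog_Mox	21.8	0.05	0.85
tm_phos_Mox2	Tm	AISEELDHALNDMTSI	269	13:met_sulfone;15:phospho	2	phospho	tm_ser283	tm_analog_Mox2	23.0	0.05	0.85
tm_ref_HIAEDADR	Tm	HIAEDADR	1	-	2	reference	-	-	24.2	0.05	1.50
tm_ref_SLEAQAEK	Tm	SLEAQAEK	1	-	2	reference	-	-	25.4	0.05	1.05
tm_ref_IQLVEEELDR	Tm	IQLVEEELDR	1	-	2	reference	-	-	26.6	0.05	0.75
tm_ref_LVIIESDLER	Tm	LVIIESDLER	1	-	2	reference	-	-	27.8	0.05	1.60
tm_ref_SIDDLEDELYAQK	Tm	SIDDLEDELYAQK	1	-	2	reference	-	-	29.0	0.05	0.95
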