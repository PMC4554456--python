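strain_id	origin_group	papC	papGIII	sfa_foc	iha	hra	ibeA	fyuA	irp2	iroN	aer	ireA	kpsMTII	neuC	ompT	traT	hlyC	cnf1	usp	sat	clbQ	b2_subgroup	o_type	colicin_phage
human_exclusive_000	human_exclusive	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	II		
human_exclusive_001	human_exclusive	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	II		
human_exclusive_002	human_exclusive	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	II		
human_exclusive_003	human_exclusive	1	0	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	II		
human_exclusive_004	human_exclusive	1	0	1	0	1	1	1	1	1	1	0	1	1	1	1	1	1	1	0	1	II		
human_exclusive_005	human_exclusive	1	0	1	0	1	1	1	1	1	1	0	1	1	1	1	1	1	1	0	1	II		
human_exclusive_006	human_exclusive	1	0	1	0	1	1	1	1	1	1	0	1	1	1	1	1	0	1	0	1	IX		
human_exclusive_007	human_exclusive	1	0	1	0	0	1	1	1	1	1	0	1	1	1	1	0	0	1	0	1	IX		
human_exclusive_008	human_exclusive	1	0	1	0	0	0	1	1	1	0	0	1	1	1	1	0	0	1	0	1	IX		
human_exclusive_009	human_exclusive	0	0	1	0	0	0	1	1	1	0	0	1	1	1	1	0	0	1	0	1	IX		
human_exclusive_010	human_exclusive	0	0	0	0	0	0	1	1	1	0	0	1	1	1	0	0	0	1	0	1	I		
human_exclusive_011	human_exclusive	0	0	0	0	0	0	1	1	1	0	0	1	1	1	0	0	0	1	0	1	I		
human_exclusive_012	human_exclusive	0	0	0	0	0	0	1	1	1	0	0	0	0	1	0	0	0	1	0	0	I		
human_exclusive_013	human_exclusive	0	0	0	0	0	0	1	1	1	0	0	0	0	1	0	0	0	1	0	0	IV		
human_exclusive_014	human_exclusive	0	0	0	0	0	0	1	1	1	0	0	0	0	1	0	0	0	1	0	0	IV		
human_exclusive_015	human_exclusive	0	0	0	0	0	0	1	1	1	0	0	0	0	1	0	0	0	1	0	0	IV		
human_exclusive_016	human_exclusive	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	0	1	0	0	VII		
human_exclusive_017	human_exclusive	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	0	1	0	0	VII		
human_exclusive_018	human_exclusive	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	0	1	0	0	VIII		
human_exclusive_019	human_exclusive	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	V		
human_nonexclusive_000	human_nonexclusive	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	I		
human_nonexclusive_001	human_nonexclusive	1	0	0	1	0	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	I		
human_nonexclusive_002	human_nonexclusive	1	0	0	1	0	1	1	1	1	0	1	1	1	1	1	0	0	1	1	0	I		
human_nonexclusive_003	human_nonexclusive	1	0	0	1	0	1	1	1	1	0	1	1	1	1	1	0	0	1	0	0	IX		
human_nonexclusive_004	human_nonexclusive	0	0	0	0	0	0	1	1	1	0	0	1	1	1	1	0	0	1	0	0	IX		
human_nonexclusive_005	human_nonexclusive	0	0	0	0	0	0	1	1	1	0	0	1	0	1	1	0	0	1	0	0	IX		
human_nonexclusive_006	human_nonexclusive	0	0	0	0	0	0	1	1	0	0	0	1	0	1	1	0	0	1	0	0	V		
human_nonexclusive_007	human_nonexclusive	0	0	0	0	0	0	1	1	0	0	0	0	0	1	1	0	0	1	0	0	V		
human_nonexclusive_008	human_nonexclusive	0	0	0	0	0	0	1	1	0	0	0	0	0	1	0	0	0	1	0	0	VII		
human_nonexclusive_009	human_nonexclusive	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	VIII		
animal_000	animal	0	0	1	0	1	1	1	1	1	1	1	1	1	1	1	1	0	1	0	1	unassigned		
animal_001	animal	0	0	1	0	1	1	1	1	1	0	1	1	1	1	1	0	0	1	0	1	unassigned		
animal_002	animal	0	0	0	0	1	1	1	1	1	0	1	1	1	1	1	0	0	1	0	0	unassigned		
animal_003	animal	0	0	0	0	1	1	1	1	1	0	1	1	0	1	1	0	0	1	0	0	unassigned		
animal_004	animal	0	0	0	0	1	1	1	1	1	0	0	1	0	1	1	0	0	1	0	0	unassigned		
animal_005	animal	0	0	0	0	0	1	1	1	1	0	0	1	0	1	1	0	0	1	0	0	unassigned		
animal_006	animal	0	0	0	0	0	0	1	1	0	0	0	1	0	1	0	0	0	0	0	0	III		
animal_007	animal	0	0	0	0	0	0	1	1	0	0	0	1	0	1	0	0	0	0	0	0	III		
animal_008	animal	0	0	0	0	0	0	1	1	0	0	0	0	0	1	0	0	0	0	0	0	III		
animal_009	animal	0	0	0	0	0	0	1	1	0	0	0	0	0	1	0	0	0	0	0	0	II		
animal_010	animal	0	0	0	0	0	0	1	1	0	0	0	0	0	1	0	0	0	0	0	0	I		
animal_011	animal	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	V		
animal_012	animal	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	VIII		
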