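gene_id	theta_dir1	theta_dir2	M_pooled	P_pooled	chi2	p	q	status
G00000	0.558491	0.508271	634	561	4.45941	0.0347094	0.0867735	BIPARENTAL
G00001	0.564972	0.556452	338	264	9.09635	0.00256121	0.012806	BIPARENTAL
G00002	0.486692	0.493716	531	552	0.407202	0.523393	0.581548	BIPARENTAL
G00003	0.49635	0.460586	817	893	3.37778	0.0660811	0.132162	BIPARENTAL
G00004	0.513793	0.550781	290	256	2.11722	0.145651	0.26482	BIPARENTAL
G00005	0.592516	0.520446	565	454	12.0913	0.000506586	0.00337724	BIPARENTAL
G00006	0.45359	0.476954	497	573	5.39813	0.0201583	0.0575952	BIPARENTAL
G00007	0.484064	0.480084	472	507	1.25128	0.263309	0.438848	BIPARENTAL
G00008	0.48519	0.498305	638	661	0.407236	0.523376	0.581548	BIPARENTAL
G00009	0.210191	0.0703125	84	486	283.516	1.28665e-63	1.28665e-62	PEG_MODERATE
G00010	0.50384	0.495108	581	581	0	1	1	BIPARENTAL
G00011	0.471037	0.503045	722	755	0.737305	0.390525	0.516663	BIPARENTAL
G00012	0.522241	0.475089	584	585	0.000855432	0.976667	1	BIPARENTAL
G00013	0.490818	0.539496	615	579	1.08543	0.297487	0.446023	BIPARENTAL
G00014	0.493671	0.599291	286	233	5.41233	0.019995	0.0575952	BIPARENTAL
G00015	0.949735	0.948956	768	41	653.311	4.25529e-144	8.51058e-143	MEG_STRONG
G00016	0.465574	0.494208	270	294	1.02128	0.312216	0.446023	BIPARENTAL
G00017	0.49925	0.515745	1403	1360	0.6692	0.413331	0.516663	BIPARENTAL
G00018	0.417722	0.490132	248	293	3.74307	0.053027	0.117838	BIPARENTAL
G00019	0.444444	0.483161	693	799	7.53083	0.00606519	0.0242608	BIPARENTAL
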