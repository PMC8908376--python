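gene_id	annotation	transcript_id	OF	LRS	duplicate_seq
Ghir_D01G000100	ELO/SUR4 family	Ghir_D01G000100.1	8.247181314	0	0
Ghir_D01G000100	ELO/SUR4 family	Ghir_D01G000100.2	5.849377026	1.3980718	0
Ghir_A10G001030	HD zipper protein protodermal factor 2	Ghir_A10G001030.1	0.285908775	0.0775192	1
Ghir_A10G001030	HD zipper protein protodermal factor 2	Ghir_A10G001030.2	1.082713488	1.0809891	1
Ghir_A10G001030	HD zipper protein protodermal factor 2	Ghir_A10G001030.3	2.907309878	0	0
Ghir_D09G019020	NAC domain-containing protein 62-like	Ghir_D09G019020.1	2.640708144	3.0826249	0
Ghir_D09G019020	NAC domain-containing protein 62-like	Ghir_D09G019020.2	1.314970249	1.8542175	0
Ghir_D09G019020	NAC domain-containing protein 62-like	Ghir_D09G019020.3	1.44367189	1.9737428	0
Ghir_D09G019020	NAC domain-containing protein 62-like	Ghir_D09G019020.4	2.6234633	0	0
Ghir_A09G012990	glycerol-3-phosphate dehydrogenase	Ghir_A09G012990.1	0.087107046	0.4593403	1
Ghir_A09G012990	glycerol-3-phosphate dehydrogenase	Ghir_A09G012990.2	1.204346712	0.4166236	1
Ghir_A09G012990	glycerol-3-phosphate dehydrogenase	Ghir_A09G012990.3	0.875061288	0.8913321	1
Ghir_A09G012990	glycerol-3-phosphate dehydrogenase	Ghir_A09G012990.4	2.617127776	0	1
Ghir_D01G006540	Benzoquinone reductase	Ghir_D01G006540.1	6.268913584	3.9051894	0
Ghir_D01G006540	Benzoquinone reductase	Ghir_D01G006540.2	0.999345589	0.690696	0
Ghir_D01G006540	Benzoquinone reductase	Ghir_D01G006540.3	1.020565494	0	0
Ghir_D10G025770	Hypothetical protein	Ghir_D10G025770.1	0.92436369	0.0527247	0
Ghir_D10G025770	Hypothetical protein	Ghir_D10G025770.2	1.094223231	0.2255871	0
Ghir_D10G025770	Hypothetical protein	Ghir_D10G025770.3	0.534289745	0	0
Ghir_D10G025770	Hypothetical protein	Ghir_D10G025770.4	1.084769108	0.1948385	0
Ghir_A05G038240	WRKY transcription factor 1	Ghir_A05G038240.1	4.778754111	1.9936975	1
Ghir_A05G038240	WRKY transcription factor 1	Ghir_A05G038240.2	2.929963278	0.137295	1
Ghir_A05G038240	WRKY transcription factor 1	Ghir_A05G038240.3	0.634027231	0.033738	1
Ghir_A05G038240	WRKY transcription factor 1	Ghir_A05G038240.4	0.940046443	0.0363838	1
Ghir_A05G038240	WRKY transcription factor 1	Ghir_A05G038240.5	1.671006617	0.0342636	1
Ghir_A05G038240	WRKY transcription factor 1	Ghir_A05G038240.6	0.451709621	0	1
Ghir_D05G003410	Serine-threonine protein kinase	Ghir_D05G003410.1	2.98741965	0.6356541	0
Ghir_D05G003410	Serine-threonine protein kinase	Ghir_D05G003410.2	0.303920993	0.0050133	0
Ghir_D05G003410	Serine-threonine protein kinase	Ghir_D05G003410.3	0.280408817	0	0
Ghir_D05G003410	Serine-threonine protein kinase	Ghir_D05G003410.4	0.096578968	0.0057262	0
Ghir_D11G022110	bHLH61 like transcription factor	Ghir_D11G022110.1	0.235100837	0	1
Ghir_D11G022110	bHLH61 like transcription factor	Ghir_D11G022110.2	2.182144669	1.0477708	1
Ghir_D11G022110	bHLH61 like transcription factor	Ghir_D11G022110.3	1.617503963	0.7769445	0
Ghir_A08G022470	WVD1 like 1 isoform	Ghir_A08G022470.1	1.282175262	0.2576479	0
Ghir_A08G022470	WVD1 like 1 isoform	Ghir_A08G022470.2	0.095796175	0.2643491	1
Ghir_A08G022470	WVD1 like 1 isoform	Ghir_A08G022470.3	0.099241334	0.8651611	1
Ghir_A08G022470	WVD1 like 1 isoform	Ghir_A08G022470.4	0.589878515	0.8751675	0
Ghir_A08G022470	WVD1 like 1 isoform	Ghir_A08G022470.5	0.227819923	0	0
Ghir_A08G022470	WVD1 like 1 isoform	Ghir_A08G022470.6	0.202128056	0	1
Ghir_A08G022470	WVD1 like 1 isoform	Ghir_A08G022470.7	1.320330436	0.0007414	0
Ghir_A11G025670	Hypothetical protein	Ghir_A11G025670.1	2.417842256	0.7236608	1
Ghir_A11G025670	Hypothetical protein	Ghir_A11G025670.2	0.188235059	0	0
Ghir_A11G025670	Hypothetical protein	Ghir_A11G025670.3	0.238984911	0.3046851	1
Ghir_D01G005620	Hypothetical protein	Ghir_D01G005620.1	2.047156551	1.1493537	0
Ghir_D01G005620	Hypothetical protein	Ghir_D01G005620.2	0.153845536	0	0
Ghir_D01G005620	Hypothetical protein	Ghir_D01G005620.3	0.888239423	0.7282053	0
Ghir_D01G020410	Hypothetical protein	Ghir_D01G020410.1	0.073779111	0	0
Ghir_D04G015610	bifunctional epoxide hydrolase 2 like gene	Ghir_D04G015610.1	0.053649379	0	1
Ghir_D04G015610	bifunctional epoxide hydrolase 2 like gene	Ghir_D04G015610.2	5.945628677	1.2868179	1
Ghir_A09G014480	Hypothetical protein	Ghir_A09G014480.1	0.0413986	0	1
Ghir_A09G014480	Hypothetical protein	Ghir_A09G014480.2	1.144999148	0.6043513	1
Ghir_A12G003890	Hypothetical protein	Ghir_A12G003890.1	0.011841959	0	0
Ghir_A12G003890	Hypothetical protein	Ghir_A12G003890.2	4.091971001	0.926886	0
Ghir_A09G013880	Hypothetical protein	Ghir_A09G013880.1	0.740766125	0.2872205	0
Ghir_A09G013880	Hypothetical protein	Ghir_A09G013880.2	3.114859556	1.437379	0
Ghir_A09G013880	Hypothetical protein	Ghir_A09G013880.3	0.781812072	0.3974635	0
Ghir_A09G013880	Hypothetical protein	Ghir_A09G013880.4	0.007735155	0	0
Ghir_D12G002480	LAG1 longevity assurance homolg2-like	Ghir_D12G002480.1	0.001137838	0	0
Ghir_D12G002480	LAG1 longevity assurance homolg2-like	Ghir_D12G002480.2	2.875775739	0.410619	0
Ghir_D05G007320	Hypothetical protein	Ghir_D05G007320.1		0	0
Ghir_D05G007320	Hypothetical protein	Ghir_D05G007320.2	7.705065032	3.6233814	0
Ghir_D05G007320	Hypothetical protein	Ghir_D05G007320.3	0.616319112	0.0705858	0
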