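drug_id	name	target_count	groups	nida_category
DB00316	Acetaminophen	2	approved	opioids and morphine derivatives
DB00404	Alprazolam	20	approved;illicit	depressants
DB01351	Amobarbital	10	approved;illicit	depressants
DB00182	Amphetamine	4	approved;illicit	stimulants
DB01541	Boldenone	1	experimental;illicit	other compounds
DB00475	Chlordiazepoxide	19	approved;illicit	depressants
DB00907	Cocaine	8	approved;illicit	stimulants
DB00318	Codeine	3	approved;illicit	opioids and morphine derivatives
DB01189	Desflurane	7	approved	other compounds
DB00514	Dextromethorphan	4	approved	other compounds
DB00829	Diazepam	18	approved;illicit	depressants
DB00228	Enflurane	8	approved	other compounds
DB00898	Ethanol	7	approved	other compounds
DB00813	Fentanyl	3	approved;illicit	opioids and morphine derivatives
DB01544	Flunitrazepam	6	approved;illicit	depressants
DB01440	Gamma hydroxybutyric acid	1	approved;illicit	depressants
DB01159	Halothane	17	approved	other compounds
DB01452	Heroin	3	approved;illicit	opioids and morphine derivatives
DB00956	Hydrocodone	2	approved;illicit	opioids and morphine derivatives
DB00327	Hydromorphone	3	approved;illicit	opioids and morphine derivatives
DB00753	Isoflurane	7	approved	other compounds
DB01221	Ketamine	3	approved	dissociative anesthetics
DB00186	Lorazepam	20	approved	depressants
DB04829	Lysergic acid diethylamide	0	illicit;withdrawn	hallucinogens
DB00454	Meperidine	6	approved	opioids and morphine derivatives
DB01577	Methamphetamine	11	approved;illicit	stimulants
DB04833	Methaqualone	0	illicit;withdrawn	depressants
DB01028	Methoxyflurane	7	approved	other compounds
DB00422	Methylphenidate	3	approved;investigational	stimulants
DB01442	MMDA	8	experimental;illicit	stimulants
DB00295	Morphine	3	approved	opioids and morphine derivatives
DB00486	Nabilone	2	approved	other compounds
DB00984	Nandrolone phenpropionate	0	approved;illicit	other compounds
DB00184	Nicotine	11	approved	stimulants
DB00621	Oxandrolone	1	approved	other compounds
DB00497	Oxycodone	3	approved;illicit	opioids and morphine derivatives
DB00312	Pentobarbital	10	approved	depressants
DB03575	Phencyclidine	2	experimental;illicit	dissociative anesthetics
DB01174	Phenobarbital	10	approved	depressants
DB00647	Propoxyphene	3	approved;illicit	opioids and morphine derivatives
DB00418	Secobarbital	10	approved	depressants
DB01236	Sevoflurane	7	approved	other compounds
DB00624	Testosterone	1	approved	other compounds
DB00897	Triazolam	20	approved;illicit;withdrawn	depressants
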