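name	formula	kegg_id	fragments	rt	standard
Allantoin	C4H6N4O3	C02350			
Arginine	C6H14N4O2	C00062	60.0556;70.0651;116.0706;130.0975;158.0924;175.119	5.0	1
Histamine	C5H9N3	C00388			
Histidine	C6H9N3O2	C00135	83.0604;93.0447;95.0604;110.0713;156.0768	5.0	1
Citrulline	C6H13N3O3	C00327			
Glutamine	C5H10N2O3	C00064	56.0495;84.0444;101.0709;130.0499;147.0764	4.8	1
Glutamate	C5H9NO4	C00025	56.0495;84.0444;102.0550;130.0499;148.0604	4.4	1
Serine	C3H7NO3	C00065			
Hydroxyproline	C5H9NO3	C01157			
Hypotaurine	C2H7NO2S	C00519			
Proline	C5H9NO2	C00148			
Cystathionine	C7H14N2O4S	C02291	88.0393;134.0270;177.0328;205.0641;223.0747	5.4	1
Cystine	C6H12N2O4S2	C00491			
Glutathione	C10H17N3O6S	C00051			
Methionine	C5H11NO2S	C00073	56.0495;61.0112;104.0528;133.0318;150.0583	4.9	1
Homocysteine	C4H9NO2S	C00155			
S-Adenosylmethionine	C15H22N6O5S	C00019			
S-Adenosylhomocysteine	C14H20N6O5S	C00021	88.0393;134.0270;136.0618;250.0937;385.1284	4.8	1
5-Methylthioadenosine	C11H15N5O3S	C00170			
Adenosine	C10H13N5O4	C00212	57.0214;71.0240;119.0352;136.0618;268.1040	4.6	1
Guanosine	C10H13N5O5	C00387			
Cytidine	C9H13N3O5	C00475			
Pantothenic acid	C9H17NO5	C00864			
Taurine	C2H7NO3S	C00245			
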