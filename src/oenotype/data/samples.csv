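sample_id,region,variety,wine_type,vintage,isolates
GB,Santorini,Assyrtiko,white,2020,5
A6,Santorini,Assyrtiko,white,2020,15
A26,Pelion,Assyrtiko,white,2020,21
K21,Pelion,Xinomavro,red,2019,9
K29,Pelion,Xinomavro,red,2020,18
K23,Pelion,Xinomavro,red,2020,24
K24,Pelion,Xinomavro,red,2018,21
A30,Nemea,Assyrtiko,white,2020,12
K32,Nemea,Agiorgitiko,red,2019,18
K33,Nemea,Agiorgitiko,red,2019,15
K34,Nemea,Agiorgitiko,red,2019,17
A9,Nemea,Roditis,white,2019,5
A19,Goumenissa,50 Malagouzia/50 Muscat,white,2020,5
K16,Goumenissa,Xinomavro,red,2020,5
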