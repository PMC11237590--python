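genus	fermentation_type
Leuconostoc	heterofermentative
Weissella	heterofermentative
Oenococcus	heterofermentative
Fructilactobacillus	heterofermentative
Levilactobacillus	heterofermentative
Lentilactobacillus	heterofermentative
Limosilactobacillus	heterofermentative
Furfurilactobacillus	heterofermentative
Paucilactobacillus	heterofermentative
Secundilactobacillus	heterofermentative
Lactobacillus	homofermentative
Lactiplantibacillus	homofermentative
Latilactobacillus	homofermentative
Companilactobacillus	homofermentative
Lacticaseibacillus	homofermentative
Ligilactobacillus	homofermentative
Loigolactobacillus	homofermentative
Pediococcus	homofermentative
Lactococcus	homofermentative
Enterococcus	homofermentative
Vagococcus	homofermentative
Streptococcus	homofermentative
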