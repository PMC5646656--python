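species	group	material	two_n	fn	formula
O. minor	Octopodiformes	gills	60	108	42M+6SM+4ST+8T
O. vulgaris	Octopodiformes	embryos	60	76	14M+2SM+8ST+36T
A. fangsiao	Octopodiformes	gills	60	108	32M+16SM+12T
C. chinensis	Octopodiformes	gills	60	104	38M+6SM+8ST+8T
S. lycidas	Decapodiformes	wild eggs	92	172	66M+14SM+10ST+2T
S. esculenta	Decapodiformes	wild eggs	92	164	48M+24SM+14ST+6T
S. lessoniana	Decapodiformes	wild eggs	92	156	54M+10SM+24ST+4T
P. edulis	Decapodiformes	embryos	92	160	50M+18SM+16ST+8T
H. bleekeri	Decapodiformes	embryos	92	166	54M+20SM+18ST
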