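species	O. minor	O. vulgaris	A. fangsiao	C. chinensis	S. lycidas	S. esculenta	S. lessoniana	P. edulis	H. bleekeri
O. minor		0.5894	0.7594	0.8184	0.5244	0.3747	0.4401	0.4839	0.2742
O. vulgaris	0.5291		0.5495	0.5540	0.4183	0.3765	0.4725	0.4392	0.3057
A. fangsiao	0.2760	0.6000		0.7976	0.5423	0.5075	0.4515	0.4963	0.2640
C. chinensis	0.2013	0.5912	0.2262		0.5343	0.4744	0.5467	0.3846	0.3663
S. lycidas	0.6460	0.8722	0.6122	0.6271		0.7871	0.6328	0.6297	0.5990
S. esculenta	0.9809	0.9782	0.6776	0.7471	0.2399		0.5809	0.5594	0.6051
S. lessoniana	0.8214	0.7494	0.7960	0.6034	0.4570	0.5431		0.5280	0.3650
P. edulis	0.7265	0.8230	0.7011	0.9550	0.4620	0.5822	0.5904		0.5984
H. bleekeri	1.2954	1.1845	1.3323	1.0101	0.5120	0.5030	0.6940	0.5140
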