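Megaselia shadeae	Fig. 2
Head		Remarks
SA ratio	1	
VIF position	VFO adjacent	
SPS vesicles	absent	
Palpal setae length	long	
Labellum spinosity	spinose	
Thorax		
Anepisternum	bare	
Relative halter color	same	
# NP setae	2	
NP cleft	absent	
Scutellar setae	2+2	
Leg		
ts1 palisade	1-4	
t2 palisade	0.67	
t3 comb bifurcate	absent	
t3 setulae	PD	
f3 basal setae	B<AV	
f3 basal setae differentiation	absent	
Wing	Fig. 3	
Wing Length (mm)	1.56	
Subcosta	incomplete	
Hair at base of R	long	
R_2+3	present	large fork
Costal index	0.65	
Costal ratios	1.25:1.00:1	
Costal setae length (mm)	0.09	
Number alular setae	3	
Alular setae length (mm)	0.15	
Wing color	strongly infuscated	
Genitalia	Figs 4, 5	
AT length	AT>E	
E setation	hairs only	
Relative posterior setation	T6~E~H<C	
General Remarks		
wing with central, bubbled, pigmented spot
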