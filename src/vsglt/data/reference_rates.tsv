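# q_gc_total = -0.7
# temperature_K = 298.15
transition	k0	k0_units	eta	epsilon	note
12	2212000	1/(M*s)	-0.05	0.15	extracellular Na+ binding
21	343000	1/s	0.05	-0.15	extracellular Na+ release
23	540300	1/(M*s)	-0.05	0	extracellular galactose binding
32	9.592	1/s	0.05	0	galactose release to the outside
34	3012	1/s	-0.25	0.35	occluded -> inward isomerization (inner gate opening)
43	630600	1/s	0.25	-0.35	inner gate closure with substrates bound
45	2037	1/s	0	0	stochastic intracellular release of Na+ and galactose
54	1.276	1/(M^2*s)	0	0	intracellular rebinding of both substrates
51	27.62	1/s	0.35	0	apo reset, inward -> outward; voltage-driven
15	117.2	1/s	-0.35	0	apo collapse, outward -> inward
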