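!!Species
Name	Role	DefaultTotal
Ca	elementary	10
CaM	elementary	10
CaM_Ca1	complex	0
CaM_Ca2	complex	0
CaM_Ca3	complex	0
CaM_Ca4	complex	0
PP2B	elementary	1
PP2B_CaM	complex	0
PP2B_CaM_Ca1	complex	0
PP2B_CaM_Ca2	complex	0
PP2B_CaM_Ca3	complex	0
PP2B_CaM_Ca4	complex	0
CaMKII	elementary	20
CaMKII_CaM	complex	0
CaMKII_CaM_Ca1	complex	0
CaMKII_CaM_Ca2	complex	0
CaMKII_CaM_Ca3	complex	0
CaMKII_CaM_Ca4	complex	0
pCaMKII	elementary	0
pCaMKII_CaM	complex	0
pCaMKII_CaM_Ca1	complex	0
pCaMKII_CaM_Ca2	complex	0
pCaMKII_CaM_Ca3	complex	0
pCaMKII_CaM_Ca4	complex	0
PP1	elementary	1
!!Reaction
Id	Formula	Kind	RateExpression
R1	CaM + Ca <=> CaM_Ca1	mass_action_reversible	
R2	CaM_Ca1 + Ca <=> CaM_Ca2	mass_action_reversible	
R3	CaM_Ca2 + Ca <=> CaM_Ca3	mass_action_reversible	
R4	CaM_Ca3 + Ca <=> CaM_Ca4	mass_action_reversible	
R5	PP2B + CaM <=> PP2B_CaM	mass_action_reversible	
R6	PP2B + CaM_Ca1 <=> PP2B_CaM_Ca1	mass_action_reversible	
R7	PP2B + CaM_Ca2 <=> PP2B_CaM_Ca2	mass_action_reversible	
R8	PP2B + CaM_Ca3 <=> PP2B_CaM_Ca3	mass_action_reversible	
R9	PP2B + CaM_Ca4 <=> PP2B_CaM_Ca4	mass_action_reversible	
R10	PP2B_CaM + Ca <=> PP2B_CaM_Ca1	mass_action_reversible	
R11	PP2B_CaM_Ca1 + Ca <=> PP2B_CaM_Ca2	mass_action_reversible	
R12	PP2B_CaM_Ca2 + Ca <=> PP2B_CaM_Ca3	mass_action_reversible	
R13	PP2B_CaM_Ca3 + Ca <=> PP2B_CaM_Ca4	mass_action_reversible	
R14	CaMKII + CaM <=> CaMKII_CaM	mass_action_reversible	
R15	CaMKII + CaM_Ca1 <=> CaMKII_CaM_Ca1	mass_action_reversible	
R16	CaMKII + CaM_Ca2 <=> CaMKII_CaM_Ca2	mass_action_reversible	
R17	CaMKII + CaM_Ca3 <=> CaMKII_CaM_Ca3	mass_action_reversible	
R18	CaMKII + CaM_Ca4 <=> CaMKII_CaM_Ca4	mass_action_reversible	
R19	CaMKII_CaM + Ca <=> CaMKII_CaM_Ca1	mass_action_reversible	
R20	CaMKII_CaM_Ca1 + Ca <=> CaMKII_CaM_Ca2	mass_action_reversible	
R21	CaMKII_CaM_Ca2 + Ca <=> CaMKII_CaM_Ca3	mass_action_reversible	
R22	CaMKII_CaM_Ca3 + Ca <=> CaMKII_CaM_Ca4	mass_action_reversible	
R23	pCaMKII + CaM <=> pCaMKII_CaM	mass_action_reversible	
R24	pCaMKII + CaM_Ca1 <=> pCaMKII_CaM_Ca1	mass_action_reversible	
R25	pCaMKII + CaM_Ca2 <=> pCaMKII_CaM_Ca2	mass_action_reversible	
R26	pCaMKII + CaM_Ca3 <=> pCaMKII_CaM_Ca3	mass_action_reversible	
R27	pCaMKII + CaM_Ca4 <=> pCaMKII_CaM_Ca4	mass_action_reversible	
R28	pCaMKII_CaM + Ca <=> pCaMKII_CaM_Ca1	mass_action_reversible	
R29	pCaMKII_CaM_Ca1 + Ca <=> pCaMKII_CaM_Ca2	mass_action_reversible	
R30	pCaMKII_CaM_Ca2 + Ca <=> pCaMKII_CaM_Ca3	mass_action_reversible	
R31	pCaMKII_CaM_Ca3 + Ca <=> pCaMKII_CaM_Ca4	mass_action_reversible	
R32	pCaMKII <=> CaMKII	mass_action_reversible	
R33	CaMKII_CaM_Ca4 -> pCaMKII_CaM_Ca4	custom	kautMax * CaMKII_CaM_Ca4**2
R34	pCaMKII_CaM_Ca4 -> CaMKII_CaM_Ca4	custom	kdeph * PP1 * pCaMKII_CaM_Ca4
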