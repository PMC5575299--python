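# Default cofactor / supporting-molecule exclusion list (smiles<TAB>name).
# These are curated away from substrate databases: they appear in enzymatic
# reactions as cofactors or supporting species, not as principal substrates.
# Edit or replace freely; matching is by canonical structure, not by string.
O	water
Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O	ATP
Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O	ADP
Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O	AMP
NC(=O)c1ccc[n+](C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(O)C3O)C(O)C2O)c1	NAD+
NC(=O)C1=CN(C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(O)C3O)C(O)C2O)C=CC1	NADH
NC(=O)c1ccc[n+](C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(OP(=O)(O)O)C3O)C(O)C2O)c1	NADP+
Cc1cc2nc3c(=O)[nH]c(=O)n(CC(O)C(O)C(O)COP(=O)(O)OP(=O)(O)OCC4OC(n5cnc6c(N)ncnc65)C(O)C4O)c3nc2cc1C	FAD
Cc1cc2nc3c(=O)[nH]c(=O)n(CC(O)C(O)C(O)COP(=O)(O)O)c3nc2cc1C	FMN
CC(C)(COP(=O)(O)OP(=O)(O)OCC1OC(n2cnc3c(N)ncnc32)C(O)C1OP(=O)(O)O)C(O)C(=O)NCCC(=O)NCCS	coenzyme A
OP(=O)(O)O	phosphate
OP(=O)(O)OP(=O)(O)O	pyrophosphate
O=C=O	carbon dioxide
O=O	dioxygen
OO	hydrogen peroxide
N	ammonia
[Na+]	sodium ion
[K+]	potassium ion
[Mg+2]	magnesium ion
[Ca+2]	calcium ion
[Zn+2]	zinc ion
[Fe+2]	iron(II) ion
[Fe+3]	iron(III) ion
[Cl-]	chloride
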