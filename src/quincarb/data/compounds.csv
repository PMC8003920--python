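id,name,formula_printed,formula_name_derived,smiles,counterion,quaternized,smiles_inferred
1,"3-(N,N-Dimethylcarbamoyloxy)quinuclidine",,C10H18N2O2,CN(C)C(=O)OC1CN2CCC1CC2,,0,1
2,"N-Methyl-3-(N,N-dimethylcarbamoyloxy)quinuclidinium iodide",,C11H21IN2O2,CN(C)C(=O)OC1C[N+]2(C)CCC1CC2,[I-],1,1
3,"N-Benzyl-3-(N,N-dimethylcarbamoyloxy)quinuclidinium bromide",C17H25BrN2O2,C17H25BrN2O2,CN(C)C(=O)OC1C[N+]2(Cc3ccccc3)CCC1CC2,[Br-],1,0
4,"N-(4-Nitrobenzyl)-3-(N,N-dimethylcarbamoyloxy)quinuclidinium bromide",C17H24BrN3O4,C17H24BrN3O4,CN(C)C(=O)OC1C[N+]2(Cc3ccc(cc3)[N+](=O)[O-])CCC1CC2,[Br-],1,0
5,"N-(4-Chlorobenzyl)-3-(N,N-dimethylcarbamoyloxy)quinuclidinium bromide",C17H24BrClN2O2,C17H24BrClN2O2,CN(C)C(=O)OC1C[N+]2(Cc3ccc(Cl)cc3)CCC1CC2,[Br-],1,0
6,"3-(N,N-Diethylcarbamoyloxy)quinuclidine",,C12H22N2O2,CCN(CC)C(=O)OC1CN2CCC1CC2,,0,0
7,"N-Methyl-3-(N,N-diethylcarbamoyloxy)quinuclidinium iodide",C13H25IN2O2,C13H25IN2O2,CCN(CC)C(=O)OC1C[N+]2(C)CCC1CC2,[I-],1,0
8,"N-Benzyl-3-(N,N-diethylcarbamoyloxy)quinuclidinium bromide",C19H29BrN2O2,C19H29BrN2O2,CCN(CC)C(=O)OC1C[N+]2(Cc3ccccc3)CCC1CC2,[Br-],1,0
9,"N-(3-Bromobenzyl)-3-(N,N-diethylcarbamoyloxy)quinuclidinium bromide",C19H28Br2N2O2,C19H28Br2N2O2,CCN(CC)C(=O)OC1C[N+]2(Cc3cccc(Br)c3)CCC1CC2,[Br-],1,0
10,"N-(4-Chlorobenzyl)-3-(N,N-diethylcarbamoyloxy)quinuclidinium bromide",C19H28BrClN2O2,C19H28BrClN2O2,CCN(CC)C(=O)OC1C[N+]2(Cc3ccc(Cl)cc3)CCC1CC2,[Br-],1,0
11,3-(N-Phenylcarbamoyloxy)quinuclidine,,C14H18N2O2,O=C(Nc1ccccc1)OC1CN2CCC1CC2,,0,1
12,N-Benzyl-3-(N-phenylcarbamoyloxy)quinuclidinium bromide,C21H25BrN2O2,C21H25BrN2O2,O=C(Nc1ccccc1)OC1C[N+]2(Cc3ccccc3)CCC1CC2,[Br-],1,0
13,N-(3-Chlorobenzyl)-3-(N-phenylcarbamoyloxy)quinuclidinium bromide,C22H27BrN2O2,C21H24BrClN2O2,O=C(Nc1ccccc1)OC1C[N+]2(Cc3cccc(Cl)c3)CCC1CC2,[Br-],1,0
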