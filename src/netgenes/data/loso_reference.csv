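organism,auroc_deg10,auroc_deg15,training_cohort
Acinetobacter sp. ADP1,0.83,0.87,True
Burkholderia pseudomallei K96243,0.65,0.72,True
Bacillus subtilis,0.87,0.90,True
Burkholderia thailandensis E264,0.90,0.95,True
Bacteroides thetaiotaomicron VPI-5482,0.72,0.70,True
Escherichia coli K-12 substr MG1655,0.85,0.90,True
Caulobacter crescentus NA1000,0.91,0.91,True
Campylobacter jejuni,0.66,0.67,True
Francisella tularensis novicida U112,0.75,0.81,True
Haemophilus influenzae,0.53,0.65,True
Helicobacter pylori 26695,0.59,0.67,True
Mycoplasma genitalium,0.62,0.82,True
Mycoplasma pulmonis,0.81,0.75,True
Pseudomonas aeruginosa UCBPP-PA14,0.77,0.76,True
Pseudomonas aeruginosa,0.67,0.81,True
Porphyromonas gingivalis ATCC 33277,0.77,0.88,True
Mycobacterium tuberculosis H37Rv,0.74,0.90,True
Staphylococcus aureus NCTC 8325,0.82,0.92,True
Staphylococcus aureus N315,0.85,0.70,True
Shewanella oneidensis,0.88,0.80,True
Streptococcus pneumoniae R6,0.72,0.92,True
Streptococcus pyogenes NZ131,0.85,0.74,True
Streptococcus sanguinis SK36,0.92,0.86,True
Salmonella typhimurium LT2,0.70,0.95,True
Sphingomonas wittichii RW1,0.82,0.72,True
Salmonella enterica serovar Typhi Ty2,0.89,0.72,True
Vibrio cholerae,0.63,0.85,True
Acinetobacter baumannii ATCC 17978,0.69,0.79,False
Burkholderia cenocepacia J2315,0.72,0.79,False
Campylobacter jejuni 81176,0.78,0.82,False
Mycobacterium tuberculosis H37Rv II,0.72,0.80,False
Mycoplasma pneumoniae M129,0.81,0.72,False
Ralstonia solanacearum GMI1000,0.79,0.78,False
Rhodopseudomonas palustris CGA009,0.75,0.69,False
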