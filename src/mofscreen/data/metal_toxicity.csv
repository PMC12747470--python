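element,verdict,note,representative_ld50_mg_per_kg
Zr,biocompatible,zirconium salts show very low acute oral toxicity; ZrCl4 oral-rat LD50 ~1688 mg/kg and Zr is a trace dietary element,1688
Ti,biocompatible,titanium is bioinert; TiO2 oral-rat LD50 >10000 mg/kg,10000
Ca,biocompatible,essential macroelement; CaCl2 oral-rat LD50 ~1000 mg/kg at salt level only,1000
Mg,biocompatible,essential macroelement; MgCl2 oral-rat LD50 ~2800 mg/kg,2800
Na,biocompatible,essential electrolyte,3000
K,biocompatible,essential electrolyte; KCl oral-rat LD50 ~2600 mg/kg,2600
Sr,biocompatible,low acute toxicity; SrCl2 oral-rat LD50 ~2250 mg/kg,2250
Mn,biocompatible,essential trace element at low dose; MnCl2 oral-rat LD50 ~1484 mg/kg,1484
Mo,biocompatible,essential trace element,4000
Fe,not_biocompatible,essential but acutely toxic in overload; FeCl3 oral-rat LD50 ~450 mg/kg; commonly whitelisted on in-vivo evidence,450
Zn,not_biocompatible,essential but ZnCl2 oral-rat LD50 ~350 mg/kg; commonly whitelisted on in-vivo evidence,350
Cu,not_biocompatible,CuSO4 oral-rat LD50 ~300 mg/kg,300
Al,not_biocompatible,neurotoxicity concerns in chronic exposure,3700
Cd,not_biocompatible,carcinogenic heavy metal; CdCl2 oral-rat LD50 ~88 mg/kg,88
Ni,not_biocompatible,carcinogenic and sensitizing; NiCl2 oral-rat LD50 ~105 mg/kg,105
Pb,not_biocompatible,cumulative neurotoxin,105
Hg,not_biocompatible,highly toxic heavy metal; HgCl2 oral-rat LD50 ~1 mg/kg,1
Cr,not_biocompatible,Cr(VI) species carcinogenic,80
Co,not_biocompatible,CoCl2 oral-rat LD50 ~80 mg/kg; cardiomyopathy risk,80
Ag,not_biocompatible,argyria and ionic silver toxicity,100
As,not_biocompatible,arsenic compounds acutely toxic and carcinogenic,20
Ba,not_biocompatible,soluble barium salts acutely toxic; BaCl2 oral-rat LD50 ~118 mg/kg,118
Be,not_biocompatible,berylliosis; highly toxic,90
Tl,not_biocompatible,highly toxic heavy metal,16
V,not_biocompatible,vanadium salts acutely toxic; V2O5 oral-rat LD50 ~10 mg/kg,10
Sn,not_biocompatible,organotin toxicity concerns,700
Sb,not_biocompatible,antimony salts toxic,100
La,not_biocompatible,lanthanide with limited biocompatibility data,4200
Ce,not_biocompatible,lanthanide with limited biocompatibility data,4200
Gd,not_biocompatible,free Gd(III) is toxic (nephrogenic systemic fibrosis),100
U,not_biocompatible,radioactive and nephrotoxic,114
Th,not_biocompatible,radioactive,1000
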