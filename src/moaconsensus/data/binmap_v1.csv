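scheme,label,bin
verhaar,Class 1 (narcosis or baseline toxicity),N
verhaar,Class 2 (less inert compounds),N
verhaar,Class 3 (unspecific reactivity),S
verhaar,Class 4 (compounds and groups of compounds acting by a specific mechanism),S
verhaar,Class 5 (not classifiable),U
aster,Nonpolar narcosis,N
aster,Polar narcosis,N
aster,Ester narcosis,N
aster,Diester toxicity,S
aster,Reactive,S
aster,Chloro-diester-based reactivity,S
aster,Carbonyl (C=0)-based reactivity,S
aster,Carbonyl reactivity,S
aster,Alkylation/arylation-based reactivity,S
aster,Acylation-based reactivity,S
aster,Sulfhydryl (-S-H)-based reactivity,S
aster,Reactive dinitroaromatic group,S
aster,Nitroso-based reactivity,S
aster,Quinoline reactivity,S
aster,Acetamidophenol reactivity,S
aster,Reactive diketones,S
aster,Acrylate toxicity,S
aster,N-halogenated acetophenone inhibition,S
aster,Hydrazine-based reactivity,S
aster,Isocyanate (-N=C=O)-based reactivity,S
aster,Pyridinium compounds,S
aster,Neurotoxicant: DDT-type,S
aster,Neurotoxicant: pyrethroid,S
aster,Neurotoxicant: cyclodiene-type,S
aster,Neurotoxicant: strychnine,S
aster,Neurotoxicant: nicotine,S
aster,Organophosphate-mediated AChE inhibition,S
aster,Carbamate-mediated AChE inhibition,S
aster,Uncoupler of oxidative phosphorylation,S
aster,Respiratory blocker: azides and cyanides,S
aster,Unknown mode of action or out of domain,U
test,Narcosis,N
test,Reactivity,S
test,Neurotoxicity,S
test,AChE inhibition,S
test,Electron transport inhibition,S
test,Iono/osmoregulatory/circulatory impairment,S
test,Unknown or out of domain,U
oasis,Base surface narcotics,N
oasis,Narcotic amines,N
oasis,Phenols and anilines,N
oasis,"Alpha, beta-unsaturated alcohols",N
oasis,Esters,N
oasis,Reactive unspecified,S
oasis,Aldehyde,S
oasis,Unknown or out of domain,U
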