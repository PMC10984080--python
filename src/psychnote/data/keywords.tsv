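# Tiered psychosis keyword lists (term <TAB> tier). Tiers: base, strict, broad.
# Entries are stems/surface forms intended for case-insensitive substring matching.
circumstantial	base
clang association	base
delusion	base
derailment	base
flight of idea	base
formal thought disorder	base
hallucination	base
loosening of association	base
paranoia	base
persecutory idea	base
psychosi	base
psychotic	base
running commentary	base
somatic passivity	base
tangential	base
thought alienation	base
thought block	base
thought disorder	base
thought interference	base
abnormal belief	strict
abnormal perception	strict
deluded	strict
hallicinat	strict
hallucat	strict
halluciant	strict
halluciat	strict
hallucinat	strict
hallucnat	strict
halluicnat	strict
halucinat	strict
passivity	strict
persecutory	strict
though broadcast	strict
thought blocked	strict
thought broadcast	strict
thought disordered	strict
thought echo	strict
thought insertion	strict
thought withdrawal	strict
aggitation	broad
altered perception	broad
auditory disturbance	broad
bizarre behaviour	broad
bizarre belief	broad
bizarre idea	broad
clanging	broad
delusion-like	broad
delusionary disjoint	broad
disordered	broad
disorganis	broad
echolalia	broad
elated mood	broad
elation	broad
flat affect	broad
ftd	broad
grandiose	broad
guarded	broad
halluc	broad
highly agitated	broad
highly aroused	broad
highly distressed	broad
hostile	broad
hostility	broad
hypomanic	broad
illogical	broad
illusion	broad
incoherence	broad
incoherent	broad
jealousy	broad
knights move	broad
loose association	broad
manic	broad
mute	broad
neologism	broad
nihilistic idea	broad
odd belief	broad
olfactory	broad
over inclusive	broad
over valued	broad
overvalued	broad
paranoid	broad
parnoid	broad
perceptual abnormalit	broad
perceptual disturbance	broad
pressured	broad
referential	broad
religiou	broad
religious theme	broad
running commentarie	broad
seeing shadow	broad
seeing shape	broad
somatic	broad
special abilitie	broad
suspicion	broad
suspicious guarded	broad
suspiciousne	broad
tactile	broad
tangencial	broad
tangenital	broad
third person	broad
unusual belief	broad
unusual experience	broad
word salad	broad
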