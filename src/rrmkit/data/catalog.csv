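rrm_frequency,wavelength_nm,functional_group,super_family
0.002,100 K,"Circumsporosoite, PfEMP1, EBA, ICHIT (malaria)",
0.0234,20 K,Hemoglobin,
0.027,7444,Protein A-VHIII,Tumor regulation
0.031,6484,Antitumor agents (TNF + IL-2 + IFN-beta + human M-CSF),Tumor regulation
0.0313,6422,Oncogenes,Tumor regulation
0.039,5154,IL-1,Tumor regulation
0.0430,4674,Phospholipases,Tumor regulation
0.0439,4579,Insulin multimer,Tumor regulation
0.0446,4508,Glucocorticoide receptors,Tumor regulation
0.0459,4379,Homeo box proteins,Tumor regulation
0.0488,4119,Enhancers,Tumor regulation
0.049,4102,TNF receptors,Tumor regulation
0.051,3941,TNFs,Tumor regulation
0.054,3722,Proto-oncogenes,Tumor regulation
0.0590,3407,Cytochrome B,
0.062,3242,EGF-EGF receptor,
0.0703,2859,Neurotoxins,
0.0781,2574,Operators,
0.0820,2451,Interferons,
0.0820,2451,Myoglobins,
0.0839,2396,Bacterial repressors,Viral-bacterial infection
0.0947,2122,Heat shock proteins,Viral-bacterial infection
0.096,2094,Tubulins A + B,Viral-bacterial infection
0.0990,2030,Repressors,Viral-bacterial infection
0.1054,1907,Phage repressors,Viral-bacterial infection
0.110,1827,EBA-RBC (malaria interaction with red blood cells),Viral-bacterial infection
0.115,1748,Myxoma virus,Viral-bacterial infection
0.162,1241,IGFBP,
0.173,1162,Telomere binding,
0.186,1081,HIV envelope,
0.188,1069,Telomere,
0.2363,851,Chymotrypsins,
0.281,715,Purple (bacteria),
0.285,705,TERT + telomerase RNA + progerin,Growth
0.288,698,EGFs,Growth
0.289,695,Growth hormons + NGF + proliferins,Growth
0.2929,686,Growth factors (CSF + EGF + IL-2),Growth
0.297,678,"CSF, Ubiquitins, EPA",Growth
0.300,670,"IL-2, IL-4, IL-6",Growth
0.308,653,IL-2-IL2 receptor,Growth
0.3203,628,Glucagons,Growth
0.3281,613,Lysozymes,Enzymes
0.3400,591,Myosins,Enzymes
0.3437,585,Promoters,Enzymes
0.3447,583,Trypsins,Enzymes
0.346,581,Red (rhodopsin),Enzymes
0.35,574,RNA polymerase,Enzymes
0.355,566,Green (rhodopsin and chlorophylls),Enzymes
0.3555,565,Protease inhibitors,Enzymes
0.3770,533,Proteases,Enzymes
0.379,530,Flavodoxins,Enzymes
0.3828,525,Insulin receptors,Enzymes
0.383,525,Insulins,Enzymes
0.4040,498,NGFs,Enzymes
0.4121,488,Amylases,Enzymes
0.4297,468,Kinases,Enzymes
0.434,463,Tubulins beta,Structural proteins
0.4423,454,Fibrinogens,Structural proteins
0.449,448,Tubulins alpha,Structural proteins
0.4512,445,"FGFs, FGF receptors",
0.453,444,IL-12,
0.4609,436,Serine proteases,
0.4687,429,SOS operators,
0.475,423,Blue (rhodopsin and bioluminescent proteins),Blue
0.4765,422,Cytochrome C,Blue
0.4800,419,Actins,
0.4922,408,ACH receptors,
0.4922,408,IGFs,
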