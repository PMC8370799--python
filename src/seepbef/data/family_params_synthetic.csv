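family,species,mi,ri,calc_score,provenance
Capitellidae,Capitella_sp_a,2,4,0,queiros
Capitellidae,Notomastus_sp,2,3,0,queiros
Dorvilleidae,Dorvillea_sp,3,3,0,synthetic-expert
Dorvilleidae,Ophryotrocha_sp,3,2,0,synthetic-expert
Spionidae,Prionospio_sp,3,3,0,queiros
Ampharetidae,Amphisamytha_sp,1,2,0,synthetic-expert
Maldanidae,Maldane_sp,2,2,0,queiros
Syllidae,Exogone_sp,3,1,0,queiros
Cirratulidae,Chaetozone_sp,2,2,0,queiros
Nereididae,Neanthes_sp,3,3,0,queiros
Thyasiridae,Thyasira_sp,2,2,4,synthetic-expert
Lucinidae,Lucinoma_sp,2,2,5,synthetic-expert
Vesicomyidae,Calyptogena_sp,2,2,5,synthetic-expert
Solemyidae,Acharax_sp,2,3,5,synthetic-expert
Provannidae,Provanna_sp,2,1,5,synthetic-expert
Pyramidellidae,Odostomia_sp,2,1,4,synthetic-expert
Leuconidae,Leucon_sp,3,2,3,synthetic-expert
Nannastacidae,Cumella_sp,3,2,3,synthetic-expert
Ampeliscidae,Ampelisca_sp,3,2,1,queiros
Munnopsidae,Ilyarachna_sp,3,1,1,synthetic-expert
Typhlotanaidae,Typhlotanais_sp,2,2,1,synthetic-expert
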