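reference,trapping_mechanism,cell_lines,diameter_um,vm_over_vt,t_exp_h,t_model_published_h,sample_kind
Frimat 2011,resistive,SW580; HT29; MCF-7,17.9,112,,28,single_cell
Kukhtevich 2011,resistive,K562,20,127,,31,single_cell
Occhetta 2015,resistive,HeLa,16,729,,180,single_cell
Das 2013,resistive,TOV112D,250,138,24,34,spheroid
Ota 2011,inertial,HepG2,450,168,,41,spheroid
Astolfi 2016,sedimentation,22Rv1; PC3; TOV112D; OV90,380,208,48,52,micro_dissected_tissue
Anada 2012 (600 um),sedimentation,HepG2,600,52,24,13,spheroid
Anada 2012 (310 um),sedimentation,HepG2,310,376,48,93,spheroid
Patra 2013,sedimentation,TOV3041G; TOV112D; OV90; OV866(2),130,53,12,13,spheroid
Patra 2016,sedimentation,HepG2,225,92,24,23,spheroid
Frey 2014,open_microfluidics,HCT-116 eGFP,400,470,,116,spheroid
Marimuthu 2018,open_microfluidics,OV90,500,378,24,92,spheroid
Grimes 2014,open_microfluidics,DLD1,585,79,24,20,spheroid
Torisawa 2009,open_microfluidics,MCF-7; HepG2,260,165,48,41,spheroid
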