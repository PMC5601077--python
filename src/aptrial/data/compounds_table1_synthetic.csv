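compound,source_id,channel,ic50_uM,hill,eftpc_max_uM,tdp_category
BaCl2,I,I_K1,4.0,1.0,1.0,0
Bepridil,I,I_Kr,0.15,1.0,0.033,1
Bepridil,I,I_Na,2.9,1.0,0.033,1
Bepridil,I,I_CaL,2.8,1.0,0.033,1
Dofetilide,I,I_Kr,0.03,1.0,0.002,1
Flecainide,I,I_Kr,1.5,1.0,0.75,1
Flecainide,I,I_Na,6.2,1.0,0.75,1
Lidocaine,I,I_Na,38.0,1.0,2.9,0
Lidocaine,I,I_Kr,295.0,1.0,2.9,0
Mexiletine,I,I_Na,43.0,1.0,2.5,0
Mexiletine,I,I_Kr,62.0,1.0,2.5,0
Moxifloxacin,I,I_Kr,65.0,1.0,3.2,1
Nimodipine,I,I_CaL,0.005,1.0,0.0002,0
Nisoldipine,I,I_CaL,0.002,1.0,0.0002,0
Phenytoin,I,I_Na,50.0,1.0,4.0,0
Primidone,I,I_Na,600.0,1.0,10.0,0
Procainamide,I,I_Kr,139.0,1.0,38.0,1
Procainamide,I,I_Na,310.0,1.0,38.0,1
Ranolazine,I,I_Kr,12.0,1.0,2.0,3
Ranolazine,I,I_NaL,6.0,1.0,2.0,3
Sparfloxacin,I,I_Kr,18.0,1.0,1.5,1
Verapamil,II,I_Kr,0.5,1.0,0.081,NC
Verapamil,II,I_CaL,0.1,1.0,0.081,NC
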