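name,phase,dfG_ref_kJ_mol,S_ref_kJ_mol_K,cp_A,cp_B,cp_C,vdw_a_L2atm_mol2,vdw_b_L_mol,V_liquid_kJ_Pa_mol
CO2,gas,-394.36,0.21379,2.852945,4.731338e-03,-2.155318e-06,3.640,0.04267,
O2,gas,0.0,0.20515,3.577051,-8.505845e-04,-2.352801e-06,1.382,0.03186,
CH4,gas,-50.72,0.18626,5.059131,-1.041002e-02,-2.607244e-05,2.283,0.04278,
H2O,liquid,-237.13,0.06995,16.347250,-4.763198e-02,-7.772440e-05,5.536,0.03049,1.8e-08
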