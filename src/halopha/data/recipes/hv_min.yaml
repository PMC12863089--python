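# Hv-min defined medium (growth-permissive): mixed lactate/glycerol/succinate
# carbon source. Concentrations in mM unless g_per_l is given. C/N/P are atom
# counts per formula unit; `counted: false` marks buffer components excluded
# from nutrient elemental sums. `atomic_masses` is the mass-basis convention
# under which this recipe's nominal C/N/P ratio (62.8 : 2.3 : 1.0) was
# derived (phosphorus reference mass 32 g/mol); `standard_masses` are the
# IUPAC values for users who prefer them.
name: hv_min
atomic_masses: {C: 12.011, N: 14.007, P: 32.0}
standard_masses: {C: 12.011, N: 14.007, P: 30.974}
components:
  - {name: Tris-HCl pH 7.5, mM: 15.9, C: 4, N: 1, counted: false}
  - {name: NaCl, mM: 2600.0}
  - {name: MgCl2, mM: 93.8}
  - {name: MgSO4, mM: 90.3}
  - {name: KCl, mM: 60.0}
  - {name: NH4Cl, mM: 5.3, N: 1}
  - {name: CaCl2, mM: 6.4}
  - {name: K2HPO4, mM: 0.6, P: 1}
  - {name: KH2PO4, mM: 0.4, P: 1}
  - {name: MnCl2, mM: 0.0019}
  - {name: ZnSO4, mM: 0.0016}
  - {name: FeSO4, mM: 0.0088}
  - {name: CuSO4, mM: 0.0002}
  - {name: thiamine, mM: 0.0032, C: 12, N: 4}
  - {name: biotin, mM: 0.0004, C: 10, N: 2}
  - {name: sodium DL-lactate, mM: 32.0, C: 3}
  - {name: glycerol, mM: 3.7, C: 3}
  - {name: sodium succinate, mM: 15.0, C: 4}
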