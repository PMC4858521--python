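# Architecture template library, v1: the ten most abundant archaeal type IV
# pili variants plus the archaellum, as declarative role->multiplicity
# models.  Requirement keys are coarse roles except in the archaellum, whose
# seven components are matched by family component tags (flaI is not a
# generic secretion_ATPase for template purposes, and vice versa).
# Multiplicities are inclusive [min, max] gene counts within one locus.
templates:
  clade1:
    # Complex euryarchaeal system (methanococci/methanobacteria/thermococci):
    # ATPase + two TadC platforms + FleN/MinD ATPase + the 9-TM peptidase
    # (EppA) + at least five minor pilins + adhesins + membrane accessories;
    # the small (~70 aa) major pilins are usually encoded in trans.
    required:
      secretion_ATPase: [1, 1]
      tadC: [2, 2]
      fleN_minD: [1, 1]
      peptidase_9TM: [1, 1]
      minor_pilin: [5, 9]
      adhesin: [1, 2]
      membrane_accessory: [2, 3]
      major_pilin: [1, 9]
    optional: [regulator, cytoplasmic_accessory, s_layer]
  archaellum:
    # The seven core components: FlaI, FlaH, FlaJ, FlaF, FlaG (one each),
    # 1-9 archaellins (FlaA/FlaB), 1-3 FlaC/D/E genes (fusions count once).
    required:
      flaI: [1, 1]
      flaH: [1, 1]
      flaJ: [1, 1]
      flaF: [1, 1]
      flaG: [1, 1]
      archaellin: [1, 9]
      flaCDE: [1, 3]
    optional: [regulator, peptidase_5TM]
  clade2_pilA:
    # PilA-based euryarchaeal system (PilB3-like locus): ATPase/2xTadC module
    # with the shared minor pilin; PilA majors interact in trans.
    required:
      secretion_ATPase: [1, 1]
      tadC: [2, 2]
      major_pilin: [1, 6]
      minor_pilin: [1, 1]
    optional: [s_layer, fleN_minD, peptidase_5TM]
  clade2_B:
    # Second euryarchaeal variant (PilB4-like locus) with its own major
    # pilin, several minors and a membrane accessory.
    required:
      secretion_ATPase: [1, 1]
      tadC: [1, 1]
      major_pilin: [1, 2]
      minor_pilin: [2, 3]
      membrane_accessory: [1, 1]
    optional: [peptidase_5TM, s_layer]
  sub4C:
    # Halobacterial hybrid system: clade-2-like pilin set (including the
    # shared signature minor pilin) on a crenarchaeal ATPase/TadC module.
    required:
      secretion_ATPase: [1, 1]
      tadC: [1, 1]
      major_pilin: [1, 1]
      minor_pilin: [4, 5]
    optional: [peptidase_5TM, s_layer]
  sub4F:
    # Hybrid system with a stand-alone-prone PilA major pilin, an S-layer
    # like protein and a coiled-coil cytoplasmic subunit.
    required:
      secretion_ATPase: [1, 1]
      tadC: [1, 1]
      major_pilin: [1, 2]
      cytoplasmic_accessory: [1, 1]
    optional: [s_layer, fleN_minD, peptidase_5TM]
  sulfolobales_simple:
    # Minimal three-component plan of Sulfolobales/Desulfurococcales pili
    # (clades 4A/4H/4I/4J): ATPase, one or two TadC genes, PilA majors.
    required:
      secretion_ATPase: [1, 1]
      tadC: [1, 2]
      major_pilin: [1, 3]
    optional: [peptidase_5TM, s_layer, adhesin]
  sub4B:
    # Thermoproteales system: two TadC genes, two PilA majors, plus a large
    # signal-peptide protein (minor pilin or adhesin).
    required:
      secretion_ATPase: [1, 1]
      tadC: [2, 2]
      major_pilin: [2, 2]
      adhesin: [1, 1]
    optional: [s_layer, regulator]
  sub4E:
    # Conserved Thermoproteales system with a signature minor pilin plus one
    # membrane and one cytoplasmic component.
    required:
      secretion_ATPase: [1, 1]
      tadC: [1, 1]
      major_pilin: [1, 2]
      minor_pilin: [1, 1]
      membrane_accessory: [1, 1]
      cytoplasmic_accessory: [1, 1]
    optional: [peptidase_5TM]
  sub4G:
    # Highly complex Pyrobaculum/Thermoproteus system: diverged ATPase/TadC,
    # PilA major, several minors, S-layer like protein, adhesin, FleN/MinD
    # ATPase, two membrane and two cytoplasmic accessories.
    required:
      secretion_ATPase: [1, 1]
      tadC: [1, 1]
      major_pilin: [1, 1]
      minor_pilin: [2, 4]
      adhesin: [1, 1]
      fleN_minD: [1, 1]
      membrane_accessory: [2, 2]
      cytoplasmic_accessory: [2, 2]
    optional: [s_layer, regulator]
  sub4D:
    # The unusual two-component Thermoproteales system: ATPase plus a 4-5 TM
    # membrane protein; no pilins or secreted proteins ever occur in these
    # loci (a TFIIB homolog often does).
    required:
      secretion_ATPase: [1, 1]
      membrane_accessory: [1, 1]
    forbidden: [major_pilin, minor_pilin, archaellin, adhesin, s_layer]
    optional: [regulator]
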