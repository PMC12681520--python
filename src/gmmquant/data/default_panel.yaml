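# Default analyte panel: 33 quantification targets (17 uremic toxins + 16 bile
# acids, of which GCA, CDCA and GB are excluded for on-column accumulation,
# leaving 16 UTs + 14 BAs = 30 quantified targets) plus the two isotope-labelled
# internal standards.  Calibration range 0.005-20 uM for every target.
# MRM transition masses are optional metadata and never used in computation.
intstd_nominal:
  negative: 10.0   # p-CS-d7 spike, uM in the injected extract
  positive: 1.0    # GDCA-d6 spike, uM in the injected extract
matrices: [plasma, feces]
dilution_schemes:
  plasma: [1, 2, 50]   # neat, 1:1, 1:49
  feces: [1, 2, 10]    # neat, 1:1, 1:9
analytes:
  # ---- internal standards -------------------------------------------------
  - {id: p-CS-d7, name: p-Cresol sulfate-d7, class: uremic_toxin,
     esi_mode: negative, internal_standard: null, is_internal_standard: true,
     calibration_range: [0.005, 20.0]}
  - {id: GDCA-d6, name: Glycodeoxycholic acid-d6, class: secondary_bile_acid,
     esi_mode: positive, internal_standard: null, is_internal_standard: true,
     calibration_range: [0.005, 20.0]}
  # ---- uremic toxins ------------------------------------------------------
  - {id: p-CS, name: p-Cresol sulfate, class: uremic_toxin, esi_mode: negative}
  - {id: PS, name: Phenyl sulfate, class: uremic_toxin, esi_mode: negative}
  - {id: IS, name: Indoxyl sulfate, class: uremic_toxin, esi_mode: negative}
  - {id: MPS, name: 2-Methoxyphenylsulfate, class: uremic_toxin, esi_mode: negative}
  - {id: HA, name: Hippuric acid, class: uremic_toxin, esi_mode: negative}
  - {id: DG, name: Diethyl glutarate, class: uremic_toxin, esi_mode: positive}
  - {id: APN, name: 2-Aminophenol, class: uremic_toxin, esi_mode: positive}
  - {id: MCC, name: 4-Methylcatechol, class: uremic_toxin, esi_mode: positive}
  - {id: CMG, name: Cinnamoylglycine, class: uremic_toxin, esi_mode: positive}
  - {id: PAG, name: Phenylacetylglycine, class: uremic_toxin, esi_mode: positive}
  - {id: HHA, name: m-Hydroxyhippuric acid, class: uremic_toxin, esi_mode: positive}
  - {id: PAGlu, name: Phenylacetylglutamine, class: uremic_toxin, esi_mode: positive}
  - {id: TMAO, name: Trimethylamine N-oxide, class: uremic_toxin, esi_mode: positive}
  - {id: GB, name: 4-Guanidinobutyric acid, class: uremic_toxin, esi_mode: positive,
     excluded: true, excluded_reason: accumulates on the column}
  - {id: NAG, name: N-Acetylglutamine, class: uremic_toxin, esi_mode: positive}
  - {id: ImP, name: Imidazolepropionic acid, class: uremic_toxin, esi_mode: positive}
  - {id: DMG, name: Dimethylglycine, class: uremic_toxin, esi_mode: positive}
  # ---- primary bile acids -------------------------------------------------
  - {id: CA, name: Cholic acid, class: primary_bile_acid, esi_mode: negative}
  - {id: CDCA, name: Chenodeoxycholic acid, class: primary_bile_acid,
     esi_mode: negative, excluded: true, excluded_reason: accumulates on the column}
  - {id: GCA, name: Glycocholic acid, class: primary_bile_acid, esi_mode: positive,
     excluded: true, excluded_reason: accumulates on the column}
  - {id: TCA, name: Taurocholic acid, class: primary_bile_acid, esi_mode: positive}
  - {id: "ω-MCA", name: omega-Muricholic acid, class: primary_bile_acid,
     esi_mode: negative}
  - {id: "G-γ-MCA", name: Glyco-gamma-muricholic acid,
     class: primary_bile_acid, esi_mode: positive}
  - {id: TCDCA, name: Taurochenodeoxycholic acid, class: primary_bile_acid,
     esi_mode: positive, conjugate_group: taurine_conjugates}
  - {id: GCDCA, name: Glycochenodeoxycholic acid, class: primary_bile_acid,
     esi_mode: positive, conjugate_group: glycine_conjugates}
  # ---- secondary bile acids -----------------------------------------------
  - {id: UDCA, name: Ursodeoxycholic acid, class: secondary_bile_acid, esi_mode: negative}
  - {id: KLCA, name: 12-Ketolithocholic acid, class: secondary_bile_acid, esi_mode: negative}
  - {id: LCA, name: Lithocholic acid, class: secondary_bile_acid, esi_mode: negative}
  - {id: DCA, name: Deoxycholic acid, class: secondary_bile_acid, esi_mode: negative}
  - {id: TDCA, name: Taurodeoxycholic acid, class: secondary_bile_acid,
     esi_mode: positive, conjugate_group: taurine_conjugates}
  - {id: TUDCA, name: Tauroursodeoxycholic acid, class: secondary_bile_acid,
     esi_mode: positive, conjugate_group: taurine_conjugates}
  - {id: GDCA, name: Glycodeoxycholic acid, class: secondary_bile_acid,
     esi_mode: positive, conjugate_group: glycine_conjugates}
  - {id: GUDCA, name: Glycoursodeoxycholic acid, class: secondary_bile_acid,
     esi_mode: positive, conjugate_group: glycine_conjugates}
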