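# Receptor geometry dictionary: TM helix residue ranges (author numbering),
# domain anchor residues and TM6 kink quadruplets for the two gonadotropin
# receptors. Ranges are inclusive; all selections default to CA atoms.
fshr:
  description: >
    Follicle-stimulating hormone receptor, AlphaFold model AF-P23945
    conventions (695 residues, single chain).
  chain: null            # AF model has one chain; match any
  tm_helices:
    tm1: [362, 392]
    tm2: [397, 432]
    tm3: [437, 472]
    tm4: [487, 507]
    tm5: [532, 557]
    tm6: [567, 597]
    tm7: [607, 626]
  anchors:
    lrr: 31              # middle of the first beta-strand of the LRR
    hr: 303              # middle of the hinge-region alpha-helix
    tm: 460              # middle of TM helix 3
  kink:
    upper_pair: [597, 585]   # Calpha pair spanning the upper half of TM6
    lower_pair: [581, 565]   # Calpha pair spanning the lower half of TM6
    reference_angle_deg: 44.0

lhcgr:
  description: >
    Luteinizing hormone / chorionic gonadotropin receptor, cryo-EM structure
    PDB 7FII conventions (chain R, segment PROD; 613 residues modelled).
  chain: R
  tm_helices:
    tm1: [360, 387]
    tm2: [392, 420]
    tm3: [437, 470]
    tm4: [480, 504]
    tm5: [522, 552]
    tm6: [565, 597]
    tm7: [602, 625]
  anchors:
    lrr: 55
    hr: 304
    tm: 431              # TM anchor used for the LRR-TM distance
    tm_hr: 452           # TM anchor used for the TM-HR distance
  kink:
    upper_pair: [594, 586]
    lower_pair: [578, 563]
    reference_angle_deg: 37.0
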