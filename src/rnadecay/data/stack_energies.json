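{
 "comment": "RNA nearest-neighbor stack dG37 (kcal/mol) keyed by 'P1,P2' where P = left-arm base + its partner, read 5'->3' along the left arm. WC values from the standard Turner compilation; wobble stacks partly tabulated, otherwise a weak default of -1.00. Hairpin loop initiation penalties by loop length.",
 "hairpin_loop": {
  "3": 5.4,
  "4": 5.6,
  "5": 5.7,
  "6": 5.4,
  "7": 6.0,
  "8": 5.5
 },
 "mismatch_penalty": 1.0,
 "stack": {
  "AU,AU": -0.93,
  "AU,CG": -2.24,
  "AU,GC": -2.08,
  "AU,GU": -0.55,
  "AU,UA": -1.1,
  "AU,UG": -1.36,
  "CG,AU": -2.11,
  "CG,CG": -3.26,
  "CG,GC": -2.36,
  "CG,GU": -1.41,
  "CG,UA": -2.08,
  "CG,UG": -2.11,
  "GC,AU": -2.35,
  "GC,CG": -3.42,
  "GC,GC": -3.26,
  "GC,GU": -1.53,
  "GC,UA": -2.24,
  "GC,UG": -2.51,
  "GU,AU": -1.0,
  "GU,CG": -2.51,
  "GU,GC": -2.11,
  "GU,GU": 0.47,
  "GU,UA": -1.36,
  "GU,UG": -1.0,
  "UA,AU": -1.33,
  "UA,CG": -2.35,
  "UA,GC": -2.11,
  "UA,GU": -1.0,
  "UA,UA": -0.93,
  "UA,UG": -1.0,
  "UG,AU": -1.0,
  "UG,CG": -1.53,
  "UG,GC": -1.41,
  "UG,GU": -1.0,
  "UG,UA": -0.55,
  "UG,UG": -0.3
 },
 "version": "1.0"
}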