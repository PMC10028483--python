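# Synthetic default code vocabulary (editable stand-in for a site's real
# code lists).  Entries are code PREFIXES on normalised codes (dots
# stripped, upper-case), keyed by code system.
t2d:
  ICD9: ["25000", "25002"]
  ICD10: ["E11"]
t1d:
  ICD9: ["25001", "25003"]
  ICD10: ["E10"]
oa:
  ICD9: ["715"]
  ICD10: ["M15", "M16", "M17", "M18", "M19"]
inflammatory_arthritis:
  ICD9: ["714"]
  ICD10: ["M05", "M06"]
# hip / knee total arthroplasty CPT stand-ins
joint_replacement_cpt: ["27130", "27447"]
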