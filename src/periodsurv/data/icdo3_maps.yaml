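# Default ICD-O-3 grouping tables. These are editable configuration data,
# not code: registries revise morphology groupings, so analyses should pin
# the mapping they used. Morphology codes are 4-digit ICD-O-3 histology
# codes; only behaviour /3 (malignant) records are classified.
subtype_map:
  "CLL/SLL": [9823, 9670]
  "DLBCL": [9680, 9684]
  "FL": [9690, 9691, 9695, 9698]
  "MCL": [9673]
  "MZL": [9689, 9699, 9764]
  "PTCL": [9702, 9705, 9708, 9709, 9714, 9716, 9717, 9718, 9719, 9726, 9827, 9831, 9834, 9837]
# Topography codes treated as nodal primaries; everything else is extranodal.
nodal_sites: ["C770", "C771", "C772", "C773", "C774", "C775", "C776", "C777", "C778", "C779"]
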