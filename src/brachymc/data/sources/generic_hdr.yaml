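# Generic HDR Ir-192 source (community benchmark seed).
# Nominal dimensions after the published generic-source description used by
# the model-based dose-calculation benchmark test cases: pure-iridium
# cylindrical core inside an AISI 316L stainless-steel capsule with a short
# drive-cable stub.  All values editable; cm.
name: generic_hdr
core:
  radius: 0.030        # 0.60 mm diameter
  half_length: 0.175   # 3.5 mm active length
  material: iridium
  density: 22.42
capsule:
  radius: 0.045        # 0.90 mm outer diameter
  half_length: 0.195   # 0.2 mm end caps beyond the core
  material: steel316
  density: 8.0
cable:
  radius: 0.035
  length: 0.20
  material: steel316
  density: 5.6         # stranded cable, reduced effective density
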