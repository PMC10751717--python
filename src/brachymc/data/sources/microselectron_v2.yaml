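# microSelectron HDR v2-style Ir-192 source (clinical afterloader seed).
# Nominal published dimensions; cm.
name: microselectron_v2
core:
  radius: 0.0325       # 0.65 mm diameter
  half_length: 0.180   # 3.6 mm active length
  material: iridium
  density: 22.42
capsule:
  radius: 0.045        # 0.90 mm outer diameter
  half_length: 0.2025
  material: steel316
  density: 8.0
cable:
  radius: 0.035
  length: 0.20
  material: steel316
  density: 5.6
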