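# spectrum: ir192
# compiled: 2026-09-28
# provenance: Ir-192 photon emission lines (gammas plus Os/Pt K
#   X-rays) compiled from the standard nuclear decay-data
#   tabulations; lines below 0.01% per decay and L X-rays omitted
#   (fully absorbed in the source core).
# total_yield_per_decay: 2.298950
# intensity_weighted_mean_keV: 354.833
# columns: E_keV intensity_per_decay
61.486 0.012000
63.000 0.020500
65.122 0.026300
66.831 0.044600
71.300 0.006800
75.749 0.015300
77.850 0.004600
136.343 0.001990
201.311 0.004730
205.794 0.033400
283.267 0.002660
295.957 0.287100
308.455 0.297000
316.506 0.828600
374.485 0.007260
416.469 0.006700
420.520 0.000690
468.069 0.478400
484.575 0.031900
489.060 0.004380
588.581 0.045200
604.411 0.082000
612.462 0.053400
884.537 0.002910
1061.480 0.000530
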