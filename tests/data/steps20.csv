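plant_id,step_cm
fixture20,0.689367
fixture20,0.834365
fixture20,0.840323
fixture20,0.975848
fixture20,1.056844
fixture20,1.290524
fixture20,1.459193
fixture20,1.498903
fixture20,1.640524
fixture20,2.023190
fixture20,2.206532
fixture20,2.372854
fixture20,2.454217
fixture20,5.244976
fixture20,6.349191
fixture20,6.988004
fixture20,8.322424
fixture20,8.497896
fixture20,11.122409
fixture20,48.732657
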