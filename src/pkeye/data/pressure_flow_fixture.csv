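membrane_id,mwco_kda,exposed_diameter_mm,pressure_mmHg,flow_uL_min,experiment,source
visking_12_14_d20,12-14,20.0,150.0,0.66,area_sweep_150mmHg,"pursing rig, 12-14 kDa membrane, 20.0 mm clamp, fixed 150 mmHg"
visking_12_14_d15,12-14,15.0,150.0,0.54,area_sweep_150mmHg,"pursing rig, 12-14 kDa membrane, 15.0 mm clamp, fixed 150 mmHg"
visking_12_14_d5,12-14,5.0,150.0,0.05,area_sweep_150mmHg,"pursing rig, 12-14 kDa membrane, 5.0 mm clamp, fixed 150 mmHg"
visking_12_14_d20,12-14,20.0,361.0,2.0,mwco_sweep_2uLmin,"pursing rig, 12-14 kDa membrane, 20.0 mm clamp, ~2.0 uL/min operating point"
visking_50_d20,50,20.0,342.0,2.0,mwco_sweep_2uLmin,"pursing rig, 50 kDa membrane, 20.0 mm clamp, ~2.0 uL/min operating point"
visking_300_d20,300,20.0,7.0,2.0,mwco_sweep_2uLmin,"pursing rig, 300 kDa membrane, 20.0 mm clamp, ~2.0 uL/min operating point"
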