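{
  "description": "Synthetic default arterial path from the aorta to the anterior cerebral artery (A2). Segment dimensions are representative adult human values (length cm, internal radius cm, blood flow mL/s, intima-media wall thickness mm) assembled from vascular-anatomy literature; edit freely.",
  "segments": [
    {"name": "aorta", "length_cm": 25.0, "radius_cm": 1.25, "flow_ml_s": 85.0, "wall_mm": 1.3, "flow_scale": 1.0},
    {"name": "common_carotid", "length_cm": 18.0, "radius_cm": 0.31, "flow_ml_s": 7.0, "wall_mm": 0.75, "flow_scale": 1.0},
    {"name": "internal_carotid", "length_cm": 14.0, "radius_cm": 0.24, "flow_ml_s": 4.8, "wall_mm": 0.6, "flow_scale": 1.0},
    {"name": "anterior_cerebral", "length_cm": 5.0, "radius_cm": 0.11, "flow_ml_s": 1.5, "wall_mm": 0.35, "flow_scale": 1.0}
  ]
}
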