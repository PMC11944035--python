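# Upright standing posture held in microgravity: same joint angles as the
# relaxed 1 g stance, gravity switched off.
name: sm0g
gravity_factor: 0.0
joint_angles:
  sternoclavicular_protraction: 23.0
  sternoclavicular_elevation: 11.5
  shoulder_flexion: 8.0
  shoulder_abduction: 10.0
  elbow_flexion: 8.0
  elbow_pronation: -20.0
  hip_flexion: -6.0
  hip_abduction: 5.0
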