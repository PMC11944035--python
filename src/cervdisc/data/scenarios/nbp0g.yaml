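# Neutral body posture in microgravity: semi-crouched float with ~24 deg
# neck flexion, from in-flight kinematic observations.
name: nbp0g
gravity_factor: 0.0
joint_angles:
  neck_flexion: 24.0
  shoulder_flexion: 39.0
  shoulder_abduction: 35.0
  elbow_flexion: 77.0
  elbow_pronation: 60.0
  hip_flexion: 55.0
  hip_abduction: 16.0
  hip_external_rotation: 17.0
  knee_flexion: 55.0
  ankle_plantarflexion: 21.0
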