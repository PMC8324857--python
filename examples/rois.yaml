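- name: posterior_left_atrium
  structures:
  - left_atrium
  radius: 500.0
  mode: any
- name: pv_hilum
  structures:
  - pulmonary_vein_left
  - pulmonary_vein_middle
  - pulmonary_vein_right
  - left_atrium
  radius: 500.0
  mode: any
- name: svc_ra_root
  structures:
  - superior_vena_cava
  - right_atrium
  radius: 500.0
  mode: any
- name: left_av_sulcus
  structures:
  - coronary_sinus
  radius: 500.0
  mode: any
- name: anterior_interatrial_sulcus
  structures:
  - left_atrium
  - right_atrium
  radius: 500.0
  mode: all
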