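A:
  audition:
  - - - - 0.9
        - 0.9
      - - 0.9
        - 0.9
    - - - 0.2
        - 0.2
      - - 0.2
        - 0.2
    - - - 0.2
        - 0.2
      - - 0.2
        - 0.2
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
  - - - - 0.05
        - 0.05
      - - 0.05
        - 0.05
    - - - 0.8
        - 0.8
      - - 0.8
        - 0.8
    - - - 0.8
        - 0.8
      - - 0.8
        - 0.8
    - - - 0.2
        - 0.2
      - - 0.2
        - 0.2
    - - - 0.2
        - 0.2
      - - 0.2
        - 0.2
  - - - - 0.05
        - 0.05
      - - 0.05
        - 0.05
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.8
        - 0.8
      - - 0.8
        - 0.8
    - - - 0.8
        - 0.8
      - - 0.8
        - 0.8
  proprio-baro:
  - - - - 1.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 1.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 1.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 1.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 1.0
        - 0.0
      - - 0.0
        - 0.0
  - - - - 0.0
        - 0.0
      - - 1.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 1.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 1.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 1.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 1.0
        - 0.0
  - - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
  - - - - 0.0
        - 0.0
      - - 0.0
        - 1.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 1.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 1.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 1.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 1.0
  vision:
  - - - - 1.0
        - 0.0
      - - 1.0
        - 1.0
    - - - 0.5
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.5
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
  - - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.5
        - 0.0
      - - 1.0
        - 1.0
    - - - 0.5
        - 0.0
      - - 1.0
        - 1.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
  - - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 1.0
        - 0.0
      - - 1.0
        - 1.0
  - - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
    - - - 1.0
        - 0.0
      - - 1.0
        - 1.0
    - - - 0.0
        - 0.0
      - - 0.0
        - 0.0
  - - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
    - - - 0.0
        - 1.0
      - - 0.0
        - 0.0
B:
  creatures:
  - - - 0.9496
      - 0.1296
      - 0.09
      - 0.0
      - 0.0
    - - 0.0252
      - 0.5904
      - 0.0
      - 0.0
      - 0.0
    - - 0.0252
      - 0.0
      - 0.8200000000000001
      - 0.0
      - 0.09
    - - 0.0
      - 0.28
      - 0.0
      - 1.0
      - 0.0
    - - 0.0
      - 0.0
      - 0.09
      - 0.0
      - 0.91
  - - - 0.9496
      - 0.1296
      - 0.09
      - 0.0
      - 0.0
    - - 0.0252
      - 0.5904
      - 0.0
      - 0.0
      - 0.0
    - - 0.0252
      - 0.0
      - 0.8200000000000001
      - 0.0
      - 0.09
    - - 0.0
      - 0.28
      - 0.0
      - 1.0
      - 0.0
    - - 0.0
      - 0.0
      - 0.09
      - 0.0
      - 0.91
  - - - 1.0
      - 0.9
      - 0.9
      - 0.0
      - 0.0
    - - 0.0
      - 0.09999999999999998
      - 0.0
      - 0.9
      - 0.0
    - - 0.0
      - 0.0
      - 0.09999999999999998
      - 0.0
      - 0.9
    - - 0.0
      - 0.0
      - 0.0
      - 0.09999999999999998
      - 0.0
    - - 0.0
      - 0.0
      - 0.0
      - 0.0
      - 0.09999999999999998
  - - - 1.0
      - 0.18
      - 0.09
      - 0.0
      - 0.0
    - - 0.0
      - 0.8200000000000001
      - 0.0
      - 0.0
      - 0.0
    - - 0.0
      - 0.0
      - 0.8200000000000001
      - 0.0
      - 0.09
    - - 0.0
      - 0.0
      - 0.0
      - 1.0
      - 0.0
    - - 0.0
      - 0.0
      - 0.09
      - 0.0
      - 0.91
  heart:
  - - - 1.0
      - 1.0
    - - 0.0
      - 0.0
  - - - 0.0
      - 0.0
    - - 1.0
      - 1.0
  - - - 0.0
      - 0.0
    - - 1.0
      - 1.0
  - - - 1.0
      - 1.0
    - - 0.0
      - 0.0
  motion:
  - - - 1.0
      - 1.0
    - - 0.0
      - 0.0
  - - - 0.0
      - 0.0
    - - 1.0
      - 1.0
  - - - 1.0
      - 1.0
    - - 0.0
      - 0.0
  - - - 0.0
      - 0.0
    - - 1.0
      - 1.0
C:
  audition:
  - 1.0
  - -1.0
  - -2.0
  proprio-baro:
  - 1.0
  - -1.0
  - -10.0
  - 0.0
  vision:
  - 2.0
  - -1.0
  - 1.0
  - -10.0
  - -0.5
D:
  creatures:
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  heart:
  - 1.0
  - 0.0
  motion:
  - 1.0
  - 0.0
E:
- 0.14285714285714285
- 0.14285714285714285
- 0.14285714285714285
- 0.14285714285714285
- 0.14285714285714285
- 0.14285714285714285
- 0.14285714285714285
U:
- - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
- - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
- - 2
  - 2
  - 2
  - 3
  - 3
  - 3
  - 0
- - 2
  - 1
  - 0
  - 3
  - 1
  - 0
  - 1
- - 2
  - 1
  - 0
  - 3
  - 1
  - 0
  - 0
actions:
- roam-scan
- orient
- fight-or-flight
- freeze
config:
  context: safe
  eps_sound: 0.1
  lesioned: true
  p_attract: 0.28
  p_evade: 0.9
  p_wander: 0.18
factors:
- levels:
  - none
  - cat-distal
  - dog-distal
  - cat-proximal
  - dog-proximal
  name: creatures
- levels:
  - moving
  - still
  name: motion
- levels:
  - moderate-low
  - high
  name: heart
horizon: 6
modalities:
- levels:
  - silence
  - soft-sound
  - loud-sound
  name: audition
- levels:
  - empty-horizon
  - dot-on-horizon
  - dog-shape
  - cat-shape
  - blur
  name: vision
- levels:
  - no-pressure-moving
  - no-pressure-still
  - pressure-moving
  - pressure-still
  name: proprio-baro
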