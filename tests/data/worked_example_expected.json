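{
 "components": [
  "c1",
  "c2",
  "c3"
 ],
 "effects": [
  "e1",
  "e2"
 ],
 "z": [
  [
   0.8,
   0.4
  ],
  [
   1.0,
   0.5
  ],
  [
   0.3,
   0.3
  ]
 ],
 "H": [
  0.9092748525610018,
  0.9808340377961402
 ],
 "omega": [
  0.8255913306713477,
  0.1744086693286513
 ],
 "adjusted": [
  [
   0.3302365322685391,
   0.034881733865730256
  ],
  [
   0.2476773992014043,
   0.026161300399297694
  ],
  [
   0.049535479840280866,
   0.010464520159719078
  ]
 ],
 "network_score": [
  0.7302365322685387,
  0.9127956653356734,
  0.2999999999999997
 ],
 "effect_score": [
  0.6274494113102242,
  0.07150755442474703
 ],
 "component_score": [
  0.36511826613426934,
  0.273838699600702,
  0.05999999999999994
 ],
 "content_ratio": [
  0.5,
  0.3,
  0.2
 ]
}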