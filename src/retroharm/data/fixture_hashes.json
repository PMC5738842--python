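{
  "SPEEDY.csv": "cbfb39ff6c24e6704656a7eb8db577b99b3dca7e29e95a4817b7aef39250be2d",
  "KISS.csv": "f3f360826bb54b796341bc9b2aa1ba31021cf8a57c98a5ae02d57632acf9317c",
  "Ballabeina.csv": "42638e267431d766c0bb7593558c55769dd3615640c1851aba651915ac085eeb",
  "dictionary.csv": "1c20a23df6cd1bcfd9b1231d45eba3cd239bec82e647732d63c3175673d73883"
}
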