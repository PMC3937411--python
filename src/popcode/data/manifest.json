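{
  "fixtures.json": "6debf4173a9a0ee609e71b80f0c3ed10ca78edb43bc7d36676253d2b29b62351"
}
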