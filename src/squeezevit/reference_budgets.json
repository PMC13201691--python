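{
  "_note": "Published parameter and MAC budgets of baseline architectures used only as read-only reference constants for reduction-percentage reporting; they are printed values, never recomputed here.",
  "params_millions": {
    "ResNet": 11.69,
    "DenseNet": 7.98,
    "SqueezeNet": 1.25,
    "MobileNet": 3.5,
    "ShuffleNet": 7.39,
    "MobileViT": 0.95
  },
  "macs_billions": {
    "ResNet": 1.81,
    "DenseNet": 2.83,
    "SqueezeNet": 0.83,
    "MobileNet": 0.3,
    "ShuffleNet": 0.58,
    "MobileViT": 0.2
  }
}
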