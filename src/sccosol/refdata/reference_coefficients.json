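{
  "model": "modified_arrhenius",
  "scale_note": "Coefficients are in natural units (mole-fraction output). The published table prints a1, a2, a3, a5, a6 in units of 1e-6 (value here = printed value x 1e-6); a4 is unscaled and carries MPa units.",
  "provenance": "published",
  "coefficients": {
    "sorafenib-tosylate": [1.4247605573e-06, -5.0052921e-08, -3.8582767436e-04, 45.3662839688, 0.0, 3.49064452e-07],
    "sunitinib-malate": [2.647256734e-07, -1.4200164959e-06, 1.35566373666e-03, 36.284064755, 0.0, -1.28796352e-05],
    "azathioprine": [9.468557792e-07, -1.63521099e-08, -2.66098396089e-04, 24.1069578946, 8.36900373e-06, -4.83860672e-06],
    "busulfan": [6.0280909168e-05, -1.6630567159e-05, -1.34460675047e-03, 78.2721455261, 7.67145899e-05, 0.0],
    "tamoxifen": [1.4411848954e-04, -4.2703480295e-05, -1.97401401538e-03, 99.6434546809, 4.105460792e-05, 6.14532671e-06],
    "letrozole": [8.7649418657e-06, -2.9569956441e-06, 4.9401407763e-06, 80.8669042062, 4.145085191e-06, -5.3838515e-07],
    "tamsulosin": [7.923204828e-07, 1.478689559e-07, -3.68263373717e-04, 35.1646118112, 0.0, 2.51134612e-06],
    "capecitabine": [4.8093681561e-05, -1.2750147899e-05, -2.03779351684e-03, 123.5222953031, 7.1813407e-06, -8.09385756e-06],
    "paclitaxel": [6.8347581e-09, 2.53752394e-08, -6.6152385278e-06, 14.6087222619, -2.28448049e-05, 1.73239309e-05],
    "5-fluorouracil": [5.186887168e-07, -1.340640969e-07, -1.3960950338e-06, 44.0728502801, -1.02690278e-05, 1.17076e-05],
    "thymidine": [2.122407854e-07, 9.4685158e-09, -7.03123673279e-05, 18.0254848942, -2.5133078e-06, 1.301138517e-05],
    "decitabine": [1.1768771002e-04, -1.0092201917e-05, -2.5295933253e-02, 74.7951605316, 4.83284747e-05, 0.0]
  }
}
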