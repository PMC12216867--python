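{
  "note": "Best-effort Joback group assignments. Acyclic polyols are structurally unambiguous; ring-sugar assignments are marked unverified because no assignment built from the packaged group table reproduces the published critical-volume values (e.g. glucopyranose gives V_c = 421.5, not 460). Downstream consumers should prefer the packaged descriptor table for ring sugars.",
  "molecules": [
    {"molecule": "Xylitol", "verified": true,
     "groups": [{"name": "-CH2-", "ring": false, "count": 2},
                {"name": ">CH-", "ring": false, "count": 3},
                {"name": "-OH", "ring": false, "count": 5}]},
    {"molecule": "Sorbitol", "verified": true,
     "groups": [{"name": "-CH2-", "ring": false, "count": 2},
                {"name": ">CH-", "ring": false, "count": 4},
                {"name": "-OH", "ring": false, "count": 6}]},
    {"molecule": "Mannitol", "verified": true,
     "groups": [{"name": "-CH2-", "ring": false, "count": 2},
                {"name": ">CH-", "ring": false, "count": 4},
                {"name": "-OH", "ring": false, "count": 6}]},
    {"molecule": "Maltitol", "verified": false,
     "groups": [{"name": "-CH2-", "ring": false, "count": 3},
                {"name": ">CH-", "ring": false, "count": 5},
                {"name": ">CH-", "ring": true, "count": 5},
                {"name": "-CH2-", "ring": true, "count": 1},
                {"name": "-O-", "ring": false, "count": 2},
                {"name": "-OH", "ring": false, "count": 9}]},
    {"molecule": "Glucose", "verified": false,
     "groups": [{"name": ">CH-", "ring": true, "count": 5},
                {"name": "-CH2-", "ring": false, "count": 1},
                {"name": "-O-", "ring": false, "count": 1},
                {"name": "-OH", "ring": false, "count": 5}]},
    {"molecule": "Xylose", "verified": false,
     "groups": [{"name": ">CH-", "ring": true, "count": 4},
                {"name": "-CH2-", "ring": true, "count": 1},
                {"name": "-O-", "ring": false, "count": 1},
                {"name": "-OH", "ring": false, "count": 4}]}
  ]
}
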