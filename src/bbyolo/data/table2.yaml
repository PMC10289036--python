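# Default anchor priors (input-image pixels) for the four detection scales.
# Feature-map grids at 608x608 input: 152x152, 76x76, 38x38, 19x19
# (strides 4, 8, 16, 32).  One 12-anchor set per ripeness class, three
# anchors per scale, as obtained by IoU-distance k-means++ on the labelled
# berry boxes.
grids: [152, 76, 38, 19]
anchors:
  ripe:
    - [[13, 39], [13, 44], [46, 9]]      # 152 x 152
    - [[35, 53], [41, 60], [65, 46]]     # 76 x 76
    - [[120, 19], [181, 39], [54, 157]]  # 38 x 38
    - [[276, 56], [272, 104], [399, 82]] # 19 x 19
  semi-ripe:
    - [[11, 33], [17, 32], [40, 13]]
    - [[38, 51], [42, 55], [73, 45]]
    - [[125, 34], [167, 45], [67, 134]]
    - [[265, 53], [261, 113], [387, 113]]
  unripe:
    - [[15, 24], [22, 29], [29, 15]]
    - [[41, 49], [52, 60], [75, 46]]
    - [[132, 25], [155, 51], [87, 123]]
    - [[259, 67], [249, 153], [369, 134]]
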