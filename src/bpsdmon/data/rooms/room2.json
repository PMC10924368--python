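{
  "name": "room2",
  "boundary": [[0, 0], [6, 0], [6, 5], [0, 5]],
  "furniture": [
    {"name": "cabinet", "rect": [0.1, 1.8, 0.6, 3.2]},
    {"name": "table", "rect": [2.2, 1.9, 3.4, 2.8]},
    {"name": "shelf", "rect": [4.5, 1.6, 4.9, 2.1]},
    {"name": "sofa", "rect": [1.4, 4.4, 3.2, 4.9]}
  ],
  "places": {"dining": [0.9, 1.0], "living": [5.3, 1.0], "bedroom": [5.5, 4.3]},
  "roadmap": [[0.9, 3.2], [0.9, 1.0], [3.0, 0.8], [5.3, 1.0], [5.55, 2.6], [5.5, 4.3]],
  "follow_bounds": [1.3, 1.8],
  "wandering": {
    "mode": "pacing",
    "rect_centers": [[2.0, 3.8], [5.2, 3.8]]
  },
  "wandering_route": [[2.0, 3.8], [5.2, 3.8]]
}
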