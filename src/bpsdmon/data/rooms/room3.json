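{
  "name": "room3",
  "boundary": [[0, 0], [10, 0], [10, 8], [0, 8]],
  "furniture": [
    {"name": "dining_table", "rect": [2.8, 0.5, 4.0, 1.2]},
    {"name": "side_table", "rect": [2.0, 4.6, 3.0, 5.4]},
    {"name": "tv_bench", "rect": [9.4, 1.5, 9.9, 2.8]},
    {"name": "central_table", "rect": [4.4, 4.2, 5.8, 5.2]},
    {"name": "chair", "rect": [5.8, 0.5, 6.4, 1.1]},
    {"name": "bookcase", "rect": [6.4, 2.6, 7.0, 3.2]},
    {"name": "plant", "rect": [7.9, 2.6, 8.35, 3.1]}
  ],
  "places": {"dining": [2.0, 2.2], "living": [8.5, 2.0], "bedroom": [8.5, 6.6]},
  "roadmap": [[1.4, 5.6], [2.0, 2.2], [5.0, 1.6], [8.5, 2.0], [8.6, 4.2], [8.5, 6.6]],
  "follow_bounds": [1.3, 2.1],
  "wandering": {
    "mode": "pacing",
    "rect_centers": [[3.2, 6.8], [7.0, 6.8]]
  },
  "wandering_route": [[3.2, 6.8], [7.0, 6.8]]
}
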