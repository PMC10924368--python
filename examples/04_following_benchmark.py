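"""Compare the three person-following controllers in one room.

The target walks the dining -> living -> bedroom roadmap at ten speeds;
for each controller we report the power consumption rate (robot distance
over target distance — smaller is cheaper), the walking-speed detection
error, and lost/collision counts.  The band follower (2) and the fuzzy
adaptive follower (3) are more economical than constant following (1).
"""

from bpsdmon import FuzzyConfig, fuzzy_desired_distance, run_following_benchmark

cfg = FuzzyConfig(dist_min=1.3, dist_max=2.1)
print("Fuzzy desired distance (room1 band 1.3-2.1 m):")
for speed, dev in [(0.0, 0.0), (0.65, 0.25), (1.3, 0.5)]:
    d = fuzzy_desired_distance(speed, dev, cfg)
    print(f"  speed {speed:4.2f} m/s, deviation {dev:4.2f} -> follow at {d:.2f} m")

print("\nroom1 benchmark (10 target speeds each):")
for alg in (1, 2, 3):
    m = run_following_benchmark("room1", alg)
    print(f"  algorithm {alg}: power rate {m.power_rate:.2f}, "
          f"speed MAE {m.mae:.3f} m/s, lost {m.lost_times}, "
          f"collisions {m.collision_times}")
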