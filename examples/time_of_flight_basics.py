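"""Time-of-flight arithmetic of the reflection fixture.

The transducer focus sits at known one-way distances from the four vertical
sample boundaries. A shear wave launched at the focus reflects off each wall
and returns; dividing each two-way path by its arrival time gives four
per-boundary speeds whose mean is the sample's shear-wave speed (SWS).
"""

from swetof import FixtureGeometry, compute_sws, predict_arrival_times, two_way_paths

geometry = FixtureGeometry()  # 3.0, 6.2, 9.2, 12.0 mm one-way

print("one-way distances [mm]:", geometry.one_way_distances)
print("two-way paths     [mm]:", two_way_paths(geometry))

# In a 1.0 m/s medium (a mid-range hydrogel) the reflections arrive at:
times = predict_arrival_times(geometry, sws=1.0)
print("predicted arrivals at 1.0 m/s [ms]:", times)

# Inverting measured arrival times reproduces the speed; a perturbed first
# arrival changes only the first per-path speed, and the mean averages the
# error down -- the reason the method reads four boundaries, not one.
est = compute_sws(geometry, (5.0, 12.4, 18.4, 24.0))
print("per-path speeds [m/s]:", tuple(round(s, 3) for s in est.per_path_speeds))
print(f"mean SWS {est.mean_sws:.3f} m/s, variance {est.speed_variance:.4f} (m/s)^2")
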