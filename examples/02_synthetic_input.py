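"""The synthetic population-coded tactile stream.

Generates one minute of frames: 0-2 contacts per frame (two-finger
contacts 180 degrees apart), circularity-scaled Gaussian bumps over the
periodic orientation dimension, ~3.33 frames per second.  Prints summary
statistics of the stream and shows one frame in ASCII.
"""

import numpy as np

from dnfip import FieldGrid, InputScenario, generate_series

grid = FieldGrid(n_sites=100)
scenario = InputScenario(duration=60.0, seed=4)
series = generate_series(scenario, grid)

print(f"frames: {series.n_frames}  (frame every {series.frame_dt:.3f} s)")
print(f"amplitude range: [{series.frames.min():.2f}, {series.frames.max():.2f}] "
      f"(amplitude_scale = {scenario.amplitude_scale})")
active = np.mean(series.frames.max(axis=1) > 0.1)
print(f"fraction of frames with a contact: {active:.2f}")

k = int(np.argmax(series.frames.max(axis=1)))
frame = series.frames[k]
print(f"\nstrongest frame (#{k}, t = {k * series.frame_dt:.1f} s), "
      "one character per 2 sites:")
levels = " .:-=+*#%@"
row = "".join(levels[int(v / 6.001 * 9)] for v in frame[::2])
print("  |" + row + "|")
print("   0        90       180       270      360   orientation [deg]")
print("\nTwo bumps 180 deg apart are a two-finger contact; bump height is")
print("the contact circularity scaled to activation units.")
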