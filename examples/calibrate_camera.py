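"""Calibrate a ground-plane homography from four surveyed key points.

An operator measures the real-world positions (meters) of four landmarks on
the ground and reads off their pixel coordinates in a camera frame; the
normalized DLT then gives the world->image map, whose inverse performs the
bird's-eye-view recovery for every detected pedestrian.
"""

import numpy as np

from sdmon import estimate_homography, image_to_world, world_to_image

# four surveyed landmarks: a 20 m x 20 m square on the ground, and where
# its corners appear in a 1920x1080 oblique camera view
world = [(0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0)]
image = [(360.0, 1000.0), (1560.0, 1000.0), (1250.0, 330.0), (670.0, 330.0)]

h = estimate_homography(world, image)
print("estimated world->image homography M:")
print(np.array_str(h.m, precision=4, suppress_small=True))

pixel = (960.0, 700.0)
ground = image_to_world(h, pixel)
back = world_to_image(h, ground)
print(f"\npixel {pixel} -> ground ({ground[0]:.2f} m, {ground[1]:.2f} m)")
print(f"re-projected -> ({back[0]:.1f}, {back[1]:.1f}) px (round trip)")
# The ground coordinates are metric: distances between two mapped pixels
# are real distances in meters, which is what violation detection needs.
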