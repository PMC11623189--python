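"""Fit the feed-surface boundary curve from marked highest-feed points.

Thirteen points are marked along the top of the feed pile in the image
(y grows downward); a least-squares polynomial through them separates a
mouth that is touching the feed (at/below the curve) from one hovering
above it inside the trough rail.
"""

import numpy as np

from feedtrack import FeedPoint, TroughRegion, classify_zone, fit_boundary

# 13 marked points on a gently curved feed surface, plus marking noise
rng = np.random.default_rng(0)
x = np.linspace(100, 1820, 13)
y = 800 + 40 * ((x - 960) / 860) ** 2 + rng.normal(0, 2, size=13)
points = [FeedPoint(float(a), float(b)) for a, b in zip(x, y)]

curve = fit_boundary(points, degree=3)
print("fitted coefficients (highest degree first):", np.round(curve.coefficients, 6))
print(f"residual sum of squares: {curve.rss:.2f} px^2 over {len(points)} points")

trough = TroughRegion([(100, 650), (1820, 650), (1820, 1000), (100, 1000)])
for pt in [(960, 500), (960, 780), (960, 820)]:
    print(f"point {pt}: {classify_zone(pt, curve, trough).value}")
# OUTSIDE = not in the trough rail; PICKING_ZONE = head in the rail but
# above the feed; FEEDING_ZONE = mouth at/below the fitted feed surface.
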