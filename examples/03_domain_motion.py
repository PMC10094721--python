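"""Two-domain opening metrics: center distance and principal-axis angle.

Builds rod-like domain clouds at the closed- and open-state geometries
(42.3 A / 38.2 deg and 47.2 A / 58.8 deg), adds 0.1 A coordinate noise, and
recovers both metrics with the gyration-tensor analysis - the same numbers
that track the pendulum-like opening of the PLAT domain away from the
catalytic domain.
"""

import numpy as np

from loxtraj import synthetic as syn
from loxtraj.core import Frame
from loxtraj.geometry import geometric_center_distance, principal_axis_angle

rng = np.random.default_rng(3)
for state, (dist, angle) in {"closed": (42.3, 38.2), "open": (47.2, 58.8)}.items():
    geom = syn.DomainGeometry(center_distance=dist, axis_angle=angle,
                              points_per_domain=500, aspect_ratio=10.0)
    dom = syn.build_two_domain_cloud(geom, seed=11)
    noisy = Frame(coords=dom.coords + rng.normal(0, 0.1, dom.coords.shape))
    a, b = dom.info["domain_a"], dom.info["domain_b"]
    print(f"{state:6s}: built {dist:5.1f} A / {angle:4.1f} deg -> recovered "
          f"{geometric_center_distance(noisy, a, b):6.2f} A / "
          f"{principal_axis_angle(noisy, a, b):5.2f} deg")
print("Recovery within 0.5 A / 2 deg shows the metrics separate the two")
print("conformational states cleanly at realistic noise levels.")
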