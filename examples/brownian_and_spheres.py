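"""Off-lattice agents: Brownian point particles and sphere relaxation.

Point agents have no volume and diffuse freely; spherical agents carry a
radius and push apart until no pair overlaps.  Prints the mean squared
displacement of the random walkers (linear in time for Brownian motion)
and the worst remaining overlap in the relaxed colony.
"""

import math

from hybridgrid import AgentGrid, PointAgent, RandomSource, SphericalAgent, linear_spring

rng = RandomSource(1)

# --- Brownian point agents -------------------------------------------------
grid = AgentGrid(40, 40, PointAgent, latticeBound=False, wrapX=True, wrapY=True)
walkers = [grid.new_agent_pt(20.0, 20.0) for _ in range(300)]
disp = {a: [0.0, 0.0] for a in walkers}  # unwrapped displacement
sigma = 0.25
for step in range(200):
    for a in walkers:
        dx, dy = rng.gaussian(0, sigma), rng.gaussian(0, sigma)
        disp[a][0] += dx
        disp[a][1] += dy
        a.move_pt((a.x + dx) % 40, (a.y + dy) % 40)
msd = sum(dx * dx + dy * dy for dx, dy in disp.values()) / len(walkers)
print(f"Brownian walkers: MSD after 200 steps = {msd:.2f} "
      f"(expected 2*sigma^2*steps = {2 * sigma**2 * 200:.2f})")

# --- Spherical agents relaxing to contact ----------------------------------
colony = AgentGrid(20, 20, SphericalAgent, latticeBound=False, rng=rng)
spheres = []
for _ in range(40):
    a = colony.new_agent_pt(9 + 2 * rng.next_double(), 9 + 2 * rng.next_double())
    a.radius = 0.5
    spheres.append(a)
law = linear_spring(0.4)
for _ in range(600):
    for a in spheres:
        a.sum_forces(2.0, law)
    for a in spheres:
        a.integrate_motion(0.5)
worst = max(a.radius + b.radius - math.hypot(a.x - b.x, a.y - b.y)
            for i, a in enumerate(spheres) for b in spheres[i + 1:])
print(f"Sphere colony: worst residual overlap after relaxation = {worst:.4f} "
      "(<= 0 means every pair is at or beyond contact)")
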