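"""Stochastic population-lattice tumor with rare driver mutations.

Four coupled population fields share a 100x100 lattice: wild-type cells
and the three mutant combinations (A, B, AB).  Each step, in order:
deaths, divisions capped by the per-position carrying capacity of
100,000 cells, mutation shifts (probability 2e-6 per division for each
driver), then nearest-neighbor migration.  Mutants divide faster, so a
successful mutant clone expands as a growing sector.

Prints the total population per genotype over time; rare-event dynamics
differ run to run (change the seed to see different mutation histories).
"""

import numpy as np

from hybridgrid import PopulationField, RandomSource, von_neumann_hood

SIZE, CAP = 100, 100_000
DEATH, MIGRATE = 0.05, 0.05
DIV = {"wt": 0.10, "A": 0.13, "B": 0.13, "AB": 0.17}
MUT = 2e-6

rng = RandomSource(7)
fields = {g: PopulationField(SIZE, SIZE) for g in DIV}
fields["wt"].set_pop((SIZE // 2) * SIZE + SIZE // 2, 1000)
hood = von_neumann_hood(False)

for step in range(300):
    divisions = {}
    for g, f in fields.items():
        c = f.counts
        deaths = rng.binomial_array(c, DEATH)
        births = rng.binomial_array(c, DIV[g])
        # divisions stop at the local carrying capacity
        total = sum(fl.counts for fl in fields.values())
        room = np.maximum(CAP - total, 0)
        births = np.minimum(births, room)
        f._d += births - deaths
        divisions[g] = births
    for f in fields.values():
        f.update()
    # mutation shifts: a vanishing fraction of this step's divisions
    for src, dst, in (("wt", "A"), ("wt", "B"), ("A", "AB"), ("B", "AB")):
        movers = rng.binomial_array(np.minimum(divisions[src], fields[src].counts), MUT)
        fields[src]._d -= movers
        fields[dst]._d += movers
    for f in fields.values():
        f.update()
        f.distribute_all(hood, [MIGRATE / 4] * 4, rng)
        f.update()
    if step % 50 == 0 or step == 299:
        totals = {g: f.total() for g, f in fields.items()}
        print(f"step {step:3d}: " + "  ".join(f"{g}={n:,}" for g, n in totals.items()))

print("Mutant clones (A, B) arise stochastically once the dividing "
      "population is large enough that 2e-6 per division becomes likely.")
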