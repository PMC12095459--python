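# polariscape

Boolean-network attractors, Waddington epigenetic landscapes, and
noise-induced macrophage polarization dynamics.

## The problem

Tumor-associated macrophages are strikingly plastic: the molecular signals
of the tumor microenvironment (TME) push them between anti-tumoral (M1)
and tumor-supportive (M2a–M2d and hybrid) phenotypes.  `polariscape`
implements a three-stage model of this process for systems biologists:

1. **Boolean regulatory network** — phenotypes are the attractors of a
   synchronous logical network over transcription factors and external
   signals; basin-of-attraction sizes measure phenotype stability, and
   clamping nodes ON/OFF (overexpression/knockout) produces
   perturbation-scan tables.
2. **Epigenetic landscape** — attractors are embedded in the plane
   (t-SNE) and aggregated into the potential

   F(u, v) = min_i  a_i [ (u − u_i)² + (v − v_i)² ],

   one well per phenotype with steepness `a_i` derived from its basin
   size.  The induced partition of the plane is a multiplicatively
   weighted Voronoi diagram; the lowest point of each boundary is the
   *mountain pass* between two phenotypes.
3. **Stochastic dynamics** — the epigenetic state follows the
   reaction–diffusion system dx = (Ax + a(x))dt + dW on a 1-D spatial
   domain, with diffusion A, drift a(x) = −∇F̃ (F̃ the mollified
   potential) and additive Wiener noise of magnitude σ per component
   (white or colored); a 0-D reduction d(u,v) = −∇F̃ dt + σ dW serves for
   fast ensemble studies.  Basin-to-basin transitions of this process are
   *noise-induced polarization* events; their first-passage times grow
   like exp(2ΔF/σ²) with the pass height ΔF as σ shrinks.

Everything is testable offline: a fixtures module generates toy Boolean
networks with hand-verifiable attractors and a synthetic 13-phenotype
reference landscape (5 spatial clusters, one anti-tumoral) emulating the
topology of the macrophage system.  See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import polariscape as ps
from polariscape.mollify import MollifiedLandscape, MollifierConfig

# 1. Boolean stage: a toy network with known attractors
net = ps.make_toy_network("pair-reporter")      # A<->B, C = NOT A
for a in ps.find_attractors(net):
    print(a.states, a.basin_size)
# ((0, 1, 0), (1, 0, 1)) 4        <- 2-cycle, basin 4 of 8 states
# ((0, 0, 1),) 2
# ((1, 1, 0),) 2

# 2. Landscape stage: the packaged 13-phenotype reference landscape
ls = ps.make_reference_landscape()
print(ls.n)                                      # 13
assign = ps.cluster_centers(ls)
print(ps.cluster_composition(ls, assign)[0])     # ('M1', 'M1M2d')

# 3. Stochastic stage: polarization of an M1 macrophage under TME noise
moll = MollifiedLandscape(ls, MollifierConfig(radius=0.05))
cfg = ps.SDEConfig(sigma=0.27, dt=0.01, t_end=600.0, x0="M1", seed=1)
traj = ps.simulate_sde(ls, moll, cfg)
events = ps.detect_transitions(ps.occupancy(traj, ls))
print(ps.polarization_sequence(events, start="M1")[:4])
# ['M1', 'M1M2d', 'M1', 'M1M2d']   <- flickers over the lowest pass first
```

The first printed block is the exact attractor enumeration (basins 4/2/2
partitioning the 8 states); the landscape block confirms the 13 phenotype
wells and that the anti-tumoral cluster is exactly {M1, M1M2d}; the last
line is one replicate's polarization itinerary, which at σ = 0.27 starts
with the M1 → M1M2d hop through the lowest mountain pass and, over the
full horizon, typically wanders on into the pro-tumoral M2aM2d valley.

A command-line interface mirrors the library:

```bash
polariscape fixtures --reference-landscape --out ref.json
polariscape simulate --landscape ref.json --sigma 0.27 --start M1 \
    --t 600 --eps 0.05 --seed 1 --out traj.csv
polariscape analyze --traj traj.csv --landscape ref.json --out-prefix run1
polariscape exits --landscape ref.json --start M1 \
    --sigmas 0.05,0.1,0.15,0.2 --reps 200 --t 150 --seed 1 --out exits.csv
```

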