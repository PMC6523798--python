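# lassokit

Statistical mechanics of **lasso-shaped polymers**: a closed loop with
one or two linear tails attached at a bridge vertex — the polymer
counterpart of complex lasso proteins, whose backbone loop is closed by
a disulfide bridge and pierced by a terminal tail.

The package answers two questions and connects them to proteins:

1. **How likely is a lasso to be threaded?** Phantom (ideal) lassos are
   sampled uniformly — equilateral polygon loops (action-angle
   diagonal/dihedral construction) with random-walk tails — and
   classified by the *minimal surface method*: a near-minimal
   triangulated disk is spanned on the loop and transversal tail
   crossings are counted with signs. The trivial-lasso probability
   P(N, t; L0) decays towards a **non-zero asymptote** P∞ — even an
   infinite lasso can stay unthreaded — following
   `P = P∞ + c_α exp(−α·x) + c_β exp(−β·x)` in each length, and the
   piercing spectrum is summarised by the domination number
   `d(N, t) = max p : P(n ≥ p | n > 0) > 1/2`.
2. **What does threading do to the loop?** A Metropolis Monte Carlo
   bead-spring ring (harmonic bonds k = 20000 kJ/mol/nm², r0 = 0.38 nm;
   repulsive A/r¹² excluded volume) threaded by an infinite periodic
   thread of thickness factor w measures Rg, distension
   D = (2Rg/r0)·sin(π/N), and the gyration-ellipsoid asphericity A and
   prolateness P, with scaling fits `⟨Rg⟩ = c_r + a_r N^ν`,
   `⟨A⟩ = A∞ + a_A N^μ`, `⟨P⟩ = P∞ + a_P N^−0.47`. Threading flattens
   and slightly inflates the loop (higher D and A at fixed N).
3. **Protein bridge.** PDB chains are reduced to Cα traces, disulfide
   loops and tails are extracted, classified with the same surface
   method, and compared against the fitted polymer expectation;
   observed-threaded loops with model threading probability < 0.2 are
   flagged as candidate functional lassos.

## Worked example

```python
import numpy as np
from lassokit import (sample_equilateral_polygon, build_lasso,
                      classify_lasso, SimConfig, run_simulation,
                      shape_record)

rng = np.random.default_rng(7)
loop = sample_equilateral_polygon(100, rng)      # unit-edge 100-gon
lasso = build_lasso(loop, [100], rng)            # one 100-step tail
label, record = classify_lasso(lasso)
print(label.label, record.totals)

traj = run_simulation(SimConfig(n=50, w=0, temperature=100.0, seed=7,
                                target_frames=200))
rec = shape_record(traj.frames[-1], r0=0.38)
print(round(rec.rg, 3), round(rec.asphericity, 3))
```

prints (seed 7):

```
L0 [0]
1.443 0.079
```

— this particular phantom lasso happens to be trivial (class L0, zero
piercings of the loop's spanning surface; at N = t = 100 roughly a third
of phantom lassos are), and the last recorded frame of the 50-bead
excluded-volume ring has Rg ≈ 1.44 nm with instantaneous asphericity
0.079, close to the ensemble mean (≈ 0.085 at this size).

The numbered drivers under `analysis/` run the full study at desk
scale and write tables under `results/`:

```bash
python analysis/01_phantom_ensemble.py      # sample + classify phantom lassos
python analysis/02_threading_statistics.py  # decay fits, domination numbers
python analysis/03_loop_simulations.py      # MC sweeps, free and threaded
python analysis/04_shape_scaling.py         # nu, A_inf, P_inf, prefactor ratios
python analysis/05_protein_comparison.py    # protein stage on synthetic PDBs
```

A thin CLI mirrors the library (`lassokit sample|classify|stats|
simulate|shapes|proteins|reproduce`).

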