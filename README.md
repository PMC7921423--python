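# condensates

Simulation and quantification tools for crowding-driven protein
condensation, built around the biology of ASK3: a stress kinase that
demixes into liquid-like condensates within seconds of hyperosmotic cell
shrinkage and redisperses when cell volume recovers. The package is for
computational cell biologists who want to (a) reproduce and extend the
lattice model that explains why macromolecular crowding is the driving
force of this condensation, and (b) run the same quantification pipelines
— FRAP rates from particle tracks, condensate counts/amounts from images
— on their own or on synthetic data.

## What's inside

* **`condensates.lattice`** — a rejection kinetic Monte Carlo (rKMC)
  simulator: ASK3 units and slow obstacles (integrated crowder
  macromolecules) diffuse on a bounded 2D grid with single occupancy.
  A move is accepted iff its rate `k` exceeds a uniform draw `r`;
  free ASK3 diffusion has `k1 = 1`, obstacle diffusion `k5 = 0.01`, and a
  move breaking `n_lost` ASK3–ASK3 contacts is accepted with
  `k3 = A·exp(−n_lost·ΔE/θ)` (defaults `A = 1`, `ΔE/θ = 1`).
* **`condensates.clusters`** — condensate proxies: 4-connected components
  of ≥ 6 ASK3 units; count / mean size / mean ± SEM across replicates.
* **`condensates.experiments`** — the shrink sweep (fixed molecules,
  shrinking grid = osmotic shrinkage), the expansion reversal
  (55×55 → 120×120 = volume recovery) and the no-obstacle control, with
  full-scale and desk-scale presets.
* **`condensates.frap`** — FRAP rate [%] for fast-moving condensates from
  spot-tracker tables: track filtering, bleached/reference grouping,
  `F_i(t)/F_i,Before` normalisation, false-positive removal, quench
  correction `G_i(t)`, and
  `FRAP rate(t) = (G(t) − G_Min)/(1 − G_Min) × 100`.
* **`condensates.imaging`** — per-cell condensate count/size inside a
  mask (Gaussian filter → local threshold → particle analysis) and the in
  vitro condensate amount (mean total particle intensity over five
  fields, internal-standard normalised).
* **`condensates.synth`** — seed-deterministic generators with ground
  truth: FRAP track tables (bleach depth, mobile fraction, recovery τ,
  acquisition quench), planted-spot images, hand-built lattice states.

See `docs/methods.md` for the model, its assumptions and all defaults.

## Worked example

`examples/shrink_sweep.py` (6 replicates, 5×10⁶ steps, 500 ASK3 units +
1500 obstacles per grid) prints:

```
 width  height  mean_count  sem_count  mean_size  sem_size  n_replicates
    45      45       12.33       0.71       8.08      0.24             6
    48      48       22.17       1.30       8.44      0.24             6
    55      55       17.50       0.92       8.59      0.22             6
    70      70        9.50       0.76       7.36      0.15             6
    90      90        2.17       0.54       5.25      1.05             6
   120     120        0.00       0.00       0.00      0.00             6
```

Reading it: at the roomy 120×120 grid (a relaxed cell) no cluster of ≥ 6
units exists; shrinking the grid raises both the number and the size of
clusters — condensation by crowding — but at the near-jammed 45×45 grid
mean size falls again (8.08 < 8.44–8.59) while clusters remain numerous:
excessive crowding fragments free space and arrests cluster growth. The
other scripts in `examples/` demonstrate the expansion reversal (count
decays from ~17.5 to ~6 after the grid is restored, with a transient
size overshoot), the FRAP pipeline recovering a planted 50% mobile
fraction (`plateau FRAP rate: 50.0%`), and exact planted-spot counting.

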