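# pacpipe

Phase–amplitude coupling (PAC) analysis for developmental scalp EEG.

During the first years of life, the phase of slower cortical rhythms
(alpha–beta, 2–20 Hz) begins to modulate the amplitude of gamma-band
activity (40–100 Hz). `pacpipe` implements the complete analysis chain used
to quantify this coupling in infant/toddler resting EEG and to ask how it
changes with age:

1. **Segmentation & QC** — 2-s windows, joint-probability artifact
   rejection (3 SD rule along two dimensions), random selection of exactly
   30 windows (60 s of data) per recording.
2. **Filter bank** — zero-phase complex FIR filters (Blackman-windowed
   cosine/sine carriers): low-frequency centers 2–20 Hz (2-Hz bandwidth),
   high-frequency centers 40–100 Hz (20-Hz bandwidth); frequency pairs with
   overlapping magnitude responses are excluded.
3. **Modulation index** — high-frequency amplitude binned into 18 × 20°
   bins of low-frequency phase, averaged over the 30 segments, and scored
   by the Kullback–Leibler modulation index

   MI = (log N − H(P)) / log N,  N = 18,

   where P is the normalized binned amplitude distribution. 200 surrogate
   MI values from circular amplitude time-shifts (0.1–1.9 s, per segment)
   yield MI_norm, the z-score of MI against its surrogate null. *Phase max*
   is the phase bin holding the largest mean amplitude.
4. **PAC+ cluster inference** — per channel, a paired t-map of MI_raw vs
   the surrogate mean across recordings, thresholded at p < 0.05, grouped
   by 4-connectivity over the (LF, HF) grid, with cluster mass
   Σ(t − t_crit) assessed against a flip-half permutation null (MI_raw and
   surrogate mean swapped in a random half of recordings, 200 permutations,
   95th percentile retention).
5. **Age trends** — Pearson correlation of mean MI_norm in PAC+ cells with
   age; per-phase-bin correlations of phase-max proportions with age
   (Bonferroni, 18 tests); anterior/posterior regional splits and circular
   means of phase preference.

A first-class synthetic-data module generates coupled-oscillation signals
(LF carrier, amplitude-modulated HF carrier, pink 1/f noise) and whole
cohorts with regional phase preferences (anterior −110°, posterior +70°)
and age-increasing coupling depth, so every stage is testable end to end
without access to any infant dataset. See `docs/methods.md` for models,
parameters, and design choices.

## Worked example

```python
import pacpipe as pp

# a strongly coupled test signal: 8 Hz phase modulates 64 Hz amplitude,
# envelope peaking at +90 deg, pink noise background
params = pp.SimSignalParams(lf_hz=8, hf_hz=64, phase_pref_deg=90,
                            coupling_depth=0.8, duration_s=60, seed=42)
rec = pp.simulate_coupled_signal(params)

seg = pp.select_segments(pp.segment_recording(rec), 30, seed=0)
bank = pp.build_filterbank(lf_centers=[8.0], hf_centers=[64.0])
pac = pp.compute_pac_map(seg, bank, n_surr=200, seed=1)
cell = pac.cell("Cz", 8.0, 64.0)
print(f"MI_raw={cell.mi_raw:.4f}  MI_norm={cell.mi_norm:.1f}  "
      f"phase max={cell.phase_max_deg:+.0f} deg")
```

prints

```
MI_raw=0.0218  MI_norm=26.7  phase max=+90 deg
```

MI_raw is small in absolute terms (KL divergences of mildly non-uniform
18-bin distributions are), but it sits 26 surrogate standard deviations
above the time-shift null — decisive coupling — and the preferred phase is
recovered exactly at the simulated +90° bin.

The same chain runs from the shell:

```bash
pacpipe simulate-cohort --n-subjects 14 --out-dir cohort/
pacpipe pac --manifest cohort/manifest.tsv --seed 1 --out-dir results/
pacpipe validate-filters        # phase-preference integrity harness
```

`pacpipe pac` writes `pac_map.tsv`, `clusters.tsv`, `cluster_cells.tsv`,
`phase_trends.tsv`, `per_recording.tsv`, a rejection log, and a
`run_log.json` containing every seed needed to replay the run.

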