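# calmech

Analysis toolkit for experiments that grow neuronal–glial cultures on soft,
extracellular-matrix-mimicking hydrogel substrates and ask two questions at
once: *are the neurons functionally active*, and *how stiff is the substrate
they grew on?*

The package has two arms, mirroring the two measurement modalities:

**Functional Ca²⁺ imaging.** Spontaneously active somata are found in
fluorescence time-lapse stacks (e.g. OGB-AM-loaded cultures recorded at
30 Hz for 20 s) by a dual-threshold pixel criterion: a pixel is active when
its trace contains a peak rising above the pixel's time-averaged
fluorescence by more than 5% of that average **and** by more than 4× the
smallest temporal standard deviation over all pixels (the stack's noise
floor). Neighbouring active pixels are merged into cell-level ROIs
(bounding box < 20×20 px), traces are corrected for photobleaching by the
simple-ratio method — each frame rescaled by `b(0)/b(t)`, the ratio of
initial to current mean background intensity outside all ROIs — and each
neuron is quantified by

- event frequency `f = N_events / T` (Hz),
- relative amplitude `δF/F = (F_peak − F₀)/F₀` (%),
- decay constant τ from a non-linear least-squares fit of
  `F(t) = A·exp(−t/τ) + C` to each post-peak segment (fits whose mean
  squared relative error exceeds 0.05% are flagged and excluded),
- cross-neuron synchrony by windowed event coincidence (±0.1 s).

**Substrate mechanics.** AFM nanoindentation force curves (colloidal probe,
sphere radius R = 3.325 µm, cantilever k ≈ 4 N/m, 120 nN setpoint) are
fitted with the Hertz sphere-on-plane contact model

    F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2}

to yield the Young modulus E, aggregated hierarchically
(curves → locations → samples). Oscillatory-rheology sweeps are reduced to
the storage modulus G′ at 10 Hz and converted to a compressive (Young)
modulus via the incompressible-gel relation

    E = 2 G′ (1 + ν),   ν = 0.5.

Because raw recordings of this kind are rarely deposited, the package ships
a first-class synthetic-data generator (`calmech.simulate`) that renders
movies with known ground truth (Poisson event trains, instantaneous-rise /
exponential-decay transients, multiplicative bleaching, camera noise) and
Hertz force curves with known modulus, so the whole pipeline is testable
end to end.

## Worked example

```python
from calmech import SimConfig, generate_ground_truth, render_movie, storage_to_young
from calmech.metrics import analyze_movie

cfg = SimConfig(height=96, width=96, n_cells=5, soma_radius=4,
                event_rate=0.25, tau_true=1.4, amp_true=0.06,
                bleach_fraction=0.15, noise_sd=10.0, seed=42)
stack = render_movie(generate_ground_truth(cfg), cfg)
signals, summary = analyze_movie(stack, tau_guess=1.4)
for i, s in enumerate(signals):
    print(f"neuron {i}: {len(s.events)} events, f = {s.frequency:.2f} Hz, "
          f"dF/F = {s.mean_amplitude:.2f}%, tau = {s.tau:.2f} s")
print("E(G'=26.7 kPa) =", storage_to_young(26.7e3) / 1e3, "kPa")
```

prints

```
neuron 0: 7 events, f = 0.35 Hz, dF/F = 5.73%, tau = 1.35 s
neuron 1: 8 events, f = 0.40 Hz, dF/F = 5.62%, tau = 1.31 s
neuron 2: 3 events, f = 0.15 Hz, dF/F = 6.06%, tau = 1.41 s
neuron 3: 3 events, f = 0.15 Hz, dF/F = 5.96%, tau = 1.35 s
neuron 4: 6 events, f = 0.30 Hz, dF/F = 5.72%, tau = 1.39 s
E(G'=26.7 kPa) = 80.1 kPa
```

All five simulated neurons are recovered with no background false
positives; frequencies equal the true event counts over the 20 s recording,
amplitudes sit close to the simulated 6% δF/F, and the fitted decay
constants cluster around the simulated τ = 1.4 s. The modulus line converts
a measured storage modulus of 26.7 kPa into the compressive modulus of an
incompressible gel.

The same functionality is available from the shell:

```sh
calmech simulate movie --config cfg.yaml --out movie.tif --truth truth.json
calmech analyze --stack movie.tif --out metrics.csv
calmech mechanics eq1 --gprime 26700
calmech report --metrics a.csv --metrics b.csv --out comparison.json
```

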