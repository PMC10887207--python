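# pwvkit

Arterial Pulse Wave Velocity (PWV) estimation from pulse-pair signals
acquired at low sampling rates. The toolkit reconstructs low-rate
two-channel recordings to a high rate with bandlimited (rational polyphase /
windowed-sinc) resampling, estimates per-beat Pulse Transit Time (PTT) from
grid peak fiducials, converts it to PWV with a physiological validity
filter, and validates reconstruction fidelity with zero-normalized
cross-correlation (ZNCC), Blackman-windowed segment spectra and aliasing
diagnostics. A synthetic two-channel pulse generator with exactly known
ground truth (beat times, true inter-channel delay, band content) makes
every stage testable without any external data.

## Modules

| Module | Purpose |
| --- | --- |
| `pwvkit.synthwave` | Synthetic pulse-pair generator: quasi-periodic two-Gaussian beats, pure-delay distal channel, white noise, mains harmonics, baseline drift; fully seeded. |
| `pwvkit.dspcore` | `TimeSeries`, bandlimited resampling, zero-phase 10 Hz low-pass, derivative channels, segment spectra, ZNCC, Nyquist/aliasing checks. |
| `pwvkit.pwvcalc` | Peak detection, beat pairing, PTT→PWV, validity filter (keep 0 < v ≤ 20 m/s), heart rate, trial summaries, end-to-end `analyze_recording`. |
| `pwvkit.recordio` | Plain-text CSV recording dialect (`#key=value` headers + `time,prox,dist` rows, exact round trip) and JSON reports. |
| `pwvkit.cli` | `pwvkit` command with `synth`, `reconstruct`, `analyze`, `alias-demo`, `validate` subcommands. |

## CLI quick start

```sh
# 19 s synthetic recording at 250 Hz with a true delay of 8 ms
pwvkit synth --out rec.csv --fs 250 --duration 19 --ptt 0.008 --seed 1

# reconstruct both channels to 10 kHz
pwvkit reconstruct --in rec.csv --target-fs 10000 --out rec10k.csv

# full pipeline: reconstruct, filter, detect peaks, pair beats, summarize
pwvkit analyze --in rec.csv --reconstruct-to 10000 --out report.json

# aliasing diagnostics for mains-contaminated signals at 125 vs 250 Hz
pwvkit alias-demo --fs-list 125,250 --out alias.json

# reconstruction-fidelity ZNCC against a high-rate reference recording
pwvkit validate --in rec.csv --reference ref10k.csv
```

Exit codes: 0 success, 2 usage error, 3 data/validation error,
4 computation error. All commands are deterministic given their seeds.

## Recording file format

```
#pwvkit_recording=1
#fs=250.0
#distance=0.032
#start_time=0.0
#n_samples=4750
#channels=prox,dist
#provenance={...}
time,prox,dist
0.0,0.011237...,0.009871...
...
```

Floats use shortest round-trip precision, so write→read is bit exact; the
explicit time column lets the reader verify grid uniformity and the declared
sampling rate. All units are SI (seconds, Hz, meters).
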