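# rrmkit

A tested toolkit for Resonant Recognition Model (RRM) analysis of protein
and DNA sequences:

- **encoding** — render sequences as numerical series using bundled
  electron-ion interaction potential (EIIP) tables (swappable via CSV);
- **spectra** — amplitude/phase spectra of mean-removed, zero-padded
  series; multiplicative cross-spectra over functional groups;
  signal-to-noise peak calls; phase-opposition tests;
- **photomap** — conversions between dimensionless RRM frequencies
  (cycles/residue, 0–0.5), electromagnetic wavelengths via `lambda = K/f`
  (K = 201 nm) and physical frequencies via the charge-transport estimate;
  least-squares re-estimation of K from (frequency, wavelength) pairs;
- **catalog** — the bundled, checksummed table of 68 characteristic
  frequencies per biological function with super-family labels,
  nearest-match classification, band extraction and 0.01-wide frequency
  histograms;
- **light** — light-source spectral power distributions (Planck blackbody
  and Gaussian line synthesis, CSV reader), coverage reports of catalog
  bands and a water-transparency window filter;
- **simulate** — seeded synthetic sequence groups with known embedded
  frequencies so every spectral operation is testable offline, including
  quantization back onto residue alphabets for full-pipeline checks.

## CLI

The `rrm` command wires all modules together:

```sh
rrm simulate --f0 0.25 --seed 42 --out fixtures/      # synthetic FASTA + truth
rrm cross --fasta fixtures/fixture.fasta --min-snr 1 --out-dir out/
rrm encode --fasta seqs.fasta --scale eiip_protein
rrm map --frequency 0.25 --to nm                      # -> 804
rrm fit-k --pairs pairs.csv
rrm classify --frequency 0.300
rrm histogram --bin-width 0.01
rrm coverage --preset sunlike --threshold 0.01
rrm config                                            # show effective defaults
```

`rrm cross` runs the full group analysis: encode every FASTA record, write
per-sequence spectra, multiply them into a consensus spectrum, call the
top peak if its signal-to-noise clears `min_snr` (default 20), map the
called frequency to a wavelength and list nearby catalog records.
Defaults can be set in a YAML file (`--config`), with flags overriding
file values; unknown keys are rejected.

## Notes on bundled constants

The EIIP tables and the frequency catalog are data files under
`src/rrmkit/data/` with their provenance recorded in the loading code; the
catalog file is checksummed at load time.  Physical constants (K = 201 nm,
charge velocity 7.87e5 m/s, residue spacing 3.8 Å) live in a single
`PhysicalConstants` record and are configurable.  The two catalog rows
whose wavelength column reads "100 K"/"20 K" are preserved verbatim and
excluded from every numeric path.
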