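# p31lipid

Quantitative ³¹P NMR lipidomics toolkit: synthesize or read 1D ³¹P FIDs,
process them under quantitative conditions, deconvolve overlapping
resonances, assign peaks to phospholipid classes via a packaged
chemical-shift library, and report class abundances as mol% with
presence/reporting rules and sample-quality diagnostics.

## What's inside

| Module | Role |
| --- | --- |
| `p31lipid.shift_library` | ppm-interval → lipid-class map (packaged TSV), peak assignment with tolerance, tie-breaking and busy-region (0.45–0.60 ppm) ambiguity flags |
| `p31lipid.simulate` | synthetic FID generator: damped complex exponentials, two-phosphorus cardiolipin, mass-dependent S/N, concentration-dependent shift drift, PC→LPC ageing hydrolysis, adduct shift offsets |
| `p31lipid.process` | exponential apodization (1.5 Hz), zero filling (32,768 points), Fourier transform, auto/manual phasing, polynomial baseline, ppm calibration against PC at 0.00 |
| `p31lipid.deconvolve` | noise estimation, S/N-3 peak picking, joint bounded least-squares fitting of Lorentzian / Gaussian / pseudo-Voigt lineshapes with analytic areas |
| `p31lipid.quantify` | class assignment + aggregation, 0.01%-of-total and S/N-3 reporting filters, mol% on per-phosphorus or per-molecule basis |
| `p31lipid.qc` | LPC:PC hydrolysis index, minimum-mass extrapolation (log-log slope 1), adduct drift warnings, 4–16 mg guidance window |
| `p31lipid.io_cli` | Bruker 1D reader (acqus + fid), JSON FID/spectrum dumps, run config, `p31lipid` CLI |

## CLI

```sh
# full pipeline from a scenario config (composition, mass, age, adduct, seed)
p31lipid run-all --scenario src/p31lipid/data/demo_scenario.yaml --outdir out/

# or step by step
p31lipid simulate --scenario scenario.yaml --out fid.json --truth truth.csv
p31lipid process  --in fid.json --out spectrum.json --lb 1.5 --zf 32768
p31lipid fit      --in spectrum.json --out fits.json --shape pseudo_voigt
p31lipid report   --fits fits.json --out report.json --basis per_phosphorus
p31lipid qc       --report report_t0.json --report report_t1.json --out qc.json
```

`process` also accepts a Bruker 1D directory (`acqus` + `fid`) as `--in`.
Reports are written as CSV and JSON with columns
`lipid_class, center_ppm, area, mol_pct, snr, flags, basis, library_version`.

## Notes

* The default shift library is a versioned TSV under `src/p31lipid/data/`;
  pass your own with the same columns (`lipid_class`, `ppm_low`,
  `ppm_high`, `provenance`, `ambiguous`) via `--library`.
* The 0.95–1.15 ppm interval is labelled PG with PI recorded as an
  alternate — source captions disagree, and assignments in that interval
  carry the alternate label.
* `basis=per_molecule` divides cardiolipin's area by its two ³¹P nuclei
  before mol% computation; the default `per_phosphorus` reports what the
  spectrum actually measures.
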