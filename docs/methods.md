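# Methods

## The measurement model

A GC-Orbitrap isotope-ratio measurement of an amino-acid fragment reports,
per scan, centroided mass peaks (m/z, signal S, noise N) together with the
instrument state: injection time IT, total ion current TIC, resolution
setting R (defined at m/z 200), micro-scan count μ, and the AGC target.
The targeted species are the N-trifluoroacetyl amino-acid methyl ester
fragments formed by loss of the methoxycarbonyl radical under 70 eV electron
impact; each is measured in a 10 Da scan window containing the unsubstituted,
single-¹⁵N and single-¹³C isotopologues.

### Ion counting

FTMS intensity is proportional to ion number only after normalizing by the
noise band. The conversion implemented is

    N_io = (S/N) · (C_N / z) · (R_N / R)^a · μ^b

with defaults a = b = ½ (thermal noise integrates with the square root of
transient length, and averaging μ packets scales S/N by √μ). `C_N` is an
empirically determined instrument constant — the number of charges hidden in
the noise band at the reference resolution `R_N`; the defaults (4.4 charges
at R_N = 240 000) are typical for Q Exactive-class instruments and both are
configuration keys (`cn_charges`, `rn_reference_resolution`). All four
parameters live in `IonCountSettings`.

### Window selection

Only scans acquired under regulated AGC carry interpretable ratios. Two
filters, applied in order of precedence, mark scans for exclusion:

1. **`IT_at_ceiling`** — injection time ≥ the instrument maximum (200 ms
   default). At the ceiling AGC is no longer regulating.
2. **`TICxIT_out_of_band`** — TIC × IT outside median × (1 ± 0.20). TIC × IT
   is proportional to ion flux seen by the analyzer; under healthy AGC it is
   stable. The band is measured against the *median* of the ceiling-passing
   scans because the reference must be robust to the very anomalies being
   filtered; the paper-equivalent check states a 20% tolerance without a
   reference point.

A third, optional screen (**`ratio_unstable`**, off by default) flags scans
where the cumulative ¹⁵N/¹⁴N running ratio deviates from the final cumulative
ratio by more than 3× the shot-noise uncertainty of the counts accumulated so
far. It is off by default because the corresponding published check reads as
an analyst's inspection rather than a quantitative rule; the implementation
makes it reproducible when wanted.

The integration window is the longest contiguous run of unmarked scans
(earliest run on ties, for determinism). Every excluded scan carries exactly
one primary reason code, and an acquisition with no clean scan raises an
error signaling it should be discarded.

### Ratio, delta, and replicate statistics

Isotopologue peaks are located by nearest-match within 5 ppm (ties toward
higher signal); a scan with no detectable minor peak contributes zero minor
ions rather than being dropped — at ¹⁵R ≈ 0.0037 zero-observation scans are
informative. Ion counts are summed over the window and the ratio formed as
Σminor/Σmajor (*sum-then-divide*). This equals the major-count-weighted mean
of per-scan ratios and is the estimator whose variance attains the
counting-statistics floor; an unweighted mean of scan ratios is noisier and
biased at low counts.

Deltas use conventional permil notation vs. an interleaved working standard.
Two pairing schemes are provided: `pooled_standard` (default; each sample
replicate referenced to the mean ratio of all standards in the sequence) and
`bracketing` (nearest preceding + following standard). Pooled is the
lower-variance neutral choice; bracketing is offered for drifting
instruments. Replicate sets are summarized by mean, *sample* standard
deviation (n − 1; the reporting convention for n = 5 replicate SEs implies
the sample estimator), and SE = S/√n. A single replicate has its sd/se
flagged as undefined (`None`), never reported as zero.

### Air-scale transfer

δ values move from the in-house standard frame to the atmospheric-N₂ frame
through δ_s,Air = δ_s,std + δ_std,Air + δ_s,std·δ_std,Air/1000 — the exact
composition of two ratio transforms, not an approximation. EA-IRMS anchors
for the shipped working standards (glycine 1.32‰, L-alanine 43.22‰,
D-alanine −1.05‰, L-valine 62.0‰, D-valine 5.88‰, β-alanine −14.1‰, α-AIB
8.97‰) are built in and overridable from a config table.

### Shot noise

The precision floor on a replicate delta measurement is

    σ_δ² = 2×10⁶ · (1/N_M + 1/N_m)   [‰²]

where N_M and N_m are collected major/minor isotopologue ions. The factor 2
budgets *both* measurements entering a delta — the sample and the
intensity-matched standard each contribute Poisson variance — which is why
the package's Monte-Carlo checks draw paired sample/standard replicates.
`precision_budget` inverts the law in closed form (with N_M = N_m/R the
variance collapses to 2×10⁶(1+R)/N_m) to give the minor-ion count needed for
a target SE at n replicates.

## The simulator

`orbin.simulate` generates acquisitions the reduction pipeline can process
end to end, with exact bookkeeping of the truth:

- **Ion statistics.** True ¹⁵R = 0.0036765 × (1 + δ_Air/1000); the absolute
  Air ratio is needed only here, to give simulated standards Air-scale
  values — the pipeline itself never uses it. Major and minor counts per
  scan are independent Poisson draws (exact for thinned Poisson arrivals).
  A ¹³C peak (per-carbon abundance 0.011) decorates each scan so extraction
  must discriminate the 0.00632 Da doublet, but it is outside the analyte
  ion budget.
- **AGC.** IT = min(max_IT, AGC_target/((λ_analyte + λ_background)·z)).
  A constant background flux (default 1.25×10⁶ ions/s, giving ≈160 ms IT at
  zero analyte) represents the non-analyte ion population of the scan
  window; it feeds AGC and TIC but not the analyte peaks. It is essential to
  the model: with no background, any unsaturated analyte flux pins IT at the
  ceiling and the stability filter would discard every scan — matching the
  real reason low-concentration acquisitions still run below the IT maximum.
- **Flux normalization.** `total_analyte_ions` is the expected number of
  analyte ions *collected during injection times*; because AGC couples IT to
  flux, the flux scale is solved numerically (Brent) so the expectation
  matches the configured total times the flux fraction inside the
  acquisition. A flux requiring IT below the instrument quantum (0.03 ms) or
  a total exceeding AGC capacity is a configuration error.
- **Elution profiles.** Direct mode: Gaussian (default σ = 4 s in a 30 s
  acquisition — a 10–30 s GC peak). Trapped mode: exponential bleed from a
  sample loop (default time constant 2000 s over a 600 s acquisition, i.e. a
  near-constant release, which is what a diffusion-equilibrated loop
  produces); the long profile is what multiplies the usable scan count
  (1500 scans at the default 0.4 s period vs. 75 in direct mode).
- **Write-back.** Counts are inverted to intensities through the exact
  inverse of the ion-count relation with constant per-peak noise, plus
  Gaussian m/z jitter (default σ = 1 ppm, lock-mass-grade accuracy, which
  keeps 5 ppm-tolerance extraction losses negligible); TIC is the sum of
  peak signals plus the background's signal equivalent.

Run sequences interleave standards and samples (standards first; with
n_std = n_samp + 1 they bracket every sample), with per-acquisition
generators spawned deterministically from one master seed.

### What the simulator does not emulate

Space-charge and coalescence effects, chromatographic co-elution and
isotopic fractionation across the GC peak, detector nonlinearity, drift in
instrument sensitivity, and scan-to-scan noise correlations. Passing tests
therefore demonstrate the correctness of the *reduction chain* and its
statistical behavior under ideal counting conditions — not robustness to
these instrument pathologies, which the window filters can only partially
catch.

## Default problem sizes

Test and acceptance scenarios use trapped-peak acquisitions of 75–1500 scans
and collected totals between 10⁵ and 2.8×10⁸ ions per acquisition; the
accuracy study in `scripts/acceptance.py` runs 20 independent 5+5
sample/standard sequences at 1500 scans per acquisition (the instrument's
AGC target of 2×10⁵ charges per scan then yields ≈1.1×10⁶ minor ions per
acquisition). These sizes were chosen so each study sits firmly in its
intended counting regime while remaining quick to re-run on one CPU.

## Numerical and design notes

- Atomic masses are pinned in one table (¹²C = 12 exactly, ¹H = 1.00782503,
  ¹⁴N = 14.00307401, ¹⁶O = 15.99491462, ¹⁹F = 18.99840316, ³²S = 31.97207117,
  mₑ = 0.00054858 Da; Δ(¹⁵N−¹⁴N) = 0.99703489, Δ(¹³C−¹²C) = 1.00335484 Da)
  so exact-mass comparisons are reproducible. Cation masses subtract the
  electron mass — the published glycine and α-AIB values match only with
  that correction. Published minor-isotopologue exact masses deviate from
  values computed with these constants by up to ~3×10⁻⁴ Da (their printed
  ¹⁵N−base differences are not the isotope mass difference); the package
  stores published values as annotation and treats computed masses as
  authoritative.
- Fragment compositions are frozen in code as the loss of ·COOCH₃ from the
  N-TFA methyl ester (e.g. glycine → C₃H₃F₃NO⁺); they reproduce the
  published base-peak masses within 1.5×10⁻⁴ Da.
- Scan-table CSV dialect: one row per peak with scan metadata repeated
  (columns `scan_index, rt_s, mz, intensity, noise, it_ms, tic, resolution,
  micro_scans, agc_target`); noise is carried per peak, with a per-scan
  constant expressed by repetition. Round-trips are lossless to better than
  1e−9 relative.
- Window tie-breaks (earliest longest run) and the exclusion-reason
  precedence (ceiling > band > ratio screen) are fixed for determinism.
- `required_resolution` compares the ¹⁵N/¹³C doublet requirement against the
  resolution setting scaled from m/z 200 by (200/m)^½, the Orbitrap's
  resolution–mass dependence.

## Known limitations

- Single-substitution arithmetic only; no multi-substituted isotopologues or
  fine structure.
- Single-standard normalization per compound; no drift regression or
  multi-point calibration curves, and no scale-compression correction at
  high enrichment (anchors span roughly −14‰ to +62‰; extrapolation beyond
  is a relabeling, not a validated calibration).
- No vendor binary parsing; the CSV dialect is the ingestion contract, and
  mzML adapters would sit behind the same reader interface.
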