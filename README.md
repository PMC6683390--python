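# lumipanel

Analysis pipeline for glycoprotein-capture bead assays that detect platelet
(HPA) and HLA class I antibodies in a single well. Given MFI readouts of serum
samples reacted with a panel of HPA-genotyped platelet donors, the package:

1. derives per-bead positivity cutoffs from negative-control sera
   (mean + 3 SD, MFI ≥ cutoff is positive),
2. partitions donors into reactive / non-reactive per (sample, bead),
3. deconvolves antibody specificities: for each glycoprotein bead it
   enumerates the minimal sets of anti-HPA specificities whose antigen
   carriage pattern exactly explains the donor partition, ranks them
   (smallest set first, population-frequency priors break ties), and unions
   the top-ranked set of every bead — plus anti-HLA when the HLA-capture
   bead is reactive — into the sample's final call,
4. analyses doubling-dilution series (endpoint titer, censoring, IU/mL
   conversion against a reference standard's potency), and
5. simulates complete assay runs (log-normal signal, truncated-normal
   background, per-donor Bernoulli HLA reactivity) for end-to-end testing.

A clinical fixture — four genotyped donors, four beads, nine positive
samples, published cutoffs and both methods' calls — ships inside the
package and is the primary regression surface (`reproduce-paper`).

## CLI

```sh
lumipanel reproduce-paper                  # run the packaged clinical fixture,
                                           # diff against the published calls
lumipanel cutoffs  --mfi controls.csv --out cutoffs.csv
lumipanel call     --mfi run.csv --genotypes donors.csv \
                   --cutoffs cutoffs.csv --out-dir results/
lumipanel titer    --series dilutions.csv --cutoff 75.1 --potency 100
lumipanel simulate --out-dir sim/ --n-samples 50 --seed 7
lumipanel concordance --summary results/summary.csv --reference maipa.csv
```

Exit codes: 0 success, 2 schema/validation error, 3 (with `call --strict`)
when reactivity could not be explained by any candidate specificity set.

File formats are plain UTF-8 CSV (see module docstrings in
`lumipanel/io.py`); bead panels and priors are YAML. The default bead panel
maps GPIIb/IIIa → HPA-1/3/4, GPIbα/IX → HPA-2, GPIa/IIa → HPA-5, plus an
HLA-capture bead; a CD109 (HPA-15) bead is defined but disabled by default.

## Notes on interpretation

- Borderline reactivity (within 1.25× of the cutoff, configurable) is
  reported and flagged but never drives a call on its own.
- Specificities the donor panel cannot interrogate both ways (no carrier, or
  no non-carrier) are listed as structural limitations on every call.
- Ambiguities that carriage patterns cannot resolve (e.g. anti-HPA-1a vs
  anti-HPA-4a on an all-reactive, all-HPA-1aa/4aa panel) are resolved by
  explicit, auditable prior weights — all candidate sets and their ranks
  appear in the JSON report.
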