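# sexmarker

Discovery and in-silico validation of PCR-based sex markers for species
with an XY sex-chromosome system — built around the CAPS (Cleaved
Amplified Polymorphic Sequence) strategy used to sex-genotype
*Cannabis sativa* seedlings before flowering.

The package is for plant (and animal) geneticists who have male/female
transcript sets and expression data but no Y-chromosome assembly, and
who want a cheap gel-readable genotyping assay at the end: a single
common primer pair amplifying both the X and the Y copy of a gametolog,
plus a restriction enzyme whose site exists in only one allele. On a
gel, XX individuals show the intact amplicon while XY individuals add
the digestion fragments, so one reaction reads out both genotypes with
no separate autosomal control.

## Method

Five stages, each usable on its own or through the orchestrated
pipeline:

1. **k-mer sieve** — retain transcripts containing *k*-mers (default
   k = 16) present in *every* male sample and absent from *every* female
   sample: `S = ∩ᵢ Kᵐᵢ \ ∪ⱼ Kᶠⱼ`.
2. **Expression filters** — male-bias statistics
   (log2FC = log2((μₘ+1)/(μ_f+1)), Wilcoxon rank-sum p,
   Benjamini–Hochberg FDR; pass at log2FC ≥ 1, FDR ≤ 0.05) and a strict
   filter keeping transcripts with mean male TPM > 10 and TPM = 0 in
   all female samples.
3. **Gametolog pairing** — local-alignment search of each candidate
   against supplied X loci; unambiguous near-full-length hits are
   accepted, globally aligned and ranked by X/Y divergence.
4. **CAPS design** — scan the X/Y alignment for allele-differential
   restriction sites, find conserved flanking windows, emit common
   degenerate primers (polymorphic columns as minimal IUPAC codes,
   degeneracy ≤ 16, concrete 3' base) and allele-specific probes.
5. **In-silico assay** — IUPAC-aware PCR, complete restriction
   digestion, per-genotype band prediction (XX = X digest; XY = X ∪ Y
   digests), gel-tolerant genotype calls, and endpoint TaqMan
   allele-discrimination signals (VIC = X probe, FAM = Y probe).

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

The package ships a synthetic reconstruction of the *CsPDS5* sex-marker
locus (random backbones carrying the published primer/probe footprints
and the Y-specific EcoRI site; see `sexmarker/fixtures.py`) together
with the published degenerate genotyping oligos:

```python
from sexmarker import fixtures, insilico_pcr, digest, predict_genotype_bands, \
    call_genotype
from sexmarker.synth import ECO_RI

loci = fixtures.cspds5_genomic()
for allele in ("X", "Y"):
    (amp,) = insilico_pcr(loci[allele].seq, fixtures.CSPDS5_FWD_PRIMER,
                          fixtures.CSPDS5_REV_PRIMER)
    print(allele, "amplicon:", len(amp), "bp; digest:", digest(amp, ECO_RI).bands)
```

```
X amplicon: 419 bp; digest: (419,)
Y amplicon: 419 bp; digest: (157, 262)
```

The common primers amplify 419 bp from either allele; EcoRI splits only
the Y product into 157 + 262 bp. Predicted gel patterns and a call on a
noisy observed gel:

```python
(x_amp,) = insilico_pcr(loci["X"].seq, fixtures.CSPDS5_FWD_PRIMER, fixtures.CSPDS5_REV_PRIMER)
(y_amp,) = insilico_pcr(loci["Y"].seq, fixtures.CSPDS5_FWD_PRIMER, fixtures.CSPDS5_REV_PRIMER)
patterns = predict_genotype_bands(x_amp, y_amp, ECO_RI)
for g, p in patterns.items():
    print(g.value, "->", p.bands)
print(call_genotype([160, 258, 422], patterns, tolerance_bp=10).value)
```

```
XX -> (419,)
XY -> (157, 262, 419)
XY
```

A female (or monoecious, XX) sample shows the single 419 bp band; a
male (XY) sample shows three bands. The observed bands (160, 258, 422)
match the XY pattern within the 10 bp gel tolerance.

## Command line

```sh
sexmarker simulate --seed 42 --out demo/          # synthetic cohort + truth
sexmarker sieve --males m1.fa --females f1.fa --transcripts t.fa --out sieve.tsv
sexmarker filter --expr tpm.tsv --sexes sexes.tsv --out filtered.tsv
sexmarker pair --y candidates.fa --x xloci.fa --out pairs.tsv --aln-dir alns/
sexmarker design --aln gene.aln.fa --out candidates.json
sexmarker insilico --template sample.fa --candidate candidates.json --out bands.tsv
sexmarker run --config config.yaml --out results/  # all stages
```

`run` exits 0 when at least one validated candidate is found, 3 for no
candidates and 4 for input errors.

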